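"""Parser, canonical printer and checker.

CORPUS reconstructs, from their prose descriptions, the worked query
forms of each language construct: simple selection, length sugar,
joins, relations and distance, the six track operators, value clauses,
sub-queries, DDL/DML and track loops.
"""

import random

import pytest

from stql.ast_nodes import (
    AndPred, AttrRef, BinOp, ClosestPred, Comparison, CreateTrack,
    CreateTrackAs, DropTrack, ForLoop, LengthFunc, LoadData, LocationComp,
    NotPred, OrPred, OverlapJoinSource, RawTrack, RegQuery, SubquerySource,
    TransformSource, UnionSource,
)
from stql.checker import check, check_script
from stql.parser import StqlSyntaxError, canonicalize, parse, parse_script

CORPUS = [
    # basic selection and filtering
    "SELECT * FROM T1 WHERE chr = 'chr1'",
    "SELECT DISTINCT T1.chrend - T1.chrstart + 1 FROM T1",
    "SELECT DISTINCT LENGTH(TInt) FROM T1 AS TInt",
    "SELECT * FROM T1, T2 WHERE T1.chr = T2.chr",
    "SELECT * FROM T1 RIGHT JOIN T2 WHERE T1.chr = T2.chr",
    "SELECT * FROM T1 LEFT JOIN T2 WHERE T1.chr = T2.chr",
    "SELECT * FROM T1 OUTER JOIN T2 WHERE T1.chr = T2.chr",
    # relations, constant intervals, distance, closest
    "SELECT * FROM T1 AS A, T2 AS B WHERE A OVERLAPS WITH B",
    "SELECT * FROM T1 WHERE T1 IS WITHIN [chr1, 100, 200]",
    "SELECT * FROM T1 A, T2 B WHERE A IS ADJACENT TO B AND A.value > 10",
    "SELECT * FROM T1 A, T2 B WHERE DISTANCE(A, B) < 1000",
    "SELECT * FROM T1, T2 WHERE T1 IS CLOSEST TO EACH T2",
    "SELECT * FROM T1 A, T2 B WHERE A IS UPSTREAM OF B",
    # grouping / ordering
    "SELECT chr, COUNT(*) FROM T1 WHERE value > 10 GROUP BY chr "
    "ORDER BY chr",
    "SELECT chr, AVG(value) AS meanv FROM T1 GROUP BY chr",
    # track operators with value derivation
    "SELECT * FROM COALESCE T1 WITH vd_sum USING EACH MODEL",
    "SELECT * FROM (COALESCE T1 WITH vd_max USING TOTAL MODEL) M",
    "SELECT * FROM DISCRETIZE T1 WITH vd_avg USING EACH MODEL",
    "SELECT * FROM PROJECT T1 ON T2 WITH vd_sum USING TOTAL MODEL",
    "SELECT * FROM PROJECT T1 ON GENERATE BINS WITH LENGTH 100 "
    "WITH vd_sum USING TOTAL MODEL",
    "SELECT * FROM T1 INTERSECTJOIN T2 WITH vd_sum USING EACH MODEL",
    "SELECT * FROM (T1 INTERSECTJOIN T2 WITH vd_diff USING EACH MODEL, "
    "METADATA) J",
    "SELECT * FROM T1 EXCLUSIVEJOIN T2 WITH vd_left USING EACH MODEL",
    "SELECT * FROM PROJECT T1 ON T2 WITH METADATA",
    "SELECT * FROM (T1 UNION ALL T2) NtInt",
    "SELECT * FROM (T1 UNION ALL T2 UNION ALL T1) NtInt",
    # value model spelled with the grammar keyword 'all'
    "SELECT * FROM T1 INTERSECTJOIN T2 WITH vd_sum USING ALL MODEL",
    # sub-queries and dynamically created tracks
    "SELECT * FROM (SELECT * FROM T1 WHERE value > 10) Big "
    "WHERE Big.chr = 'chr2'",
    "SELECT J.chr, J.chrstart, J.chrend, J.value FROM "
    "(T1 INTERSECTJOIN T2 WITH vd_sum USING EACH MODEL) J "
    "WHERE J.value > 2",
    # DDL / DML
    "CREATE TRACK mytrack (chr string, chrstart int, chrend int, "
    "value float)",
    "CREATE TRACK copy1 AS SELECT * FROM T1 WHERE value > 10",
    "DROP TRACK T1",
    "LOAD DATA LOCAL INPATH 'data/t.bed' INTO TRACK T1",
    "LOAD DATA LOCAL INPATH 'data/t.bed' OVERWRITE INTO TRACK T1",
    # track selection and looping
    "FOR TRACK TInt IN (SYDH TFBS, cell = 'GM12878' AND name LIKE '%Pk%') "
    "SELECT * FROM TInt COMBINED WITH UNION AS AllPeaks",
    "FOR TRACK TInt IN (SYDH TFBS) "
    "CREATE TRACK res_ AS SELECT * FROM TInt WHERE value > 1",
    # predicate combinations
    "SELECT * FROM T1 WHERE NOT (value > 3 AND chr = 'chr1') "
    "OR LENGTH(T1) >= 50",
    "SELECT * FROM T1 WHERE value > 1 AND value < 9 AND chr != 'chr3'",
    "SELECT * FROM T1 WHERE name NOT LIKE '%raw%'",
]


@pytest.mark.parametrize("text", CORPUS, ids=range(len(CORPUS)))
def test_corpus_parses_and_round_trips(text):
    ast = parse(text)
    canon = canonicalize(ast)
    assert parse(canon) == ast


def _checkable(text: str) -> bool:
    # corpus entries referencing attributes the fixture catalog lacks
    return "name NOT LIKE" not in text


@pytest.mark.parametrize(
    "text", [q for q in CORPUS if _checkable(q)], ids=range(len(CORPUS) - 1))
def test_corpus_checks_against_fixture_catalog(text, catalog):
    diags = check_script(parse_script(text), catalog,
                         chrom_sizes={"chr1": 1000})
    assert diags == [], [str(d) for d in diags]


class TestTreeShapes:
    def test_join_query_shape(self):
        q = parse("SELECT * FROM T1, T2 WHERE T1.chr = T2.chr")
        assert isinstance(q, RegQuery)
        assert q.items == "*"
        assert [s.name for s in q.sources] == ["T1", "T2"]
        assert isinstance(q.where, Comparison)
        assert q.where.left == AttrRef("T1", "chr")

    def test_length_sugar_and_distinct(self):
        q = parse("SELECT DISTINCT LENGTH(TInt) FROM T AS TInt")
        assert q.distinct
        assert isinstance(q.items[0].expr, LengthFunc)
        assert q.sources[0] == RawTrack("T", alias="TInt", as_kw=True)

    def test_arithmetic_precedence(self):
        q = parse("SELECT chrstart + chrend * 2 FROM T")
        e = q.items[0].expr
        assert isinstance(e, BinOp) and e.op == "+"
        assert isinstance(e.right, BinOp) and e.right.op == "*"
        q2 = parse("SELECT (chrstart + chrend) * 2 FROM T")
        e2 = q2.items[0].expr
        assert e2.op == "*" and isinstance(e2.left, BinOp)

    def test_predicate_precedence_not_and_or(self):
        q = parse("SELECT * FROM T WHERE NOT value = 1 AND value = 2 "
                  "OR value = 3")
        assert isinstance(q.where, OrPred)
        first = q.where.operands[0]
        assert isinstance(first, AndPred)
        assert isinstance(first.operands[0], NotPred)

    def test_unbounded_and_chain(self):
        q = parse("SELECT * FROM T WHERE value > 1 AND value > 2 "
                  "AND value > 3 AND value > 4")
        assert isinstance(q.where, AndPred)
        assert len(q.where.operands) == 4

    def test_for_loop_forms(self):
        q = parse("FOR TRACK TInt IN (SYDH TFBS, cell = 'GM12878' AND "
                  "name LIKE '%Pk%') SELECT * FROM TInt "
                  "COMBINED WITH UNION AS AllPeaks")
        assert isinstance(q, ForLoop)
        assert q.form == "union" and q.output == "AllPeaks"
        assert q.category == "SYDH TFBS"
        assert q.conditions == [("cell", "=", "GM12878"),
                                ("name", "LIKE", "%Pk%")]
        q2 = parse("FOR TRACK X IN (Cat) CREATE TRACK out_ AS "
                   "SELECT * FROM X")
        assert q2.form == "per_track"
        assert isinstance(q2.body, CreateTrackAs)

    def test_nested_sources(self):
        q = parse("SELECT * FROM PROJECT (COALESCE T1) ON "
                  "(T2 UNION ALL T3) U WITH vd_sum USING EACH MODEL")
        src = q.sources[0]
        assert isinstance(src, OverlapJoinSource) and src.op == "project"
        assert isinstance(src.left, TransformSource)
        assert isinstance(src.right, UnionSource)

    def test_closest_predicate(self):
        q = parse("SELECT * FROM T1, T2 WHERE T1 IS CLOSEST TO EACH T2")
        assert q.where == ClosestPred("T1", "T2")

    def test_ddl_shapes(self):
        c = parse("CREATE TRACK t (chr string, chrstart int, chrend int, "
                  "value float)")
        assert isinstance(c, CreateTrack)
        assert c.schema[0] == ("chr", "string")
        assert isinstance(parse("DROP TRACK t"), DropTrack)
        ld = parse("LOAD DATA LOCAL INPATH 'x.bed' OVERWRITE INTO TRACK t")
        assert isinstance(ld, LoadData) and ld.overwrite

    def test_location_comp_with_constant(self):
        q = parse("SELECT * FROM T WHERE [chr1, 100, 200] CONTAINS T")
        assert isinstance(q.where, LocationComp)
        assert q.where.left.chrstart == 100

    def test_keywords_case_insensitive(self):
        assert parse("select * from T where value > 1") == \
            parse("SELECT * FROM T WHERE value > 1")


@pytest.mark.parametrize("text", [
    "SELECT chr FROM WHERE",
    "SELECT FROM T",
    "SELECT * FROM T WHERE",
    "SELECT * FROM T WHERE value >",
    "CREATE TRACK t (chr strings)",
    "SELECT * FROM T1 INTERSECTJOIN T2 WITH vd_sum USING sometimes MODEL",
    "FOR TRACK X IN (Cat) SELECT * FROM X",  # missing COMBINED WITH UNION
    "SELECT * FROM (T1 UNION ALL T2)",  # union source needs an alias
])
def test_syntax_errors_carry_positions(text):
    with pytest.raises(StqlSyntaxError) as err:
        parse(text)
    assert err.value.line >= 1 and err.value.col >= 1


class TestChecker:
    def test_unknown_track(self, catalog):
        diags = check(parse("SELECT * FROM Tx"), catalog)
        assert any("unknown track" in str(d) for d in diags)

    def test_vd_not_applicable(self, catalog):
        diags = check(
            parse("SELECT * FROM T1 EXCLUSIVEJOIN T2 WITH vd_sum USING "
                  "EACH MODEL"), catalog)
        assert any("not applicable" in str(d) for d in diags)

    def test_ambiguous_attribute(self, catalog):
        diags = check(parse("SELECT value FROM T1, T2"), catalog)
        assert any("ambiguous" in str(d) for d in diags)

    def test_unknown_attribute(self, catalog):
        diags = check(parse("SELECT T1.score FROM T1"), catalog)
        assert any("no attribute" in str(d) for d in diags)

    def test_group_by_rule(self, catalog):
        diags = check(parse("SELECT chr, value FROM T1 GROUP BY chr"),
                      catalog)
        assert any("GROUP BY" in str(d) for d in diags)

    def test_bins_require_chrom_sizes(self, catalog):
        q = parse("SELECT * FROM PROJECT T1 ON GENERATE BINS WITH "
                  "LENGTH 100 WITH vd_sum USING EACH MODEL")
        diags = check(q, catalog, chrom_sizes=None)
        assert any("chromosome-sizes" in str(d) for d in diags)
        assert check(q, catalog, chrom_sizes={"chr1": 500}) == []

    def test_script_sees_earlier_ctas(self, catalog):
        stmts = parse_script(
            "CREATE TRACK tmp AS SELECT * FROM T1; SELECT * FROM tmp")
        assert check_script(stmts, catalog) == []

    def test_invalid_ctas_schema_flagged(self, catalog):
        stmts = parse_script("CREATE TRACK bad AS SELECT chr FROM T1")
        diags = check_script(stmts, catalog)
        assert any("not a valid signal track" in str(d) for d in diags)

    def test_union_schema_mismatch(self, catalog):
        stmts = parse_script(
            "CREATE TRACK odd (chr string, chrstart int, chrend int, "
            "value float, score float); "
            "SELECT * FROM (T1 UNION ALL odd) U")
        diags = check_script(stmts, catalog)
        assert any("different schemas" in str(d) for d in diags)


# ---------------------------------------------------------------------
# randomized grammar derivations round-trip through canonicalize


def _random_query(rng: random.Random, depth: int = 0) -> str:
    tracks = ["T1", "T2", "fig_coalesce"]
    attr = rng.choice(["value", "chrstart", "chrend"])
    preds = [
        f"{attr} > {rng.randint(0, 50)}",
        f"chr = 'chr{rng.randint(1, 3)}'",
        "A OVERLAPS WITH B",
        "A PRECEDES B",
        f"DISTANCE(A, B) < {rng.randint(1, 2000)}",
        f"LENGTH(A) >= {rng.randint(1, 200)}",
        f"A IS WITHIN [chr1, {rng.randint(1, 50)}, {rng.randint(51, 500)}]",
    ]
    pred = rng.choice(preds)
    if rng.random() < 0.5:
        pred = f"{pred} AND {rng.choice(preds)}"
    if rng.random() < 0.3:
        pred = f"NOT ({pred})"
    t1, t2 = rng.sample(tracks, 2)
    source = rng.choice([
        f"{t1} AS A, {t2} AS B",
        f"(COALESCE {t1} WITH vd_sum USING EACH MODEL) A, {t2} AS B",
        f"({t1} INTERSECTJOIN {t2} WITH vd_max USING TOTAL MODEL) A, "
        f"{t1} AS B",
        f"(PROJECT {t1} ON {t2} WITH vd_avg USING EACH MODEL) A, "
        f"{t2} AS B",
    ])
    items = rng.choice([
        "*", "A.chr, A.chrstart, A.chrend, A.value",
        "DISTINCT A.value", "A.value + 1 AS shifted",
    ])
    q = f"SELECT {items} FROM {source} WHERE {pred}"
    if depth < 1 and rng.random() < 0.3:
        q = f"SELECT * FROM ({q}) Sub WHERE Sub.value > 0"
    return q


def test_random_derivations_round_trip():
    rng = random.Random(20240917)
    for _ in range(120):
        text = _random_query(rng)
        ast = parse(text)
        canon = canonicalize(ast)
        assert parse(canon) == ast, text
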