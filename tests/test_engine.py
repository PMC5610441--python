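"""Query execution: worked join tables, grouping, DDL/DML, loops,
plans, and equivalence of optimized and naive evaluation."""

import random

import pytest

from stql import Session, naive_execute, plan
from stql.engine import Engine
from stql.fixtures import generate_random_track
from stql.model import Catalog, GenomicInterval, Track, ValidationError
from stql.parser import parse

T1T2_JOIN = "SELECT * FROM T1, T2 WHERE T1.chr = T2.chr"

EXPECTED_JOIN_ROWS = [
    ("chr1", 101, 200, 10.0, "chr1", 401, 500, 40.0),
    ("chr1", 201, 300, 20.0, "chr1", 401, 500, 40.0),
    ("chr2", 301, 400, 30.0, "chr2", 501, 600, 50.0),
]


class TestWorkedJoin:
    def test_inner_join_rows(self, session):
        got = session.run(T1T2_JOIN)
        assert got.rows == EXPECTED_JOIN_ROWS

    def test_right_join_pads_whole_chromosome(self, session):
        got = session.run(
            "SELECT * FROM T1 RIGHT JOIN T2 WHERE T1.chr = T2.chr")
        assert got.rows == EXPECTED_JOIN_ROWS + [
            (None, None, None, None, "chr3", 601, 700, 60.0)
        ]

    def test_left_join_matches_inner_here(self, session):
        # T1 has no chromosome absent from T2, so LEFT adds nothing
        got = session.run(
            "SELECT * FROM T1 LEFT JOIN T2 WHERE T1.chr = T2.chr")
        assert got.rows == EXPECTED_JOIN_ROWS

    def test_outer_join_pads_both_sides(self, session):
        got = session.run(
            "SELECT * FROM T1 OUTER JOIN T2 WHERE T1.chr = T2.chr")
        assert len(got.rows) == 4  # chr3 pad; no T1-only chromosomes


class TestSelect:
    def test_chromosome_filter(self, session):
        got = session.run("SELECT * FROM T1 WHERE chr = 'chr1'")
        assert [r[1] for r in got.rows] == [101, 201]

    def test_distinct_lengths(self, session):
        got = session.run("SELECT DISTINCT LENGTH(TInt) FROM T1 AS TInt")
        assert got.rows == [(100,)]

    def test_arithmetic_and_alias(self, session):
        got = session.run(
            "SELECT value * 2 + 1 AS scaled FROM T1 ORDER BY chr")
        assert got.columns == ["scaled"]
        assert sorted(r[0] for r in got.rows) == [21.0, 41.0, 61.0]

    def test_count_per_chromosome(self, session):
        got = session.run("SELECT chr, COUNT(*) FROM T1 WHERE value > 10 "
                          "GROUP BY chr ORDER BY chr")
        assert got.rows == [("chr1", 1), ("chr2", 1)]

    def test_aggregates_skip_null(self, session):
        cat = session.catalog
        cat.add(Track("N", [GenomicInterval("chr1", 1, 10, 4.0),
                            GenomicInterval("chr1", 20, 30, None)]))
        got = session.run("SELECT COUNT(*), COUNT(value), SUM(value), "
                          "AVG(value) FROM N")
        assert got.rows == [(2, 1, 4.0, 4.0)]

    def test_order_by_value_stable_ascending(self, session):
        got = session.run("SELECT chr, value FROM T1 ORDER BY value")
        assert [r[1] for r in got.rows] == [10.0, 20.0, 30.0]

    def test_distance_in_where(self, session):
        got = session.run("SELECT * FROM T1 A, T2 B "
                          "WHERE DISTANCE(A, B) <= 101")
        # only (201,300) vs (401,500) at distance 101 qualifies on chr1;
        # chr2 pair is at distance 101 as well
        assert len(got.rows) == 2

    def test_constant_interval_predicate(self, session):
        got = session.run(
            "SELECT * FROM T1 WHERE T1 IS WITHIN [chr1, 1, 250]")
        assert [r[1] for r in got.rows] == [101]

    def test_closest_each(self, session):
        got = session.run("SELECT * FROM T1, T2 WHERE T1 IS CLOSEST "
                          "TO EACH T2")
        assert [(r[0], r[1]) for r in got.rows] == [("chr1", 201),
                                                    ("chr2", 301)]


class TestStatements:
    def test_create_load_drop(self, session, tmp_path):
        bed = tmp_path / "three.bed"
        bed.write_text("chr1\t0\t10\nchr1\t20\t30\nchr2\t5\t8\n")
        session.run("CREATE TRACK fresh (chr string, chrstart int, "
                    "chrend int, value float)")
        session.run(f"LOAD DATA LOCAL INPATH '{bed}' INTO TRACK fresh")
        assert len(session.catalog.get("fresh")) == 3
        session.run(f"LOAD DATA LOCAL INPATH '{bed}' INTO TRACK fresh")
        assert len(session.catalog.get("fresh")) == 6
        session.run(f"LOAD DATA LOCAL INPATH '{bed}' OVERWRITE "
                    "INTO TRACK fresh")
        assert len(session.catalog.get("fresh")) == 3
        session.run("DROP TRACK fresh")
        assert "fresh" not in session.catalog

    def test_ctas_then_query(self, session):
        got = session.run("CREATE TRACK big AS SELECT * FROM T1 WHERE "
                          "value > 10; SELECT COUNT(*) FROM big")
        assert got.rows == [(2,)]

    def test_ctas_without_mandatory_attrs_rejected(self, session):
        with pytest.raises(ValidationError):
            session.run("CREATE TRACK bad AS SELECT chr FROM T1")

    def test_script_returns_last_result(self, session):
        got = session.run(
            "CREATE TRACK a1 AS SELECT * FROM T1 WHERE value > 10; "
            "CREATE TRACK a2 AS SELECT * FROM a1 WHERE value > 20; "
            "SELECT * FROM a2")
        assert len(got.rows) == 1 and got.rows[0][3] == 30.0

    def test_rejected_query_runs_nothing(self, session):
        n = len(session.catalog.track_names)
        with pytest.raises(ValidationError):
            session.run("CREATE TRACK x AS SELECT * FROM T1; "
                        "SELECT * FROM nope")
        assert len(session.catalog.track_names) == n  # no partial effects


class TestForLoop:
    def test_union_form(self, session):
        out = session.run(
            "FOR TRACK TInt IN (SYDH TFBS, cell = 'GM12878' AND name "
            "LIKE '%Pk%') SELECT * FROM TInt COMBINED WITH UNION AS "
            "AllPeaks")
        assert out.name == "AllPeaks"
        assert len(out) == 10  # two matching 5-interval tracks
        assert "AllPeaks" in session.catalog

    def test_union_form_no_match_empty(self, session):
        out = session.run("FOR TRACK X IN (SYDH TFBS, cell = 'HeLa') "
                          "SELECT * FROM X COMBINED WITH UNION AS Nothing")
        assert len(out) == 0

    def test_per_track_form_names_concatenated(self, session):
        session.run("FOR TRACK X IN (SYDH TFBS, cell = 'K562') "
                    "CREATE TRACK res_ AS SELECT * FROM X")
        assert "res_K562CtcfPk" in session.catalog


class TestPlan:
    def test_join_strategy_for_overlap_predicate(self, catalog):
        q = parse("SELECT * FROM T1 A, T2 B WHERE A OVERLAPS WITH B")
        p = plan(q, catalog)
        join = p.find("Join")[0]
        assert join.detail["strategy"] == "sort-merge"
        assert join.detail["per_chromosome"]

    def test_plain_product_otherwise(self, catalog):
        q = parse("SELECT * FROM T1, T2 WHERE T1.value > T2.value")
        p = plan(q, catalog)
        assert p.find("Join")[0].detail["strategy"] == "chromosome-product"

    def test_early_column_pruning(self, catalog):
        q = parse("SELECT chr FROM T1")
        p = plan(q, catalog)
        scan = p.find("TableScan")[0]
        assert scan.detail["columns"] is not None
        assert "value" not in scan.detail["columns"]

    def test_bins_not_materialized(self, catalog):
        q = parse("SELECT * FROM PROJECT T1 ON GENERATE BINS WITH "
                  "LENGTH 100 WITH vd_sum USING EACH MODEL")
        p = plan(q, catalog)
        ops = [n for n in p.find("TrackOp") if n.detail.get("op") == "project"]
        assert ops and ops[0].detail["materialize_bins"] is False

    def test_single_sink(self, catalog):
        q = parse("SELECT chr, COUNT(*) FROM T1 GROUP BY chr ORDER BY chr")
        p = plan(q, catalog)
        assert p.kind == "Sink"
        assert len(p.find("Sort")) == 1 and len(p.find("GroupAggregate")) == 1


PREDICATES = [
    "A.value > B.value",
    "A OVERLAPS WITH B",
    "A PRECEDES B AND DISTANCE(A, B) < 300",
    "A IS ADJACENT TO B OR A OVERLAPS WITH B",
    "NOT A OVERLAPS WITH B",
    "A CONTAINS B",
    "LENGTH(A) >= 20 AND A OVERLAPS WITH B",
    "A.chrstart <= B.chrend",
]


def test_optimized_equals_naive_on_random_tracks():
    """Sort-merge fast path and the literal per-chromosome product give
    row-identical results over randomized inputs and predicates."""
    rng = random.Random(7)
    for trial in range(40):
        cat = Catalog()
        cat.add(generate_random_track(
            1000 + trial, rng.randint(0, 30),
            chromosomes=("chr1", "chr2"), max_coord=2000,
            length_dist=("uniform", 1, 80), overlap_fraction=0.4, name="A"))
        cat.add(generate_random_track(
            2000 + trial, rng.randint(0, 30),
            chromosomes=("chr1", "chr2"), max_coord=2000,
            length_dist=("uniform", 1, 80), overlap_fraction=0.4, name="B"))
        pred = rng.choice(PREDICATES)
        q = parse(f"SELECT * FROM A, B WHERE {pred}")
        fast = Engine(cat, optimize=True).execute_query(q)
        slow = naive_execute(q, cat)
        assert sorted(fast.rows) == sorted(slow.rows), pred


def test_partition_independence(session):
    """Processing chromosomes one at a time reproduces the all-at-once
    result (the per-chromosome partitioning contract)."""
    whole = session.run(T1T2_JOIN)
    per_chrom = []
    for chrom in ("chr1", "chr2", "chr3"):
        got = session.run(
            f"SELECT * FROM T1, T2 WHERE T1.chr = T2.chr "
            f"AND T1.chr = '{chrom}'")
        per_chrom.extend(got.rows)
    assert sorted(per_chrom) == sorted(whole.rows)
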