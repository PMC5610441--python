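"""Planning and execution of checked statements.

Semantics of a multi-track query: a chromosome-by-chromosome Cartesian
product of the FROM tracks, WHERE filtering, SELECT projection with
optional DISTINCT, GROUP BY aggregation and stable ascending ORDER BY.
LEFT/RIGHT/OUTER joins pad at whole-chromosome granularity: intervals
on a chromosome absent from the other track appear once each, with the
other track's columns NULL.

The optimizer never changes results (a property the tests assert): it
prunes unreferenced attributes early, replaces the product with a
sorted proximity scan when the predicate demands overlapping/adjacent
pairs, and computes bin projections by per-interval bin arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _cartesian
from typing import Optional, Union

import pandas as pd

from . import operators, relations
from .ast_nodes import (
    AggFunc, AndPred, AttrRef, BinOp, BinsSource, ClosestPred, Comparison,
    ConstIntervalNode, CreateTrack, CreateTrackAs, DistanceFunc, DropTrack,
    ForLoop, LengthFunc, LoadData, LocationComp, NotPred, Num, OrPred,
    OverlapJoinSource, PatternMatch, RawTrack, RegQuery, Str,
    SubquerySource, TransformSource, UnionSource,
)
from .checker import check_script
from .model import (
    Catalog, ConstantInterval, GenomicInterval, StqlError, Track,
    TrackSchema, ValidationError, chrom_sort_key, interval_length,
    like_match, validate_track,
)
from .parser import parse_script
from .values import parse_value_model


class ExecutionError(StqlError):
    pass


# --------------------------------------------------------------------
# result container


class ResultTable:
    """Named, typed columns plus rows; becomes a Track only if it has
    the four mandatory attributes."""

    def __init__(self, columns: list[str], rows: list[tuple],
                 types: Optional[list[str]] = None):
        self.columns = list(columns)
        self.rows = [tuple(r) for r in rows]
        self.types = list(types) if types else ["string"] * len(self.columns)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)

    def is_valid_signal_track(self) -> bool:
        lower = {c.lower() for c in self.columns}
        return {"chr", "chrstart", "chrend", "value"} <= lower

    def to_track(self, name: str) -> Track:
        lower = [c.lower() for c in self.columns]
        missing = [m for m in ("chr", "chrstart", "chrend", "value")
                   if m not in lower]
        if missing:
            raise ValidationError(
                f"query result is not a valid signal track: missing "
                f"mandatory attributes {', '.join(missing)}"
            )
        idx = {c: lower.index(c) for c in ("chr", "chrstart", "chrend",
                                           "value")}
        extra = [(k, self.columns[k]) for k in range(len(self.columns))
                 if k not in idx.values()]
        intervals = []
        for row in self.rows:
            value = row[idx["value"]]
            meta = {name_: row[k] for k, name_ in extra
                    if row[k] is not None}
            try:
                intervals.append(GenomicInterval(
                    str(row[idx["chr"]]), int(row[idx["chrstart"]]),
                    int(row[idx["chrend"]]),
                    None if value is None else float(value), meta,
                ))
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"query result row cannot form an interval: {exc}"
                ) from None
        schema = TrackSchema.default(
            [(self.columns[k], self.types[k]) for k, _n in extra]
        )
        return Track(name, intervals, schema=schema)

    def write_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(self.columns) + "\n")
            for row in self.rows:
                fh.write("\t".join(_cell(v) for v in row) + "\n")

    def __repr__(self) -> str:
        return f"ResultTable({self.columns}, {len(self.rows)} rows)"


def _cell(v) -> str:
    if v is None:
        return "NULL"
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return str(v)


# --------------------------------------------------------------------
# logical plan (introspectable; execution consults the join strategy)


@dataclass
class PlanNode:
    kind: str  # TableScan Filter Select Join TrackOp Closest GroupAggregate Sort Sink
    detail: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)

    def walk(self):
        yield self
        for node in self.inputs:
            yield from node.walk()

    def find(self, kind: str) -> list["PlanNode"]:
        return [n for n in self.walk() if n.kind == kind]


_PROXIMITY_RELS = {
    "overlaps with", "coincides with", "contains", "is within",
    "is adjacent to", "is prefix of", "is suffix of",
}


def _conjuncts(pred):
    if isinstance(pred, AndPred):
        out = []
        for op in pred.operands:
            out.extend(_conjuncts(op))
        return out
    return [pred]


def _referenced_attrs(q: RegQuery) -> Optional[set]:
    """Attribute names referenced anywhere downstream, or None for all
    (SELECT *)."""
    if q.items == "*":
        return None
    names: set = set()

    def expr_attrs(e):
        if isinstance(e, AttrRef):
            names.add(e.attr)
        elif isinstance(e, BinOp):
            expr_attrs(e.left)
            expr_attrs(e.right)
        elif isinstance(e, AggFunc) and e.arg is not None:
            names.add(e.arg.attr)

    for it in q.items:
        expr_attrs(it.expr)

    def pred_attrs(p):
        if isinstance(p, (AndPred, OrPred)):
            for o in p.operands:
                pred_attrs(o)
        elif isinstance(p, NotPred):
            pred_attrs(p.operand)
        elif isinstance(p, Comparison):
            expr_attrs(p.left)
            expr_attrs(p.right)
        elif isinstance(p, PatternMatch):
            names.add(p.attr.attr)

    if q.where is not None:
        pred_attrs(q.where)
    for a in q.groupby + q.orderby:
        names.add(a.attr)
    # positional semantics always need the coordinates
    names.update({"chr", "chrstart", "chrend"})
    return names


def plan(q: RegQuery, catalog: Catalog) -> PlanNode:
    """Build the logical-operator DAG for a query (single sink)."""
    needed = _referenced_attrs(q)

    def source_node(src) -> PlanNode:
        if isinstance(src, RawTrack):
            cols = None if needed is None else sorted(needed)
            return PlanNode("TableScan",
                            {"track": src.name, "columns": cols})
        if isinstance(src, TransformSource):
            return PlanNode("TrackOp", {"op": src.op}, [source_node(src.track)])
        if isinstance(src, OverlapJoinSource):
            inputs = [source_node(src.left)]
            if isinstance(src.right, BinsSource):
                detail = {"op": src.op, "bins": src.right.bin_size,
                          "materialize_bins": False}
            else:
                detail = {"op": src.op}
                inputs.append(source_node(src.right))
            return PlanNode("TrackOp", detail, inputs)
        if isinstance(src, SubquerySource):
            return plan(src.query, catalog)
        if isinstance(src, UnionSource):
            return PlanNode("TrackOp", {"op": "union all"},
                            [source_node(t) for t in src.tracks])
        raise ExecutionError(f"unplannable source {type(src).__name__}")

    node: PlanNode
    children = [source_node(s) for s in q.sources]
    if isinstance(q.where, ClosestPred):
        node = PlanNode("Closest", {}, children)
    elif len(children) == 1:
        node = children[0]
    else:
        strategy = "chromosome-product"
        if q.where is not None and len(q.sources) == 2 \
                and q.join_kind is None:
            for c in _conjuncts(q.where):
                if isinstance(c, LocationComp) \
                        and c.rel in _PROXIMITY_RELS \
                        and isinstance(c.left, str) \
                        and isinstance(c.right, str):
                    strategy = "sort-merge"
                    break
        node = PlanNode(
            "Join",
            {"kind": q.join_kind or "inner", "strategy": strategy,
             "per_chromosome": True},
            children,
        )
    if q.where is not None and not isinstance(q.where, ClosestPred):
        node = PlanNode("Filter", {"pred": q.where}, [node])
    node = PlanNode("Select", {"items": q.items, "distinct": q.distinct,
                               "pruned": needed is not None}, [node])
    if q.groupby or (q.items != "*" and any(
            _has_agg(it.expr) for it in q.items)):
        node = PlanNode("GroupAggregate", {"keys": q.groupby}, [node])
    if q.orderby:
        node = PlanNode("Sort", {"keys": q.orderby}, [node])
    return PlanNode("Sink", {}, [node])


def _has_agg(expr) -> bool:
    if isinstance(expr, AggFunc):
        return True
    if isinstance(expr, BinOp):
        return _has_agg(expr.left) or _has_agg(expr.right)
    return False


# --------------------------------------------------------------------
# expression / predicate evaluation over a row environment


def _is_null(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


class _Evaluator:
    def __init__(self, env_order: list[str]):
        self.env_order = env_order  # alias per source position

    def resolve_alias(self, name: str) -> str:
        if name in self.env_order:
            return name
        raise ExecutionError(f"unknown track {name!r} in expression")

    def interval(self, env: dict, name: str):
        return env.get(self.resolve_alias(name))

    def attr(self, env: dict, ref: AttrRef):
        if ref.track is not None:
            iv = env.get(ref.track)
            if iv is None:
                if ref.track not in env:
                    raise ExecutionError(
                        f"unknown track {ref.track!r} in attribute reference"
                    )
                return None
            return iv.get(ref.attr)
        # unqualified: first source owning a non-mandatory match wins is
        # ambiguous — the checker rejects ambiguity, so take first owner
        for alias in self.env_order:
            iv = env.get(alias)
            if iv is not None and iv.get(ref.attr) is not None:
                return iv.get(ref.attr)
        # attribute exists but is NULL, or padded row
        return None

    def expr(self, env: dict, e):
        if isinstance(e, Num):
            return e.value
        if isinstance(e, Str):
            return e.value
        if isinstance(e, AttrRef):
            return self.attr(env, e)
        if isinstance(e, BinOp):
            left = self.expr(env, e.left)
            right = self.expr(env, e.right)
            if _is_null(left) or _is_null(right):
                return None
            if isinstance(left, str) or isinstance(right, str):
                raise ExecutionError(
                    f"arithmetic on non-numeric operand "
                    f"({left!r} {e.op} {right!r})"
                )
            if e.op == "+":
                return left + right
            if e.op == "-":
                return left - right
            if e.op == "*":
                return left * right
            if right == 0:
                return None
            return left / right
        if isinstance(e, LengthFunc):
            iv = self._operand(env, e.target)
            return None if iv is None else interval_length(iv)
        if isinstance(e, DistanceFunc):
            a = self._operand(env, e.left)
            b = self._operand(env, e.right)
            if a is None or b is None:
                return None
            return relations.distance(a, b)
        if isinstance(e, AggFunc):
            raise ExecutionError(
                f"aggregate {e.fn.upper()}() outside GROUP BY context"
            )
        raise ExecutionError(f"cannot evaluate {type(e).__name__}")

    def _operand(self, env: dict, operand):
        if isinstance(operand, ConstIntervalNode):
            return ConstantInterval(operand.chr, operand.chrstart,
                                    operand.chrend, operand.strand or ".")
        return self.interval(env, operand)

    def pred(self, env: dict, p) -> bool:
        if isinstance(p, AndPred):
            return all(self.pred(env, o) for o in p.operands)
        if isinstance(p, OrPred):
            return any(self.pred(env, o) for o in p.operands)
        if isinstance(p, NotPred):
            return not self.pred(env, p.operand)
        if isinstance(p, Comparison):
            left = self.expr(env, p.left)
            right = self.expr(env, p.right)
            if _is_null(left) or _is_null(right):
                return False
            if isinstance(left, str) != isinstance(right, str):
                return False
            try:
                if p.op == "=":
                    return left == right
                if p.op == "!=":
                    return left != right
                if p.op == "<":
                    return left < right
                if p.op == ">":
                    return left > right
                if p.op == "<=":
                    return left <= right
                return left >= right
            except TypeError:
                return False
        if isinstance(p, LocationComp):
            a = self._operand(env, p.left)
            b = self._operand(env, p.right)
            if a is None or b is None:
                return False
            return relations.eval_relation(p.rel, a, b)
        if isinstance(p, PatternMatch):
            v = self.attr(env, p.attr)
            if v is None:
                return False
            hit = like_match(str(v), p.pattern)
            return (not hit) if p.negated else hit
        raise ExecutionError(f"cannot evaluate predicate {type(p).__name__}")


# --------------------------------------------------------------------
# the executor


class Engine:
    def __init__(self, catalog: Optional[Catalog] = None,
                 chrom_sizes: Optional[dict] = None, optimize: bool = True):
        self.catalog = catalog or Catalog()
        self.chrom_sizes = chrom_sizes or {}
        self.optimize = optimize

    # -- FROM sources -------------------------------------------------
    def _source_track(self, src) -> tuple[str, Track]:
        """Materialize one FROM source; returns (alias, track)."""
        if isinstance(src, RawTrack):
            track = self.catalog.get(src.name)
            return src.alias or src.name, track
        if isinstance(src, TransformSource):
            _alias, inner = self._source_track(src.track)
            vc = src.value_clause
            model = parse_value_model(vc.model) if vc.model else None
            fn = operators.coalesce if src.op == "coalesce" \
                else operators.discretize
            out = fn(inner, vd=vc.vd, model=model)
            return src.alias or src.op, out
        if isinstance(src, OverlapJoinSource):
            _la, left = self._source_track(src.left)
            vc = src.value_clause
            model = parse_value_model(vc.model) if vc.model else None
            if src.op == "project":
                if isinstance(src.right, BinsSource):
                    if not self.chrom_sizes:
                        raise ValidationError(
                            "generate bins requires a chromosome-sizes file"
                        )
                    target: Union[Track, operators.BinSpec] = \
                        operators.BinSpec(src.right.bin_size, self.chrom_sizes)
                else:
                    _ra, target = self._source_track(src.right)
                out = operators.project_on(
                    left, target, vd=vc.vd, model=model, metadata=vc.metadata
                )
            else:
                _ra, right = self._source_track(src.right)
                fn = operators.intersectjoin if src.op == "intersectjoin" \
                    else operators.exclusivejoin
                out = fn(left, right, vd=vc.vd, model=model,
                         metadata=vc.metadata)
            return src.alias or src.op, out
        if isinstance(src, SubquerySource):
            result = self.execute_query(src.query)
            return src.alias, result.to_track(src.alias)
        if isinstance(src, UnionSource):
            tracks = [self._source_track(t)[1] for t in src.tracks]
            out = tracks[0]
            for t in tracks[1:]:
                out = operators.union_all(out, t)
            out.name = src.alias
            return src.alias, out
        raise ExecutionError(f"cannot evaluate source {type(src).__name__}")

    # -- row enumeration ----------------------------------------------
    def _rows(self, q: RegQuery, sources: list[tuple[str, Track]]):
        """Yield row environments {alias: interval-or-None}."""
        aliases = [a for a, _t in sources]
        if isinstance(q.where, ClosestPred):
            la = q.where.left
            ra = q.where.right
            if set((la, ra)) != set(aliases) or len(aliases) != 2:
                raise ExecutionError(
                    "IS CLOSEST TO EACH must reference the two FROM tracks"
                )
            t = dict(sources)
            for i1, i2 in relations.closest_pairs(t[la], t[ra]):
                yield {la: i1, ra: i2}
            return

        by_chrom = [t.by_chromosome() for _a, t in sources]
        kind = q.join_kind or "inner"
        all_chroms: set = set()
        for bc in by_chrom:
            all_chroms |= set(bc)
        if kind == "inner":
            chroms = set.intersection(*(set(bc) for bc in by_chrom)) \
                if by_chrom else set()
        elif kind == "left":
            chroms = set(by_chrom[0])
        elif kind == "right":
            chroms = set(by_chrom[1])
        else:  # outer
            chroms = all_chroms

        fast_pair = None
        if self.optimize and q.where is not None and len(sources) == 2 \
                and kind == "inner" and not isinstance(q.where, ClosestPred):
            for c in _conjuncts(q.where):
                if isinstance(c, LocationComp) and c.rel in _PROXIMITY_RELS \
                        and isinstance(c.left, str) \
                        and isinstance(c.right, str) \
                        and set((c.left, c.right)) == set(aliases):
                    fast_pair = True
                    break

        for chrom in sorted(chroms, key=chrom_sort_key):
            lists = []
            for bc in by_chrom:
                ivs = bc.get(chrom)
                # chromosome-granular padding: a track without intervals
                # on this chromosome contributes one NULL interval
                lists.append(ivs if ivs else [None])
            if fast_pair and all(bc.get(chrom) for bc in by_chrom):
                left = sorted(lists[0],
                              key=lambda i: (i.chrstart, i.chrend))
                right = sorted(lists[1],
                               key=lambda i: (i.chrstart, i.chrend))
                for i1 in left:
                    for i2 in right:
                        if i2.chrstart > i1.chrend + 1:
                            break
                        if i2.chrend < i1.chrstart - 1:
                            continue
                        yield {aliases[0]: i1, aliases[1]: i2}
                continue
            for combo in _cartesian(*lists):
                yield dict(zip(aliases, combo))

    # -- SELECT evaluation --------------------------------------------
    def execute_query(self, q: RegQuery) -> ResultTable:
        sources = [self._source_track(s) for s in q.sources]
        aliases = [a for a, _t in sources]
        if len(set(aliases)) != len(aliases):
            raise ValidationError("duplicate track alias in FROM clause")
        ev = _Evaluator(aliases)

        # chromosome-padded rows (an outer-join side with no intervals
        # on the chromosome) are kept regardless of the WHERE predicate,
        # matching the worked outer-join semantics
        envs = (env for env in self._rows(q, sources)
                if q.where is None or isinstance(q.where, ClosestPred)
                or any(v is None for v in env.values())
                or ev.pred(env, q.where))

        has_agg = q.items != "*" and any(_has_agg(it.expr) for it in q.items)
        if q.groupby or has_agg:
            table = self._aggregate(q, ev, envs, sources)
            if q.orderby:
                table = self._order(q, table)
        else:
            if q.orderby:
                # ORDER BY may reference source attributes that the
                # SELECT list drops, so sort the row environments
                envs = sorted(
                    envs,
                    key=lambda env: [
                        (v is not None, 0 if v is None else v)
                        for v in (ev.expr(env, a) for a in q.orderby)
                    ],
                )
            table = self._project(q, ev, envs, sources)

        if q.distinct:
            seen = set()
            rows = []
            for row in table.rows:
                if row not in seen:
                    seen.add(row)
                    rows.append(row)
            table = ResultTable(table.columns, rows, table.types)
        return table

    def _star_columns(self, sources) -> tuple[list[str], list[str], list]:
        columns, types, getters = [], [], []
        used = set()
        for k, (alias, track) in enumerate(sources):
            for n, t in track.schema.attributes:
                name = n if k == 0 else f"{alias}_{n}"
                if name in used:
                    name = f"{alias}_{n}_{k}"
                used.add(name)
                columns.append(name)
                types.append(t)
                getters.append((alias, n))
        return columns, types, getters

    def _project(self, q, ev, envs, sources) -> ResultTable:
        if q.items == "*":
            columns, types, getters = self._star_columns(sources)
            rows = []
            for env in envs:
                row = []
                for alias, attr in getters:
                    iv = env.get(alias)
                    row.append(None if iv is None else iv.get(attr))
                rows.append(tuple(row))
            return ResultTable(columns, rows, types)
        columns, types = self._item_columns(q, sources)
        rows = [tuple(ev.expr(env, it.expr) for it in q.items)
                for env in envs]
        return ResultTable(columns, rows, types)

    def _item_columns(self, q, sources) -> tuple[list[str], list[str]]:
        columns, types = [], []
        used = set()
        schema_by_alias = {a: t.schema for a, t in sources}
        for idx, it in enumerate(q.items):
            name = it.alias or _default_item_name(it.expr, idx)
            if name in used:
                qual = getattr(it.expr, "track", None)
                name = f"{qual}_{name}" if qual else f"{name}_{idx}"
            if name in used:
                name = f"{name}_{idx}"
            used.add(name)
            columns.append(name)
            types.append(_item_type(it.expr, schema_by_alias))
        return columns, types

    def _aggregate(self, q, ev, envs, sources) -> ResultTable:
        groups: dict[tuple, list[dict]] = {}
        order: list[tuple] = []
        for env in envs:
            key = tuple(ev.expr(env, a) for a in q.groupby)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(env)
        if not q.groupby and not groups:
            groups[()] = []
            order.append(())

        columns, types = self._item_columns(q, sources)
        rows = []
        for key in order:
            members = groups[key]
            row = []
            for it in q.items:
                row.append(self._agg_expr(it.expr, ev, members, key, q))
            rows.append(tuple(row))
        return ResultTable(columns, rows, types)

    def _agg_expr(self, expr, ev, members, key, q):
        if isinstance(expr, AggFunc):
            if expr.fn == "count" and expr.arg is None:
                return len(members)
            values = [ev.attr(env, expr.arg) for env in members]
            values = [v for v in values if not _is_null(v)]
            if expr.fn == "count":
                return len(values)
            if not values:
                return None
            if expr.fn == "sum":
                return sum(values)
            if expr.fn == "avg":
                return sum(values) / len(values)
            if expr.fn == "min":
                return min(values)
            return max(values)
        if isinstance(expr, BinOp):
            left = self._agg_expr(expr.left, ev, members, key, q)
            right = self._agg_expr(expr.right, ev, members, key, q)
            if _is_null(left) or _is_null(right):
                return None
            if expr.op == "+":
                return left + right
            if expr.op == "-":
                return left - right
            if expr.op == "*":
                return left * right
            return None if right == 0 else left / right
        if isinstance(expr, AttrRef):
            for k, a in enumerate(q.groupby):
                if a.attr == expr.attr and (
                    a.track == expr.track or a.track is None
                    or expr.track is None
                ):
                    return key[k]
            if members:
                return ev.expr(members[0], expr)
            return None
        if isinstance(expr, (Num, Str)):
            return expr.value
        if members:
            return ev.expr(members[0], expr)
        return None

    def _order(self, q, table: ResultTable) -> ResultTable:
        keys = []
        for a in q.orderby:
            name = a.attr
            if name in table.columns:
                keys.append(table.columns.index(name))
            else:
                qual = f"{a.track}_{a.attr}" if a.track else None
                if qual and qual in table.columns:
                    keys.append(table.columns.index(qual))
                else:
                    raise ExecutionError(
                        f"ORDER BY attribute {name!r} not in result"
                    )

        def sort_key(row):
            out = []
            for k in keys:
                v = row[k]
                # NULLs sort first; keep numeric/string comparisons apart
                out.append((v is not None, v if v is not None else 0))
            return out

        rows = sorted(table.rows, key=sort_key)
        return ResultTable(table.columns, rows, table.types)


def _default_item_name(expr, idx: int) -> str:
    if isinstance(expr, AttrRef):
        return expr.attr
    if isinstance(expr, LengthFunc):
        return "length"
    if isinstance(expr, DistanceFunc):
        return "distance"
    if isinstance(expr, AggFunc):
        if expr.arg is None:
            return f"{expr.fn}_all"
        return f"{expr.fn}_{expr.arg.attr}"
    return f"c{idx}"


def _item_type(expr, schema_by_alias) -> str:
    if isinstance(expr, AttrRef):
        if expr.track and expr.track in schema_by_alias:
            return schema_by_alias[expr.track].type_of(expr.attr) or "float"
        for schema in schema_by_alias.values():
            if schema.has(expr.attr):
                return schema.type_of(expr.attr) or "float"
        return "float"
    if isinstance(expr, LengthFunc):
        return "int"
    if isinstance(expr, AggFunc) and expr.fn == "count":
        return "int"
    return "float"


# --------------------------------------------------------------------
# naive reference evaluator (tests): literal per-chromosome product


def naive_execute(q: RegQuery, catalog: Catalog,
                  chrom_sizes: Optional[dict] = None) -> ResultTable:
    """Literal per-chromosome Cartesian-product-then-filter evaluation,
    with no optimizer passes; ground truth in equivalence tests."""
    eng = Engine(catalog, chrom_sizes, optimize=False)
    return eng.execute_query(q)


# --------------------------------------------------------------------
# session: statements, scripts, loops


class Session:
    """Holds a catalog plus chromosome sizes and runs statements.

    Tracks created by CREATE TRACK persist for the lifetime of the
    session; ``run`` accepts a single statement or a semicolon-separated
    script and returns the result of the final query (or the created
    Track for a final CTAS, or None for other statements).
    """

    def __init__(self, catalog: Optional[Catalog] = None,
                 chrom_sizes: Optional[dict] = None, workers: int = 1,
                 optimize: bool = True):
        self.catalog = catalog or Catalog()
        self.chrom_sizes = chrom_sizes or {}
        self.workers = max(1, workers)
        self.engine = Engine(self.catalog, self.chrom_sizes,
                             optimize=optimize)

    # -- public API ---------------------------------------------------
    def run(self, text: str):
        stmts = parse_script(text)
        diags = check_script(stmts, self.catalog, self.chrom_sizes)
        if diags:
            raise ValidationError(
                "query rejected:\n" + "\n".join(str(d) for d in diags)
            )
        result = None
        for stmt in stmts:
            result = self.run_statement(stmt)
        return result

    def run_statement(self, stmt):
        if isinstance(stmt, RegQuery):
            return self.engine.execute_query(stmt)
        if isinstance(stmt, CreateTrack):
            schema = TrackSchema(stmt.schema)
            self.catalog.add(Track(stmt.name, [], schema=schema))
            return None
        if isinstance(stmt, CreateTrackAs):
            table = self.engine.execute_query(stmt.query)
            track = table.to_track(stmt.name)
            violations = validate_track(track)
            if violations:
                raise ValidationError(
                    f"CREATE TRACK {stmt.name}: " + "; ".join(violations)
                )
            self.catalog.add(track)
            return track
        if isinstance(stmt, DropTrack):
            self.catalog.drop(stmt.name)
            return None
        if isinstance(stmt, LoadData):
            return self._load_data(stmt)
        if isinstance(stmt, ForLoop):
            return self.run_for_loop(stmt)
        raise ExecutionError(f"cannot execute {type(stmt).__name__}")

    def _load_data(self, stmt: LoadData):
        from .trackio import read_track

        track = self.catalog.get(stmt.track)
        loaded = read_track(stmt.path, name=stmt.track)
        if stmt.overwrite:
            track.intervals = list(loaded.intervals)
        else:
            track.intervals.extend(loaded.intervals)
        return None

    def run_for_loop(self, loop: ForLoop):
        conditions = [(a, op, v) for a, op, v in loop.conditions]
        selected = self.catalog.select(loop.category, conditions)
        if loop.form == "union":
            parts = []
            for track in selected:
                table = self._run_loop_body(loop.body, loop.var, track)
                parts.append(table.to_track(loop.output))
            if parts:
                out = parts[0]
                for p in parts[1:]:
                    out = operators.union_all(out, p)
                out.name = loop.output
            else:
                out = Track(loop.output, [], schema=TrackSchema.default())
            self.catalog.add(out, replace=True)
            return out
        # per-track form: CREATE TRACK <name><track-name> AS ...
        created = []
        for track in selected:
            table = self._run_loop_body(loop.body.query, loop.var, track)
            name = loop.body.name + track.name
            out = table.to_track(name)
            self.catalog.add(out, replace=True)
            created.append(out)
        return created

    def _run_loop_body(self, body: RegQuery, var: str,
                       track: Track) -> ResultTable:
        overlay = Catalog()
        for name in self.catalog.track_names:
            overlay.add(self.catalog.get(name))
        bound = Track(var, track.intervals, schema=track.schema)
        overlay.add(bound, replace=True)
        eng = Engine(overlay, self.chrom_sizes,
                     optimize=self.engine.optimize)
        return eng.execute_query(body)


def execute(stmt, catalog: Catalog, chrom_sizes: Optional[dict] = None):
    """One-shot statement execution against a catalog."""
    session = Session(catalog, chrom_sizes)
    return session.run_statement(stmt)
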