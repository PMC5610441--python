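"""Pre-execution validation of parsed statements.

Run immediately after parsing, before any execution: resolves track
names against the catalog (and against tracks earlier statements of the
same script will create), attribute references against schemas, value
derivation applicability, and the SQL grouping rule.  All problems are
returned as diagnostics; nothing executes if any are present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .ast_nodes import (
    AggFunc, AndPred, AttrRef, BinOp, BinsSource, ClosestPred, Comparison,
    ConstIntervalNode, CreateTrack, CreateTrackAs, DistanceFunc, DropTrack,
    ForLoop, LengthFunc, LoadData, LocationComp, NotPred, Num, OrPred,
    PatternMatch, RawTrack, RegQuery, Str, SubquerySource, TransformSource,
    UnionSource, OverlapJoinSource,
)
from .model import Catalog, TrackSchema, ValidationError
from .values import check_vd_applicable


@dataclass
class Diagnostic:
    message: str
    pos: tuple[int, int] = (0, 0)

    def __str__(self) -> str:
        line, col = self.pos
        loc = f"line {line}, column {col}: " if line else ""
        return loc + self.message


_OP_NAME = {"coalesce": "coalesce", "discretize": "discretize",
            "project": "project", "intersectjoin": "intersectjoin",
            "exclusivejoin": "exclusivejoin"}


class _Checker:
    def __init__(self, catalog: Catalog, chrom_sizes: Optional[dict],
                 extra_schemas: Optional[dict] = None):
        self.catalog = catalog
        self.chrom_sizes = chrom_sizes or {}
        # tracks promised by earlier CTAS statements of the same script
        self.extra_schemas: dict[str, TrackSchema] = dict(extra_schemas or {})
        self.diags: list[Diagnostic] = []
        self.in_for_loop = False

    def diag(self, message: str, pos=(0, 0)) -> None:
        self.diags.append(Diagnostic(message, pos))

    def schema_of_name(self, name: str) -> Optional[TrackSchema]:
        if name in self.extra_schemas:
            return self.extra_schemas[name]
        if name in self.catalog:
            return self.catalog.get(name).schema
        return None

    # -- statements ---------------------------------------------------
    def check_statement(self, stmt) -> None:
        if isinstance(stmt, RegQuery):
            self.check_query(stmt)
        elif isinstance(stmt, CreateTrack):
            if stmt.name in self.catalog or stmt.name in self.extra_schemas:
                self.diag(f"track {stmt.name!r} already exists", stmt.pos)
            self.extra_schemas[stmt.name] = TrackSchema(stmt.schema)
        elif isinstance(stmt, CreateTrackAs):
            schema = self.check_query(stmt.query)
            if stmt.name in self.catalog or stmt.name in self.extra_schemas:
                self.diag(f"track {stmt.name!r} already exists", stmt.pos)
            if schema is not None and not schema.is_valid_signal_track():
                self.diag(
                    f"result of CREATE TRACK {stmt.name} AS ... is not a "
                    "valid signal track (missing mandatory attributes)",
                    stmt.pos,
                )
            self.extra_schemas[stmt.name] = schema or TrackSchema.default()
        elif isinstance(stmt, DropTrack):
            if stmt.name in self.extra_schemas:
                del self.extra_schemas[stmt.name]
            elif stmt.name not in self.catalog:
                self.diag(f"cannot drop unknown track {stmt.name!r}", stmt.pos)
        elif isinstance(stmt, LoadData):
            if stmt.track not in self.catalog \
                    and stmt.track not in self.extra_schemas:
                self.diag(f"LOAD DATA into unknown track {stmt.track!r}",
                          stmt.pos)
        elif isinstance(stmt, ForLoop):
            self.check_for_loop(stmt)
        else:
            self.diag(f"unknown statement {type(stmt).__name__}")

    def check_for_loop(self, loop: ForLoop) -> None:
        if self.in_for_loop:
            self.diag("nested FOR TRACK IN statements are not supported",
                      loop.pos)
            return
        if loop.category not in self.catalog.categories:
            self.diag(f"unknown track category {loop.category!r}", loop.pos)
        self.in_for_loop = True
        # the loop variable stands for one selected track; its schema is
        # not known statically, assume the mandatory four
        self.extra_schemas[loop.var] = TrackSchema.default()
        try:
            if isinstance(loop.body, CreateTrackAs):
                self.check_query(loop.body.query)
            else:
                self.check_query(loop.body)
        finally:
            self.in_for_loop = False
            self.extra_schemas.pop(loop.var, None)

    # -- sources ------------------------------------------------------
    def source_alias(self, src) -> str:
        if isinstance(src, RawTrack):
            return src.alias or src.name
        if isinstance(src, (SubquerySource, UnionSource)):
            return src.alias
        return src.alias or _OP_NAME.get(getattr(src, "op", ""), "_anon")

    def source_schema(self, src) -> Optional[TrackSchema]:
        if isinstance(src, RawTrack):
            schema = self.schema_of_name(src.name)
            if schema is None:
                self.diag(f"unknown track {src.name!r}", src.pos)
            return schema
        if isinstance(src, TransformSource):
            self.source_schema(src.track)
            self._check_vd(src.op, src.value_clause, src.pos)
            if src.value_clause.metadata:
                self.diag(f"{src.op} does not inherit metadata", src.pos)
            return TrackSchema.default()
        if isinstance(src, OverlapJoinSource):
            left = self.source_schema(src.left)
            if isinstance(src.right, BinsSource):
                if src.op != "project":
                    self.diag("generated bins may only appear in project on",
                              src.pos)
                if not self.chrom_sizes:
                    self.diag(
                        "generate bins requires a chromosome-sizes file",
                        src.right.pos,
                    )
                right = TrackSchema.default()
            else:
                right = self.source_schema(src.right)
            self._check_vd(src.op, src.value_clause, src.pos)
            extra = ()
            if src.value_clause.metadata:
                donor = right if src.op == "project" else left
                if donor is not None:
                    extra = [(n, donor.type_of(n)) for n in donor.extra_names]
            return TrackSchema.default(extra)
        if isinstance(src, SubquerySource):
            schema = self.check_query(src.query)
            if schema is not None and not schema.is_valid_signal_track():
                self.diag(
                    f"subquery {src.alias!r} does not produce a valid "
                    "signal track (missing mandatory attributes)",
                    src.pos,
                )
            return schema
        if isinstance(src, UnionSource):
            schemas = [self.source_schema(t) for t in src.tracks]
            known = [s for s in schemas if s is not None]
            for s in known[1:]:
                if s != known[0]:
                    self.diag(
                        "UNION ALL operands have different schemas", src.pos
                    )
                    break
            return known[0] if known else None
        self.diag(f"unknown FROM source {type(src).__name__}", src.pos)
        return None

    def _check_vd(self, op, vc, pos) -> None:
        try:
            check_vd_applicable(op, vc.vd)
        except ValidationError as exc:
            self.diag(str(exc), pos)

    # -- queries ------------------------------------------------------
    def check_query(self, q: RegQuery) -> Optional[TrackSchema]:
        env: list[tuple[str, Optional[TrackSchema]]] = []
        for src in q.sources:
            schema = self.source_schema(src)
            alias = self.source_alias(src)
            if any(a == alias for a, _s in env):
                self.diag(f"duplicate track alias {alias!r}", q.pos)
            env.append((alias, schema))
        if q.join_kind and len(q.sources) != 2:
            self.diag(f"{q.join_kind.upper()} JOIN requires exactly two "
                      "tracks", q.pos)

        if q.where is not None:
            self.check_pred(q.where, env, q)
        for attr in q.groupby + q.orderby:
            self.check_attr(attr, env)

        has_agg = False
        if q.items != "*":
            has_agg = any(self._contains_agg(it.expr) for it in q.items)
            for it in q.items:
                self.check_expr(it.expr, env)
        if q.groupby or has_agg:
            if q.items == "*":
                self.diag("SELECT * cannot be combined with GROUP BY or "
                          "aggregates", q.pos)
            else:
                keys = {(a.track, a.attr) for a in q.groupby}
                bare = {(None, a.attr) for a in q.groupby}
                for it in q.items:
                    if self._contains_agg(it.expr):
                        continue
                    refs = self._attr_refs(it.expr)
                    for r in refs:
                        if (r.track, r.attr) not in keys \
                                and (None, r.attr) not in bare \
                                and (r.track, r.attr) not in (
                                    {(None, a.attr) for a in q.groupby}):
                            self.diag(
                                f"attribute {r.attr!r} must appear in "
                                "GROUP BY or inside an aggregate", r.pos
                            )
        return self._output_schema(q, env)

    # -- expressions / predicates ------------------------------------
    def _contains_agg(self, expr) -> bool:
        if isinstance(expr, AggFunc):
            return True
        if isinstance(expr, BinOp):
            return self._contains_agg(expr.left) or \
                self._contains_agg(expr.right)
        return False

    def _attr_refs(self, expr) -> list[AttrRef]:
        if isinstance(expr, AttrRef):
            return [expr]
        if isinstance(expr, BinOp):
            return self._attr_refs(expr.left) + self._attr_refs(expr.right)
        return []

    def check_attr(self, attr: AttrRef, env) -> None:
        if attr.track is not None:
            for alias, schema in env:
                if alias == attr.track:
                    if schema is not None and not schema.has(attr.attr):
                        self.diag(
                            f"track {attr.track!r} has no attribute "
                            f"{attr.attr!r}", attr.pos
                        )
                    return
            self.diag(f"unknown track {attr.track!r} in attribute reference",
                      attr.pos)
            return
        owners = [alias for alias, schema in env
                  if schema is not None and schema.has(attr.attr)]
        if len(owners) > 1:
            self.diag(
                f"ambiguous attribute {attr.attr!r} (defined in "
                f"{', '.join(owners)})", attr.pos
            )
        elif not owners and all(s is not None for _a, s in env):
            self.diag(f"unknown attribute {attr.attr!r}", attr.pos)

    def check_expr(self, expr, env) -> None:
        if isinstance(expr, AttrRef):
            self.check_attr(expr, env)
        elif isinstance(expr, BinOp):
            self.check_expr(expr.left, env)
            self.check_expr(expr.right, env)
        elif isinstance(expr, (LengthFunc,)):
            self._check_track_operand(expr.target, env, expr.pos)
        elif isinstance(expr, DistanceFunc):
            self._check_track_operand(expr.left, env, expr.pos)
            self._check_track_operand(expr.right, env, expr.pos)
        elif isinstance(expr, AggFunc):
            if expr.arg is not None:
                self.check_attr(expr.arg, env)
        # Num: nothing to check

    def _check_track_operand(self, operand, env, pos) -> None:
        if isinstance(operand, ConstIntervalNode):
            return
        if not any(alias == operand for alias, _s in env):
            self.diag(f"unknown track {operand!r}", pos)

    def check_pred(self, pred, env, q) -> None:
        if isinstance(pred, (AndPred, OrPred)):
            for op in pred.operands:
                self.check_pred(op, env, q)
        elif isinstance(pred, NotPred):
            self.check_pred(pred.operand, env, q)
        elif isinstance(pred, Comparison):
            self.check_expr(pred.left, env)
            self.check_expr(pred.right, env)
        elif isinstance(pred, LocationComp):
            self._check_track_operand(pred.left, env, pred.pos)
            self._check_track_operand(pred.right, env, pred.pos)
        elif isinstance(pred, PatternMatch):
            self.check_attr(pred.attr, env)
        elif isinstance(pred, ClosestPred):
            if len(q.sources) != 2:
                self.diag("IS CLOSEST TO EACH requires exactly two FROM "
                          "tracks", pred.pos)
            self._check_track_operand(pred.left, env, pred.pos)
            self._check_track_operand(pred.right, env, pred.pos)

    # -- output schema -------------------------------------------------
    def _output_schema(self, q: RegQuery, env) -> Optional[TrackSchema]:
        if q.items == "*":
            if any(s is None for _a, s in env):
                return None
            attrs = []
            used = set()
            for k, (alias, schema) in enumerate(env):
                for n, t in schema.attributes:
                    name = n if k == 0 else f"{alias}_{n}"
                    if name in used:
                        name = f"{alias}_{n}_{k}"
                    used.add(name)
                    attrs.append((name, t))
            try:
                return TrackSchema(attrs)
            except ValueError:
                return None
        attrs = []
        used = set()
        for idx, it in enumerate(q.items):
            name = it.alias or self._default_name(it.expr, idx)
            if name in used:
                name = f"{name}_{idx}"
            used.add(name)
            attrs.append((name, self._expr_type(it.expr, env)))
        try:
            return TrackSchema(attrs)
        except ValueError:
            return None

    def _default_name(self, expr, idx: int) -> str:
        if isinstance(expr, AttrRef):
            return expr.attr
        if isinstance(expr, LengthFunc):
            return "length"
        if isinstance(expr, DistanceFunc):
            return "distance"
        if isinstance(expr, AggFunc):
            base = expr.fn
            if expr.arg is None:
                return f"{base}_all"
            return f"{base}_{expr.arg.attr}"
        return f"c{idx}"

    def _expr_type(self, expr, env) -> str:
        if isinstance(expr, Str):
            return "string"
        if isinstance(expr, Num):
            return "float"
        if isinstance(expr, AttrRef):
            for _alias, schema in env:
                if schema is not None and schema.has(expr.attr):
                    return schema.type_of(expr.attr) or "float"
            return "float"
        if isinstance(expr, LengthFunc):
            return "int"
        if isinstance(expr, AggFunc) and expr.fn == "count":
            return "int"
        return "float"


def check(stmt, catalog: Catalog,
          chrom_sizes: Optional[dict] = None) -> list[Diagnostic]:
    """Validate one statement; returns diagnostics (empty list = ok)."""
    ck = _Checker(catalog, chrom_sizes)
    ck.check_statement(stmt)
    return ck.diags


def check_script(stmts, catalog: Catalog,
                 chrom_sizes: Optional[dict] = None) -> list[Diagnostic]:
    """Validate a statement sequence, letting later statements see the
    tracks earlier CTAS/CREATE statements will produce."""
    ck = _Checker(catalog, chrom_sizes)
    for stmt in stmts:
        ck.check_statement(stmt)
    return ck.diags
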