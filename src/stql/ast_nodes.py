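"""AST node types produced by the STQL parser.

Every node carries its source position (line, column) for diagnostics;
positions are excluded from structural equality so that canonicalized
text round-trips to an equal tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

Pos = tuple[int, int]


def _pos_field():
    return field(default=(0, 0), compare=False, repr=False)


# --------------------------------------------------------------------
# expressions
@dataclass
class Num:
    value: float
    pos: Pos = _pos_field()


@dataclass
class Str:
    value: str
    pos: Pos = _pos_field()


@dataclass
class AttrRef:
    track: Optional[str]  # alias/track qualifier, None if unqualified
    attr: str
    pos: Pos = _pos_field()


@dataclass
class BinOp:
    op: str  # + - * /
    left: "Expr"
    right: "Expr"
    pos: Pos = _pos_field()


@dataclass
class ConstIntervalNode:
    chr: str
    chrstart: int
    chrend: int
    strand: Optional[str] = None
    pos: Pos = _pos_field()


@dataclass
class LengthFunc:
    target: Union[str, ConstIntervalNode]  # track name or constant interval
    pos: Pos = _pos_field()


@dataclass
class DistanceFunc:
    left: Union[str, ConstIntervalNode]
    right: Union[str, ConstIntervalNode]
    pos: Pos = _pos_field()


@dataclass
class AggFunc:
    fn: str  # count sum avg min max
    arg: Union[AttrRef, str, None]  # None/'*' for COUNT(*)
    pos: Pos = _pos_field()


Expr = Union[Num, Str, AttrRef, BinOp, LengthFunc, DistanceFunc, AggFunc]


# --------------------------------------------------------------------
# predicates
@dataclass
class Comparison:
    op: str  # < = != > <= >=
    left: Expr
    right: Expr
    pos: Pos = _pos_field()


@dataclass
class LocationComp:
    left: Union[str, ConstIntervalNode]
    rel: str  # one of the eleven relation names
    right: Union[str, ConstIntervalNode]
    pos: Pos = _pos_field()


@dataclass
class PatternMatch:
    attr: AttrRef
    pattern: str
    negated: bool = False
    pos: Pos = _pos_field()


@dataclass
class NotPred:
    operand: "Pred"
    pos: Pos = _pos_field()


@dataclass
class AndPred:
    operands: list
    pos: Pos = _pos_field()


@dataclass
class OrPred:
    operands: list
    pos: Pos = _pos_field()


@dataclass
class ClosestPred:
    left: str  # track whose intervals are candidates
    right: str  # anchor track ("closest to each" of these)
    pos: Pos = _pos_field()


Pred = Union[Comparison, LocationComp, PatternMatch, NotPred, AndPred,
             OrPred, ClosestPred]


# --------------------------------------------------------------------
# FROM sources
@dataclass
class ValueClause:
    vd: Optional[str] = None  # vd_sum ...
    model: Optional[str] = None  # each | total (normalized)
    metadata: bool = False


@dataclass
class RawTrack:
    name: str
    category: Optional[str] = None
    alias: Optional[str] = None
    as_kw: bool = False  # whether 'AS' appeared before the alias
    pos: Pos = _pos_field()


@dataclass
class BinsSource:
    bin_size: int
    pos: Pos = _pos_field()


@dataclass
class TransformSource:
    op: str  # coalesce | discretize
    track: "TrackSource"
    value_clause: ValueClause = field(default_factory=ValueClause)
    alias: Optional[str] = None
    pos: Pos = _pos_field()


@dataclass
class OverlapJoinSource:
    op: str  # intersectjoin | exclusivejoin | project
    left: "TrackSource"
    right: Union["TrackSource", BinsSource]
    value_clause: ValueClause = field(default_factory=ValueClause)
    alias: Optional[str] = None
    pos: Pos = _pos_field()


@dataclass
class SubquerySource:
    query: "RegQuery"
    alias: str
    pos: Pos = _pos_field()


@dataclass
class UnionSource:
    tracks: list
    alias: str
    pos: Pos = _pos_field()


TrackSource = Union[RawTrack, TransformSource, OverlapJoinSource,
                    SubquerySource, UnionSource]


# --------------------------------------------------------------------
# statements
@dataclass
class SelectItem:
    expr: Expr
    alias: Optional[str] = None
    pos: Pos = _pos_field()


@dataclass
class RegQuery:
    items: Union[list, str]  # list[SelectItem] or '*'
    sources: list  # list[TrackSource]
    distinct: bool = False
    join_kind: Optional[str] = None  # left | right | outer (2 sources)
    where: Optional[Pred] = None
    groupby: list = field(default_factory=list)  # list[AttrRef]
    orderby: list = field(default_factory=list)  # list[AttrRef]
    pos: Pos = _pos_field()


@dataclass
class CreateTrack:
    name: str
    schema: list  # list[(attr, type)]
    pos: Pos = _pos_field()


@dataclass
class CreateTrackAs:
    name: str
    query: RegQuery
    pos: Pos = _pos_field()


@dataclass
class DropTrack:
    name: str
    pos: Pos = _pos_field()


@dataclass
class LoadData:
    path: str
    track: str
    overwrite: bool = False
    pos: Pos = _pos_field()


@dataclass
class ForLoop:
    var: str
    category: str
    conditions: list  # list[(attr, op, value)] with op in {=, LIKE, NOT LIKE}
    body: Union[RegQuery, CreateTrackAs]
    output: Optional[str] = None  # union form output name
    form: str = "union"  # union | per_track
    pos: Pos = _pos_field()


Statement = Union[RegQuery, CreateTrack, CreateTrackAs, DropTrack,
                  LoadData, ForLoop]
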