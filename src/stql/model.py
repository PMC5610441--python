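"""Core data model: genomic intervals, track schemas, tracks and the catalog.

Coordinates are 1-based and both-ends inclusive everywhere inside the
engine; conversion from on-disk conventions (BED/bedGraph are 0-based
half-open) happens exclusively in :mod:`stql.trackio`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

#: the four attributes every signal track must define (case-insensitive)
MANDATORY_ATTRS = ("chr", "chrstart", "chrend", "value")

#: attribute types admitted by CREATE TRACK
DATA_TYPES = ("string", "int", "float")


class StqlError(Exception):
    """Base class for all user-facing errors raised by the engine."""


class CatalogError(StqlError):
    """Unknown track/category or invalid catalog manipulation."""


class ValidationError(StqlError):
    """A statement failed pre-execution validation."""


@dataclass
class GenomicInterval:
    """One interval of a signal track.

    ``chrstart``/``chrend`` are 1-based inclusive genomic positions.
    ``value`` is the numeric signal or ``None`` (NULL).  ``metadata``
    holds any additional per-interval attributes, e.g. ``strand``
    ('+', '-', '.'), a name or a score.
    """

    chr: str
    chrstart: int
    chrend: int
    value: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrstart < 1:
            raise ValueError(f"chrstart must be >= 1, got {self.chrstart}")
        if self.chrend < self.chrstart:
            raise ValueError(
                f"chrend ({self.chrend}) < chrstart ({self.chrstart})"
            )

    @property
    def length(self) -> int:
        return self.chrend - self.chrstart + 1

    @property
    def strand(self) -> str:
        """Strand from metadata; missing strand means '.' (not available)."""
        s = self.metadata.get("strand")
        return s if s in ("+", "-") else "."

    def get(self, attr: str):
        a = attr.lower()
        if a == "chr":
            return self.chr
        if a == "chrstart":
            return self.chrstart
        if a == "chrend":
            return self.chrend
        if a == "value":
            return self.value
        return self.metadata.get(attr)


@dataclass(frozen=True)
class ConstantInterval:
    """A literal interval written ``[chr, start, end]`` in a query."""

    chr: str
    chrstart: int
    chrend: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.chrstart < 1 or self.chrend < self.chrstart:
            raise ValueError("invalid constant interval coordinates")

    @property
    def length(self) -> int:
        return self.chrend - self.chrstart + 1

    @property
    def value(self):
        return None

    def get(self, attr: str):
        a = attr.lower()
        if a == "chr":
            return self.chr
        if a == "chrstart":
            return self.chrstart
        if a == "chrend":
            return self.chrend
        if a == "value":
            return None
        if a == "strand":
            return self.strand
        return None


Interval = Union[GenomicInterval, ConstantInterval]


def interval_length(i: Interval) -> int:
    """Number of genomic locations covered: ``chrend - chrstart + 1``."""
    return i.chrend - i.chrstart + 1


def strand_of(i: Interval) -> str:
    return i.strand


class TrackSchema:
    """Ordered attribute names with types from {string, int, float}.

    The four mandatory names match case-insensitively; a schema lacking
    any of them describes a plain result table, not a signal track.
    """

    def __init__(self, attributes: Sequence[tuple[str, str]]):
        seen = set()
        self.attributes: list[tuple[str, str]] = []
        for name, typ in attributes:
            if typ not in DATA_TYPES:
                raise ValueError(f"unknown data type {typ!r} for {name!r}")
            key = name.lower() if name.lower() in MANDATORY_ATTRS else name
            if key in seen:
                raise ValueError(f"duplicate attribute {name!r}")
            seen.add(key)
            self.attributes.append((name, typ))

    @classmethod
    def default(cls, extra: Sequence[tuple[str, str]] = ()) -> "TrackSchema":
        return cls(
            [("chr", "string"), ("chrstart", "int"), ("chrend", "int"),
             ("value", "float"), *extra]
        )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.attributes]

    def type_of(self, name: str) -> Optional[str]:
        for n, t in self.attributes:
            if n == name or (
                n.lower() in MANDATORY_ATTRS and n.lower() == name.lower()
            ):
                return t
        return None

    def has(self, name: str) -> bool:
        return self.type_of(name) is not None

    @property
    def extra_names(self) -> list[str]:
        return [n for n, _ in self.attributes if n.lower() not in MANDATORY_ATTRS]

    def is_valid_signal_track(self) -> bool:
        lower = {n.lower() for n in self.names}
        return all(m in lower for m in MANDATORY_ATTRS)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackSchema):
            return NotImplemented
        norm = lambda a: [
            (n.lower() if n.lower() in MANDATORY_ATTRS else n, t) for n, t in a
        ]
        return norm(self.attributes) == norm(other.attributes)

    def __repr__(self) -> str:
        inner = ", ".join(f"{n} {t}" for n, t in self.attributes)
        return f"TrackSchema({inner})"


class Track:
    """A named multiset of intervals sharing one schema.

    Intervals may overlap, be adjacent or duplicate each other; operator
    outputs that forbid this (coalesce/discretize) enforce it themselves.
    """

    def __init__(
        self,
        name: str,
        intervals: Iterable[GenomicInterval] = (),
        schema: Optional[TrackSchema] = None,
        category: Optional[str] = None,
        track_attributes: Optional[dict] = None,
    ):
        self.name = name
        self.intervals: list[GenomicInterval] = list(intervals)
        self.schema = schema or TrackSchema.default()
        self.category = category
        self.track_attributes = dict(track_attributes or {})

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chromosomes(self) -> list[str]:
        return sorted({i.chr for i in self.intervals}, key=chrom_sort_key)

    def by_chromosome(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for i in self.intervals:
            out.setdefault(i.chr, []).append(i)
        return out

    def sorted_intervals(self) -> list[GenomicInterval]:
        return sorted(
            self.intervals,
            key=lambda i: (chrom_sort_key(i.chr), i.chrstart, i.chrend),
        )

    def __repr__(self) -> str:
        return f"Track({self.name!r}, {len(self.intervals)} intervals)"


_CHROM_RE = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str):
    """Lexicographic with natural number ordering: chr2 < chr10 < chrX."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in _CHROM_RE.split(chrom)
    )


def validate_track(t: Track) -> list[str]:
    """Diagnostic check; returns a list of violations (empty means ok)."""
    violations: list[str] = []
    if not t.schema.is_valid_signal_track():
        lower = {n.lower() for n in t.schema.names}
        missing = [m for m in MANDATORY_ATTRS if m not in lower]
        violations.append(
            "missing mandatory attributes: " + ", ".join(missing)
        )
    extra = t.schema.extra_names
    for idx, i in enumerate(t.intervals):
        if i.chrstart < 1:
            violations.append(f"interval {idx}: chrstart < 1")
        if i.chrend < i.chrstart:
            violations.append(f"interval {idx}: coordinate order (chrend < chrstart)")
        if i.value is not None and not isinstance(i.value, (int, float)):
            violations.append(f"interval {idx}: non-numeric value {i.value!r}")
        for name in extra:
            typ = t.schema.type_of(name)
            v = i.metadata.get(name)
            if v is None:
                continue
            if typ == "int" and not isinstance(v, int):
                violations.append(f"interval {idx}: attribute {name} not int")
            elif typ == "float" and not isinstance(v, (int, float)):
                violations.append(f"interval {idx}: attribute {name} not float")
            elif typ == "string" and not isinstance(v, str):
                violations.append(f"interval {idx}: attribute {name} not string")
    return violations


def _like_to_regex(pattern: str) -> re.Pattern:
    # SQL LIKE: % = any run, _ = any single char
    out = []
    for ch in pattern:
        if ch == "%":
            out.append(".*")
        elif ch == "_":
            out.append(".")
        else:
            out.append(re.escape(ch))
    return re.compile("^" + "".join(out) + "$", re.DOTALL)


def like_match(value: str, pattern: str) -> bool:
    return bool(_like_to_regex(pattern).match(value))


class Catalog:
    """Registry of tracks, their categories and selection attributes.

    Stands in for the multi-user metastore of a server deployment: a
    single-user, in-process registry, optionally initialized from a YAML
    file (see :func:`stql.trackio.load_catalog`).
    """

    def __init__(self) -> None:
        self._tracks: dict[str, Track] = {}
        self._categories: dict[str, list[str]] = {}

    # -- registration -------------------------------------------------
    def add(self, track: Track, replace: bool = False) -> None:
        if track.name in self._tracks and not replace:
            raise CatalogError(f"track {track.name!r} already exists")
        self._tracks[track.name] = track
        if track.category:
            names = self._categories.setdefault(track.category, [])
            if track.name not in names:
                names.append(track.name)

    def drop(self, name: str) -> None:
        if name not in self._tracks:
            raise CatalogError(f"cannot drop unknown track {name!r}")
        t = self._tracks.pop(name)
        if t.category and name in self._categories.get(t.category, []):
            self._categories[t.category].remove(name)

    # -- lookup -------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._tracks

    def get(self, name: str) -> Track:
        try:
            return self._tracks[name]
        except KeyError:
            raise CatalogError(f"unknown track {name!r}") from None

    @property
    def track_names(self) -> list[str]:
        return sorted(self._tracks)

    @property
    def categories(self) -> list[str]:
        return sorted(self._categories)

    def select(
        self,
        category: str,
        conditions: Sequence[tuple[str, str, str]] = (),
    ) -> list[Track]:
        """Tracks of a category matching every (attr, op, value) condition.

        ``op`` is ``=`` or ``LIKE`` (SQL wildcards ``%`` and ``_``); the
        pseudo-attribute ``name`` matches the track name.  Result is
        ordered lexicographically by track name.
        """
        if category not in self._categories:
            raise CatalogError(f"unknown category {category!r}")
        chosen = []
        for name in sorted(self._categories[category]):
            track = self._tracks[name]
            ok = True
            for attr, op, val in conditions:
                if attr == "name":
                    actual = track.name
                elif attr in track.track_attributes:
                    actual = str(track.track_attributes[attr])
                else:
                    raise CatalogError(
                        f"track selection attribute {attr!r} not defined "
                        f"for track {name!r}"
                    )
                op_u = op.upper()
                if op_u == "=":
                    ok = actual == val
                elif op_u == "LIKE":
                    ok = like_match(actual, val)
                elif op_u == "NOT LIKE":
                    ok = not like_match(actual, val)
                else:
                    raise CatalogError(f"unsupported selection operator {op!r}")
                if not ok:
                    break
            if ok:
                chosen.append(track)
        return chosen


def catalog_select(cat, category, conditions=()):
    """Functional alias for :meth:`Catalog.select`."""
    return cat.select(category, conditions)
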