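"""Positional relations between intervals, distance, and closest pairs.

The eleven relations form a closed set; each is false whenever the two
intervals sit on different chromosomes.  ``is upstream of`` and
``is downstream of`` additionally consult strand: the anchor (second)
interval must have a known strand, and the first interval's strand must
either match it or be unknown ('.').
"""

from __future__ import annotations

import math
from typing import Iterable, Union

from .model import ConstantInterval, GenomicInterval, Track, strand_of

Interval = Union[GenomicInterval, ConstantInterval]

#: relation names exactly as they appear in query text
RELATION_NAMES = (
    "coincides with",
    "overlaps with",
    "contains",
    "is within",
    "is adjacent to",
    "is prefix of",
    "is suffix of",
    "precedes",
    "follows",
    "is upstream of",
    "is downstream of",
)

STRAND_RELATIONS = ("is upstream of", "is downstream of")


def coincides_with(i1: Interval, i2: Interval) -> bool:
    return (
        i1.chr == i2.chr
        and i1.chrstart == i2.chrstart
        and i1.chrend == i2.chrend
    )


def overlaps_with(i1: Interval, i2: Interval) -> bool:
    return (
        i1.chr == i2.chr
        and i1.chrstart <= i2.chrend
        and i1.chrend >= i2.chrstart
    )


def contains(i1: Interval, i2: Interval) -> bool:
    return (
        i1.chr == i2.chr
        and i1.chrstart <= i2.chrstart
        and i1.chrend >= i2.chrend
    )


def is_within(i1: Interval, i2: Interval) -> bool:
    return contains(i2, i1)


def is_adjacent_to(i1: Interval, i2: Interval) -> bool:
    return i1.chr == i2.chr and (
        i1.chrend + 1 == i2.chrstart or i1.chrstart - 1 == i2.chrend
    )


def is_prefix_of(i1: Interval, i2: Interval) -> bool:
    return (
        i1.chr == i2.chr
        and i1.chrstart == i2.chrstart
        and i1.chrend <= i2.chrend
    )


def is_suffix_of(i1: Interval, i2: Interval) -> bool:
    return (
        i1.chr == i2.chr
        and i1.chrstart >= i2.chrstart
        and i1.chrend == i2.chrend
    )


def precedes(i1: Interval, i2: Interval) -> bool:
    return i1.chr == i2.chr and i1.chrend < i2.chrstart


def follows(i1: Interval, i2: Interval) -> bool:
    return i1.chr == i2.chr and i1.chrstart > i2.chrend


def is_upstream_of(i1: Interval, i2: Interval) -> bool:
    if i1.chr != i2.chr:
        return False
    s1, s2 = strand_of(i1), strand_of(i2)
    if s2 == "+" and s1 in ("+", "."):
        return precedes(i1, i2)
    if s2 == "-" and s1 in ("-", "."):
        return follows(i1, i2)
    return False


def is_downstream_of(i1: Interval, i2: Interval) -> bool:
    if i1.chr != i2.chr:
        return False
    s1, s2 = strand_of(i1), strand_of(i2)
    if s2 == "+" and s1 in ("+", "."):
        return follows(i1, i2)
    if s2 == "-" and s1 in ("-", "."):
        return precedes(i1, i2)
    return False


RELATIONS = {
    "coincides with": coincides_with,
    "overlaps with": overlaps_with,
    "contains": contains,
    "is within": is_within,
    "is adjacent to": is_adjacent_to,
    "is prefix of": is_prefix_of,
    "is suffix of": is_suffix_of,
    "precedes": precedes,
    "follows": follows,
    "is upstream of": is_upstream_of,
    "is downstream of": is_downstream_of,
}


def eval_relation(rel: str, i1: Interval, i2: Interval) -> bool:
    """Evaluate one of the eleven named relations."""
    try:
        fn = RELATIONS[rel]
    except KeyError:
        raise ValueError(f"unknown relation {rel!r}") from None
    return fn(i1, i2)


def distance(i1: Interval, i2: Interval) -> float:
    """Gap between two intervals in base pairs.

    0 when they overlap, the gap size otherwise (adjacent intervals are
    at distance 1), NaN across chromosomes.  Symmetric.
    """
    if i1.chr != i2.chr:
        return math.nan
    if i1.chrend < i2.chrstart:  # i1 precedes i2
        return i2.chrstart - i1.chrend
    if i1.chrstart > i2.chrend:  # i1 follows i2
        return i1.chrstart - i2.chrend
    return 0


def closest_pairs(
    t1: Union[Track, Iterable[GenomicInterval]],
    t2: Union[Track, Iterable[GenomicInterval]],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """For each interval of ``t2``, its closest interval(s) in ``t1``.

    Emits every (i1, i2) pair where i1 attains the minimum distance to
    i2 among same-chromosome intervals of t1; ties all survive, and an
    i2 with no same-chromosome partner yields no pair.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for i1 in t1:
        by_chrom.setdefault(i1.chr, []).append(i1)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    for i2 in t2:
        candidates = by_chrom.get(i2.chr)
        if not candidates:
            continue
        dists = [distance(i1, i2) for i1 in candidates]
        best = min(dists)
        pairs.extend(
            (i1, i2) for i1, d in zip(candidates, dists) if d == best
        )
    return pairs
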