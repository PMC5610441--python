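"""Interval-creating track operations.

All six constructs work chromosome by chromosome with sorted sweeps
(the per-chromosome Cartesian product is the semantics, not the
algorithm).  Outputs are returned sorted by (chromosome in natural
order, chrstart, chrend).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .model import (
    GenomicInterval,
    Track,
    TrackSchema,
    ValidationError,
    chrom_sort_key,
)
from .values import ValueModel, check_vd_applicable, derive_values


@dataclass
class BinSpec:
    """Genome tiling into fixed-size bins: [1,s], [s+1,2s], ... per
    chromosome, truncated at the chromosome length."""

    bin_size: int
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValidationError("bin size must be a positive integer")
        if not self.chrom_sizes:
            raise ValidationError(
                "generate bins requires a chromosome-sizes file"
            )

    def n_bins(self, chrom: str) -> int:
        size = self.chrom_sizes[chrom]
        return (size + self.bin_size - 1) // self.bin_size

    def bin_bounds(self, chrom: str, index: int) -> tuple[int, int]:
        start = index * self.bin_size + 1
        end = min((index + 1) * self.bin_size, self.chrom_sizes[chrom])
        return start, end

    def overlapping_bins(self, iv: GenomicInterval) -> range:
        """Indices of bins overlapping an interval, by direct arithmetic
        (bins are never enumerated against intervals pairwise)."""
        first = (iv.chrstart - 1) // self.bin_size
        last = (iv.chrend - 1) // self.bin_size
        return range(first, min(last, self.n_bins(iv.chr) - 1) + 1)


def _sorted_by_chrom(intervals) -> dict[str, list[GenomicInterval]]:
    by: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by.setdefault(iv.chr, []).append(iv)
    for ivs in by.values():
        ivs.sort(key=lambda i: (i.chrstart, i.chrend))
    return by


def _emit(
    name: str,
    operation: str,
    outputs: list[tuple[str, int, int]],
    contributors: list[list[tuple[GenomicInterval, int]]],
    vd: Optional[str],
    model: Optional[ValueModel],
    metadata_sources: Optional[list[Optional[GenomicInterval]]] = None,
    extra_schema: Sequence[tuple[str, str]] = (),
) -> Track:
    order = sorted(
        range(len(outputs)),
        key=lambda k: (
            chrom_sort_key(outputs[k][0]), outputs[k][1], outputs[k][2]
        ),
    )
    values = derive_values(operation, outputs, contributors, vd, model)
    intervals = []
    for k in order:
        chrom, start, end = outputs[k]
        meta = {}
        if metadata_sources is not None and metadata_sources[k] is not None:
            meta = dict(metadata_sources[k].metadata)
        intervals.append(
            GenomicInterval(chrom, start, end, values[k], meta)
        )
    return Track(name, intervals, schema=TrackSchema.default(extra_schema))


def coalesce(
    t: Track,
    vd: Optional[str] = None,
    model: Optional[ValueModel] = None,
    name: str = "coalesced",
) -> Track:
    """Merge each maximal set of transitively overlapping-or-adjacent
    intervals into one interval [min start, max end]."""
    check_vd_applicable("coalesce", vd)
    outputs: list[tuple[str, int, int]] = []
    contributors: list[list[tuple[GenomicInterval, int]]] = []
    for chrom, ivs in _sorted_by_chrom(t).items():
        group: list[GenomicInterval] = []
        hi = None
        for iv in ivs:
            if group and iv.chrstart > hi + 1:
                outputs.append((chrom, group[0].chrstart, hi))
                contributors.append([(g, 1) for g in group])
                group = []
            group.append(iv)
            hi = iv.chrend if hi is None else max(hi, iv.chrend)
        if group:
            outputs.append((chrom, group[0].chrstart, hi))
            contributors.append([(g, 1) for g in group])
    return _emit(name, "coalesce", outputs, contributors, vd, model)


def discretize(
    t: Track,
    vd: Optional[str] = None,
    model: Optional[ValueModel] = None,
    name: str = "discretized",
) -> Track:
    """Split covered regions at every input boundary into non-overlapping
    segments; segments from adjacent inputs stay adjacent."""
    check_vd_applicable("discretize", vd)
    outputs: list[tuple[str, int, int]] = []
    contributors: list[list[tuple[GenomicInterval, int]]] = []
    for chrom, ivs in _sorted_by_chrom(t).items():
        # breakpoints within each coalesced block: starts and ends+1
        cuts = sorted({iv.chrstart for iv in ivs} | {iv.chrend + 1 for iv in ivs})
        for a, b in zip(cuts[:-1], cuts[1:]):
            covering = [iv for iv in ivs if iv.chrstart <= a <= iv.chrend]
            if not covering:
                continue  # gap between blocks
            outputs.append((chrom, a, b - 1))
            contributors.append([(iv, 1) for iv in covering])
    return _emit(name, "discretize", outputs, contributors, vd, model)


def project_on(
    t1: Track,
    target: Union[Track, BinSpec],
    vd: Optional[str] = None,
    model: Optional[ValueModel] = None,
    metadata: bool = False,
    name: str = "projected",
) -> Track:
    """Transfer aggregated values of ``t1`` onto the positions of
    ``target`` intervals (or generated genome bins).

    Targets overlapping nothing get 0 when a value clause is present,
    NULL otherwise.  ``metadata`` inherits the target's attributes (the
    track defining the output positions).
    """
    check_vd_applicable("project", vd)
    outputs: list[tuple[str, int, int]] = []
    contributors: list[list[tuple[GenomicInterval, int]]] = []
    meta_sources: list[Optional[GenomicInterval]] = []
    extra: Sequence[tuple[str, str]] = ()

    if isinstance(target, BinSpec):
        by_chrom = _sorted_by_chrom(t1)
        for chrom in sorted(target.chrom_sizes, key=chrom_sort_key):
            per_bin: dict[int, list[tuple[GenomicInterval, int]]] = {}
            for iv in by_chrom.get(chrom, ()):
                for b in target.overlapping_bins(iv):
                    per_bin.setdefault(b, []).append((iv, 1))
            for b in range(target.n_bins(chrom)):
                start, end = target.bin_bounds(chrom, b)
                outputs.append((chrom, start, end))
                contributors.append(per_bin.get(b, []))
                meta_sources.append(None)
    else:
        if metadata:
            extra = [
                (n, target.schema.type_of(n)) for n in target.schema.extra_names
            ]
        by_chrom = _sorted_by_chrom(t1)
        for tgt in target:
            over = [
                (iv, 1)
                for iv in by_chrom.get(tgt.chr, ())
                if iv.chrstart <= tgt.chrend and iv.chrend >= tgt.chrstart
            ]
            outputs.append((tgt.chr, tgt.chrstart, tgt.chrend))
            contributors.append(over)
            meta_sources.append(tgt if metadata else None)

    return _emit(
        name, "project", outputs, contributors, vd, model,
        metadata_sources=meta_sources if not isinstance(target, BinSpec) else None,
        extra_schema=extra,
    )


def intersectjoin(
    t1: Track,
    t2: Track,
    vd: Optional[str] = None,
    model: Optional[ValueModel] = None,
    metadata: bool = False,
    name: str = "intersected",
) -> Track:
    """One output per overlapping pair: their intersection.  Metadata,
    when requested, is inherited from the first track's member."""
    check_vd_applicable("intersectjoin", vd)
    outputs: list[tuple[str, int, int]] = []
    contributors: list[list[tuple[GenomicInterval, int]]] = []
    meta_sources: list[Optional[GenomicInterval]] = []
    left = _sorted_by_chrom(t1)
    right = _sorted_by_chrom(t2)
    for chrom in left.keys() & right.keys():
        rs = right[chrom]
        for i1 in left[chrom]:
            # rs sorted by start: stop once i2 starts past i1's end
            for i2 in rs:
                if i2.chrstart > i1.chrend:
                    break
                if i2.chrend < i1.chrstart:
                    continue
                outputs.append(
                    (chrom, max(i1.chrstart, i2.chrstart),
                     min(i1.chrend, i2.chrend))
                )
                contributors.append([(i1, 1), (i2, 2)])
                meta_sources.append(i1 if metadata else None)
    extra = ()
    if metadata:
        extra = [(n, t1.schema.type_of(n)) for n in t1.schema.extra_names]
    return _emit(
        name, "intersectjoin", outputs, contributors, vd, model,
        metadata_sources=meta_sources, extra_schema=extra,
    )


def exclusivejoin(
    t1: Track,
    t2: Track,
    vd: Optional[str] = None,
    model: Optional[ValueModel] = None,
    metadata: bool = False,
    name: str = "excluded",
) -> Track:
    """Per first-track interval, the maximal sub-intervals not covered
    by any second-track interval (an interval may vanish, survive whole
    or split)."""
    check_vd_applicable("exclusivejoin", vd)
    outputs: list[tuple[str, int, int]] = []
    contributors: list[list[tuple[GenomicInterval, int]]] = []
    meta_sources: list[Optional[GenomicInterval]] = []
    right = _sorted_by_chrom(t2)
    # merged coverage of t2 per chromosome
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in right.items():
        spans: list[tuple[int, int]] = []
        for iv in ivs:
            if spans and iv.chrstart <= spans[-1][1] + 1:
                spans[-1] = (spans[-1][0], max(spans[-1][1], iv.chrend))
            else:
                spans.append((iv.chrstart, iv.chrend))
        merged[chrom] = spans
    for chrom, ivs in _sorted_by_chrom(t1).items():
        spans = merged.get(chrom, [])
        for i1 in ivs:
            pos = i1.chrstart
            for a, b in spans:
                if b < pos:
                    continue
                if a > i1.chrend:
                    break
                if a > pos:
                    outputs.append((chrom, pos, a - 1))
                    contributors.append([(i1, 1)])
                    meta_sources.append(i1 if metadata else None)
                pos = max(pos, b + 1)
                if pos > i1.chrend:
                    break
            if pos <= i1.chrend:
                outputs.append((chrom, pos, i1.chrend))
                contributors.append([(i1, 1)])
                meta_sources.append(i1 if metadata else None)
    extra = ()
    if metadata:
        extra = [(n, t1.schema.type_of(n)) for n in t1.schema.extra_names]
    return _emit(
        name, "exclusivejoin", outputs, contributors, vd, model,
        metadata_sources=meta_sources, extra_schema=extra,
    )


def union_all(t1: Track, t2: Track, name: str = "unioned") -> Track:
    """Multiset union of two tracks with identical schemas."""
    if t1.schema != t2.schema:
        only1 = [n for n in t1.schema.names if not t2.schema.has(n)]
        only2 = [n for n in t2.schema.names if not t1.schema.has(n)]
        detail = "; ".join(
            f"only in {t.name}: {', '.join(names)}"
            for t, names in ((t1, only1), (t2, only2))
            if names
        ) or "attribute types differ"
        raise ValidationError(f"UNION ALL schema mismatch: {detail}")
    ivs = [
        GenomicInterval(i.chr, i.chrstart, i.chrend, i.value, dict(i.metadata))
        for i in list(t1) + list(t2)
    ]
    return Track(name, ivs, schema=t1.schema)
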