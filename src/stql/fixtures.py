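"""Built-in example tracks and a seeded random-track generator.

``make_fixture_tracks`` reproduces the two worked 3-row tracks used in
the join examples plus parameterized analogues of the operator-figure
geometries (overlap chains, adjacency, containment, full coverage and
split cases), so the whole system is testable without downloads.
``write_fixtures`` dumps them as BED/bedGraph files with a catalog.
"""

from __future__ import annotations

import os

import numpy as np

from .model import Catalog, GenomicInterval, Track
from .trackio import write_track
import yaml


def _gi(chrom, start, end, value=None, **meta):
    return GenomicInterval(chrom, start, end, value, dict(meta))


def make_fixture_tracks() -> dict[str, Track]:
    """The worked example tracks plus operator-figure analogues."""
    tracks: dict[str, Track] = {}

    # the two printed 3-row tracks of the join examples
    tracks["T1"] = Track("T1", [
        _gi("chr1", 101, 200, 10.0),
        _gi("chr1", 201, 300, 20.0),
        _gi("chr2", 301, 400, 30.0),
    ])
    tracks["T2"] = Track("T2", [
        _gi("chr1", 401, 500, 40.0),
        _gi("chr2", 501, 600, 50.0),
        _gi("chr3", 601, 700, 60.0),
    ])

    # coalesce geometry: a transitively-overlapping block of four, an
    # isolated interval, and an overlapping pair
    tracks["fig_coalesce"] = Track("fig_coalesce", [
        _gi("chr1", 101, 150, 1.0),
        _gi("chr1", 131, 180, 2.0),
        _gi("chr1", 181, 230, 3.0),  # adjacent-through-overlap chain
        _gi("chr1", 215, 260, 4.0),
        _gi("chr1", 301, 350, 5.0),  # isolated
        _gi("chr1", 401, 450, 6.0),
        _gi("chr1", 441, 490, 7.0),
    ])

    # discretize geometry: overlap chain plus an adjacent pair whose
    # output segments stay adjacent
    tracks["fig_discretize"] = Track("fig_discretize", [
        _gi("chr1", 101, 150, 1.0),
        _gi("chr1", 131, 180, 2.0),
        _gi("chr1", 301, 350, 3.0),
        _gi("chr1", 351, 400, 4.0),  # adjacent to the previous
    ])

    # project geometry: target 1 covered by two inputs, target 2 by
    # three, target 3 untouched (default value 0)
    tracks["fig_project_t1"] = Track("fig_project_t1", [
        _gi("chr1", 81, 120, 1.0),
        _gi("chr1", 151, 320, 2.0),
        _gi("chr1", 331, 360, 3.0),
        _gi("chr1", 371, 410, 4.0),
    ])
    tracks["fig_project_t2"] = Track("fig_project_t2", [
        _gi("chr1", 101, 200, 1.0),
        _gi("chr1", 301, 400, 1.0),
        _gi("chr1", 501, 600, 1.0),
    ])

    # intersectjoin geometry: one interval of track 1 overlapping two
    # of track 2, one overlapping one, one overlapping none
    tracks["fig_intersect_t1"] = Track("fig_intersect_t1", [
        _gi("chr1", 101, 200, 1.0),
        _gi("chr1", 221, 320, 1.0),
        _gi("chr1", 401, 600, 1.0),
        _gi("chr1", 701, 800, 1.0),
    ])
    tracks["fig_intersect_t2"] = Track("fig_intersect_t2", [
        _gi("chr1", 151, 260, 1.0),
        _gi("chr1", 421, 460, 1.0),
        _gi("chr1", 551, 650, 1.0),
    ])

    # exclusivejoin geometry: survive intact / vanish / trimmed / split
    tracks["fig_exclusive_t1"] = Track("fig_exclusive_t1", [
        _gi("chr1", 101, 200, 1.0),
        _gi("chr1", 301, 400, 2.0),
        _gi("chr1", 411, 500, 3.0),
        _gi("chr1", 541, 660, 4.0),
    ])
    tracks["fig_exclusive_t2"] = Track("fig_exclusive_t2", [
        _gi("chr1", 291, 350, 1.0),
        _gi("chr1", 341, 430, 1.0),
        _gi("chr1", 581, 620, 1.0),
    ])
    return tracks


def make_fixture_catalog() -> Catalog:
    """Catalog with the fixture tracks plus a small peak category for
    track-selection and looping tests (two GM12878 peak tracks match
    the canonical cell/name conditions, two tracks do not)."""
    cat = Catalog()
    for track in make_fixture_tracks().values():
        cat.add(track)
    peaks = [
        ("Gm12878CtcfPk", "GM12878", 5),
        ("Gm12878Rad21Pk", "GM12878", 5),
        ("Gm12878CtcfRaw", "GM12878", 4),
        ("K562CtcfPk", "K562", 6),
    ]
    for k, (name, cell, n) in enumerate(peaks):
        ivs = [
            _gi("chr1", 1000 * (j + 1) + 100 * k + 1,
                1000 * (j + 1) + 100 * k + 200, None)
            for j in range(n)
        ]
        cat.add(Track(name, ivs, category="SYDH TFBS",
                      track_attributes={"cell": cell}))
    return cat


def write_fixtures(directory: str) -> str:
    """Write fixture tracks as BED/bedGraph plus a catalog.yaml; returns
    the catalog path."""
    os.makedirs(directory, exist_ok=True)
    cat = make_fixture_catalog()
    entries = []
    for name in cat.track_names:
        track = cat.get(name)
        has_values = all(iv.value is not None for iv in track.intervals) \
            and len(track) > 0
        fmt = "bedgraph" if has_values else "bed"
        ext = ".bedgraph" if fmt == "bedgraph" else ".bed"
        path = os.path.join(directory, name + ext)
        write_track(track, path, fmt=fmt)
        entry = {"name": name, "path": name + ext, "format": fmt}
        if track.category:
            entry["category"] = track.category
        if track.track_attributes:
            entry["attributes"] = dict(track.track_attributes)
        entries.append(entry)
    sizes_path = os.path.join(directory, "genome.chrom.sizes")
    with open(sizes_path, "w", encoding="utf-8") as fh:
        for chrom, size in (("chr1", 100000), ("chr2", 80000),
                            ("chr3", 60000)):
            fh.write(f"{chrom}\t{size}\n")
    catalog_path = os.path.join(directory, "catalog.yaml")
    with open(catalog_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"tracks": entries}, fh, sort_keys=False)
    return catalog_path


def generate_random_track(
    seed: int,
    n_intervals: int,
    chromosomes: tuple[str, ...] = ("chr1",),
    max_coord: int = 10_000,
    length_dist: tuple = ("uniform", 1, 100),
    value_dist: tuple = ("uniform", 0.0, 10.0),
    overlap_fraction: float = 0.0,
    name: str = "random",
) -> Track:
    """Seed-deterministic pseudo-random track.

    ``length_dist``/``value_dist`` are ('constant', c) or
    ('uniform', lo, hi); lengths are integers.  With probability
    ``overlap_fraction`` each interval after the first is forced to
    overlap the previously generated interval.  Values may be None via
    ('constant', None) to emulate BED input.
    """
    rng = np.random.default_rng(seed)

    def draw_length() -> int:
        kind = length_dist[0]
        if kind == "constant":
            return int(length_dist[1])
        return int(rng.integers(length_dist[1], length_dist[2] + 1))

    def draw_value():
        kind = value_dist[0]
        if kind == "constant":
            v = value_dist[1]
            return None if v is None else float(v)
        return float(
            np.round(rng.uniform(value_dist[1], value_dist[2]), 6)
        )

    max_len = length_dist[1] if length_dist[0] == "constant" \
        else length_dist[2]
    if int(max_len or 1) > max_coord:
        raise ValueError(
            f"max_coord={max_coord} cannot fit intervals of length "
            f"{max_len}"
        )

    intervals: list[GenomicInterval] = []
    prev: GenomicInterval | None = None
    for _k in range(n_intervals):
        length = draw_length()
        if prev is not None and overlap_fraction > 0 \
                and rng.random() < overlap_fraction:
            chrom = prev.chr
            lo = max(1, prev.chrstart - length + 1)
            hi = min(prev.chrend, max_coord - length + 1)
            if hi < lo:
                hi = lo
            start = int(rng.integers(lo, hi + 1))
        else:
            chrom = chromosomes[int(rng.integers(0, len(chromosomes)))]
            start = int(rng.integers(1, max_coord - length + 2))
        iv = GenomicInterval(chrom, start, start + length - 1, draw_value())
        intervals.append(iv)
        prev = iv
    return Track(name, intervals)
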