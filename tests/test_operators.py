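"""Track-creating operators: worked geometries, coverage invariants and
an external bedtools cross-check for intersection geometry."""

import shutil
import subprocess

import pytest

from stql.fixtures import generate_random_track
from stql.model import GenomicInterval, Track, TrackSchema, ValidationError
from stql.operators import (
    BinSpec, coalesce, discretize, exclusivejoin, intersectjoin,
    project_on, union_all,
)
from stql.values import ValueModel


def gi(chrom, s, e, v=None, **meta):
    return GenomicInterval(chrom, s, e, v, dict(meta))


def spans(track):
    return [(iv.chr, iv.chrstart, iv.chrend) for iv in track]


def coverage(intervals):
    out = set()
    for iv in intervals:
        out.update((iv.chr, p) for p in range(iv.chrstart, iv.chrend + 1))
    return out


class TestCoalesce:
    def test_merges_overlap_and_adjacency(self):
        t = Track("t", [gi("chr1", 1, 10), gi("chr1", 5, 12),
                        gi("chr1", 13, 20), gi("chr1", 30, 40)])
        assert spans(coalesce(t)) == [("chr1", 1, 20), ("chr1", 30, 40)]

    def test_isolated_interval_kept(self):
        t = Track("t", [gi("chr1", 301, 350)])
        assert spans(coalesce(t)) == [("chr1", 301, 350)]

    def test_empty_track(self):
        assert len(coalesce(Track("t", []))) == 0

    def test_figure_geometry(self, tracks):
        got = coalesce(tracks["fig_coalesce"])
        assert spans(got) == [("chr1", 101, 260), ("chr1", 301, 350),
                              ("chr1", 401, 490)]

    def test_outputs_never_overlap_or_touch(self):
        t = generate_random_track(7, 40, max_coord=2000,
                                  overlap_fraction=0.6)
        got = coalesce(t)
        ivs = got.sorted_intervals()
        for a, b in zip(ivs[:-1], ivs[1:]):
            if a.chr == b.chr:
                assert b.chrstart > a.chrend + 1
        assert coverage(got) == coverage(t)

    def test_disallowed_vd(self):
        with pytest.raises(ValidationError):
            coalesce(Track("t", []), vd="vd_left")


class TestDiscretize:
    def test_breakpoints_from_both_boundaries(self):
        t = Track("t", [gi("chr1", 1, 10), gi("chr1", 6, 15)])
        assert spans(discretize(t)) == [("chr1", 1, 5), ("chr1", 6, 10),
                                        ("chr1", 11, 15)]

    def test_disjoint_inputs_unchanged(self):
        t = Track("t", [gi("chr1", 1, 10), gi("chr1", 20, 30)])
        assert spans(discretize(t)) == [("chr1", 1, 10), ("chr1", 20, 30)]

    def test_adjacent_inputs_yield_adjacent_outputs(self, tracks):
        got = discretize(tracks["fig_discretize"])
        assert ("chr1", 301, 350) in spans(got)
        assert ("chr1", 351, 400) in spans(got)

    def test_middle_segment_value(self):
        t = Track("t", [gi("chr1", 1, 10, 2.0), gi("chr1", 6, 15, 4.0)])
        got = discretize(t, vd="vd_avg", model=ValueModel.EACH)
        middle = [iv for iv in got if iv.chrstart == 6][0]
        assert middle.value == pytest.approx(3.0)

    def test_coverage_preserved_and_coalesce_identity(self):
        t = generate_random_track(11, 30, max_coord=1500,
                                  overlap_fraction=0.5)
        d = discretize(t)
        assert coverage(d) == coverage(t)
        assert spans(coalesce(d)) == spans(coalesce(t))


class TestProject:
    def test_target_positions_and_total_sum(self):
        t1 = Track("a", [gi("chr1", 1, 10, 5.0)])
        target = Track("b", [gi("chr1", 1, 100, 1.0)])
        got = project_on(t1, target, vd="vd_sum", model=ValueModel.TOTAL)
        assert spans(got) == [("chr1", 1, 100)]
        assert got.intervals[0].value == pytest.approx(0.05)

    def test_untouched_target_gets_zero_with_value_clause(self):
        t1 = Track("a", [gi("chr1", 1, 10, 5.0)])
        target = Track("b", [gi("chr7", 1, 50, 1.0)])
        got = project_on(t1, target, vd="vd_sum", model=ValueModel.EACH)
        assert got.intervals[0].value == 0.0

    def test_untouched_target_null_without_value_clause(self):
        t1 = Track("a", [])
        target = Track("b", [gi("chr7", 1, 50, 1.0)])
        got = project_on(t1, target)
        assert got.intervals[0].value is None

    def test_bins_truncated_at_chromosome_end(self):
        t1 = Track("a", [gi("chr1", 1, 10, 1.0)])
        got = project_on(t1, BinSpec(100, {"chr1": 250}), vd="vd_sum",
                         model=ValueModel.EACH)
        assert spans(got) == [("chr1", 1, 100), ("chr1", 101, 200),
                              ("chr1", 201, 250)]

    def test_bins_need_chrom_sizes(self):
        with pytest.raises(ValidationError):
            BinSpec(100, {})

    def test_metadata_from_target(self):
        t1 = Track("a", [gi("chr1", 1, 10, 5.0)])
        target = Track(
            "b", [gi("chr1", 5, 20, 1.0, gene="FGF19")],
            schema=TrackSchema.default([("gene", "string")]),
        )
        got = project_on(t1, target, vd="vd_sum", model=ValueModel.EACH,
                         metadata=True)
        assert got.intervals[0].metadata["gene"] == "FGF19"
        assert got.schema.has("gene")


class TestIntersectJoin:
    def test_unit_overlap_each_sum(self):
        a = Track("a", [gi("chr1", 1, 10, 1.0)])
        b = Track("b", [gi("chr1", 6, 15, 1.0)])
        got = intersectjoin(a, b, vd="vd_sum", model=ValueModel.EACH)
        assert spans(got) == [("chr1", 6, 10)]
        assert got.intervals[0].value == 2.0

    def test_non_overlapping_produces_nothing(self):
        a = Track("a", [gi("chr1", 1, 10, 1.0)])
        b = Track("b", [gi("chr1", 20, 30, 1.0)])
        assert len(intersectjoin(a, b)) == 0

    def test_one_to_many_pairs(self):
        a = Track("a", [gi("chr1", 1, 20, 1.0)])
        b = Track("b", [gi("chr1", 1, 5, 1.0), gi("chr1", 10, 12, 1.0)])
        assert spans(intersectjoin(a, b)) == [("chr1", 1, 5),
                                              ("chr1", 10, 12)]

    def test_figure_geometry_counts(self, tracks):
        got = intersectjoin(tracks["fig_intersect_t1"],
                            tracks["fig_intersect_t2"])
        assert spans(got) == [("chr1", 151, 200), ("chr1", 221, 260),
                              ("chr1", 421, 460), ("chr1", 551, 600)]

    def test_metadata_from_first_track(self):
        a = Track("a", [gi("chr1", 1, 10, 1.0, name="peak1")],
                  schema=TrackSchema.default([("name", "string")]))
        b = Track("b", [gi("chr1", 5, 20, 1.0, name="other")],
                  schema=TrackSchema.default([("name", "string")]))
        got = intersectjoin(a, b, metadata=True)
        assert got.intervals[0].metadata["name"] == "peak1"

    def test_self_join_reproduces_geometry(self):
        t = Track("t", [gi("chr1", 1, 10, 1.0), gi("chr1", 20, 30, 2.0)])
        assert spans(intersectjoin(t, t)) == spans(t)

    def test_coverage_is_intersection(self):
        a = generate_random_track(3, 25, max_coord=1000, overlap_fraction=0.3)
        b = generate_random_track(4, 25, max_coord=1000, overlap_fraction=0.3)
        got = intersectjoin(a, b)
        assert coverage(got) == coverage(a) & coverage(b)


class TestExclusiveJoin:
    def test_split_by_covering_interval(self):
        a = Track("a", [gi("chr1", 1, 20, 1.0)])
        b = Track("b", [gi("chr1", 8, 12, 1.0)])
        assert spans(exclusivejoin(a, b)) == [("chr1", 1, 7),
                                              ("chr1", 13, 20)]

    def test_fully_covered_vanishes(self):
        a = Track("a", [gi("chr1", 5, 10, 1.0)])
        b = Track("b", [gi("chr1", 1, 6, 1.0), gi("chr1", 7, 15, 1.0)])
        assert len(exclusivejoin(a, b)) == 0

    def test_untouched_survives(self):
        a = Track("a", [gi("chr1", 1, 10, 1.0)])
        b = Track("b", [gi("chr2", 1, 10, 1.0)])
        assert spans(exclusivejoin(a, b)) == [("chr1", 1, 10)]

    def test_figure_geometry(self, tracks):
        got = exclusivejoin(tracks["fig_exclusive_t1"],
                            tracks["fig_exclusive_t2"])
        assert spans(got) == [("chr1", 101, 200), ("chr1", 431, 500),
                              ("chr1", 541, 580), ("chr1", 621, 660)]

    def test_only_vd_left_allowed(self):
        a = Track("a", [gi("chr1", 1, 10, 1.0)])
        with pytest.raises(ValidationError):
            exclusivejoin(a, a, vd="vd_sum")

    def test_self_subtraction_empty_and_coverage_law(self):
        t = generate_random_track(5, 20, max_coord=800, overlap_fraction=0.4)
        assert len(exclusivejoin(t, t)) == 0
        other = generate_random_track(6, 20, max_coord=800)
        got = exclusivejoin(t, other)
        assert coverage(got) == coverage(t) - coverage(other)


class TestUnionAll:
    def test_multiset_union(self, tracks):
        got = union_all(tracks["T1"], tracks["T2"])
        assert len(got) == 6

    def test_identity_and_duplication(self, tracks):
        t = tracks["T1"]
        assert len(union_all(t, Track("e", [], schema=t.schema))) == len(t)
        doubled = union_all(t, t)
        assert len(doubled) == 2 * len(t)

    def test_schema_mismatch_rejected(self, tracks):
        other = Track("o", [], schema=TrackSchema.default([("x", "int")]))
        with pytest.raises(ValidationError) as err:
            union_all(tracks["T1"], other)
        assert "x" in str(err.value)


@pytest.mark.skipif(shutil.which("bedtools") is None,
                    reason="bedtools not on PATH")
def test_intersect_geometry_matches_bedtools(tmp_path):
    """Independent cross-check of pairwise intersection geometry."""
    a = generate_random_track(21, 30, max_coord=5000, overlap_fraction=0.4)
    b = generate_random_track(22, 30, max_coord=5000, overlap_fraction=0.4)

    def to_bed(track, path):
        with open(path, "w") as fh:
            for iv in track.sorted_intervals():
                fh.write(f"{iv.chr}\t{iv.chrstart - 1}\t{iv.chrend}\n")

    pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
    to_bed(a, pa)
    to_bed(b, pb)
    out = subprocess.run(
        ["bedtools", "intersect", "-a", pa, "-b", pb],
        capture_output=True, text=True, check=True,
    ).stdout
    expected = sorted(
        (c, int(s) + 1, int(e))
        for c, s, e in (line.split("\t") for line in out.splitlines())
    )
    got = sorted(spans(intersectjoin(a, b)))
    assert got == expected
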