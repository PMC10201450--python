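"""Region algebra: exclusions, strand-specific merging, length statistics."""

import numpy as np
import pytest

from g4bulge.core import Interval
from g4bulge.regions import (
    exclude_repeats,
    exclude_vs_canonical,
    ks_two_sample,
    length_stats,
    merge_regions,
)
from g4bulge.scan import scan_bulged, scan_canonical


def iv(start, end, strand="+", chrom="chr1", name="."):
    return Interval(chrom, start, end, strand, name)


class TestExcludeVsCanonical:
    def test_one_nt_same_strand_overlap_removes(self):
        bs = [iv(100, 120, "+")]
        assert exclude_vs_canonical(bs, [iv(119, 140, "+")]) == []

    def test_opposite_strand_overlap_keeps(self):
        bs = [iv(100, 120, "+")]
        assert exclude_vs_canonical(bs, [iv(119, 140, "-")]) == bs

    def test_disjoint_is_identity(self):
        bs = [iv(100, 120, "+")]
        assert exclude_vs_canonical(bs, [iv(500, 540, "+")]) == bs

    def test_canonical_core_removed(self):
        # a hit whose core is itself a full canonical match is dropped even
        # without an overlapping canonical hit in the other set
        core = "GGGGAGGGAGGGAGGG"
        assert scan_canonical(core)[0].end == len(core)

        class Stub:
            chrom, start, end, strand = "chr1", 0, len(core), "+"
            core_seq = core

        assert exclude_vs_canonical([Stub()], []) == []


class TestExcludeRepeats:
    def test_hit_inside_repeat_removed(self):
        assert exclude_repeats([iv(10, 30)], [iv(0, 100, ".")]) == []

    def test_bookended_kept(self):
        hits = [iv(10, 30)]
        assert exclude_repeats(hits, [iv(30, 60, ".")]) == hits

    def test_strand_blind(self):
        assert exclude_repeats([iv(10, 30, "+")], [iv(20, 25, "-")]) == []

    def test_empty_track_identity(self):
        hits = [iv(10, 30)]
        assert exclude_repeats(hits, []) == hits


class TestMerge:
    def test_overlap_merges(self):
        regions = merge_regions([iv(10, 30, "+"), iv(25, 45, "+")])
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.strand, r.n_members) == (10, 45, "+", 2)

    def test_strands_separate(self):
        assert len(merge_regions([iv(10, 30, "+"), iv(25, 45, "-")])) == 2

    def test_bookended_not_merged(self):
        assert len(merge_regions([iv(10, 30, "+"), iv(30, 45, "+")])) == 2

    def test_idempotent_and_base_conserving(self, rng):
        hits = [
            iv(int(s), int(s) + int(l), "+" if rng.random() < 0.5 else "-")
            for s, l in zip(
                rng.integers(0, 5000, 300), rng.integers(5, 60, 300)
            )
        ]
        once = merge_regions(hits)
        twice = merge_regions(once)
        assert [(r.start, r.end, r.strand) for r in once] == [
            (r.start, r.end, r.strand) for r in twice
        ]
        # covered bases per strand conserved
        for strand in "+-":
            covered = set()
            for h in hits:
                if h.strand == strand:
                    covered.update(range(h.start, h.end))
            merged_covered = set()
            for r in once:
                if r.strand == strand:
                    merged_covered.update(range(r.start, r.end))
            assert covered == merged_covered

    def test_member_models_recorded(self):
        hits = scan_bulged("TAGAGGCGGGAGTGGAGGGCG", chrom="chr1")
        regions = merge_regions(hits)
        assert regions[0].models == ("G2B2",)


class TestLengthStats:
    def test_basic(self):
        st = length_stats([iv(0, 20), iv(100, 120), iv(200, 225)])
        assert st.mean == pytest.approx(21.667, abs=1e-3)
        assert st.median == 20
        assert st.mode == 20
        assert sum(st.histogram.values()) == pytest.approx(1)

    def test_single_item_sd_zero(self):
        assert length_stats([iv(0, 10)]).sd == 0

    def test_even_median_midpoint_and_mode_tiebreak(self):
        st = length_stats([iv(0, 19), iv(0, 21)])
        assert st.median == 20
        assert st.mode == 19  # tie broken toward the smaller length

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            length_stats([])


class TestKS:
    def test_identical_zero(self):
        d, _ = ks_two_sample([5, 6, 7], [5, 6, 7])
        assert d == 0

    def test_disjoint_one(self):
        d, p = ks_two_sample([10] * 5, [20] * 5)
        assert d == 1 and p < 0.05

    def test_derived_ecdf_sweep(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_subsample_seeded(self):
        x = list(range(100))
        y = list(range(50, 150))
        a = ks_two_sample(x, y, sample_n=30, seed=5)
        b = ks_two_sample(x, y, sample_n=30, seed=5)
        assert a == b
        with pytest.raises(ValueError):
            ks_two_sample(x, y, sample_n=1000, seed=5)


def test_pipeline_identity_without_confounders(small_planted):
    """With no repeats and no same-strand canonical overlap, the exclusion
    steps are the identity and merging only consolidates overlaps."""
    genome, truth = small_planted
    from g4bulge.scan import scan_genome

    bs = scan_genome(genome, "BS")
    cs = scan_genome(genome, "CS")
    kept = exclude_repeats(exclude_vs_canonical(bs, cs), [])
    assert set(kept) <= set(bs)
    regions = merge_regions(kept)
    assert sum(r.n_members for r in regions) == len(kept)
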