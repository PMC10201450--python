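"""Gene segments, unique assignment, strand architecture, profiles."""

import numpy as np
import pytest

from g4bulge.annotate import (
    anchored_profile,
    assign_unique,
    build_segments,
    counts_per_gene,
    find_bf_genes,
    flag_regulatory,
    gene_counts,
    proportion_ratio,
)
from g4bulge.core import Interval
from g4bulge.io import GeneModel


def gene(gene_id="g1", chrom="chr1", start=5000, end=8000, strand="+",
         exons=None, cds=(None, None)):
    exons = exons or ((start, end),)
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds[0],
        cds_end=cds[1],
    )


def iv(start, end, strand="+", chrom="chr1", name="r"):
    return Interval(chrom, start, end, strand, name)


class TestBuildSegments:
    def test_plus_promoter(self):
        seg = build_segments([gene(start=5000, end=8000, strand="+")])[0]
        assert (seg.promoter.start, seg.promoter.end) == (3000, 5000)

    def test_minus_promoter(self):
        seg = build_segments([gene(start=2000, end=5000, strand="-")])[0]
        assert (seg.promoter.start, seg.promoter.end) == (5000, 7000)

    def test_clipped_at_chrom_start(self):
        seg = build_segments([gene(start=500, end=2000, strand="+")])[0]
        assert (seg.promoter.start, seg.promoter.end) == (0, 500)

    def test_introns_from_exon_gaps(self):
        g = gene(exons=((5000, 5200), (5600, 5900), (7000, 8000)))
        seg = build_segments([g])[0]
        assert [(i.start, i.end) for i in seg.classes["intron"]] == [
            (5200, 5600), (5900, 7000)
        ]

    def test_utrs_split_at_cds(self):
        g = gene(exons=((5000, 5500), (7000, 8000)), cds=(5200, 7600))
        seg = build_segments([g])[0]
        assert [(i.start, i.end) for i in seg.classes["five_utr"]] == [(5000, 5200)]
        assert [(i.start, i.end) for i in seg.classes["three_utr"]] == [(7600, 8000)]
        assert [(i.start, i.end) for i in seg.classes["exon"]] == [
            (5200, 5500), (7000, 7600)
        ]

    def test_longest_transcript_selected(self):
        short = gene(start=5000, end=6000)
        long = GeneModel("g1", "g1.t2", "chr1", 5000, 9000, "+",
                         ((5000, 9000),))
        seg = build_segments([short, long])[0]
        assert seg.gene.transcript_id == "g1.t2"

    def test_exon_outside_span_errors(self):
        with pytest.raises(ValueError):
            gene(exons=((4000, 6000),))


class TestAssignUnique:
    @pytest.fixture
    def segs(self):
        g = gene(exons=((5000, 5500), (6000, 8000)), cds=(5200, 7600))
        return build_segments([g])

    def test_intron_sense(self, segs):
        a = assign_unique([iv(5600, 5650, "+")], segs)
        assert list(a["fine_class"]) == ["intron"]
        assert list(a["orientation"]) == ["sense"]

    def test_straddling_excluded(self, segs):
        a = assign_unique([iv(5480, 5520, "+")], segs)  # exon/intron boundary
        assert list(a["fine_class"]) == ["multiple"]

    def test_promoter_antisense(self, segs):
        a = assign_unique([iv(4000, 4050, "-")], segs)
        assert list(a["fine_class"]) == ["promoter"]
        assert list(a["orientation"]) == ["antisense"]

    def test_no_overlap_no_row(self, segs):
        assert len(assign_unique([iv(20000, 20050)], segs)) == 0


class TestGeneCounts:
    def test_toy_proportions(self):
        g1 = gene("gA", start=5000, end=8000)
        g2 = gene("gB", start=20000, end=23000)
        segs = build_segments([g1, g2])
        summary = gene_counts(
            assign_unique([iv(4500, 4550, "+")], segs), segs
        )
        assert summary.loc["promoter", "n_genes"] == 1
        assert summary.loc["promoter", "proportion"] == 0.5
        assert summary.loc["genic_or_promoter", "proportion"] == 0.5

    def test_empty(self):
        segs = build_segments([gene()])
        summary = gene_counts(assign_unique([], segs), segs)
        assert (summary[["sense_hits", "antisense_hits", "n_genes"]] == 0).all().all()

    def test_proportion_ratio(self):
        import pandas as pd

        a = pd.DataFrame({"proportion": [0.55]}, index=["promoter"])
        b = pd.DataFrame({"proportion": [0.27]}, index=["promoter"])
        assert proportion_ratio(a, b)["promoter"] == pytest.approx(2.037, abs=1e-3)


class TestRegulatoryAndBf:
    def test_flag_regulatory_or(self):
        regions = [iv(100, 120), iv(300, 320), iv(500, 520)]
        tfbs = [iv(110, 130, ".")]
        dnase = [iv(310, 330, "."), iv(110, 115, ".")]
        flags = flag_regulatory(regions, tfbs, dnase)
        assert list(flags) == [True, True, False]

    @pytest.mark.parametrize(
        "strands,expected",
        [(("+", "-"), "bf"), (("-",), "template"), ((), "none"), (("+",), "non_template")],
    )
    def test_bf_classification(self, strands, expected):
        segs = build_segments([gene(strand="+")])  # promoter [3000, 5000)
        regions = [iv(3500 + 40 * i, 3520 + 40 * i, s) for i, s in enumerate(strands)]
        out = find_bf_genes(regions, segs)
        assert out.loc[0, "promoter_occupancy"] == expected

    @pytest.mark.parametrize(
        "strands", [("+",), ("-",), ("+", "-"), ()]
    )
    def test_bf_strand_swap_symmetry(self, strands):
        # flipping every strand (gene and regions) preserves the occupancy
        # class; region offsets are taken relative to the (moving) promoter
        flip = {"+": "-", "-": "+"}
        g_plus = gene(strand="+")                      # promoter [3000, 5000)
        g_minus = GeneModel("g1", "g1.t1", "chr1", 5000, 8000, "-",
                            ((5000, 8000),))           # promoter [8000, 10000)
        seg_p = build_segments([g_plus])
        seg_m = build_segments([g_minus])
        regions_p = [
            iv(3500 + 40 * i, 3520 + 40 * i, s) for i, s in enumerate(strands)
        ]
        regions_m = [
            iv(8500 + 40 * i, 8520 + 40 * i, flip[s])
            for i, s in enumerate(strands)
        ]
        a = find_bf_genes(regions_p, seg_p).loc[0, "promoter_occupancy"]
        b = find_bf_genes(regions_m, seg_m).loc[0, "promoter_occupancy"]
        assert a == b


class TestProfiles:
    def test_single_region_offsets(self):
        track = anchored_profile([iv(95, 105)], [("chr1", 100, "+")], flank=50)
        nz = track.offsets[track.counts > 0]
        assert (nz.min(), nz.max()) == (-5, 4)
        assert track.normalized.sum() == pytest.approx(1)

    def test_minus_anchor_mirrored(self):
        track = anchored_profile([iv(95, 105)], [("chr1", 100, "-")], flank=50)
        nz = track.offsets[track.counts > 0]
        assert (nz.min(), nz.max()) == (-4, 5)

    def test_duplicate_anchor_doubles_counts(self):
        one = anchored_profile([iv(95, 105)], [("chr1", 100, "+")], flank=50)
        two = anchored_profile(
            [iv(95, 105)], [("chr1", 100, "+"), ("chr1", 100, "+")], flank=50
        )
        assert np.array_equal(two.counts, 2 * one.counts)
        assert np.allclose(two.normalized, one.normalized)

    def test_translation_invariance(self):
        a = anchored_profile([iv(95, 105)], [("chr1", 100, "+")], flank=20)
        b = anchored_profile([iv(1095, 1105)], [("chr1", 1100, "+")], flank=20)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_anchors_errors(self):
        with pytest.raises(ValueError):
            anchored_profile([iv(95, 105)], [], flank=50)


class TestCountsPerGene:
    @pytest.fixture
    def segs(self):
        return build_segments([gene(strand="+")])  # promoter [3000,5000), body [5000,8000)

    def test_non_template_promoter(self, segs):
        regions = [iv(3100, 3120, "+"), iv(3200, 3220, "+"), iv(3300, 3320, "+")]
        assert counts_per_gene(regions, segs, "promoter", "non_template")[0] == 3
        assert counts_per_gene(regions, segs, "promoter", "template")[0] == 0

    def test_region_counted_once_across_windows(self, segs):
        spanning = [iv(4990, 5010, "+")]  # touches promoter and body
        assert counts_per_gene(spanning, segs, "promoter+gene_body", "both")[0] == 1
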