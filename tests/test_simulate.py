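"""Synthetic data: genomes, planted motifs, gene models."""

import numpy as np
import pytest

from g4bulge.core import Interval, revcomp
from g4bulge.io import chrom_sizes
from g4bulge.scan import scan_bulged, scan_canonical
from g4bulge.simulate import (
    MotifSpec,
    plant_motifs,
    random_motif,
    simulate_gene_models,
    simulate_genome,
    simulate_motif_free,
)


class TestSimulateGenome:
    def test_seeded_identical(self):
        a = simulate_genome(1, 10_000, 0.5, seed=7)
        b = simulate_genome(1, 10_000, 0.5, seed=7)
        assert a == b

    @pytest.mark.parametrize("gc,alphabet", [(0.0, set("AT")), (1.0, set("GC"))])
    def test_gc_extremes(self, gc, alphabet):
        g = simulate_genome(1, 5000, gc, seed=1)
        assert set(g["chr1"]) <= alphabet

    def test_gc_close_to_target(self):
        g = simulate_genome(1, 100_000, 0.42, seed=2)
        gc = sum(c in "GC" for c in g["chr1"]) / 100_000
        assert abs(gc - 0.42) < 0.02

    def test_bad_args(self):
        with pytest.raises(ValueError):
            simulate_genome(1, 0, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_genome(1, 100, 1.5, seed=1)


class TestPlantMotifs:
    def test_plant_and_recover_canonical(self):
        genome = {"chr1": "T" * 400}
        motif = "GGGAGGGAGGGAGGG"
        spec = MotifSpec(
            "CANONICAL", motif, Interval("chr1", 100, 100 + len(motif), "+")
        )
        planted, truth = plant_motifs(genome, [spec])
        hits = scan_canonical(planted["chr1"])
        assert [(h.start, h.end) for h in hits] == [(100, 115)]
        assert truth[0].name == "CANONICAL"

    def test_minus_strand_reverse_complement(self):
        genome = {"chr1": "T" * 100}
        seq = "TAGAGGCGGGAGTGGAGGGCG"
        spec = MotifSpec("G2B2", seq, Interval("chr1", 10, 10 + len(seq), "-"))
        planted, truth = plant_motifs(genome, [spec])
        assert planted["chr1"][10 : 10 + len(seq)] == revcomp(seq)
        assert truth[0].strand == "-"
        assert scan_bulged(revcomp(planted["chr1"]))  # motif reads on -

    def test_outside_untouched_and_length_conserved(self):
        genome = simulate_genome(1, 1000, 0.4, seed=3)
        motif = "GGGAGGGAGGGAGGG"
        spec = MotifSpec(
            "CANONICAL", motif, Interval("chr1", 200, 200 + len(motif), "+")
        )
        planted, _ = plant_motifs(genome, [spec])
        assert len(planted["chr1"]) == 1000
        assert planted["chr1"][:200] == genome["chr1"][:200]
        assert planted["chr1"][215:] == genome["chr1"][215:]

    def test_overlapping_specs_error(self):
        genome = {"chr1": "T" * 100}
        s1 = MotifSpec("CANONICAL", "GGGAGGGAGGGAGGG", Interval("chr1", 10, 25, "+"))
        s2 = MotifSpec("CANONICAL", "GGGAGGGAGGGAGGG", Interval("chr1", 20, 35, "+"))
        with pytest.raises(ValueError):
            plant_motifs(genome, [s1, s2])


class TestRandomMotif:
    @pytest.mark.parametrize("model", ["G3B1", "G3B2", "G2B2"])
    def test_accepted_models_scan_to_their_label(self, model, rng):
        for _ in range(20):
            seq = random_motif(model, rng)
            assert any(
                h.start == 0 and h.end == len(seq) and h.model == model
                for h in scan_bulged(seq)
            )

    @pytest.mark.parametrize("model", ["G1B3", "G0B4"])
    def test_negative_controls_never_match(self, model, rng):
        for _ in range(20):
            seq = random_motif(model, rng)
            assert scan_bulged(seq) == []
            assert scan_canonical(seq) == []

    def test_canonical_spans_whole_string(self, rng):
        seq = random_motif("CANONICAL", rng)
        assert any(
            h.start == 0 and h.end == len(seq) for h in scan_canonical(seq)
        )


def test_motif_free_background_is_clean():
    seq = simulate_motif_free(20_000, 0.4, seed=13)
    assert scan_bulged(seq) == [] and scan_canonical(seq) == []
    assert scan_bulged(revcomp(seq)) == [] and scan_canonical(revcomp(seq)) == []


class TestGeneModels:
    def test_deterministic(self, background_genome):
        a = simulate_gene_models(background_genome, 8, (2, 4), seed=21)
        b = simulate_gene_models(background_genome, 8, (2, 4), seed=21)
        assert a == b

    def test_intron_count_and_strands(self, background_genome):
        genes = simulate_gene_models(background_genome, 8, (3, 3), seed=22)
        assert {g.strand for g in genes} == {"+", "-"}
        for g in genes:
            assert len(g.exons) == 3
            gaps = [
                s1 - e0 for (_, e0), (s1, _) in zip(g.exons, g.exons[1:])
            ]
            assert len(gaps) == 2 and all(gap > 0 for gap in gaps)
            assert g.cds_start is not None and g.cds_start < g.cds_end
            sizes = chrom_sizes(background_genome)
            assert 0 <= g.start < g.end <= sizes[g.chrom]

    def test_minus_gene_tss_rightmost(self, background_genome):
        genes = simulate_gene_models(background_genome, 6, (1, 2), seed=23)
        for g in genes:
            if g.strand == "-":
                assert g.tss == g.end - 1

    def test_capacity_error(self):
        tiny = {"chr1": "A" * 6000}
        with pytest.raises(ValueError):
            simulate_gene_models(tiny, 50, (2, 3), seed=24)
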