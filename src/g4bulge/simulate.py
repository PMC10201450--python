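"""Synthetic genomes, planted motifs and gene annotations.

Everything downstream of the scanners is testable without external
downloads: this module simulates i.i.d.-base genomes at a chosen GC content,
generates random motif instances from each model grammar, plants them at
known coordinates (the truth set), and simulates simple protein-coding gene
annotations (one transcript per gene, with CDS so UTRs can be derived).

Backgrounds for precision tests are made motif-free by rejection sampling
against both scanners; planted instances are locally re-validated after
planting so junction effects with the surrounding background cannot create
matches overlapping a negative-control window or destroy a planted one.
All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ACCEPTED_BS_MODELS, Interval, revcomp
from .io import GeneModel, Genome
from .regions import exclude_vs_canonical
from .scan import (
    MotifHit,
    apply_bs_filters,
    hit_from_layout,
    scan_bulged,
    scan_canonical,
    scan_genome,
)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MotifSpec:
    """A motif instance to plant: model label, sequence, target interval.

    Minus-strand specs are planted as the reverse complement of ``sequence``
    (the motif reads forward on its own strand).
    """

    model: str
    sequence: str
    position: Interval

    def __post_init__(self):
        if len(self.sequence) != len(self.position):
            raise ValueError(
                f"sequence length {len(self.sequence)} does not fit "
                f"{self.position}"
            )


def simulate_genome(
    n_chrom: int,
    length: int,
    gc_fraction: float = 0.4,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Genome:
    """I.i.d. random genome at the requested GC content (seeded)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    p = [at, gc, gc, at]
    return {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=length, p=p))
        for i in range(n_chrom)
    }


def _random_seq(rng, length, gc) -> str:
    at = (1 - gc) / 2
    return "".join(rng.choice(BASES, size=length, p=[at, gc / 2, gc / 2, at]))


# ---------------------------------------------------------------------------
# random motif instances


def _loop(rng, lo, hi) -> str:
    # loops over {A, T, C}: a loop guanine is legal but would blur the
    # intended layout of a planted instance
    return "".join(rng.choice(["A", "T", "C"], size=rng.integers(lo, hi + 1)))


def _insertion(rng, max_len=3) -> str:
    return "".join(rng.choice(["A", "T", "C"], size=rng.integers(1, max_len + 1)))


def _bulged_stem(rng, n_ins: int) -> str:
    """A stem of three guanines with ``n_ins`` insertions (0-2)."""
    slots = ["", ""]
    for slot in rng.choice(2, size=n_ins, replace=False):
        slots[slot] = _insertion(rng)
    return "G" + slots[0] + "G" + slots[1] + "G"


def random_motif(model: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """A random sequence instance of a model grammar.

    Accepted models are re-validated against the scanner filters (and
    re-drawn on failure, e.g. when a sampled loop/insertion creates a CC);
    negative-control models are built so that no sub-layout can reach two
    intact stems: G1B3 instances contain exactly one GGG run, G0B4 none.
    """
    for _ in range(max_tries):
        if model == "CANONICAL":
            stems = ["G" * rng.integers(3, 5) for _ in range(4)]
            loops = [_loop(rng, 1, 7) for _ in range(3)]
        elif model in ACCEPTED_BS_MODELS:
            if model == "G3B1":
                layout = [1, 0, 0, 0]
            elif model == "G3B2":
                layout = [2, 0, 0, 0]
            else:  # G2B2
                layout = [1, 1, 0, 0]
            layout = [layout[i] for i in rng.permutation(4)]
            stems = [_bulged_stem(rng, k) for k in layout]
            loops = [_loop(rng, 1, 3) for _ in range(3)]
        elif model == "G1B3":
            layout = [1, 1, 1, 0]
            layout = [layout[i] for i in rng.permutation(4)]
            stems = [_bulged_stem(rng, k) for k in layout]
            loops = [_loop(rng, 1, 3) for _ in range(3)]
        elif model == "G0B4":
            stems = [_bulged_stem(rng, rng.integers(1, 3)) for _ in range(4)]
            loops = [_loop(rng, 1, 3) for _ in range(3)]
        else:
            raise ValueError(f"unknown model {model!r}")
        seq = (
            stems[0] + loops[0] + stems[1] + loops[1] + stems[2] + loops[2] + stems[3]
        )
        if model == "CANONICAL":
            hits = scan_canonical(seq)
            if any(h.start == 0 and h.end == len(seq) for h in hits):
                return seq
            continue
        if model in ACCEPTED_BS_MODELS:
            g = [i for i, (c, st) in enumerate(_stem_gs(stems, loops)) if c == "G"]
            hit = hit_from_layout(seq, g)
            ok, _ = apply_bs_filters(hit)
            if ok and hit.model == model:
                return seq
            continue
        # negative controls: structural guarantees
        runs = _g_run_lengths(seq)
        n_ggg = sum(1 for r in runs if r >= 3)
        if (model == "G1B3" and n_ggg == 1 and max(runs) == 3) or (
            model == "G0B4" and n_ggg == 0
        ):
            if not scan_bulged(seq) and not scan_canonical(seq):
                return seq
    raise RuntimeError(f"could not generate a {model} instance")


def _stem_gs(stems, loops):
    """(char, is_stem) pairs for the concatenated motif, stems marked."""
    out = []
    for i, stem in enumerate(stems):
        out.extend((c, True) for c in stem)
        if i < 3:
            out.extend((c, False) for c in loops[i])
    return out


def _g_run_lengths(seq: str) -> List[int]:
    runs, n = [], 0
    for c in seq:
        if c == "G":
            n += 1
        else:
            if n:
                runs.append(n)
            n = 0
    if n:
        runs.append(n)
    return runs or [0]


# ---------------------------------------------------------------------------
# planting


def plant_motifs(
    genome: Genome,
    motif_specs: Sequence[MotifSpec],
    seed: Optional[int] = None,
) -> Tuple[Genome, List[Interval]]:
    """Plant motif instances at fixed coordinates.

    Returns the modified genome and the truth track (one interval per
    planted instance, named by its model). The genome is unchanged outside
    the planted windows; overlapping specs are an error. Minus-strand
    motifs are planted as reverse complements.
    """
    del seed  # positions are explicit; kept for interface uniformity
    seen: Dict[str, List[Tuple[int, int]]] = {}
    for spec in motif_specs:
        iv = spec.position
        if iv.end > len(genome[iv.chrom]):
            raise ValueError(f"{iv} outside chromosome")
        for s, e in seen.get(iv.chrom, []):
            if iv.start < e and s < iv.end:
                raise ValueError(f"planted windows overlap at {iv}")
        seen.setdefault(iv.chrom, []).append((iv.start, iv.end))
    chroms = {name: list(seq) for name, seq in genome.items()}
    truth: List[Interval] = []
    for spec in motif_specs:
        iv = spec.position
        planted = spec.sequence if iv.strand != "-" else revcomp(spec.sequence)
        chroms[iv.chrom][iv.start : iv.end] = planted
        truth.append(
            Interval(iv.chrom, iv.start, iv.end, iv.strand, spec.model)
        )
    return {name: "".join(seq) for name, seq in chroms.items()}, truth


def simulate_motif_free(
    length: int,
    gc_fraction: float = 0.4,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_rounds: int = 60,
) -> str:
    """A random sequence with no accepted match on either strand.

    Rejection sampling: scan, re-draw the bases under every hit (plus a
    small margin), repeat until clean.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length, gc_fraction))
    for _ in range(max_rounds):
        genome = {"x": "".join(seq)}
        hits = scan_genome(genome, "BS") + scan_genome(genome, "CS")
        if not hits:
            return "".join(seq)
        for h in hits:
            lo, hi = max(0, h.start - 2), min(length, h.end + 2)
            seq[lo:hi] = _random_seq(rng, hi - lo, gc_fraction)
    raise RuntimeError("rejection sampling did not converge")


def _window_hits(sub: str, lo: int, hi: int) -> List[MotifHit]:
    """Accepted bulged hits of both strands of ``sub`` (= genome[lo:hi])."""
    hits = [
        MotifHit(h.chrom, h.start + lo, h.end + lo, "+", h.model, h.stems,
                 h.loops, h.core_seq)
        for h in scan_bulged(sub)
    ]
    L = hi - lo
    for h in scan_bulged(revcomp(sub)):
        hits.append(
            MotifHit(h.chrom, lo + L - h.end, lo + L - h.start, "-", h.model,
                     h.stems, h.loops, h.core_seq)
        )
    return hits


def _window_canonical(sub: str, lo: int, hi: int) -> List[MotifHit]:
    hits = [
        MotifHit(h.chrom, h.start + lo, h.end + lo, "+", h.model, h.stems,
                 h.loops, h.core_seq)
        for h in scan_canonical(sub)
    ]
    L = hi - lo
    for h in scan_canonical(revcomp(sub)):
        hits.append(
            MotifHit(h.chrom, lo + L - h.end, lo + L - h.start, "-", h.model,
                     h.stems, h.loops, h.core_seq)
        )
    return hits


def build_planted_genome(
    length: int = 1_000_000,
    n_motifs: int = 200,
    model_mix: Sequence[str] = (
        "CANONICAL",
        "G3B1",
        "G3B2",
        "G2B2",
        "G1B3",
        "G0B4",
    ),
    gc_fraction: float = 0.35,
    seed: Optional[int] = None,
    chrom: str = "chr1",
    min_separation: int = 150,
) -> Tuple[Genome, List[Interval]]:
    """A motif-free background with planted instances of known coordinates.

    Models are planted in round-robin over ``model_mix`` on random strands.
    Each instance is padded by one non-G base on both sides (so maximal
    G-runs cannot extend across the junction) and locally validated after
    planting: a positive instance must be recovered at its exact coordinates
    and must not be covered by a same-strand canonical match; a negative
    control's neighbourhood must contain no accepted bulged match at all.
    The truth track names each inner (unpadded) interval by its model.
    """
    rng = np.random.default_rng(seed)
    background = simulate_motif_free(length, gc_fraction, rng=rng)
    seq = list(background)
    truth: List[Interval] = []
    occupied: List[Tuple[int, int]] = []

    for i in range(n_motifs):
        model = model_mix[i % len(model_mix)]
        strand = "+" if rng.random() < 0.5 else "-"
        planted_ok = False
        for _ in range(300):
            motif = random_motif(model, rng)
            padded = "T" + motif + "T"
            if strand == "-":
                padded_fwd = revcomp(padded)
            else:
                padded_fwd = padded
            start = int(rng.integers(0, length - len(padded)))
            end = start + len(padded)
            if any(
                start - min_separation < e and s < end + min_separation
                for s, e in occupied
            ):
                continue
            saved = seq[start:end]
            seq[start:end] = padded_fwd
            lo, hi = max(0, start - 100), min(length, end + 100)
            window = "".join(seq[lo:hi])
            bs = _window_hits(window, lo, hi)
            inner = (start + 1, end - 1)
            if model in ("G1B3", "G0B4"):
                ok = not any(h.start < end and start < h.end for h in bs)
            else:
                cs = _window_canonical(window, lo, hi)
                if model == "CANONICAL":
                    ok = any(
                        h.start == inner[0] and h.end == inner[1]
                        and h.strand == strand
                        for h in cs
                    )
                else:
                    exact = [
                        h
                        for h in bs
                        if h.start == inner[0]
                        and h.end == inner[1]
                        and h.strand == strand
                        and h.model == model
                    ]
                    covered = any(
                        c.strand == strand
                        and c.start < inner[1]
                        and inner[0] < c.end
                        for c in cs
                    )
                    ok = bool(exact) and not covered
            if ok:
                occupied.append((start, end))
                truth.append(
                    Interval(chrom, inner[0], inner[1], strand, model)
                )
                planted_ok = True
                break
            seq[start:end] = saved
        if not planted_ok:
            raise RuntimeError(f"could not place a {model} instance")
    return {chrom: "".join(seq)}, truth


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(
    genome: Genome,
    n_genes: int,
    exon_geometry: Tuple[int, int] = (1, 5),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    promoter_len: int = 2000,
) -> List[GeneModel]:
    """Simple protein-coding gene annotation: one transcript per gene.

    Genes are placed without overlap (including promoter room), on both
    strands, each with ``exon_geometry`` = (min, max) exons and a CDS
    starting inside the first and ending inside the last exon, so that 5'
    and 3' UTRs exist. Deterministic per seed; raises when ``n_genes`` does
    not fit.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sizes = {c: len(s) for c, s in genome.items()}
    chroms = list(sizes)
    genes: List[GeneModel] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    lo_e, hi_e = exon_geometry
    attempts = 0
    while len(genes) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            raise ValueError(
                f"cannot place {n_genes} genes in this genome"
            )
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = rng.integers(120, 300, size=n_exons)
        intron_lens = rng.integers(200, 800, size=max(0, n_exons - 1))
        span = int(exon_lens.sum() + intron_lens.sum())
        limit = sizes[chrom] - span - promoter_len
        if limit <= promoter_len:
            continue
        start = int(rng.integers(promoter_len, limit))
        if any(
            start - promoter_len < e and s < start + span + promoter_len
            for s, e in occupied[chrom]
        ):
            continue
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        end = exons[-1][1]
        strand = "+" if len(genes) % 2 == 0 else "-"
        cds_start = exons[0][0] + int(rng.integers(30, exon_lens[0] - 30))
        cds_end = exons[-1][0] + int(rng.integers(30, exon_lens[-1] - 30))
        if cds_end <= cds_start:
            continue
        gid = f"gene{len(genes) + 1}"
        genes.append(
            GeneModel(
                gene_id=gid,
                transcript_id=f"{gid}.t1",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        occupied[chrom].append((start, end))
    return genes


def random_intervals(
    genome_sizes: Dict[str, int],
    n: int,
    length_range: Tuple[int, int] = (20, 40),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    strand: str = ".",
    name: str = ".",
) -> List[Interval]:
    """Uniform random intervals (test/background plumbing)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = list(genome_sizes)
    weights = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, genome_sizes[chrom] - ln + 1))
        out.append(Interval(chrom, start, start + ln, strand, name))
    return out
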