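"""Gene-segment assignment, strand architecture and anchored profiles.

Gene segments are derived from one transcript per gene (the longest, when a
gene has several): a promoter of 2 kb upstream of the TSS in gene
orientation, 5'/3' UTRs and coding exons split at the CDS boundaries,
introns as the gaps between exons. Orientation of a motif region relative
to a gene is *sense* when the region lies on the gene's own strand — the
non-template strand, carrying the mRNA-like sequence — and *antisense*
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Interval
from .io import GeneModel

FINE_CLASSES = ("promoter", "five_utr", "exon", "intron", "three_utr")


@dataclass
class GeneSegments:
    """Derived segments of one gene (all intervals on the gene's strand)."""

    gene: GeneModel
    promoter: Optional[Interval]
    classes: Dict[str, List[Interval]] = field(default_factory=dict)

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def strand(self) -> str:
        return self.gene.strand

    @property
    def body(self) -> Interval:
        g = self.gene
        return Interval(g.chrom, g.start, g.end, g.strand, g.gene_id)


def build_segments(
    gene_models: Sequence[GeneModel],
    promoter_len: int = 2000,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> List[GeneSegments]:
    """Derive promoter/UTR/exon/intron segments, one transcript per gene.

    The promoter spans ``promoter_len`` bases upstream of the TSS in gene
    orientation, clipped at chromosome edges. Without CDS information the
    whole exon set is classed as ``exon`` and no UTRs are emitted.
    """
    by_gene: Dict[str, GeneModel] = {}
    for g in gene_models:
        cur = by_gene.get(g.gene_id)
        if cur is None or (g.end - g.start) > (cur.end - cur.start):
            by_gene[g.gene_id] = g

    out: List[GeneSegments] = []
    for g in by_gene.values():
        if g.strand == "+":
            p_lo, p_hi = g.start - promoter_len, g.start
        else:
            p_lo, p_hi = g.end, g.end + promoter_len
        p_lo = max(p_lo, 0)
        if chrom_sizes is not None:
            p_hi = min(p_hi, chrom_sizes[g.chrom])
        promoter = (
            Interval(g.chrom, p_lo, p_hi, g.strand, g.gene_id)
            if p_lo < p_hi
            else None
        )

        exons = list(g.exons)
        introns = [
            Interval(g.chrom, e0, s1, g.strand, g.gene_id)
            for (_, e0), (s1, _) in zip(exons, exons[1:])
            if e0 < s1
        ]
        classes: Dict[str, List[Interval]] = {c: [] for c in FINE_CLASSES}
        if promoter is not None:
            classes["promoter"] = [promoter]
        classes["intron"] = introns

        def _iv(s, e):
            return Interval(g.chrom, s, e, g.strand, g.gene_id)

        if g.cds_start is not None:
            if g.strand == "+":
                up = (g.start, g.cds_start)   # 5'UTR side
                down = (g.cds_end, g.end)     # 3'UTR side
            else:
                up = (g.cds_end, g.end)
                down = (g.start, g.cds_start)
            for s, e in exons:
                for (lo, hi), cls in ((up, "five_utr"), (down, "three_utr")):
                    a, b = max(s, lo), min(e, hi)
                    if a < b:
                        classes[cls].append(_iv(a, b))
                a, b = max(s, g.cds_start), min(e, g.cds_end)
                if a < b:
                    classes["exon"].append(_iv(a, b))
        else:
            classes["exon"] = [_iv(s, e) for s, e in exons]
        out.append(GeneSegments(gene=g, promoter=promoter, classes=classes))
    out.sort(key=lambda s: (s.gene.chrom, s.gene.start))
    return out


def _overlap(a_start, a_end, iv: Interval) -> bool:
    return a_start < iv.end and iv.start < a_end


def assign_unique(
    regions: Sequence, segments: Sequence[GeneSegments]
) -> pd.DataFrame:
    """Assign regions to gene segments with unique-mapping semantics.

    One row per (region, gene) pair with any overlap of the promoter or
    gene body. ``fine_class`` is the segment class when the region overlaps
    exactly one of promoter/5'UTR/exon/intron/3'UTR for that gene, else
    ``"multiple"``; ``coarse_class`` distinguishes promoter vs gene body the
    same way. Multi-class regions are excluded from segment-level counts but
    still count toward overall gene positivity.
    """
    rows = []
    for ri, r in enumerate(regions):
        for seg in segments:
            g = seg.gene
            if r.chrom != g.chrom:
                continue
            in_body = _overlap(r.start, r.end, seg.body)
            in_prom = seg.promoter is not None and _overlap(
                r.start, r.end, seg.promoter
            )
            if not (in_body or in_prom):
                continue
            fine = [
                c
                for c in FINE_CLASSES
                if any(_overlap(r.start, r.end, iv) for iv in seg.classes[c])
            ]
            rows.append(
                {
                    "region": ri,
                    "gene_id": g.gene_id,
                    "orientation": "sense" if r.strand == g.strand else "antisense",
                    "fine_class": fine[0] if len(fine) == 1 else "multiple",
                    "coarse_class": (
                        "promoter"
                        if in_prom and not in_body
                        else "gene_body"
                        if in_body and not in_prom
                        else "multiple"
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region", "gene_id", "orientation", "fine_class", "coarse_class"],
    )


def gene_counts(
    assignments: pd.DataFrame, segments: Sequence[GeneSegments]
) -> pd.DataFrame:
    """Per-segment-class summary of uniquely mapped regions.

    Returns one row per class — the five fine classes, the two coarse
    classes and ``genic_or_promoter`` (any overlap, no uniqueness filter) —
    with sense/antisense hit counts, the number of genes with at least one
    hit (a gene counts once regardless of orientation) and the proportion of
    all genes.
    """
    n_genes = len(segments)
    rows = []

    def _summarize(label, sub):
        sense = int((sub["orientation"] == "sense").sum())
        anti = int((sub["orientation"] == "antisense").sum())
        genes = sub["gene_id"].nunique()
        rows.append(
            {
                "segment": label,
                "sense_hits": sense,
                "antisense_hits": anti,
                "n_genes": genes,
                "proportion": genes / n_genes if n_genes else 0.0,
            }
        )

    _summarize("genic_or_promoter", assignments)
    for cls in ("promoter", "gene_body"):
        _summarize(cls, assignments[assignments["coarse_class"] == cls])
    for cls in ("five_utr", "exon", "intron", "three_utr"):
        _summarize(cls, assignments[assignments["fine_class"] == cls])
    return pd.DataFrame(rows).set_index("segment")


def proportion_ratio(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> pd.Series:
    """Ratio of gene-positivity proportions between two summaries."""
    return summary_a["proportion"] / summary_b["proportion"]


def flag_regulatory(
    regions: Sequence,
    tfbs: Sequence[Interval] = (),
    dnase: Sequence[Interval] = (),
) -> np.ndarray:
    """Flag regions overlapping >=1 nt with a TFBS or DNase track (strand-blind)."""
    from .regions import _overlaps_any

    track = list(tfbs) + list(dnase)
    if not track:
        return np.zeros(len(regions), dtype=bool)
    return _overlaps_any(regions, track, stranded=False)


def find_bf_genes(
    regions: Sequence, segments: Sequence[GeneSegments]
) -> pd.DataFrame:
    """Classify promoter motif occupancy per gene.

    ``none`` / ``non_template`` (regions only on the gene strand) /
    ``template`` (only on the opposite strand) / ``bf`` (back-forward: both
    strands occupied simultaneously).
    """
    rows = []
    for seg in segments:
        g = seg.gene
        sense = anti = False
        if seg.promoter is not None:
            for r in regions:
                if r.chrom == g.chrom and _overlap(r.start, r.end, seg.promoter):
                    if r.strand == g.strand:
                        sense = True
                    else:
                        anti = True
        status = (
            "bf"
            if sense and anti
            else "non_template"
            if sense
            else "template"
            if anti
            else "none"
        )
        rows.append({"gene_id": g.gene_id, "promoter_occupancy": status})
    return pd.DataFrame(rows)


@dataclass
class ProfileTrack:
    """Per-nucleotide occupancy around a set of anchors.

    ``offsets[i]`` is the position relative to the anchor in anchor
    orientation; ``counts[i]`` the number of (anchor, position) pairs covered
    by at least one region; ``normalized`` sums to 1 when any position is
    covered.
    """

    flank: int
    offsets: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray


def anchored_profile(
    regions: Sequence,
    anchors: Sequence[Tuple[str, int, str]],
    flank: int = 2000,
    orient_by_gene: bool = True,
) -> ProfileTrack:
    """Coverage-counted frequency profile around anchors.

    ``anchors`` are ``(chrom, position, strand)`` triples. For each anchor
    and each offset in [-flank, flank) the profile gains 1 if any region
    covers the corresponding genomic base; minus-strand anchors (when
    ``orient_by_gene``) read offsets in gene orientation (mirrored). The
    normalized track divides by the total count.
    """
    if not len(anchors):
        raise ValueError("anchored_profile requires at least one anchor")
    # merged boolean coverage per chromosome
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    cov = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        cov[chrom] = (np.array(ms), np.array(me))

    counts = np.zeros(2 * flank, dtype=float)
    for chrom, pos, strand in anchors:
        if chrom not in cov:
            continue
        ms, me = cov[chrom]
        minus = orient_by_gene and strand == "-"
        lo, hi = (pos - flank + 1, pos + flank + 1) if minus else (pos - flank, pos + flank)
        i = np.searchsorted(me, lo, side="right")
        while i < len(ms) and ms[i] < hi:
            a, b = max(ms[i], lo), min(me[i], hi)
            if minus:
                # genomic g in [a,b) -> offset pos - g
                counts[flank + pos - b + 1 : flank + pos - a + 1] += 1
            else:
                counts[a - pos + flank : b - pos + flank] += 1
            i += 1
    total = counts.sum()
    return ProfileTrack(
        flank=flank,
        offsets=np.arange(-flank, flank),
        counts=counts,
        normalized=counts / total if total > 0 else counts.copy(),
    )


def counts_per_gene(
    regions: Sequence,
    segments: Sequence[GeneSegments],
    scope: str = "promoter+gene_body",
    strand_mode: str = "non_template",
) -> np.ndarray:
    """Number of regions overlapping each gene's scope on the chosen strand.

    ``scope`` is ``promoter``, ``gene_body`` or ``promoter+gene_body``;
    ``strand_mode`` is ``non_template`` (gene strand), ``template`` or
    ``both``. A region overlapping several scope windows of one gene counts
    once. Output order matches ``segments``.
    """
    if scope not in ("promoter", "gene_body", "promoter+gene_body"):
        raise ValueError(f"bad scope {scope!r}")
    if strand_mode not in ("non_template", "template", "both"):
        raise ValueError(f"bad strand_mode {strand_mode!r}")
    out = np.zeros(len(segments), dtype=int)
    for gi, seg in enumerate(segments):
        g = seg.gene
        windows = []
        if scope in ("promoter", "promoter+gene_body") and seg.promoter is not None:
            windows.append((seg.promoter.start, seg.promoter.end))
        if scope in ("gene_body", "promoter+gene_body"):
            windows.append((g.start, g.end))
        n = 0
        for r in regions:
            if r.chrom != g.chrom:
                continue
            if strand_mode == "non_template" and r.strand != g.strand:
                continue
            if strand_mode == "template" and r.strand == g.strand:
                continue
            if any(r.start < e and s < r.end for s, e in windows):
                n += 1
        out[gi] = n
    return out
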