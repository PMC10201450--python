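"""Post-scan interval set algebra.

Pipeline order mirrors the discovery workflow: scan both grammars, drop
bulged matches that collide with canonical matches on the same strand, drop
anything inside annotated repeats, then merge what remains into
strand-specific regions. Overlap always means at least one shared nucleotide
under half-open arithmetic: book-ended intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import Interval
from .scan import MotifHit, scan_canonical


@dataclass(frozen=True)
class Region:
    """A strand-specific merged region of overlapping motif hits."""

    chrom: str
    start: int
    end: int
    strand: str
    n_members: int
    models: Tuple[str, ...]  # member model labels, in member order

    @property
    def name(self) -> str:
        return "|".join(sorted(set(self.models))) or "."

    @property
    def score(self):
        return self.n_members

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LengthStats:
    mean: float
    median: float
    mode: int
    sd: float
    n: int
    histogram: Dict[int, float]  # length -> normalized frequency


def _overlaps_any(items, track: Sequence, stranded: bool) -> np.ndarray:
    """Boolean flag per item: does it share >=1 nt with any track interval."""
    by_key: Dict = {}
    for t in track:
        key = (t.chrom, t.strand) if stranded else t.chrom
        by_key.setdefault(key, []).append((t.start, t.end))
    # sorted, merged start/end arrays per key for a binary-search test
    merged = {}
    for key, ivs in by_key.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[key] = (np.array(ms), np.array(me))
    flags = np.zeros(len(items), dtype=bool)
    for i, it in enumerate(items):
        key = (it.chrom, it.strand) if stranded else it.chrom
        if key not in merged:
            continue
        ms, me = merged[key]
        j = np.searchsorted(ms, it.end) - 1  # last track start < item end
        flags[i] = j >= 0 and me[j] > it.start
    return flags


def exclude_vs_canonical(
    bs_hits: Sequence[MotifHit], cs_hits: Sequence
) -> List[MotifHit]:
    """Remove bulged hits that collide with the canonical motif.

    A bulged hit is dropped when (a) its core is itself a full canonical
    match, or (b) it shares at least one nucleotide with a canonical hit on
    the same strand. Opposite-strand overlap never removes.
    """
    overlap = _overlaps_any(bs_hits, cs_hits, stranded=True)
    kept = []
    for hit, hit_overlaps in zip(bs_hits, overlap):
        if hit_overlaps:
            continue
        core = getattr(hit, "core_seq", None)  # absent on plain intervals
        if core is not None and any(
            c.start == 0 and c.end == len(core) for c in scan_canonical(core)
        ):
            continue
        kept.append(hit)
    return kept


def exclude_repeats(hits: Sequence, repeat_track: Sequence[Interval]) -> List:
    """Remove hits sharing >=1 nt with any repeat interval (strand-blind;
    repeat annotation is effectively unstranded for this purpose)."""
    overlap = _overlaps_any(hits, repeat_track, stranded=False)
    return [h for h, o in zip(hits, overlap) if not o]


def merge_regions(hits: Sequence) -> List[Region]:
    """Merge overlapping same-strand hits into regions.

    The union of intervals sharing at least one nucleotide, computed per
    (chromosome, strand); book-ended hits stay separate. Idempotent.
    """
    groups: Dict[Tuple[str, str], List] = {}
    for h in hits:
        groups.setdefault((h.chrom, h.strand), []).append(h)
    regions: List[Region] = []
    for (chrom, strand), members in groups.items():
        members.sort(key=lambda h: (h.start, h.end))
        cur: List = []
        cur_end = None
        for h in members:
            if cur and h.start < cur_end:
                cur.append(h)
                cur_end = max(cur_end, h.end)
            else:
                if cur:
                    regions.append(_make_region(chrom, strand, cur, cur_end))
                cur = [h]
                cur_end = h.end
        if cur:
            regions.append(_make_region(chrom, strand, cur, cur_end))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return regions


def _make_region(chrom, strand, members, end) -> Region:
    return Region(
        chrom=chrom,
        start=min(m.start for m in members),
        end=end,
        strand=strand,
        n_members=len(members),
        models=tuple(getattr(m, "model", getattr(m, "name", ".")) for m in members),
    )


def length_stats(items: Sequence) -> LengthStats:
    """Descriptive statistics of item lengths.

    Mode ties break toward the smaller length; the median of an even-sized
    sample is the midpoint; sd is the population standard deviation.
    """
    if not len(items):
        raise ValueError("length_stats of an empty collection")
    lengths = np.array([len(i) for i in items])
    values, counts = np.unique(lengths, return_counts=True)
    mode = int(values[np.argmax(counts)])  # argmax -> first = smallest value
    hist = {int(v): c / len(lengths) for v, c in zip(values, counts)}
    return LengthStats(
        mean=float(lengths.mean()),
        median=float(np.median(lengths)),
        mode=mode,
        sd=float(lengths.std(ddof=0)),
        n=len(lengths),
        histogram=hist,
    )


def ks_two_sample(
    x_lengths: Sequence[float],
    y_lengths: Sequence[float],
    sample_n: Optional[int] = None,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of length distributions.

    When ``sample_n`` is given, both samples are subsampled to that size
    without replacement (seeded), matching the same-size-sample comparison
    used when populations differ greatly in size. Returns (D, asymptotic p).
    """
    x = np.asarray(x_lengths, dtype=float)
    y = np.asarray(y_lengths, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sample_n is not None:
        if sample_n > x.size or sample_n > y.size:
            raise ValueError("sample_n exceeds population size")
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=sample_n, replace=False)
        y = rng.choice(y, size=sample_n, replace=False)
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
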