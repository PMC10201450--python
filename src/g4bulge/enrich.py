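"""Background-matched enrichment statistics against experimental peak sets.

The enrichment score (ES) of a query interval set against a peak set is the
ratio of positive-overlap proportions between the query and a random
background matched for interval length (and optionally chromosome), where an
interval is *positive* when it shares at least one nucleotide with any peak.
Inference on the ratio of the two binomial proportions uses the score test
with a Katz log-ratio 95% CI, falling back to the exact conditional
(hypergeometric) test when any contingency cell is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import (
    confint_proportions_2indep,
    test_proportions_2indep,
)

from .core import Interval

_MAX_ATTEMPT_FACTOR = 1000


@dataclass(frozen=True)
class EnrichmentResult:
    a: int          # positive query overlaps
    n1: int         # query sample size
    b: int          # positive background overlaps
    n2: int         # background sample size
    es: float       # (a/n1) / (b/n2)
    ci_low: float
    ci_high: float
    p_value: float
    method: str     # "score" or "exact"


@dataclass(frozen=True)
class BootstrapRatioResult:
    query_ratios: np.ndarray
    background_ratios: np.ndarray
    p_value: float
    median_query: float
    median_background: float


def _sorted_track(intervals: Sequence) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for t in intervals:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        out[chrom] = (np.array(ms), np.array(me))
    return out


def _hits_track(track, chrom: str, start: int, end: int) -> bool:
    if chrom not in track:
        return False
    ms, me = track[chrom]
    j = np.searchsorted(ms, end) - 1
    return j >= 0 and me[j] > start


def overlap_flags(intervals: Sequence, peaks: Sequence) -> np.ndarray:
    """Boolean flag per interval: shares >=1 nt with any peak (strand-blind)."""
    track = _sorted_track(peaks)
    return np.array(
        [_hits_track(track, iv.chrom, iv.start, iv.end) for iv in intervals],
        dtype=bool,
    )


def sample_background(
    query_intervals: Sequence,
    genome_sizes: Dict[str, int],
    n: Optional[int] = None,
    match_chrom: bool = True,
    exclusion_set: Sequence = (),
    seed: Optional[int] = None,
    genome: Optional[Dict[str, str]] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Interval]:
    """Draw length-matched random background intervals.

    For each of ``n`` query intervals (sampled without replacement when ``n``
    is below the pool size) one random interval of identical length is
    placed — on the same chromosome when ``match_chrom``, otherwise on a
    length-weighted random chromosome — rejecting draws that overlap the
    exclusion set or contain N (when ``genome`` is given). Deterministic per
    seed; raises after a bounded number of rejected attempts.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pool = list(query_intervals)
    if n is None:
        n = len(pool)
    if n > len(pool):
        raise ValueError("n exceeds the query pool size")
    idx = rng.choice(len(pool), size=n, replace=False) if n < len(pool) else np.arange(n)
    excl = _sorted_track(exclusion_set)
    chroms = list(genome_sizes)
    weights = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    out: List[Interval] = []
    max_attempts = _MAX_ATTEMPT_FACTOR * n
    attempts = 0
    for i in idx:
        q = pool[i]
        length = q.end - q.start
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "background sampling failed: could not place a "
                    f"{length}-nt interval outside the exclusion set"
                )
            chrom = q.chrom if match_chrom else chroms[rng.choice(len(chroms), p=weights)]
            hi = genome_sizes[chrom] - length
            if hi < 0:
                continue
            start = int(rng.integers(0, hi + 1))
            end = start + length
            if _hits_track(excl, chrom, start, end):
                continue
            if genome is not None and "N" in genome[chrom][start:end]:
                continue
            out.append(Interval(chrom, start, end, ".", "background"))
            break
    return out


def enrichment_score(a: int, n1: int, b: int, n2: int) -> EnrichmentResult:
    """2x2 contingency enrichment of positive-overlap proportions.

    ES = (a/n1)/(b/n2); 95% CI by the Katz log-ratio method; two-sided p by
    the score test on the ratio of the two binomial proportions, replaced by
    the exact conditional (Fisher/hypergeometric) p when any cell of the
    table is below 5. With ``b == 0`` the ES is infinite and only the exact
    p is reported.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("counts outside [0, n]")
    table = np.array([[a, n1 - a], [b, n2 - b]])
    exact_needed = b == 0 or table.min() < 5
    if b == 0:
        es = float("inf") if a > 0 else float("nan")
        ci = (float("nan"), float("nan"))
    else:
        es = (a / n1) / (b / n2)
        ci = confint_proportions_2indep(
            a, n1, b, n2, compare="ratio", method="log", alpha=0.05
        )
    if exact_needed:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        method = "exact"
    else:
        p = float(
            test_proportions_2indep(
                a, n1, b, n2, compare="ratio", method="score", value=1
            ).pvalue
        )
        method = "score"
    return EnrichmentResult(
        a=a, n1=n1, b=b, n2=n2, es=float(es),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=p, method=method,
    )


def enrichment_test(
    query: Sequence,
    peaks: Sequence,
    genome_sizes: Dict[str, int],
    n: Optional[int] = None,
    match_chrom: bool = True,
    exclusion_set: Optional[Sequence] = None,
    seed: Optional[int] = None,
    genome: Optional[Dict[str, str]] = None,
) -> EnrichmentResult:
    """End-to-end enrichment of a query set in a peak set.

    Samples a matched background (excluding, by default, the query intervals
    themselves), counts positive overlaps on both sides and delegates to
    :func:`enrichment_score`.
    """
    rng = np.random.default_rng(seed)
    pool = list(query)
    if n is None or n > len(pool):
        n = len(pool)
    idx = rng.choice(len(pool), size=n, replace=False) if n < len(pool) else np.arange(n)
    sample = [pool[i] for i in idx]
    background = sample_background(
        sample,
        genome_sizes,
        n=n,
        match_chrom=match_chrom,
        exclusion_set=pool if exclusion_set is None else exclusion_set,
        genome=genome,
        rng=rng,
    )
    a = int(overlap_flags(sample, peaks).sum())
    b = int(overlap_flags(background, peaks).sum())
    return enrichment_score(a, n, b, n)


def bootstrap_ratio_test(
    query_pool: Sequence,
    background_sampler: Callable[[Sequence, np.random.Generator], Sequence],
    peaks: Sequence,
    n_samples: int = 100,
    sample_size: int = 1000,
    seed: Optional[int] = None,
) -> BootstrapRatioResult:
    """Repeated-sample comparison of positive-overlap ratios.

    Draws ``n_samples`` samples of ``sample_size`` intervals without
    replacement from the query pool; for each, ``background_sampler(sample,
    rng)`` supplies a matched random set. The per-sample positive ratios of
    the two groups are compared with a two-sided Mann-Whitney U test (exact
    for min(n) <= 8, tie-corrected normal approximation otherwise).
    """
    pool = list(query_pool)
    if sample_size > len(pool):
        raise ValueError("sample_size exceeds the query pool")
    rng = np.random.default_rng(seed)
    track = _sorted_track(peaks)

    def ratio(ivs) -> float:
        return float(
            np.mean([_hits_track(track, i.chrom, i.start, i.end) for i in ivs])
        )

    q_ratios = np.empty(n_samples)
    b_ratios = np.empty(n_samples)
    for k in range(n_samples):
        idx = rng.choice(len(pool), size=sample_size, replace=False)
        sample = [pool[i] for i in idx]
        q_ratios[k] = ratio(sample)
        b_ratios[k] = ratio(background_sampler(sample, rng))
    method = "exact" if n_samples <= 8 else "asymptotic"
    res = stats.mannwhitneyu(
        q_ratios, b_ratios, alternative="two-sided", method=method
    )
    return BootstrapRatioResult(
        query_ratios=q_ratios,
        background_ratios=b_ratios,
        p_value=float(res.pvalue),
        median_query=float(np.median(q_ratios)),
        median_background=float(np.median(b_ratios)),
    )


def mann_whitney_ratio(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U on two ratio samples (exact for tiny n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if min(x.size, y.size) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
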