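"""Kolmogorov-Waring distribution for per-gene motif counts.

The Kolmogorov-Waring family arises as the stationary law of a birth-death
process balancing gain and loss events; it is a skewed count distribution
with a power-law-like right tail, suited to the per-gene frequency
distribution of motif regions where few genes carry very many regions while
most carry few. It is defined by the recurrence

    p_{k+1} = p_k * theta * (k + alpha) / (k + 1 + beta),   k >= 0,

with theta in (0, 1], alpha, beta > 0, and p_0 fixed by normalization.
Under the full birth-death model the zero class has the closed form
p_0 = 1 - alpha/beta (for alpha < beta), which doubles as the probability
that a gene's motif content goes unobserved; both the closed form and the
normalization-based p_0 of the fitted pmf are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

_TAIL_TOL = 1e-9


def kw_pmf(
    theta: float,
    alpha: float,
    beta: float,
    k_max: Optional[int] = None,
    tail_tol: float = _TAIL_TOL,
) -> np.ndarray:
    """Probability vector of the Kolmogorov-Waring distribution.

    Normalized over 0..K where K is at least ``k_max`` and is auto-extended
    until the (bounded) tail mass beyond K falls below ``tail_tol``.
    Raises for parameters whose series does not converge
    (theta = 1 with beta - alpha <= 1).
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if theta == 0:
        p = np.zeros((k_max or 0) + 1)
        p[0] = 1.0
        return p
    if theta == 1 and beta - alpha <= 1:
        raise ValueError(
            "non-convergent tail: theta = 1 requires beta - alpha > 1"
        )
    K = max(64, (k_max or 0) + 1)
    while True:
        k = np.arange(K - 1, dtype=float)
        log_ratio = np.log(theta) + np.log(k + alpha) - np.log(k + 1 + beta)
        logq = np.concatenate([[0.0], np.cumsum(log_ratio)])
        q = np.exp(logq - logq.max())
        total = q.sum()
        # geometric / power-law bound on the mass beyond K
        if theta < 1:
            tail = q[-1] * theta / (1 - theta)
        else:
            s = beta + 1 - alpha  # tail exponent, > 1 by the check above
            tail = q[-1] * K / (s - 1)
        if tail < tail_tol * total:
            break
        if K > 1 << 24:
            raise ValueError("tail does not converge within bounds")
        K *= 2
    return q / total


def p0_closed_form(alpha: float, beta: float) -> float:
    """Zero-class probability 1 - alpha/beta of the stationary process."""
    if not 0 < alpha < beta:
        raise ValueError("requires 0 < alpha < beta")
    return 1.0 - alpha / beta


def kw_rvs(
    theta: float,
    alpha: float,
    beta: float,
    size: int,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Draw counts from the distribution (inverse-pmf sampling)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    p = kw_pmf(theta, alpha, beta)
    return rng.choice(len(p), size=size, p=p)


@dataclass(frozen=True)
class KWFit:
    theta: float
    alpha: float
    beta: float
    p0_closed: float     # 1 - alpha/beta (closed form)
    p0_pmf: float        # zero class of the normalized fitted pmf
    loglik: float
    k_max: int
    n: int
    zero_truncated: bool

    def pmf(self, k_max: Optional[int] = None) -> np.ndarray:
        return kw_pmf(self.theta, self.alpha, self.beta, k_max=k_max)


def _nll(params: np.ndarray, counts_k: np.ndarray, weights: np.ndarray,
         zero_truncated: bool) -> float:
    t, la, ld = params
    theta = float(expit(t))
    with np.errstate(over="ignore"):
        alpha = float(np.exp(la))
        beta = alpha + float(np.exp(ld))
    if not (np.isfinite(alpha) and np.isfinite(beta)) or alpha > 1e9 or beta > 1e9:
        return 1e12
    try:
        p = kw_pmf(theta, alpha, beta, k_max=int(counts_k[-1]))
    except (ValueError, FloatingPointError, OverflowError):
        return 1e12
    with np.errstate(divide="ignore"):
        logp = np.log(p[counts_k])
    if zero_truncated:
        logp = logp - np.log1p(-p[0])
    val = -float(np.dot(weights, logp))
    return val if np.isfinite(val) else 1e12


def fit_kw(
    counts: Sequence[int],
    zero_truncated: bool = False,
    seed: Optional[int] = None,
) -> KWFit:
    """Maximum-likelihood Kolmogorov-Waring fit of a count sample.

    Multi-start bounded optimization over (theta, alpha, beta - alpha) on
    transformed coordinates, with a grid of initial values for theta and the
    alpha/beta ratio; ``zero_truncated`` conditions the likelihood on counts
    >= 1 (for samples where the zero class is unobservable). Deterministic:
    the ``seed`` is part of the contract but the optimization itself uses no
    randomness.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size < 50:
        raise ValueError("need at least 50 observations")
    if counts.min() < 0:
        raise ValueError("counts must be nonnegative")
    if counts.min() == counts.max():
        raise ValueError("degenerate sample: all counts equal")
    if zero_truncated and counts.min() == 0:
        raise ValueError("zero-truncated fit given zero counts")
    uniq, w = np.unique(counts, return_counts=True)
    mean = float(counts.mean())

    best = None
    for theta0 in (0.5, 0.9, 0.99):
        for ratio0 in (0.5, 0.9, 0.99):
            beta0 = max(mean + 1.0, 2.0)
            alpha0 = ratio0 * beta0
            x0 = np.array(
                [logit(theta0), np.log(alpha0), np.log(beta0 - alpha0)]
            )
            res = minimize(
                _nll,
                x0,
                args=(uniq, w.astype(float), zero_truncated),
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
    t, la, ld = best.x
    theta = float(expit(t))
    alpha = float(np.exp(la))
    beta = alpha + float(np.exp(ld))
    p = kw_pmf(theta, alpha, beta, k_max=int(uniq[-1]))
    return KWFit(
        theta=theta,
        alpha=alpha,
        beta=beta,
        p0_closed=p0_closed_form(alpha, beta),
        p0_pmf=float(p[0]),
        loglik=-float(best.fun),
        k_max=len(p) - 1,
        n=int(counts.size),
        zero_truncated=zero_truncated,
    )


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two probability vectors."""
    n = max(len(p), len(q))
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: len(p)] = p
    qq[: len(q)] = q
    return 0.5 * float(np.abs(pp - qq).sum())
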