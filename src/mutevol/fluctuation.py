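"""Luria-Delbrueck fluctuation-test estimation.

The mutant-count distribution is computed with the Ma-Sandri-Sarkar
recursion; the expected number of mutations per culture (m) is estimated by
maximum likelihood using the exact score recursion, with the per-division
mutation rate given by mu = m / Nt.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .simulate import FluctuationAssay

#: counts above this are right-censored into a single tail bin
DEFAULT_KMAX = 10_000


def ld_pmf(m: float, k_max: int) -> np.ndarray:
    """Luria-Delbrueck probabilities p_0 ... p_{k_max} at parameter m.

    Ma-Sandri-Sarkar recursion:
        p_0 = exp(-m)
        p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1)
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m)
    if m == 0 or k_max == 0:
        return p
    # w[d-1] = 1/(d+1) where d = k - i
    w = 1.0 / np.arange(2, k_max + 2)
    for k in range(1, k_max + 1):
        p[k] = (m / k) * np.dot(p[:k], w[k - 1 :: -1])
    return p


def _pmf_and_derivative(m: float, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    """p_k and dp_k/dm via the differentiated recursion."""
    p = ld_pmf(m, k_max)
    dp = np.zeros(k_max + 1)
    dp[0] = -math.exp(-m)
    if m > 0:
        w = 1.0 / np.arange(2, k_max + 2)
        for k in range(1, k_max + 1):
            ww = w[k - 1 :: -1]
            dp[k] = p[k] / m + (m / k) * np.dot(dp[:k], ww)
    return p, dp


def _bin_counts(counts: np.ndarray, k_max: int) -> tuple[np.ndarray, int]:
    """Histogram of counts 0..k_max plus the number right-censored above."""
    counts = np.asarray(counts, dtype=np.int64)
    tail = int((counts > k_max).sum())
    hist = np.bincount(counts[counts <= k_max], minlength=k_max + 1)
    return hist, tail


def ld_loglik(m: float, counts: np.ndarray, k_max: int = DEFAULT_KMAX) -> float:
    """Log-likelihood of observed mutant counts at parameter m.

    Counts above ``k_max`` contribute through the censored tail mass
    1 - sum_{k<=k_max} p_k.
    """
    k_cap = min(int(np.max(counts, initial=0)), k_max)
    hist, tail = _bin_counts(counts, k_cap)
    p = ld_pmf(m, k_cap)
    with np.errstate(divide="ignore"):
        ll = float(np.dot(hist, np.log(np.where(hist > 0, p, 1.0))))
    if tail:
        tail_mass = max(1.0 - p.sum(), 1e-300)
        ll += tail * math.log(tail_mass)
    return ll


@dataclass
class LDEstimate:
    """Maximum-likelihood fluctuation-test estimate."""

    m_hat: float  # expected mutations per culture
    mu_hat: float  # per-division mutation rate, m_hat / Nt
    loglik: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    label: str = ""
    degenerate: bool = False  # all counts zero


def _score(m: float, hist: np.ndarray, tail: int, k_cap: int) -> float:
    """d log L / dm."""
    p, dp = _pmf_and_derivative(m, k_cap)
    nz = hist > 0
    s = float(np.dot(hist[nz], dp[nz] / p[nz]))
    if tail:
        tail_mass = max(1.0 - p.sum(), 1e-300)
        s += tail * (-dp.sum()) / tail_mass
    return s


def ld_mle(
    assay: FluctuationAssay,
    k_max: int = DEFAULT_KMAX,
    ci: bool = False,
) -> LDEstimate:
    """Maximum-likelihood m (and mu = m/Nt) for a fluctuation assay.

    The score equation is solved by safeguarded root bracketing on the
    exact derivative recursion; an optional 95% profile-likelihood interval
    for m uses the 1.92 log-likelihood drop.
    """
    counts = np.asarray(assay.counts, dtype=np.int64)
    if counts.size < 2:
        raise ValueError("need at least two cultures")
    if counts.max(initial=0) == 0:
        warnings.warn("all mutant counts are zero; m_hat = 0 is degenerate")
        return LDEstimate(
            m_hat=0.0, mu_hat=0.0, loglik=0.0, label=assay.label,
            degenerate=True,
        )
    k_cap = min(int(counts.max()), k_max)
    hist, tail = _bin_counts(counts, k_cap)

    # bracket the root of the score: score > 0 at small m, < 0 at large m
    lo = 1e-9
    n0 = int(hist[0])
    # P0 estimate -ln(f0) seeds the upper bracket when zeros exist
    hi = max(1.0, 2.0 * (-math.log(max(n0, 0.5) / counts.size)))
    for _ in range(60):
        if _score(hi, hist, tail, k_cap) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("fluctuation MLE failed to bracket the optimum")
    if _score(lo, hist, tail, k_cap) <= 0:
        m_hat = lo
    else:
        m_hat = float(
            optimize.brentq(
                _score, lo, hi, args=(hist, tail, k_cap), xtol=1e-12,
                rtol=1e-12,
            )
        )
    ll = ld_loglik(m_hat, counts, k_max)
    est = LDEstimate(
        m_hat=m_hat,
        mu_hat=m_hat / assay.n_final,
        loglik=ll,
        label=assay.label,
    )
    if ci:
        target = ll - 1.92

        def drop(m):
            return ld_loglik(m, counts, k_max) - target

        lo_ci = None
        try:
            if drop(1e-9) < 0:
                lo_ci = float(optimize.brentq(drop, 1e-9, m_hat, xtol=1e-10))
        except ValueError:
            pass
        hi_ci = None
        upper = m_hat * 2 + 1
        for _ in range(60):
            if drop(upper) < 0:
                hi_ci = float(
                    optimize.brentq(drop, m_hat, upper, xtol=1e-10)
                )
                break
            upper *= 2
        est.ci_low, est.ci_high = lo_ci, hi_ci
    return est


def fold_change(estimate_a: LDEstimate, estimate_b: LDEstimate) -> float:
    """Ratio of per-division rates mu_a / mu_b; NaN when mu_b is zero."""
    if estimate_b.mu_hat == 0:
        warnings.warn("reference rate is zero; fold change undefined")
        return math.nan
    return estimate_a.mu_hat / estimate_b.mu_hat
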