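"""Covariance-aware association of pool allele frequencies with resistance.

Analytic core of the hierarchical population model: allele frequencies are
standardized per locus, the across-population covariance Omega of the
standardized frequencies (shared demographic history plus sampling noise) is
estimated by the method of moments, and a contrast statistic

    C2_l = (c' a_l)^2 / (c' Omega c)

with a zero-sum contrast vector c (+1 resistant, -1 susceptible) is referred
to a chi-square distribution with 1 d.f.  Decision rules follow the scan
design: local false discovery rate (Grenander density estimator) below 0.2,
and an approximate Gaussian Bayes factor above 5 deciban.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def standardize(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardized frequency deviations a_lj = (p_lj - pi_l)/sqrt(pi_l(1-pi_l)).

    pi_l is the unweighted pool mean.  Returns (a matrix, keep mask); loci
    with pi in {0, 1} cannot be standardized and are masked out.
    """
    freqs = np.asarray(freqs, dtype=float)
    pi = freqs.mean(axis=1)
    keep = (pi > 0.0) & (pi < 1.0)
    if not keep.all():
        log.warning("standardize: dropped %d loci with mean frequency 0 or 1",
                    int((~keep).sum()))
    a = np.full_like(freqs, np.nan)
    sd = np.sqrt(pi[keep] * (1.0 - pi[keep]))
    a[keep] = (freqs[keep] - pi[keep, None]) / sd[:, None]
    return a[keep], keep


def estimate_omega(a: np.ndarray) -> np.ndarray:
    """Method-of-moments Omega = (1/L) sum a_l a_l', ridge-regularized.

    The ridge epsilon = 1e-6 * trace/J guarantees positive-definiteness.
    Binomial sampling noise inflates the diagonal; no subtraction is applied
    (keeps the matrix PD).
    """
    a = np.asarray(a, dtype=float)
    L, J = a.shape
    if L < J:
        raise ValueError(f"need at least {J} loci to estimate a {J}x{J} covariance")
    omega = a.T @ a / L
    eps = 1e-6 * np.trace(omega) / J
    return omega + eps * np.eye(J)


@dataclass
class ContrastResult:
    c2: np.ndarray
    p_value: np.ndarray
    y: np.ndarray  # signed standardized contrast
    lfdr: np.ndarray | None = None
    db: np.ndarray | None = None  # Bayes factor in deciban


def c2_statistic(a: np.ndarray, omega: np.ndarray, contrast: np.ndarray) -> ContrastResult:
    """Per-locus contrast statistic and chi-square(1) upper-tail p-value."""
    c = np.asarray(contrast, dtype=float)
    if abs(c.sum()) > 1e-9:
        raise ValueError("contrast vector must sum to zero")
    denom = float(c @ omega @ c)
    if denom <= 0:
        raise ValueError("contrast variance c'Omega*c is not positive")
    y = (a @ c) / np.sqrt(denom)
    c2 = y**2
    p = stats.chi2.sf(c2, df=1)
    return ContrastResult(c2=c2, p_value=p, y=y)


def grenander_density(p_sorted: np.ndarray) -> np.ndarray:
    """Grenander (monotone non-increasing) density of p-values.

    Slopes of the least concave majorant of the ECDF on [0, 1], evaluated at
    the sorted sample points; computed by pool-adjacent-violators on the
    slope sequence.  Deterministic, no bandwidth.
    """
    m = len(p_sorted)
    x = np.concatenate([[0.0], p_sorted, [1.0]])
    y = np.concatenate([[0.0], np.arange(1, m + 1) / m, [1.0]])
    dx = np.diff(x)
    dy = np.diff(y)
    # LCM slopes: isotonic (non-increasing) fit of dy/dx weighted by dx
    def slope(ddy, ddx):
        return ddy / ddx if ddx > 0 else np.inf

    dys: list[float] = []
    dxs: list[float] = []
    counts: list[int] = []
    for i in range(len(dx)):
        dys.append(dy[i])
        dxs.append(dx[i])
        counts.append(1)
        while len(dys) > 1 and slope(dys[-2], dxs[-2]) <= slope(dys[-1], dxs[-1]):
            y2, x2, n2 = dys.pop(), dxs.pop(), counts.pop()
            dys[-1] += y2
            dxs[-1] += x2
            counts[-1] += n2
    out = np.repeat([slope(a, b) for a, b in zip(dys, dxs)], counts)
    # density at sample point i = slope of the segment to its left
    return np.maximum(out[:m], 1e-300)


def local_fdr(p_values: np.ndarray) -> np.ndarray:
    """Local false discovery rate lfdr(p) = min(1, pi0 / f(p)).

    pi0 = min(1, #{p > 0.5} / (0.5 m)); f is the Grenander density.  lfdr is
    non-decreasing in p by monotonicity of f.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m < 100:
        log.warning("local_fdr on %d p-values: estimate will be unstable", m)
    pi0 = min(1.0, (p > 0.5).sum() / (0.5 * m))
    order = np.argsort(p, kind="stable")
    dens = grenander_density(p[order])
    lfdr_sorted = np.minimum(1.0, pi0 / dens)
    lfdr_sorted = np.maximum.accumulate(lfdr_sorted)  # enforce monotonicity
    out = np.empty(m)
    out[order] = lfdr_sorted
    return out


def approx_bayes_factor(y: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Gaussian conjugate Bayes factor in deciban for the standardized
    contrast y: N(0, 1+tau) vs N(0, 1) ->
    BF = (1+tau)^(-1/2) exp(y^2 tau / (2 (1+tau))); dB = 10 log10 BF."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    y = np.asarray(y, dtype=float)
    log_bf = -0.5 * np.log(1.0 + tau) + y**2 * tau / (2.0 * (1.0 + tau))
    return 10.0 * log_bf / np.log(10.0)
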