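"""Analytic calibration of crossover intensities to a target map distance.

The Perkins estimator d = 100(TT/2 + 3 NPD)/n is exactly unbiased for
intervals receiving at most two crossovers per bivalent but saturates for
three or more, so at realistic interval sizes the expected estimate falls
slightly below 100 * E[crossovers]/2.  For parameter-recovery studies the
generating intensities are therefore calibrated so that the *expected
Perkins distance* over an interval equals the target map length.

The expectation is computed analytically:

* the per-bivalent crossover count in a window of length ``t`` is the sum
  of a stationary gamma-renewal count (class I) and an independent Poisson
  count (class II); the renewal count distribution follows from
  P(N >= j) = P(X_e + X_2 + ... + X_j <= t) with X_e the equilibrium
  (forward-recurrence) first interval, evaluated by numerical convolution;
* given k crossovers, the expected value of TT/2 + 3 NPD follows the
  classical tetrad-type chain PD -> TT; TT -> (1/4, 1/2, 1/4);
  NPD -> TT under no chromatid interference.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .genmap import ConfigurationError, PathwayParams

__all__ = [
    "tetrad_type_probs",
    "perkins_moment",
    "renewal_count_pmf",
    "expected_perkins_distance",
    "calibrate_to_distance",
]

_KMAX = 40


def tetrad_type_probs(k: int) -> tuple[float, float, float]:
    """(PD, TT, NPD) probabilities for exactly k crossovers in an interval."""
    p = np.array([1.0, 0.0, 0.0])
    chain = np.array([[0.0, 1.0, 0.0], [0.25, 0.5, 0.25], [0.0, 1.0, 0.0]])
    for _ in range(k):
        p = p @ chain
    return float(p[0]), float(p[1]), float(p[2])


def perkins_moment(k: int) -> float:
    """E[TT/2 + 3 NPD] for a tetrad with exactly k interval crossovers.

    Equals k/2 for k <= 2 (the estimator's unbiased range) and falls
    below it for k >= 3.
    """
    _, tt, npd = tetrad_type_probs(k)
    return tt / 2.0 + 3.0 * npd


def renewal_count_pmf(
    t: float, intensity: float, shape: float, kmax: int = _KMAX, grid: int = 4001
) -> np.ndarray:
    """P(N = 0..kmax) for a stationary gamma renewal process on [0, t]."""
    if intensity == 0 or t == 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    mu = 1.0 / intensity
    theta = 1.0 / (intensity * shape)
    u = np.linspace(0.0, t, grid)
    sf = stats.gamma.sf(u, shape, scale=theta)
    # H_j = P(N >= j); H_1 is the forward-recurrence CDF at t
    H = [1.0, (t * sf[-1] + mu * stats.gamma.cdf(t, shape + 1, scale=theta)) / mu]
    fe = sf / mu  # equilibrium density on the grid
    for j in range(2, kmax + 2):
        g = stats.gamma.cdf(t - u, (j - 1) * shape, scale=theta)
        hj = float(np.trapezoid(fe * g, u))
        H.append(hj)
        if hj < 1e-14:
            break
    H = np.array(H + [0.0] * (kmax + 2 - len(H)))
    pmf = H[:-1] - H[1:]
    return np.clip(pmf[: kmax + 1], 0.0, None)


def expected_perkins_distance(
    interval_length: float, params: PathwayParams, kmax: int = _KMAX
) -> float:
    """Expected Perkins estimate (cM) for an interval under the two-pathway model.

    Assumes the unconditioned process (no obligate-crossover rejection):
    counts are the independent sum of the stationary class I renewal count
    and the class II Poisson count in the interval.
    """
    pmf1 = renewal_count_pmf(
        interval_length, params.class1_intensity, params.interference_shape, kmax
    )
    lam2 = params.class2_intensity * interval_length
    pmf2 = stats.poisson.pmf(np.arange(kmax + 1), lam2) if lam2 > 0 else None
    pmf = pmf1 if pmf2 is None else np.convolve(pmf1, pmf2)[: kmax + 1]
    moments = np.array([perkins_moment(k) for k in range(pmf.size)])
    return float(100.0 * (pmf * moments).sum())


def calibrate_to_distance(
    target_d: float, interval_length: float, base: PathwayParams
) -> PathwayParams:
    """Scale both pathway intensities so E[Perkins distance] = target_d.

    Keeps the class I : class II proportion and the interference shape of
    ``base``; only the total intensity is rescaled.  Used to generate
    parameter-recovery datasets whose estimator is centred on the truth.
    """
    if base.total_intensity == 0:
        raise ConfigurationError("cannot calibrate: both intensities are zero")
    if target_d <= 0:
        raise ConfigurationError(f"target distance must be > 0, got {target_d}")

    def scaled(s: float) -> PathwayParams:
        return PathwayParams(
            class1_intensity=base.class1_intensity * s,
            interference_shape=base.interference_shape,
            class2_intensity=base.class2_intensity * s,
            obligate_co=base.obligate_co,
        )

    def f(s: float) -> float:
        return expected_perkins_distance(interval_length, scaled(s)) - target_d

    # naive scale: 2 crossovers per Morgan, exact in the unbiased range
    s0 = (2.0 * target_d / 100.0) / (base.total_intensity * interval_length)
    lo, hi = s0 * 0.8, s0 * 1.6
    while f(lo) > 0:
        lo *= 0.5
    while f(hi) < 0:
        hi *= 1.5
    s = brentq(f, lo, hi, xtol=1e-10)
    return scaled(s)
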