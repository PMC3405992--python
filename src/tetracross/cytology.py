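"""Cytology-level statistics: chiasma summaries, epistasis grouping, foci tests.

Covers the downstream numerics of a chiasma/foci counting experiment:
per-genotype summaries, fold-decrease and residual-percent arithmetic,
one-way ANOVA followed by a Student-Newman-Keuls (SNK) multiple-comparison
grouping, and Welch t-tests computable from summary statistics alone
(mean, SD, n) when raw counts are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ChiasmaSummary",
    "FociSummary",
    "SNKResult",
    "summarize_chiasma",
    "residual_percent",
    "fold_decrease",
    "anova_snk",
    "welch_t_from_summary",
]


@dataclass(frozen=True)
class ChiasmaSummary:
    genotype: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class FociSummary:
    stage: str
    genotype: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class SNKResult:
    """ANOVA F/p plus SNK letter groups (shared letter = not different)."""

    F: float
    p: float
    letters: dict[str, str]
    alpha: float


def summarize_chiasma(counts: Sequence[float], genotype: str) -> ChiasmaSummary:
    """Sample mean, SD (n-1 denominator) and n of per-cell chiasma counts."""
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty chiasma count vector")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return ChiasmaSummary(genotype, float(x.mean()), sd, int(x.size))


def residual_percent(mutant_mean: float, wt_mean: float, digits: int = 0) -> float:
    """Residual level as a percentage of wild type: 100 * mutant / wt.

    Rounded to ``digits`` decimals (default: nearest integer percent,
    the usual print convention).
    """
    if wt_mean <= 0:
        raise ValueError(f"wild-type mean must be > 0, got {wt_mean}")
    return round(100.0 * mutant_mean / wt_mean, digits)


def fold_decrease(wt_mean: float, mutant_mean: float, digits: int = 1) -> float:
    """Fold decrease wt / mutant, 1 decimal by default; inf when mutant = 0."""
    if mutant_mean < 0:
        raise ValueError(f"mutant mean must be >= 0, got {mutant_mean}")
    if mutant_mean == 0:
        return float("inf")
    return round(wt_mean / mutant_mean, digits)


# ---------------------------------------------------------------------------
# ANOVA + Student-Newman-Keuls
# ---------------------------------------------------------------------------


def _snk_letters(
    names: list[str],
    means: np.ndarray,
    mse: float,
    df_error: int,
    n_harmonic: float,
    alpha: float,
) -> dict[str, str]:
    """Stepwise SNK on sorted means; returns compact letter display.

    Means are sorted ascending; a stretch of r adjacent means is
    homogeneous if the studentized range of its extremes does not exceed
    the critical value q(alpha, r, df).  Significant stretches are split
    recursively (standard SNK step-down); maximal homogeneous stretches
    each receive one letter.  Exact ties are never declared different
    (their range statistic is 0 < q_crit).
    """
    k = len(names)
    order = np.argsort(means, kind="stable")
    m = means[order]
    se = np.sqrt(mse / n_harmonic)

    homogeneous: list[tuple[int, int]] = []

    def different(i: int, j: int) -> bool:
        # Is the stretch i..j (inclusive) heterogeneous at its range level?
        r = j - i + 1
        diff = m[j] - m[i]
        if diff == 0:
            return False
        if se == 0:
            return True  # zero within-group variance: any mean gap is real
        q = diff / se
        q_crit = stats.studentized_range.ppf(1.0 - alpha, r, df_error)
        return bool(q > q_crit)

    def step(i: int, j: int) -> None:
        if i > j:
            return
        if i == j or not different(i, j):
            homogeneous.append((i, j))
            return
        step(i, j - 1)
        step(i + 1, j)

    step(0, k - 1)
    # keep maximal stretches only, in left-to-right order
    homogeneous = sorted(set(homogeneous))
    maximal = [
        (a, b)
        for a, b in homogeneous
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in homogeneous)
    ]
    letters = {name: "" for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (a, b) in enumerate(maximal):
        ch = alphabet[idx % len(alphabet)]
        for pos in range(a, b + 1):
            letters[names[order[pos]]] += ch
    return letters


def anova_snk(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> SNKResult:
    """One-way ANOVA followed by an SNK grouping of the genotype means.

    Genotypes sharing a letter are not significantly different at
    ``alpha``.  Unbalanced designs use the harmonic mean group size in the
    range statistic (standard SNK practice).
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, x in zip(names, arrays):
        if x.size < 2:
            raise ValueError(f"group {g!r} has n < 2")
    F, p = stats.f_oneway(*arrays)
    N = sum(x.size for x in arrays)
    k = len(arrays)
    df_error = N - k
    mse = sum((x.size - 1) * x.var(ddof=1) for x in arrays) / df_error
    n_harmonic = k / sum(1.0 / x.size for x in arrays)
    means = np.array([x.mean() for x in arrays])
    letters = _snk_letters(names, means, mse, df_error, n_harmonic, alpha)
    return SNKResult(float(F), float(p), letters, alpha)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> tuple[float, float, float]:
    """Welch two-sample t-test from summary statistics.

    Returns ``(t, df, p_two_sided)`` with Satterthwaite degrees of
    freedom.  Degenerate SDs (both 0) with equal means give t = 0, p = 1
    by convention; degenerate SDs with unequal means are an error.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
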