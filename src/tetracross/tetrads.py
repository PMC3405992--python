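"""Tetrad classification, Perkins map distances, and interference ratios.

A two-marker tetrad falls in one of three configurations: parental ditype
(PD: two spores carry both markers, two carry neither), tetratype (TT: one
spore of each of the four combinations) and non-parental ditype (NPD: two
spores carry only the first marker, two only the second).  The Perkins
estimator converts the tallies to a map distance,

    d = 100 * (TT/2 + 3*NPD) / n   [cM],

which corrects single- and double-crossover classes under random chromatid
assignment (it saturates for triple and higher crossovers, a negligible
class at the interval sizes handled here).

Interference between adjacent intervals is quantified as the ratio of the
target interval's map distance among tetrads that do carry a recombination
event in the neighbouring interval (conditioning class TT or NPD) to the
distance among tetrads that do not.  Independent (Poisson) crossovers give
a ratio of 1; positive interference drives it below 1.  The accompanying
test of independence is a G-test of homogeneity on the stratum x
{PD, TT, NPD} table, with a tetrad-resampling bootstrap CI on the ratio as
a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TetradRecord

__all__ = [
    "IntervalCounts",
    "MapEstimate",
    "InterferenceResult",
    "classify_interval",
    "classify_table",
    "count_intervals",
    "perkins_distance",
    "stratify_by_adjacent",
    "interference_ratio",
    "joint_interval_counts",
]

CLASSES = ("PD", "TT", "NPD")


@dataclass(frozen=True)
class IntervalCounts:
    """PD/TT/NPD tallies for one marker interval."""

    interval_id: str
    PD: int
    TT: int
    NPD: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("PD", "TT", "NPD", "n_excluded"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.PD + self.TT + self.NPD


@dataclass(frozen=True)
class MapEstimate:
    """Perkins map distance (cM) with its delta-method standard error."""

    interval_id: str
    d: float
    se: float | None
    counts: IntervalCounts


@dataclass(frozen=True)
class InterferenceResult:
    """Stratified map distances and their ratio for an interval pair.

    ``ratio = d_with / d_without`` where the strata condition on a
    recombination event (TT or NPD) in the adjacent interval; ``ratio`` is
    NaN (flagged by ``defined=False``) when a stratum is empty or
    ``d_without`` is 0.
    """

    target_interval: str
    conditioning_interval: str
    d_with: float
    d_without: float
    ratio: float
    n_with: int
    n_without: int
    test_statistic: float
    p_value: float
    method: str
    defined: bool = True
    ci_low: float | None = None
    ci_high: float | None = None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _spore_columns(table: pd.DataFrame, marker: str) -> np.ndarray:
    cols = [f"s{i}_{marker}" for i in range(1, 5)]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"unknown marker {marker!r}: missing columns {missing}")
    return table[cols].to_numpy(dtype=np.int64)


def classify_interval(tetrad: TetradRecord, marker_index_a: int, marker_index_b: int) -> str:
    """Classify one tetrad for one interval: 'PD', 'TT', 'NPD' or 'excluded'.

    Restricts each spore to its (a, b) allele pair; any marker not
    segregating 2:2 makes the tetrad 'excluded'.  The result is invariant
    under spore permutation.
    """
    a = [s[marker_index_a] for s in tetrad.spores]
    b = [s[marker_index_b] for s in tetrad.spores]
    if sum(a) != 2 or sum(b) != 2:
        return "excluded"
    pairs = sorted(zip(a, b))
    if pairs == [(0, 0), (0, 0), (1, 1), (1, 1)]:
        return "PD"
    if pairs == [(0, 1), (0, 1), (1, 0), (1, 0)]:
        return "NPD"
    return "TT"


def classify_table(
    table: pd.DataFrame, marker_a: str, marker_b: str
) -> pd.Series:
    """Vectorised PD/TT/NPD/excluded classification of a wide tetrad table."""
    a = _spore_columns(table, marker_a)
    b = _spore_columns(table, marker_b)
    ok = (a.sum(axis=1) == 2) & (b.sum(axis=1) == 2)
    c11 = ((a == 1) & (b == 1)).sum(axis=1)
    c10 = ((a == 1) & (b == 0)).sum(axis=1)
    out = np.where(c11 == 2, "PD", np.where(c10 == 2, "NPD", "TT"))
    out = np.where(ok, out, "excluded")
    return pd.Series(out, index=table.index, name=f"{marker_a}-{marker_b}")


def count_intervals(
    table: pd.DataFrame, marker_a: str, marker_b: str, interval_id: str | None = None
) -> IntervalCounts:
    """Tally PD/TT/NPD over a tetrad table; excluded rows counted separately."""
    if len(table) == 0:
        raise ValueError("empty tetrad table")
    cls = classify_table(table, marker_a, marker_b)
    vc = cls.value_counts()
    return IntervalCounts(
        interval_id=interval_id or f"{marker_a}-{marker_b}",
        PD=int(vc.get("PD", 0)),
        TT=int(vc.get("TT", 0)),
        NPD=int(vc.get("NPD", 0)),
        n_excluded=int(vc.get("excluded", 0)),
    )


# ---------------------------------------------------------------------------
# Perkins mapping
# ---------------------------------------------------------------------------


def perkins_distance(counts: IntervalCounts) -> MapEstimate:
    """Perkins map distance d = 100 * (TT/2 + 3*NPD) / n, in cM.

    The standard error comes from the multinomial delta method,

        Var(d) = (100^2 / n) * [p_TT/4 + 9 p_NPD - (p_TT/2 + 3 p_NPD)^2],

    with plug-in proportions.
    """
    n = counts.n
    if n == 0:
        raise ValueError(f"no classified tetrads for {counts.interval_id}")
    p_tt = counts.TT / n
    p_npd = counts.NPD / n
    d = 100.0 * (p_tt / 2.0 + 3.0 * p_npd)
    var = (100.0**2 / n) * (p_tt / 4.0 + 9.0 * p_npd - (p_tt / 2.0 + 3.0 * p_npd) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return MapEstimate(counts.interval_id, d, se, counts)


# ---------------------------------------------------------------------------
# Interference
# ---------------------------------------------------------------------------


def _check_adjacent(
    table: pd.DataFrame, target: tuple[str, str], conditioning: tuple[str, str]
) -> None:
    shared = set(target) & set(conditioning)
    if len(shared) != 1:
        raise ValueError(
            f"intervals {target} and {conditioning} are not adjacent "
            "(they must share exactly one marker)"
        )


def stratify_by_adjacent(
    table: pd.DataFrame,
    target: tuple[str, str],
    conditioning: tuple[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tetrads by presence of a crossover in the conditioning interval.

    A tetrad carries an adjacent crossover iff its conditioning-interval
    class is TT or NPD.  Tetrads excluded in either interval are dropped
    from both strata.  Returns ``(with_adjacent, without_adjacent)``.
    """
    _check_adjacent(table, target, conditioning)
    cond = classify_table(table, *conditioning)
    targ = classify_table(table, *target)
    keep = (cond != "excluded") & (targ != "excluded")
    has_co = keep & cond.isin(("TT", "NPD"))
    return table[has_co], table[keep & ~has_co]


def joint_interval_counts(
    table: pd.DataFrame,
    target: tuple[str, str],
    conditioning: tuple[str, str],
) -> np.ndarray:
    """3x3 joint counts: rows = target class, cols = conditioning class."""
    targ = classify_table(table, *target)
    cond = classify_table(table, *conditioning)
    keep = (cond != "excluded") & (targ != "excluded")
    out = np.zeros((3, 3), dtype=np.int64)
    ti = pd.Categorical(targ[keep], categories=CLASSES).codes
    ci = pd.Categorical(cond[keep], categories=CLASSES).codes
    np.add.at(out, (ti, ci), 1)
    return out


def _perkins_from_class_counts(c: np.ndarray) -> np.ndarray:
    """Perkins d for count vectors [..., (PD, TT, NPD)]; NaN when n = 0."""
    c = np.asarray(c, dtype=float)
    n = c.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * (c[..., 1] / 2.0 + 3.0 * c[..., 2]) / n


def _bootstrap_ratio_ci(
    joint: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the ratio, resampling whole tetrads.

    The joint (target x conditioning) classification is a 9-cell
    multinomial, so resampling tetrads reduces to resampling the 9 cell
    counts.
    """
    n = int(joint.sum())
    p = joint.ravel() / n
    draws = rng.multinomial(n, p, size=n_boot).reshape(n_boot, 3, 3)
    with_c = draws[:, :, 1] + draws[:, :, 2]  # conditioning TT or NPD
    without_c = draws[:, :, 0]
    d_with = _perkins_from_class_counts(with_c)
    d_without = _perkins_from_class_counts(without_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = d_with / d_without
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _g_test(table_2x3: np.ndarray) -> tuple[float, float]:
    """G-test of homogeneity; zero-sum columns are dropped."""
    t = np.asarray(table_2x3, dtype=float)
    t = t[:, t.sum(axis=0) > 0]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    g, p, _, _ = stats.chi2_contingency(t, correction=False, lambda_="log-likelihood")
    return float(g), float(p)


def interference_ratio(
    table: pd.DataFrame,
    target: tuple[str, str],
    conditioning: tuple[str, str],
    *,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
    interval_id: str | None = None,
    conditioning_id: str | None = None,
) -> InterferenceResult:
    """Adjacent-interval interference ratio with a G-test of independence.

    ``d_with`` and ``d_without`` are Perkins distances of the target
    interval within the stratum of tetrads with / without a crossover in
    the conditioning interval; ``ratio = d_with / d_without`` (1 under
    independence, < 1 under positive interference).  The p-value is from a
    G-test of homogeneity of the target's (PD, TT, NPD) composition across
    strata; a percentile bootstrap CI (tetrad resampling) is attached when
    ``n_boot > 0``.
    """
    _check_adjacent(table, target, conditioning)
    joint = joint_interval_counts(table, target, conditioning)
    with_c = joint[:, 1] + joint[:, 2]
    without_c = joint[:, 0]
    n_with = int(with_c.sum())
    n_without = int(without_c.sum())
    tid = interval_id or "-".join(target)
    cid = conditioning_id or "-".join(conditioning)
    if n_with == 0 or n_without == 0:
        return InterferenceResult(
            tid, cid, float("nan"), float("nan"), float("nan"),
            n_with, n_without, float("nan"), float("nan"),
            method="g_test", defined=False,
        )
    d_with = float(_perkins_from_class_counts(with_c))
    d_without = float(_perkins_from_class_counts(without_c))
    defined = d_without > 0
    ratio = d_with / d_without if defined else float("nan")
    g, p = _g_test(np.stack([with_c, without_c]))
    ci_low = ci_high = None
    if n_boot > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        ci_low, ci_high = _bootstrap_ratio_ci(joint, n_boot, rng)
    return InterferenceResult(
        tid, cid, d_with, d_without, ratio, n_with, n_without,
        g, p, method="g_test", defined=defined, ci_low=ci_low, ci_high=ci_high,
    )
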