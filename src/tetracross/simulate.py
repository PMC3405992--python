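"""Two-pathway meiotic crossover simulator.

Crossovers are placed on each bivalent on the genetic (cM) scale by two
independent point processes:

* class I (interfering): a stationary renewal process whose inter-event
  spacings are gamma distributed with shape ``interference_shape`` and mean
  ``1 / class1_intensity``.  Shape 1 recovers a homogeneous Poisson process
  (no interference); larger shapes give increasingly regular spacing
  (positive interference).  The first event is drawn from the length-biased
  equilibrium (forward-recurrence) distribution so that event counts in any
  sub-interval are translation invariant.
* class II (non-interfering): a homogeneous Poisson process.

Each crossover joins the two homologs: it involves one strand carrying
each parental origin at the event position, chosen uniformly and
independently (no chromatid interference).  A tetrad is read out by
exchanging the distal continuations of the two chosen strands at each
event in position order, then scoring marker presence per strand; every
tetrad therefore segregates 2:2 by construction, and the tetrad-type
transitions follow the classical chain (PD -> TT; TT -> 1/4 PD, 1/2 TT,
1/4 NPD; NPD -> TT).

Chiasmata are scored with the standard metaphase I convention: a bivalent
with crossovers on a single centromere arm is a rod (1 chiasma); one with
crossovers on both arms is a ring (2 chiasmata); a bivalent without any
crossover is a univalent pair (0).

Two code paths produce tetrads: a per-bivalent object path
(:func:`simulate_bivalent` / :func:`derive_tetrad`) used for inspection and
small-scale work, and a vectorised batch path (:func:`simulate_tetrads`)
used for large experiments.  They implement the same model and are checked
against each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import (
    ConfigurationError,
    GeneticMap,
    GenotypePreset,
    PathwayParams,
    marker_chromosome,
)

__all__ = [
    "CrossoverEvent",
    "BivalentOutcome",
    "TetradRecord",
    "ChiasmaScore",
    "draw_class1_positions",
    "draw_class2_positions",
    "enforce_obligate",
    "assign_chromatids",
    "simulate_bivalent",
    "derive_tetrad",
    "score_chiasmata",
    "simulate_tetrads",
    "simulate_experiment",
    "tetrads_to_frame",
]


@dataclass(frozen=True)
class CrossoverEvent:
    """One crossover: position (cM), pathway ('I' or 'II'), chromatid pair.

    ``chromatid_pair = (i, j)`` selects, at the event position, the
    ``i``-th of the two strands carrying homolog 1's allele and the
    ``j``-th of the two carrying homolog 2's allele (each index in
    {0, 1}, strands ordered by chromatid number).  Before any exchange
    this is simply one chromatid of each homolog.
    """

    position: float
    pathway: str
    chromatid_pair: tuple[int, int]


@dataclass(frozen=True)
class BivalentOutcome:
    """All crossover events on one bivalent in one meiosis, sorted."""

    map: GeneticMap
    events: tuple[CrossoverEvent, ...]

    def __post_init__(self) -> None:
        pos = [e.position for e in self.events]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError("events must be sorted by position")


@dataclass(frozen=True)
class TetradRecord:
    """Marker presence (0/1) in each of the four spores of one meiosis."""

    tetrad_id: str
    spores: tuple[tuple[int, ...], ...]
    qc: str = "ok"

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise ValueError("a tetrad has exactly 4 spores")


@dataclass(frozen=True)
class ChiasmaScore:
    count: int
    univalent_pair: bool


# ---------------------------------------------------------------------------
# Stationary gamma renewal process
# ---------------------------------------------------------------------------


class _EquilibriumGamma:
    """Sampler for the forward-recurrence distribution of a gamma renewal.

    For inter-event law Gamma(shape k, scale b) with mean mu = k*b, the
    equilibrium density is f_e(x) = S_k(x) / mu, with CDF
    F_e(x) = (x * S_k(x) + mu * F_{k+1}(x)) / mu.  Sampling is by inverse
    transform on a dense precomputed grid.
    """

    def __init__(self, shape: float, scale: float, grid_size: int = 8192):
        self.shape = shape
        self.scale = scale
        mu = shape * scale
        # Cover essentially all equilibrium mass: the k+1 gamma dominates
        # the tail of F_e.
        hi = stats.gamma.ppf(1 - 1e-12, shape + 1, scale=scale)
        x = np.linspace(0.0, hi, grid_size)
        sf = stats.gamma.sf(x, shape, scale=scale)
        cdf1 = stats.gamma.cdf(x, shape + 1, scale=scale)
        fe = (x * sf + mu * cdf1) / mu
        fe[0] = 0.0
        self._x = x
        self._fe = np.maximum.accumulate(fe)  # guard tiny numerical dips

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(0.0, self._fe[-1], size=n)
        return np.interp(u, self._fe, self._x)


_EQ_CACHE: dict[tuple[float, float], _EquilibriumGamma] = {}


def _equilibrium_gamma(shape: float, scale: float) -> _EquilibriumGamma:
    key = (float(shape), float(scale))
    if key not in _EQ_CACHE:
        if len(_EQ_CACHE) > 32:
            _EQ_CACHE.clear()
        _EQ_CACHE[key] = _EquilibriumGamma(*key)
    return _EQ_CACHE[key]


def _check_intensity(value: float, name: str) -> None:
    if not np.isfinite(value) or value < 0:
        raise ConfigurationError(f"{name} must be finite and >= 0, got {value}")


# ---------------------------------------------------------------------------
# Per-bivalent operations
# ---------------------------------------------------------------------------


def draw_class1_positions(
    gmap: GeneticMap, params: PathwayParams, rng: np.random.Generator
) -> list[float]:
    """Positions (cM, sorted) of class I crossovers on one bivalent.

    A realisation of the stationary gamma renewal process on
    ``[0, gmap.length]``: the first point comes from the equilibrium
    forward-recurrence distribution, subsequent gaps are iid
    Gamma(interference_shape, 1 / (intensity * shape)).
    """
    _check_intensity(params.class1_intensity, "class1_intensity")
    if params.class1_intensity == 0:
        return []
    shape = params.interference_shape
    scale = 1.0 / (params.class1_intensity * shape)
    pos: list[float] = []
    x = float(_equilibrium_gamma(shape, scale).sample(1, rng)[0])
    while x <= gmap.length:
        pos.append(x)
        x += rng.gamma(shape, scale)
    return pos


def draw_class2_positions(
    gmap: GeneticMap, params: PathwayParams, rng: np.random.Generator
) -> list[float]:
    """Positions (cM, sorted) of class II crossovers: homogeneous Poisson."""
    _check_intensity(params.class2_intensity, "class2_intensity")
    if params.class2_intensity == 0:
        return []
    k = rng.poisson(params.class2_intensity * gmap.length)
    return sorted(rng.uniform(0.0, gmap.length, size=k).tolist())


def enforce_obligate(
    draw: Callable[[], list], rng: np.random.Generator, max_tries: int = 1_000_000
) -> tuple[list, int]:
    """Rejection-sample whole-bivalent draws until at least one event.

    Returns ``(events, n_rejections)``.  The caller must guarantee the
    draw has positive acceptance probability; ``max_tries`` is a hard
    guard against a silently impossible configuration.
    """
    for attempt in range(max_tries):
        events = draw()
        if events:
            return events, attempt
    raise ConfigurationError(
        "obligate crossover unattainable: draw produced no events "
        f"in {max_tries} attempts (are both pathway intensities zero?)"
    )


def assign_chromatids(
    events: Sequence[tuple[float, str]], rng: np.random.Generator
) -> list[CrossoverEvent]:
    """Assign each event a uniform chromatid pair (no chromatid interference).

    The pair indexes one strand of each parental origin at the event
    position (see :class:`CrossoverEvent`), so successive crossovers are
    never genetically silent for flanking markers.
    """
    pos = [p for p, _ in events]
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("events must be sorted by position")
    out = []
    for p, pathway in events:
        pair = (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
        out.append(CrossoverEvent(p, pathway, pair))
    return out


def simulate_bivalent(
    gmap: GeneticMap, params: PathwayParams, rng: np.random.Generator
) -> BivalentOutcome:
    """One bivalent: draw both pathways, enforce the obligate CO if set."""

    def draw() -> list[tuple[float, str]]:
        ev = [(p, "I") for p in draw_class1_positions(gmap, params, rng)]
        ev += [(p, "II") for p in draw_class2_positions(gmap, params, rng)]
        ev.sort(key=lambda t: t[0])
        return ev

    if params.obligate_co:
        if params.total_intensity == 0:
            raise ConfigurationError(
                "obligate_co requires a positive pathway intensity"
            )
        events, _ = enforce_obligate(draw, rng)
    else:
        events = draw()
    return BivalentOutcome(gmap, tuple(assign_chromatids(events, rng)))


def derive_tetrad(outcome: BivalentOutcome, tetrad_id: str = "t0") -> TetradRecord:
    """Read the four spores of a tetrad off a bivalent outcome.

    Parental phase: homolog 1 (chromatids 0 and 1) carries every marker
    allele, homolog 2 (chromatids 2 and 3) carries none.  Each crossover
    exchanges the distal continuations of one strand of each parental
    origin at its position (the pair indices select among them); marker
    presence is then read per strand.  Segregation is 2:2 for every
    marker by construction, so ``qc`` is always ``"ok"``.
    """
    origin = [1, 1, 0, 0]  # allele carried distally by each chromatid
    markers = outcome.map.marker_positions
    geno = [[0] * len(markers) for _ in range(4)]
    done = [False] * len(markers)

    def read_until(limit: float) -> None:
        for j, mp in enumerate(markers):
            if not done[j] and mp <= limit:
                for c in range(4):
                    geno[c][j] = origin[c]
                done[j] = True

    for ev in outcome.events:
        read_until(ev.position)
        ones = [c for c in range(4) if origin[c] == 1]
        zeros = [c for c in range(4) if origin[c] == 0]
        a = ones[ev.chromatid_pair[0]]
        b = zeros[ev.chromatid_pair[1]]
        origin[a], origin[b] = origin[b], origin[a]
    read_until(outcome.map.length)
    return TetradRecord(tetrad_id, tuple(tuple(g) for g in geno), qc="ok")


def score_chiasmata(outcome: BivalentOutcome) -> ChiasmaScore:
    """Metaphase I chiasma count for one bivalent: rod = 1, ring = 2.

    Crossovers on one centromere arm only give a rod bivalent (1 chiasma);
    crossovers on both arms give a ring (2); no crossover gives a pair of
    univalents (0).  The count never exceeds 2 regardless of the true
    number of crossovers.
    """
    cen = outcome.map.centromere_pos
    left = any(e.position < cen for e in outcome.events)
    right = any(e.position >= cen for e in outcome.events)
    count = int(left) + int(right)
    return ChiasmaScore(count, univalent_pair=(count == 0))


# ---------------------------------------------------------------------------
# Vectorised batch engine
# ---------------------------------------------------------------------------


def _class1_flat(
    L: float, intensity: float, shape: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Flat (meiosis_index, position) arrays for n stationary renewal draws."""
    if intensity == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    scale = 1.0 / (intensity * shape)
    cur = _equilibrium_gamma(shape, scale).sample(n, rng)
    mi_parts, pos_parts = [], []
    active = np.nonzero(cur <= L)[0]
    while active.size:
        mi_parts.append(active)
        pos_parts.append(cur[active].copy())
        cur[active] += rng.gamma(shape, scale, size=active.size)
        active = active[cur[active] <= L]
    if not mi_parts:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(mi_parts), np.concatenate(pos_parts)


def _class2_flat(
    L: float, intensity: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if intensity == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    counts = rng.poisson(intensity * L, size=n)
    mi = np.repeat(np.arange(n, dtype=np.int64), counts)
    return mi, rng.uniform(0.0, L, size=int(counts.sum()))


def _draw_events_flat(
    L: float, params: PathwayParams, n: int, rng: np.random.Generator, obligate: bool
) -> tuple[np.ndarray, np.ndarray]:
    """All crossover positions for n bivalents, flat and unsorted."""
    mi1, p1 = _class1_flat(L, params.class1_intensity, params.interference_shape, n, rng)
    mi2, p2 = _class2_flat(L, params.class2_intensity, n, rng)
    mi = np.concatenate([mi1, mi2])
    pos = np.concatenate([p1, p2])
    if obligate:
        if params.total_intensity == 0:
            raise ConfigurationError("obligate_co requires a positive pathway intensity")
        while True:
            counts = np.bincount(mi, minlength=n)
            empty = np.nonzero(counts == 0)[0]
            if empty.size == 0:
                break
            m = empty.size
            rmi1, rp1 = _class1_flat(
                L, params.class1_intensity, params.interference_shape, m, rng
            )
            rmi2, rp2 = _class2_flat(L, params.class2_intensity, m, rng)
            mi = np.concatenate([mi, empty[rmi1], empty[rmi2]])
            pos = np.concatenate([pos, rp1, rp2])
    return mi, pos


def _marker_genotypes(
    mi: np.ndarray,
    pos: np.ndarray,
    chrom_a: np.ndarray,
    chrom_b: np.ndarray,
    n: int,
    marker_positions: np.ndarray,
) -> np.ndarray:
    """Genotype (n, 4 chromatids, M markers) from flat, per-meiosis-sorted events.

    Walks events in position order rank by rank (vectorised across
    meioses): markers passed since the previous event inherit the current
    allele origins, then the event swaps the distal origins of one
    strand of each parental origin (``chrom_a``/``chrom_b`` in {0, 1}
    index among the strands currently carrying allele 1 / allele 0).
    """
    M = marker_positions.size
    origin = np.tile(np.array([1, 1, 0, 0], dtype=np.int8), (n, 1))
    geno = np.zeros((n, 4, M), dtype=np.int8)
    done = np.zeros((n, M), dtype=bool)

    counts = np.bincount(mi, minlength=n)
    starts = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=starts[1:])
    K = int(counts.max()) if counts.size else 0
    for k in range(K):
        rows = np.nonzero(counts > k)[0]
        flat = starts[rows] + k
        p = pos[flat]
        for j in range(M):
            hit = rows[(~done[rows, j]) & (marker_positions[j] <= p)]
            geno[hit, :, j] = origin[hit]
            done[hit, j] = True
        # strand columns sorted: carriers of allele 1 first (stable order)
        cols = np.argsort(-origin[rows], axis=1, kind="stable")
        ar = np.arange(rows.size)
        A = cols[ar, chrom_a[flat]]
        B = cols[ar, 2 + chrom_b[flat]]
        origin[rows, A] = 0
        origin[rows, B] = 1
    for j in range(M):
        rest = np.nonzero(~done[:, j])[0]
        geno[rest, :, j] = origin[rest]
    return geno


def _genotype_frame(
    geno: np.ndarray, marker_names: Sequence[str], id_prefix: str = "t"
) -> pd.DataFrame:
    n = geno.shape[0]
    width = max(6, len(str(n)))
    data: dict[str, object] = {
        "tetrad_id": [f"{id_prefix}{i:0{width}d}" for i in range(n)]
    }
    for s in range(4):
        for j, name in enumerate(marker_names):
            data[f"s{s + 1}_{name}"] = geno[:, s, j].astype(np.int64)
    data["qc"] = "ok"
    return pd.DataFrame(data)


def simulate_tetrads(
    gmap: GeneticMap,
    params: PathwayParams,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate ``n`` tetrads for the marker-bearing chromosome.

    Returns the wide tetrad table (one row per tetrad, columns
    ``s{1..4}_{marker}`` with 0/1 marker presence, plus ``tetrad_id`` and
    ``qc``).  Honour ``params.obligate_co`` for the whole bivalent.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if len(gmap.markers) < 2:
        raise ConfigurationError("tetrad simulation needs >= 2 markers")
    mi, pos = _draw_events_flat(gmap.length, params, n, rng, params.obligate_co)
    tot = mi.size
    a = rng.integers(0, 2, size=tot)
    b = rng.integers(0, 2, size=tot)
    order = np.lexsort((pos, mi))
    geno = _marker_genotypes(
        mi[order], pos[order], a[order], b[order], n, np.asarray(gmap.marker_positions)
    )
    return _genotype_frame(geno, gmap.marker_names)


def simulate_experiment(
    genome: Sequence[GeneticMap],
    params: PathwayParams,
    preset: GenotypePreset,
    n_meioses: int,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full experiment: tetrad table plus per-cell cytology.

    Every chromosome of the genome is simulated per meiosis; chiasmata are
    scored per bivalent (rod/ring convention, capped at 2) and summed per
    cell, univalent pairs contribute 2 univalents each.  Tetrad genotypes
    are read from the marker-bearing chromosome only.

    The obligate-crossover constraint is applied per bivalent whenever
    ``params.obligate_co`` is set and the preset leaves a positive total
    intensity; a fully crossover-less genotype (e.g. *spo11*) yields
    univalents, matching its cytology.

    Returns ``(tetrads, cytology)`` where cytology has columns
    ``cell_id, genotype, chiasmata, univalents``.
    """
    genome = list(genome)
    if not genome:
        raise ConfigurationError("empty genome")
    if n_meioses < 1:
        raise ConfigurationError("n_meioses must be >= 1")
    eff = params.scaled(preset)
    obligate = eff.obligate_co and eff.total_intensity > 0

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    streams = ss.spawn(len(genome))
    n = n_meioses
    chiasma = np.zeros(n, dtype=np.int64)
    univ = np.zeros(n, dtype=np.int64)
    tetrads = None
    target = marker_chromosome(genome)
    for gmap, child in zip(genome, streams):
        rng = np.random.default_rng(child)
        mi, pos = _draw_events_flat(gmap.length, eff, n, rng, obligate)
        left = np.bincount(mi[pos < gmap.centromere_pos], minlength=n) > 0
        right = np.bincount(mi[pos >= gmap.centromere_pos], minlength=n) > 0
        score = left.astype(np.int64) + right.astype(np.int64)
        chiasma += score
        univ += 2 * (score == 0)
        if gmap is target:
            tot = mi.size
            a = rng.integers(0, 2, size=tot)
            b = rng.integers(0, 2, size=tot)
            order = np.lexsort((pos, mi))
            geno = _marker_genotypes(
                mi[order],
                pos[order],
                a[order],
                b[order],
                n,
                np.asarray(gmap.marker_positions),
            )
            tetrads = _genotype_frame(geno, gmap.marker_names)
    assert tetrads is not None
    width = max(6, len(str(n)))
    cyto = pd.DataFrame(
        {
            "cell_id": [f"c{i:0{width}d}" for i in range(n)],
            "genotype": preset.name,
            "chiasmata": chiasma,
            "univalents": univ,
        }
    )
    return tetrads, cyto


def tetrads_to_frame(
    records: Sequence[TetradRecord], marker_names: Sequence[str]
) -> pd.DataFrame:
    """Convert TetradRecord objects to the wide tetrad table."""
    data: dict[str, list] = {"tetrad_id": [r.tetrad_id for r in records]}
    for s in range(4):
        for j, name in enumerate(marker_names):
            data[f"s{s + 1}_{name}"] = [r.spores[s][j] for r in records]
    data["qc"] = [r.qc for r in records]
    return pd.DataFrame(data)
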