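import numpy as np
import pandas as pd
import pytest

from tetracross import GeneticMap, PathwayParams

MARKERS = (("R", 60.0), ("Y", 82.84), ("C", 95.69))


@pytest.fixture
def marker_map() -> GeneticMap:
    """Chromosome 5 with the three fluorescent markers (I5a = 22.84 cM, I5b = 12.85 cM)."""
    return GeneticMap("Chr5", 110.0, 45.0, MARKERS)


@pytest.fixture
def poisson_params() -> PathwayParams:
    """Class I disabled: pure Poisson crossovers (independence null)."""
    return PathwayParams(
        class1_intensity=0.0,
        interference_shape=1.0,
        class2_intensity=0.02,
        obligate_co=False,
    )


@pytest.fixture
def wildtype_params() -> PathwayParams:
    return PathwayParams()


def make_joint_table(joint_counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Build a wide 3-marker tetrad table with given (I5a, I5b) joint classes.

    The Y marker is fixed at [1, 1, 0, 0]; R and C patterns are chosen to
    realise the requested PD/TT/NPD class against Y.
    """
    patterns = {
        "PD": [1, 1, 0, 0],
        "TT": [1, 0, 1, 0],
        "NPD": [0, 0, 1, 1],
    }
    rows = []
    i = 0
    for (cls_ab, cls_bc), count in joint_counts.items():
        r, c = patterns[cls_ab], patterns[cls_bc]
        y = patterns["PD"]
        for _ in range(count):
            row = {"tetrad_id": f"t{i:06d}"}
            for s in range(4):
                row[f"s{s + 1}_R"] = r[s]
                row[f"s{s + 1}_Y"] = y[s]
                row[f"s{s + 1}_C"] = c[s]
            row["qc"] = "ok"
            rows.append(row)
            i += 1
    return pd.DataFrame(rows)


def enumerate_tetrad_types(k: int) -> dict[str, float]:
    """Brute-force oracle: type frequencies for k interval crossovers.

    Enumerates all 4**k chromatid assignments (one strand of each current
    parental origin per crossover, uniform) by explicit strand bookkeeping,
    independent of the simulator's implementation.
    """
    from itertools import product

    counts = {"PD": 0, "TT": 0, "NPD": 0}
    for combo in product(range(4), repeat=k):
        origin = [1, 1, 0, 0]
        for choice in combo:
            ones = [c for c in range(4) if origin[c] == 1]
            zeros = [c for c in range(4) if origin[c] == 0]
            a, b = ones[choice // 2], zeros[choice % 2]
            origin[a], origin[b] = origin[b], origin[a]
        # left marker parental [1,1,0,0], right marker = origin
        pairs = sorted(zip([1, 1, 0, 0], origin))
        if pairs == [(0, 0), (0, 0), (1, 1), (1, 1)]:
            counts["PD"] += 1
        elif pairs == [(0, 1), (0, 1), (1, 0), (1, 0)]:
            counts["NPD"] += 1
        else:
            counts["TT"] += 1
    total = 4**k
    return {t: c / total for t, c in counts.items()}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
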