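#!/usr/bin/env python
"""Adjacent-interval crossover interference: worked example and simulations.

Three analyses:

1. the worked example: interference ratios from the recorded stratified
   wild-type distances (with / without an adjacent crossover);
2. the independence null: 100,000 simulated tetrads with class I disabled
   (pure Poisson crossovers) — the ratio should be statistically
   indistinguishable from 1;
3. interfering wild-type simulation (gamma shape 5, 85% class I): the
   ratio falls well below 1, qualitatively matching the measured 0.38/0.33.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tetracross import (
    GeneticMap,
    PathwayParams,
    interference_ratio,
    simulate_tetrads,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 20120726


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []

    strat = pd.read_csv(ROOT / "data" / "stratified_distances.csv")
    for r in strat.itertuples(index=False):
        ratio = round(r.d_with / r.d_without, 2)
        print(f"measured {r.interval} ({r.genotype}): "
              f"{r.d_with} / {r.d_without} cM -> interference ratio {ratio}")
        rows.append({"analysis": "measured", "interval": r.interval,
                     "d_with": r.d_with, "d_without": r.d_without,
                     "ratio": ratio, "p": None})

    gmap = GeneticMap("Chr5", 110.0, 45.0, (("R", 60.0), ("Y", 82.84), ("C", 95.69)))
    configs = [
        ("poisson_null", 1,
         PathwayParams(class1_intensity=0.0, interference_shape=1.0,
                       class2_intensity=0.02, obligate_co=False), 100_000),
        ("interfering_wt", 2, PathwayParams(obligate_co=False), 60_000),
    ]
    for name, sub, params, n in configs:
        rng = np.random.default_rng([SEED, sub])
        table = simulate_tetrads(gmap, params, n, rng)
        res = interference_ratio(table, ("R", "Y"), ("Y", "C"),
                                 n_boot=10_000, rng=rng)
        print(f"simulated {name}: ratio = {res.ratio:.3f} "
              f"[95% CI {res.ci_low:.3f}, {res.ci_high:.3f}], "
              f"G = {res.test_statistic:.1f}, p = {res.p_value:.3g} (n = {n})")
        rows.append({"analysis": name, "interval": "I5a|I5b",
                     "d_with": round(res.d_with, 2),
                     "d_without": round(res.d_without, 2),
                     "ratio": round(res.ratio, 3), "p": res.p_value})

    out = RESULTS / "interference.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
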