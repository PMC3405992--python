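#!/usr/bin/env python
"""Perkins map distances for intervals I5a and I5b, wild type vs mutant.

Computes d = 100(TT/2 + 3 NPD)/n with delta-method standard errors from
the recorded PD/TT/NPD tallies (data/interval_counts.csv), and, when the
simulated datasets from 01_simulate_datasets.py are present, the same
estimates from the simulated tetrad tables for comparison.
"""

from pathlib import Path

import pandas as pd

from tetracross import count_intervals, perkins_distance
from tetracross.io import read_counts_csv, read_tetrad_csv

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

INTERVALS = {"I5a": ("R", "Y"), "I5b": ("Y", "C")}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for c in read_counts_csv(ROOT / "data" / "interval_counts.csv"):
        est = perkins_distance(c)
        rows.append({"source": "measured", "interval": c.interval_id,
                     "d_cM": round(est.d, 2), "se": round(est.se, 2),
                     "PD": c.PD, "TT": c.TT, "NPD": c.NPD, "n": c.n})
        print(f"measured  {c.interval_id:<12} d = {est.d:6.2f} +- {est.se:.2f} cM"
              f"  (n = {c.n})")

    for preset, label in [("wild_type", "wt"), ("hei10", "hei10-2")]:
        path = RESULTS / f"tetrads_{preset}.csv"
        if not path.exists():
            continue
        table = read_tetrad_csv(path)
        for iv, (a, b) in INTERVALS.items():
            c = count_intervals(table, a, b, interval_id=f"{iv}:{label}")
            est = perkins_distance(c)
            rows.append({"source": "simulated", "interval": c.interval_id,
                         "d_cM": round(est.d, 2), "se": round(est.se, 2),
                         "PD": c.PD, "TT": c.TT, "NPD": c.NPD, "n": c.n})
            print(f"simulated {c.interval_id:<12} d = {est.d:6.2f} +- {est.se:.2f} cM"
                  f"  (n = {c.n})")

    out = RESULTS / "map_distances.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
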