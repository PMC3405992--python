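#!/usr/bin/env python
"""Chiasma and focus-count statistics.

From the recorded per-genotype summaries: fold decrease and residual
percentage of chiasma formation in the class-I-deficient mutants, and
summary-only Welch t-tests between focus counts at successive prophase
stages.  From simulated cytology (wild type, class-I null, partial
class-I presets drawn from one run): per-genotype summaries and the
ANOVA + Student-Newman-Keuls epistasis grouping.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tetracross import (
    PathwayParams,
    anova_snk,
    default_genome,
    fold_decrease,
    get_preset,
    residual_percent,
    simulate_experiment,
    summarize_chiasma,
    welch_t_from_summary,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 20120726


def measured_arithmetic() -> None:
    chi = pd.read_csv(ROOT / "data" / "chiasma_summary.csv").set_index("group")
    col_wt, col_mut = chi.loc["Col-0", "mean"], chi.loc["hei10-2", "mean"]
    print(f"Col-0 {col_wt} vs hei10-2 {col_mut} chiasmata/cell: "
          f"{fold_decrease(col_wt, col_mut)}-fold decrease, "
          f"{residual_percent(col_mut, col_wt):.0f}% residual")
    ws = chi[chi["background"] == "Ws"].drop(index="Ws-4")
    ws_mut = float((ws["mean"] * ws["n"]).sum() / ws["n"].sum())
    ws_wt = chi.loc["Ws-4", "mean"]
    print(f"Ws alleles pooled {ws_mut:.4f} vs Ws-4 {ws_wt}: "
          f"{fold_decrease(ws_wt, ws_mut)}-fold, "
          f"{residual_percent(ws_mut, ws_wt, digits=1)}% residual")


def foci_tests() -> None:
    foci = pd.read_csv(ROOT / "data" / "foci_summary.csv")
    pairs = [
        ("Col-0@early_zygotene", "Col-0@zygotene_pachytene"),
        ("Ws-4@early_zygotene", "Ws-4@zygotene_pachytene"),
        ("Col-0@late_pachytene", "Col-0@diakinesis"),
        ("Ws-4@late_pachytene", "Ws-4@diakinesis"),
    ]
    by = foci.set_index("group")
    for a, b in pairs:
        ra, rb = by.loc[a], by.loc[b]
        t, df, p = welch_t_from_summary(ra["mean"], ra["sd"], int(ra["n"]),
                                        rb["mean"], rb["sd"], int(rb["n"]))
        print(f"foci {a} vs {b}: Welch t = {t:.2f}, df = {df:.1f}, p = {p:.3g}")


def simulated_epistasis() -> None:
    genome = default_genome()
    n_cells = 150  # cytological studies score on the order of 10^2 cells
    groups = {}
    for i, name in enumerate(["wild_type", "hei10", "msh4", "mer3", "spo11"]):
        # the obligate-CO guarantee is a class I function: enforce it only
        # where that pathway is intact
        params = PathwayParams(obligate_co=(name == "wild_type"))
        _, cyto = simulate_experiment(genome, params, get_preset(name),
                                      n_cells, SEED + 40 + i)
        groups[name] = cyto["chiasmata"].to_numpy(dtype=float)
        s = summarize_chiasma(groups[name], name)
        print(f"simulated {name}: {s.mean:.2f} +- {s.sd:.2f} chiasmata/cell (n={s.n})")
    # epistasis grouping among the class-I-affected genotypes
    res = anova_snk({k: v for k, v in groups.items() if k != "wild_type"})
    print(f"ANOVA F = {res.F:.1f}, p = {res.p:.3g}; SNK letters: {res.letters}")
    rows = [{"genotype": g, "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
             "n": len(x), "snk": res.letters.get(g, "")} for g, x in groups.items()]
    out = RESULTS / "chiasma_stats.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    measured_arithmetic()
    foci_tests()
    simulated_epistasis()


if __name__ == "__main__":
    main()
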