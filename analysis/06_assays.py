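#!/usr/bin/env python
"""Downstream assays: stress-induced mutability and qPCR expression.

Mutability: wild type (2-fold heat induction of the forward-mutation
frequency) vs a hypermutable SG-defective strain (12-fold, inside the
reported 3-15x band); frequencies, folds and P-values from replicate
plating counts.  qPCR: HSP12-like hyperinduction (wild type peaks 16-fold,
mutant 10x higher) normalized to a reference gene and scaled to percent of
the wild-type maximum.  Outputs: results/mutability.tsv,
results/expression.tsv, results/expression_tests.tsv.
"""

from pathlib import Path

import pandas as pd

from sgscreen import assays, io, simulate

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    # --- CAN1-style forward-mutation assay -------------------------------
    design = simulate.MutabilityDesign(
        frequencies={
            ("wt", "control"): 1e-6, ("wt", "heat"): 2e-6,
            ("sg-defective", "control"): 1e-6, ("sg-defective", "heat"): 1.2e-5,
        },
        replicates=3, seed=31,
    )
    plating = simulate.generate_mutability(design)
    mut = assays.mutability_table(plating, "wt")
    io.write_tsv(mut, RESULTS / "mutability.tsv")
    for _, row in mut.iterrows():
        p = "" if pd.isna(row["p_vs_wt"]) else f", P vs wt = {row['p_vs_wt']:.3f}"
        print(f"{row['strain']}: fold induction {row['fold']:.1f} "
              f"± {row['fold_se']:.1f}{p}")

    # --- qPCR time course -------------------------------------------------
    tps = [0.0, 30.0, 60.0]
    folds = {
        ("HSP12", "wt", 0.0): 1.0, ("HSP12", "wt", 30.0): 8.0,
        ("HSP12", "wt", 60.0): 16.0,
        ("HSP12", "mft1", 0.0): 1.0, ("HSP12", "mft1", 30.0): 80.0,
        ("HSP12", "mft1", 60.0): 160.0,
    }
    qdesign = simulate.QpcrDesign(
        genes=["ACT1", "HSP12"], reference_gene="ACT1",
        strains=["wt", "mft1"], timepoints=tps, fold_changes=folds,
        efficiencies={"ACT1": 2.0, "HSP12": 1.95}, ct_noise_sd=0.1,
        replicates=3, seed=57,
    )
    ct, curve = simulate.generate_qpcr(qdesign)
    eff = {g: assays.pcr_efficiency(sub)[0] for g, sub in curve.groupby("gene")}
    print(f"fitted efficiencies: "
          + ", ".join(f"{g}={e:.3f}" for g, e in eff.items()))
    expr = assays.expression_table(ct, "ACT1", eff, "wt")
    scaled, tests = assays.percent_of_wt_max(expr, "wt")
    io.write_tsv(scaled, RESULTS / "expression.tsv")
    io.write_tsv(tests, RESULTS / "expression_tests.tsv")
    peak = scaled[(scaled["strain"] == "mft1") & (scaled["timepoint"] == 60.0)]
    stars = tests.set_index("timepoint").loc[60.0, "stars"]
    print(f"mft1 HSP12 at 60 min: {peak['pct_of_wt_max'].mean():.0f}% of wt max "
          f"({stars or 'n.s.'})")


if __name__ == "__main__":
    main()
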