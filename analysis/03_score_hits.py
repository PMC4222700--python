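#!/usr/bin/env python
"""Phenotype scores, hit calling and cross-stress profiles for the mini screen.

Each strain's per-field fractions are scored against the wild type
(S = (f_mut − f_wt)/f_wt × 100), the joint hit rule (|S| > 20 and P < 0.05)
is applied per condition, and decreased-SG hits are profiled across the two
stresses.  Outputs: results/phenotypes.tsv, results/hits_<condition>.tsv,
results/cross_stress.tsv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from sgscreen import io, screen

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    summaries = io.read_tsv(RESULTS / "summaries.tsv")
    all_results: dict[str, list] = {}
    for cond in summaries["condition"].unique():
        sub = summaries[summaries["condition"] == cond]
        wt = screen.StrainMeasurement(
            "wt", cond, list(sub.loc[sub["strain"] == "wt", "fraction"])
        )
        res = []
        for strain in sub["strain"].unique():
            if strain == "wt":
                continue
            mut = screen.StrainMeasurement(
                strain, cond, list(sub.loc[sub["strain"] == strain, "fraction"])
            )
            res.append(screen.strain_phenotype(mut, wt))
        all_results[cond] = res

    phen = pd.DataFrame(
        [dataclasses.asdict(r) for res in all_results.values() for r in res]
    )
    io.write_tsv(phen, RESULTS / "phenotypes.tsv")

    hit_tables = {}
    for cond, res in all_results.items():
        table = screen.select_hits(res)
        hit_tables[cond] = table
        io.write_tsv(table, RESULTS / f"hits_{cond.replace(' ', '-')}.tsv")
        hits = table[table["hit"]]
        print(f"{cond}: {len(hits)} hits of {len(table)} strains "
              f"({', '.join(hits['strain'])})")

    labels, counts = screen.cross_stress_profile(hit_tables)
    io.write_tsv(labels, RESULTS / "cross_stress.tsv")
    print("decreased-SG hit overlap across stresses:")
    for _, row in counts.iterrows():
        print(f"  {row['conditions']}: {row['n_strains']} strain(s)")


if __name__ == "__main__":
    main()
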