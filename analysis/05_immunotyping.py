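#!/usr/bin/env python
"""Siglec-15 x CD8 immunotyping (TMIT).

Crosses Siglec-15 status in the tumor compartment (5% cutoff) with CD8
T-cell infiltration (total-area density, cohort-median cutoff) into four
groups, reports group proportions, compares TAM density between the
CD8-low groups, and runs four-group Kaplan-Meier / log-rank on DFS.
Writes ``<out>/tables/tmit.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from siglec15_tme import immunotyping as im
from siglec15_tme.tables import read_patient_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    tables = out / "tables"
    if not (tables / "densities.csv").exists():
        raise SystemExit("run analysis/02_phenotype_quantify.py first")

    dens = pd.read_csv(tables / "densities.csv", dtype={"patient_id": str})
    expr = pd.read_csv(tables / "compartment_expression.csv",
                       dtype={"patient_id": str})
    patients = read_patient_table(out / "cohort" / "patients.csv")

    s15 = expr[expr["compartment"] == "TC"][["patient_id", "percent_positive"]]
    cd8 = dens[(dens["phenotype"] == "CD8T") & (dens["area_kind"] == "total")][
        ["patient_id", "density"]]
    feats = s15.rename(columns={"percent_positive": "s15_tc_pct"}).merge(
        cd8.rename(columns={"density": "cd8_density"}), on="patient_id")

    tmit = im.assign_tmit(feats, "s15_tc_pct", "cd8_density", s15_cutoff=5.0)
    tmit.to_csv(tables / "tmit.csv", index=False)
    props = im.tmit_group_proportions(tmit)
    print("TMIT proportions (TC, CD8 cutoff = cohort median density):")
    print(props.round(1).to_string(index=False))

    comp = im.tmit_group_comparison(tmit, dens, phenotype="TAM")
    a, b = comp["contrast"]
    print(f"TAM density {a} vs {b}: medians "
          f"{comp['group_medians'][a]:.1f} vs {comp['group_medians'][b]:.1f} "
          f"/mm^2, Mann-Whitney p={comp['contrast_p']:.3g} "
          f"(Kruskal-Wallis p={comp['kruskal_p']:.3g})")

    prop = im.s15_proportion_by_cd8(tmit)
    print("Siglec-15-high proportion by CD8 group:",
          {k: round(v, 3) for k, v in prop["s15_high_prop_by_cd8"].items()},
          f"chi-square p={prop['p']:.3g}")

    fit = im.tmit_survival(tmit, patients, endpoint="DFS")
    print(f"four-group DFS log-rank: p={fit.logrank_p:.4f}")


if __name__ == "__main__":
    main()
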