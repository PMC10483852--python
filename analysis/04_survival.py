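#!/usr/bin/env python
"""Cutoff determination and survival stratification.

Determines fixed (1/5/25%) and Youden-optimal cutoffs for Siglec-15
percent-positive in the tumor and macrophage compartments, runs
Kaplan-Meier / log-rank stratified by the configured cutoffs (TC 5%,
MC 16%), univariate and stepwise multivariate Cox regression over the
clinical covariates, and a median-split survival analysis of a spatial
feature (CD8 density around Siglec-15+ tumor cells at r=20 um).
Writes ``cutoffs.csv``, ``survival_results.csv`` and ``km_curves.csv``.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from siglec15_tme import survival as sv
from siglec15_tme.tables import read_patient_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out)
    tables = out / "tables"
    expr_path = tables / "compartment_expression.csv"
    if not expr_path.exists():
        raise SystemExit("run analysis/02_phenotype_quantify.py first")

    expr = pd.read_csv(expr_path, dtype={"patient_id": str})
    wide = expr.pivot(index="patient_id", columns="compartment",
                      values="percent_positive").rename(
        columns={"TC": "s15_tc_pct", "MC": "s15_mc_pct"})
    pats = read_patient_table(out / "cohort" / "patients.csv").merge(
        wide, left_on="patient_id", right_index=True)

    cut_rows = []
    for feat in ("s15_tc_pct", "s15_mc_pct"):
        sub = pats.dropna(subset=[feat])
        y = sv.youden_cutoff(sub[feat], sub["dfs_event"], feature=feat)
        cut_rows.append({"feature": feat, "method": "youden",
                         "cutoff": y.cutoff, "youden_j": y.youden_j})
        for method, cut in sv.FIXED_CUTOFFS.items():
            cut_rows.append({"feature": feat, "method": method, "cutoff": cut,
                             "youden_j": np.nan})
        print(f"{feat}: Youden cutoff {y.cutoff:.2f}% (J={y.youden_j:.2f})")
    pd.DataFrame(cut_rows).to_csv(tables / "cutoffs.csv", index=False)

    pats["s15_tc_high"] = sv.classify_high(pats["s15_tc_pct"], 5.0).astype(int)
    pats["s15_mc_high"] = sv.classify_high(pats["s15_mc_pct"], 16.0).astype(int)
    pats["t2_4"] = (pats["t_class"] == "T2_4").astype(int)
    pats["n1_2"] = (pats["n_class"] == "N1_2").astype(int)
    pats["age_ge_60"] = (pats["age_years"] >= 60).astype(int)
    pats["male"] = (pats["sex"] == "M").astype(int)

    km_frames, rows = [], []
    for feat in ("s15_tc_high", "s15_mc_high"):
        grp = np.where(pats[feat] == 1, f"{feat}=high", f"{feat}=low")
        fit = sv.km_logrank(pats["dfs_months"], pats["dfs_event"], grp)
        fit.curves["stratification"] = feat
        km_frames.append(fit.curves)
        rows.append({"analysis": f"km_{feat}", "covariate": feat, "hr": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p": fit.logrank_p,
                     "method": "logrank"})
        print(f"DFS log-rank by {feat}: p={fit.logrank_p:.4f}")

    cox = sv.cox_regression(
        pats, ["male", "age_ge_60", "smoking", "t2_4", "n1_2",
               "s15_tc_high", "s15_mc_high"],
        mode="multivariate_stepwise",
    )
    print("Cox regression (DFS):")
    for r in cox.cox.itertuples(index=False):
        rows.append({"analysis": f"cox_{r.mode}", "covariate": r.covariate,
                     "hr": r.hr, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "p": r.p, "method": "cox"})
        print(f"  [{r.mode}] {r.covariate:<12} HR {r.hr:5.2f} "
              f"({r.ci_low:.2f}-{r.ci_high:.2f}) p={r.p:.4f}")

    spatial_path = tables / "spatial.csv"
    if spatial_path.exists():
        spatial = pd.read_csv(spatial_path, dtype={"patient_id": str})
        feat = spatial[
            (spatial["comparison"] == "cd8_around_tumor_by_s15")
            & (spatial["stratum"] == "S15+ tumor")
            & (spatial["radius_um"] == 20.0)
        ][["patient_id", "spatial_density"]].rename(
            columns={"spatial_density": "cd8_around_s15pos_tumor_r20"})
        pats = pats.merge(feat, on="patient_id", how="left")
        try:
            fit = sv.stratify_by_spatial_feature(
                pats, "cd8_around_s15pos_tumor_r20", "DFS")
            fit.curves["stratification"] = "cd8_around_s15pos_tumor_r20"
            km_frames.append(fit.curves)
            rows.append({"analysis": "km_cd8_around_s15pos_tumor_r20",
                         "covariate": "cd8_around_s15pos_tumor_r20",
                         "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": fit.logrank_p, "method": "logrank"})
            print("DFS log-rank by CD8 density around S15+ tumor cells "
                  f"(median split): p={fit.logrank_p:.4f}")
        except Exception as e:  # noqa: BLE001
            print(f"spatial-feature stratification not evaluable: {e}")

    pd.DataFrame(rows).to_csv(tables / "survival_results.csv", index=False)
    pd.concat(km_frames, ignore_index=True).to_csv(tables / "km_curves.csv",
                                                   index=False)


if __name__ == "__main__":
    main()
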