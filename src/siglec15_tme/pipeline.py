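"""Config-driven end-to-end orchestration.

``run_pipeline`` executes the analysis stages in order —

    data (simulate or load) -> phenotyping -> quantification ->
    spatial statistics -> cutoffs / survival -> immunotyping (TMIT)

— writing one tidy CSV per stage plus a ``manifest.json`` recording the
config hash, seed, package version, per-stage row counts and the SHA-256
of every output, so a rerun with the same config and seed is verifiably
identical.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .tables import (
    ConfigurationError,
    PanelConfig,
    read_cell_table,
    read_patient_table,
    read_roi_table,
)
from . import phenotyping as ph
from . import spatial as sp
from . import survival as sv
from . import immunotyping as im
from .simulate import SimConfig, generate_cohort, write_cohort

log = logging.getLogger("siglec15_tme")

__all__ = ["PipelineError", "run_pipeline", "default_run_config"]

_KNOWN_PHENOTYPES = {"tumor", "TAM", "Treg", "Teff", "CD8T", "other", "CD4T", "M2TAM"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_run_config(n_patients: int = 40) -> dict:
    """A complete, self-contained simulate-then-analyze configuration."""
    return {
        "simulate": {"n_patients": n_patients},
        "radii_um": [20.0, 40.0, 60.0, 80.0],
        "spatial_mode": "disc",
        "s15_cutoffs": {"TC": 5.0, "MC": 16.0},
        "spatial_comparisons": [
            {
                "name": "cd8_around_tam_by_s15",
                "target": {"phenotype": "CD8T"},
                "strata": {
                    "S15+ TAM": {"phenotype": "TAM", "positive": ["Siglec15"]},
                    "S15- TAM": {"phenotype": "TAM", "negative": ["Siglec15"]},
                },
            },
            {
                "name": "cd8_around_tumor_by_s15",
                "target": {"phenotype": "CD8T"},
                "strata": {
                    "S15+ tumor": {"phenotype": "tumor", "positive": ["Siglec15"]},
                    "S15- tumor": {"phenotype": "tumor", "negative": ["Siglec15"]},
                },
            },
        ],
        "survival_feature": {
            "name": "cd8_density_around_s15pos_tumor_r20",
            "comparison": "cd8_around_tumor_by_s15",
            "stratum": "S15+ tumor",
            "radius_um": 20.0,
        },
        "tmit": {"compartment": "TC", "cd8_phenotype": "CD8T", "area_kind": "total"},
        "endpoint": "DFS",
        "seed": 0,
    }


def _validate_config(config: dict) -> None:
    for comp in config.get("spatial_comparisons", []):
        names = [comp["target"]["phenotype"]] + [
            s["phenotype"] for s in comp["strata"].values()
        ]
        for nm in names:
            if nm not in _KNOWN_PHENOTYPES:
                raise ConfigurationError(
                    f"spatial comparison {comp.get('name')!r} references unknown "
                    f"phenotype {nm!r}; known: {sorted(_KNOWN_PHENOTYPES)}"
                )
    radii = config.get("radii_um", [])
    if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
        raise ConfigurationError("radii_um must be positive and ascending")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run all stages; returns frames, output paths and the manifest."""
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    panel = PanelConfig(tuple(config["panel"]["markers"])) if "panel" in config \
        else PanelConfig()
    results: dict = {}
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
        results[name] = df

    # -- data ---------------------------------------------------------
    try:
        if "simulate" in config:
            sim = SimConfig.from_dict({**config["simulate"], "seed": seed})
            cohort = generate_cohort(sim)
            write_cohort(cohort, outdir / "cohort")
            cells, rois, patients = cohort.cells, cohort.rois, cohort.patients
            log.info("simulated cohort: %d patients, %d ROIs, %d cells",
                     len(patients), len(rois), len(cells))
        else:
            inputs = config["inputs"]
            rois = read_roi_table(inputs["rois"])
            cells = read_cell_table(inputs["cells"], panel=panel, rois=rois)
            patients = read_patient_table(inputs["patients"])
            log.info("loaded %d cells, %d ROIs, %d patients",
                     len(cells), len(rois), len(patients))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("data", e) from e

    # -- phenotyping ---------------------------------------------------
    try:
        cells = ph.assign_phenotypes(cells, panel=panel)
        counts = cells["phenotype"].value_counts()
        log.info("phenotyped %d cells: %s", len(cells), counts.to_dict())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("phenotyping", e) from e

    # -- quantification ------------------------------------------------
    try:
        expr = ph.compartment_percent(cells, rois, "Siglec15")
        save("compartment_expression", expr)
        dens = ph.density_by_area(
            cells, rois,
            phenotypes=("CD8T", "CD4T", "Treg", "Teff", "TAM", "M2TAM"),
        )
        save("densities", dens)
        m2 = ph.m2_ratio_category(cells, rois)
        save("m2_ratio", m2)

        cuts = config.get("s15_cutoffs", {"TC": 5.0, "MC": 16.0})
        wide = expr.pivot(index="patient_id", columns="compartment",
                          values="percent_positive")
        status = pd.DataFrame({
            "patient_id": wide.index,
            "tc_high": sv.classify_high(wide["TC"], cuts["TC"]).astype(float),
            "mc_high": sv.classify_high(wide["MC"], cuts["MC"]).astype(float),
        })
        status.loc[wide["TC"].isna().to_numpy(), "tc_high"] = np.nan
        status.loc[wide["MC"].isna().to_numpy(), "mc_high"] = np.nan
        joint = ph.joint_s15_classification(status)
        save("joint_s15_classification", joint)
        results["s15_status"] = status
    except Exception as e:  # noqa: BLE001
        raise PipelineError("quantification", e) from e

    # -- spatial -------------------------------------------------------
    try:
        radii = tuple(config.get("radii_um", sp.DEFAULT_RADII_UM))
        mode = config.get("spatial_mode", "disc")
        all_stats, all_tests = [], []
        for comp in config.get("spatial_comparisons", []):
            stats_df, tests_df = sp.stratified_spatial_comparison(
                cells, rois, strata=comp["strata"], target=comp["target"],
                radii_um=radii, mode=mode,
            )
            stats_df.insert(0, "comparison", comp["name"])
            tests_df.insert(0, "comparison", comp["name"])
            all_stats.append(stats_df)
            all_tests.append(tests_df)
        spatial_df = pd.concat(all_stats, ignore_index=True) if all_stats else \
            pd.DataFrame()
        tests_df = pd.concat(all_tests, ignore_index=True) if all_tests else \
            pd.DataFrame()
        save("spatial", spatial_df)
        save("spatial_tests", tests_df)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("spatial", e) from e

    # -- survival ------------------------------------------------------
    try:
        endpoint = config.get("endpoint", "DFS")
        dur, ev = sv.endpoint_columns(endpoint)
        pats = patients.merge(
            wide.rename(columns={"TC": "s15_tc_pct", "MC": "s15_mc_pct"}),
            left_on="patient_id", right_index=True, how="left",
        )
        cut_rows = []
        for feat in ("s15_tc_pct", "s15_mc_pct"):
            sub = pats.dropna(subset=[feat, ev])
            for method, cut in sv.FIXED_CUTOFFS.items():
                cut_rows.append({"feature": feat, "method": method,
                                 "cutoff": cut, "youden_j": np.nan})
            yr = sv.youden_cutoff(sub[feat], sub[ev], feature=feat)
            cut_rows.append({"feature": feat, "method": "youden",
                             "cutoff": yr.cutoff, "youden_j": yr.youden_j})
        save("cutoffs", pd.DataFrame(cut_rows))

        cuts = config.get("s15_cutoffs", {"TC": 5.0, "MC": 16.0})
        pats["s15_tc_high"] = sv.classify_high(pats["s15_tc_pct"], cuts["TC"]).astype(int)
        pats["s15_mc_high"] = sv.classify_high(pats["s15_mc_pct"], cuts["MC"]).astype(int)
        pats["t2_4"] = (pats["t_class"] == "T2_4").astype(int)
        pats["n1_2"] = (pats["n_class"] == "N1_2").astype(int)
        pats["age_ge_60"] = (pats["age_years"] >= 60).astype(int)
        pats["male"] = (pats["sex"] == "M").astype(int)

        km_frames, surv_rows = [], []
        for feat in ("s15_tc_high", "s15_mc_high"):
            grp = np.where(pats[feat] == 1, f"{feat}=high", f"{feat}=low")
            fit = sv.km_logrank(pats[dur], pats[ev], grp)
            fit.curves["stratification"] = feat
            km_frames.append(fit.curves)
            surv_rows.append({"analysis": f"km_{feat}", "covariate": feat,
                              "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                              "p": fit.logrank_p, "method": "logrank"})
        cox = sv.cox_regression(
            pats, ["male", "age_ge_60", "smoking", "t2_4", "n1_2",
                   "s15_tc_high", "s15_mc_high"],
            duration_col=dur, event_col=ev, mode="multivariate_stepwise",
        )
        for row in cox.cox.itertuples(index=False):
            surv_rows.append({"analysis": f"cox_{row.mode}", "covariate": row.covariate,
                              "hr": row.hr, "ci_low": row.ci_low,
                              "ci_high": row.ci_high, "p": row.p, "method": "cox"})

        sf = config.get("survival_feature")
        if sf and len(spatial_df):
            sel = spatial_df[
                (spatial_df["comparison"] == sf["comparison"])
                & (spatial_df["stratum"] == sf["stratum"])
                & (spatial_df["radius_um"] == float(sf["radius_um"]))
            ][["patient_id", "spatial_density"]].rename(
                columns={"spatial_density": sf["name"]}
            )
            pats = pats.merge(sel, on="patient_id", how="left")
            try:
                fit = sv.stratify_by_spatial_feature(pats, sf["name"], endpoint)
                fit.curves["stratification"] = sf["name"]
                km_frames.append(fit.curves)
                surv_rows.append({"analysis": f"km_{sf['name']}",
                                  "covariate": sf["name"], "hr": np.nan,
                                  "ci_low": np.nan, "ci_high": np.nan,
                                  "p": fit.logrank_p, "method": "logrank"})
            except Exception as e:  # noqa: BLE001
                log.warning("spatial-feature stratification skipped: %s", e)
        save("survival_results", pd.DataFrame(surv_rows))
        save("km_curves", pd.concat(km_frames, ignore_index=True))
        results["patients_features"] = pats
    except Exception as e:  # noqa: BLE001
        raise PipelineError("survival", e) from e

    # -- immunotyping --------------------------------------------------
    try:
        tconf = config.get("tmit", {})
        comp = tconf.get("compartment", "TC")
        feat_col = "s15_tc_pct" if comp == "TC" else "s15_mc_pct"
        cd8 = dens[(dens["phenotype"] == tconf.get("cd8_phenotype", "CD8T"))
                   & (dens["area_kind"] == tconf.get("area_kind", "total"))][
            ["patient_id", "density"]].rename(columns={"density": "cd8_density"})
        feats = pats[["patient_id", feat_col]].merge(cd8, on="patient_id", how="left")
        cuts = config.get("s15_cutoffs", {"TC": 5.0, "MC": 16.0})
        tmit = im.assign_tmit(
            feats, s15_col=feat_col, cd8_col="cd8_density",
            s15_cutoff=cuts[comp], compartment=comp,
        )
        save("tmit", tmit)
        results["tmit_proportions"] = im.tmit_group_proportions(tmit)
        try:
            results["tmit_comparison"] = im.tmit_group_comparison(
                tmit, dens, phenotype="TAM"
            )
        except Exception as e:  # noqa: BLE001
            log.warning("TMIT group comparison skipped: %s", e)
            results["tmit_comparison"] = None
        try:
            fit = im.tmit_survival(tmit, patients, endpoint=endpoint)
            results["tmit_survival_p"] = fit.logrank_p
        except Exception as e:  # noqa: BLE001
            log.warning("TMIT survival skipped: %s", e)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("immunotyping", e) from e

    # -- manifest ------------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config_hash": cfg_hash,
        "seed": seed,
        "version": __version__,
        "counts": {
            "cells": int(len(cells)),
            "rois": int(len(rois)),
            "patients": int(len(patients)),
        },
        "outputs": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    results["cells"] = cells
    results["rois"] = rois
    results["patients"] = patients
    return results
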