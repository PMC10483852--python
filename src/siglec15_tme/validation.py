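"""Calibration and recovery experiments over the pipeline.

Each routine here sets up a self-contained experiment — a printed-
arithmetic reconstruction, an oracle-agreement sweep, or a planted-truth
simulation — runs the relevant pipeline stage, and returns the measured
quantities as a plain dict.  They back both the test suite and the
``scripts/acceptance.py`` report.

The reference computations used for agreement checks (the exhaustive
all-pairs neighbor search and the exhaustive Youden threshold scan) are
deliberately naive, independent re-implementations: they share no code
path with the accelerated versions they validate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .immunotyping import assign_tmit, tmit_group_comparison, tmit_group_proportions
from .phenotyping import (
    assign_phenotypes,
    compartment_percent,
    density_by_area,
    joint_s15_classification,
    m2_ratio_category,
)
from .simulate import (
    Interaction,
    SimConfig,
    generate_cohort,
    generate_roi,
    simulate_ph_cohort,
)
from .spatial import neighbors_within, spatial_density
from .survival import cox_regression, km_logrank, youden_cutoff
from .tables import DEFAULT_MARKERS

__all__ = [
    "reconstruct_printed_cohort",
    "neighbor_oracle_check",
    "poisson_intensity_recovery",
    "planted_interaction_check",
    "logrank_rejection_rate",
    "cox_ci_coverage",
    "youden_oracle_check",
    "tmit_recovery",
]


# ---------------------------------------------------------------------------
# printed-arithmetic cohort reconstruction
# ---------------------------------------------------------------------------

def reconstruct_printed_cohort(
    n_patients: int = 213,
    s15_high_frac: float = 0.282,
    high_split: tuple[float, float, float] = (0.52, 0.05, 0.43),
    m2_fracs: tuple[float, float, float] = (0.107, 0.199, 0.693),
) -> dict:
    """Rebuild the cohort-level Siglec-15 classification from proportions.

    Integer patient counts are reconstructed by rounding the published
    cohort proportions (total Siglec-15-high fraction; its split into
    both-compartments / tumor-only / macrophage-only; the M2-ratio
    category fractions), then fed through the joint classification and
    M2-ratio categorization exactly as measured data would be.
    """
    n_high = round(s15_high_frac * n_patients)
    n_both = round(high_split[0] * n_high)
    n_tc_only = round(high_split[1] * n_high)
    n_mc_only = round(high_split[2] * n_high)
    n_low = n_patients - (n_both + n_tc_only + n_mc_only)
    tc = [True] * n_both + [True] * n_tc_only + [False] * n_mc_only + [False] * n_low
    mc = [True] * n_both + [False] * n_tc_only + [True] * n_mc_only + [False] * n_low
    status = pd.DataFrame(
        {"patient_id": [f"P{i:03d}" for i in range(n_patients)],
         "tc_high": tc, "mc_high": mc}
    )
    joint = joint_s15_classification(status).set_index("label")

    # M2-ratio categories: plant one representative fraction per band
    # (4/10, 6/10, 8/10 CD163+ among ten S15+ TAMs per patient)
    n_cat = [round(f * n_patients) for f in m2_fracs]
    n_cat[2] = n_patients - n_cat[0] - n_cat[1]
    rows = []
    pid = 0
    for n_pat, k_pos in zip(n_cat, (4, 6, 8)):
        for _ in range(n_pat):
            for j in range(10):
                rows.append(
                    {"id": f"P{pid:03d}-c{j}", "roi": f"P{pid:03d}-roi1",
                     "x": 10.0 * (j + 1), "y": 10.0,
                     "pos": ["CD68", "Siglec15"] + (["CD163"] if j < k_pos else [])}
                )
            pid += 1
    cells = _build_cells(rows)
    rois = pd.DataFrame(
        {"roi_id": [f"P{i:03d}-roi1" for i in range(n_patients)],
         "patient_id": [f"P{i:03d}" for i in range(n_patients)],
         "width_um": 931.0, "height_um": 698.0,
         "area_tumor_mm2": 0.3, "area_stroma_mm2": 0.349838}
    )
    m2 = m2_ratio_category(assign_phenotypes(cells), rois)
    cat_counts = m2["category"].value_counts()
    pct = lambda k: 100.0 * cat_counts.get(k, 0) / n_patients

    out = {
        "joint_both_high_pct": round(float(joint.loc["both_high", "percent"]), 1),
        "joint_tc_only_pct": round(float(joint.loc["tc_only", "percent"]), 1),
        "joint_mc_only_pct": round(float(joint.loc["mc_only", "percent"]), 1),
        "joint_both_low_pct": round(float(joint.loc["both_low", "percent"]), 1),
        "s15_high_tc_pct": round(
            float(joint.loc["both_high", "percent"] + joint.loc["tc_only", "percent"]), 1
        ),
        "s15_high_mc_pct": round(
            float(joint.loc["both_high", "percent"] + joint.loc["mc_only", "percent"]), 1
        ),
        "s15_high_total_pct": round(100.0 * n_high / n_patients, 1),
        "m2_low_pct": round(pct("low"), 1),
        "m2_intermediate_pct": round(pct("intermediate"), 1),
        "m2_high_pct": round(pct("high"), 1),
        "m2_intermediate_plus_high_pct": round(
            pct("intermediate") + pct("high"), 1
        ),
        "n_patients": n_patients,
    }
    return out


def _build_cells(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(
        {"cell_id": [r["id"] for r in rows],
         "roi_id": [r["roi"] for r in rows],
         "x_um": [r["x"] for r in rows], "y_um": [r["y"] for r in rows],
         "tissue_class": "stroma"}
    )
    for m in DEFAULT_MARKERS:
        df[f"{m}_call"] = [m in r["pos"] for r in rows]
    return df


# ---------------------------------------------------------------------------
# neighbor-search oracle agreement
# ---------------------------------------------------------------------------

def _all_pairs_neighbors(ref: pd.DataFrame, tgt: pd.DataFrame, r: float):
    """Exhaustive O(n^2) reference search over the full distance matrix."""
    rx = ref[["x_um", "y_um"]].to_numpy(float)
    tx = tgt[["x_um", "y_um"]].to_numpy(float)
    rid = ref["cell_id"].to_numpy()
    tid = tgt["cell_id"].to_numpy()
    out = []
    for i in range(len(rx)):
        d = np.hypot(tx[:, 0] - rx[i, 0], tx[:, 1] - rx[i, 1])
        keep = (d <= r) & (tid != rid[i])
        out.append(np.sort(d[keep]))
    return out


def neighbor_oracle_check(
    n_instances: int = 50, max_cells: int = 2000, seed: int = 11
) -> dict:
    """Accelerated neighbor search vs exhaustive all-pairs, bit-exact."""
    rng = np.random.default_rng(seed)
    n_exact = 0
    max_count_diff = 0
    for _ in range(n_instances):
        n = int(rng.integers(10, max_cells + 1))
        n_ref = int(rng.integers(1, n))
        xy = rng.uniform(0, 931, size=(n, 2))
        ids = np.array([f"c{i}" for i in range(n)])
        # overlapping sets so self-exclusion is exercised
        ref_idx = rng.choice(n, size=n_ref, replace=False)
        ref = pd.DataFrame({"cell_id": ids[ref_idx], "x_um": xy[ref_idx, 0],
                            "y_um": xy[ref_idx, 1]})
        tgt = pd.DataFrame({"cell_id": ids, "x_um": xy[:, 0], "y_um": xy[:, 1]})
        r = float(rng.uniform(10, 90))
        got = neighbors_within(ref, tgt, r)
        want = _all_pairs_neighbors(ref, tgt, r)
        exact = len(got) == len(want) and all(
            np.array_equal(g, w) for g, w in zip(got, want)
        )
        n_exact += exact
        if not exact:
            max_count_diff = max(
                max_count_diff,
                max(abs(len(g) - len(w)) for g, w in zip(got, want)),
            )
    return {"agreement_rate": n_exact / n_instances, "n_instances": n_instances,
            "max_count_diff": max_count_diff}


# ---------------------------------------------------------------------------
# Poisson-intensity recovery
# ---------------------------------------------------------------------------

def poisson_intensity_recovery(
    n_rois: int = 500, lam: float = 100.0, radius_um: float = 40.0,
    ref_rate: float = 50.0, seed: int = 5,
) -> dict:
    """Disc-mode density on homogeneous Poisson targets estimates lambda.

    Reference cells within ``radius_um`` of the ROI border are excluded
    (guard margin), since discs clipped by the frame would otherwise bias
    the estimate downward; with interior references the estimator is
    unbiased and the cohort mean should sit within Monte-Carlo error of
    the target intensity.
    """
    cfg = SimConfig(
        intensities={"other": (lam, lam), "CD8T": (ref_rate, ref_rate)},
        interactions=[], patient_sd_log=0.0, cd8_high_prob=0.0,
        tmit_tam_multiplier=1.0,
    )
    rng = np.random.default_rng(seed)
    per_roi = []
    for i in range(n_rois):
        cells, _ = generate_roi(cfg, rng, roi_id=f"r{i}")
        ref = cells[cells["CD8_call"]]
        ref = ref[
            (ref["x_um"] >= radius_um) & (ref["x_um"] <= cfg.roi_width_um - radius_um)
            & (ref["y_um"] >= radius_um) & (ref["y_um"] <= cfg.roi_height_um - radius_um)
        ]
        if len(ref) == 0:
            continue
        tgt = cells[~cells["CD8_call"]]
        dens = spatial_density(neighbors_within(ref, tgt, radius_um), radius_um)
        per_roi.append(dens)
    per_roi = np.asarray(per_roi)
    mean = float(per_roi.mean())
    se = float(per_roi.std(ddof=1) / math.sqrt(len(per_roi)))
    return {"lambda_true": lam, "lambda_hat": mean, "mc_se": se,
            "z_score": (mean - lam) / se, "n_rois": int(len(per_roi))}


# ---------------------------------------------------------------------------
# planted attraction / exclusion recovery
# ---------------------------------------------------------------------------

def _interaction_config(kind: str) -> SimConfig:
    marker_model = {k: dict(v) for k, v in SimConfig().marker_model.items()}
    marker_model["s15_mc"] = {"mu": 0.0, "sigma": 0.0, "load": 0.0}  # p = 0.5
    common = dict(
        marker_model=marker_model, patient_sd_log=0.0, cd8_high_prob=0.0,
        tmit_tam_multiplier=1.0,
    )
    if kind == "attraction":
        return SimConfig(
            intensities={"TAM": (250.0, 250.0), "CD8T": (150.0, 150.0)},
            interactions=[Interaction("TAM", {"Siglec15": True}, "CD8T",
                                      "attraction", strength=3.0, sigma_um=10.0)],
            **common,
        )
    return SimConfig(
        intensities={"TAM": (200.0, 200.0), "CD8T": (400.0, 400.0)},
        interactions=[Interaction("TAM", {"Siglec15": True}, "CD8T",
                                  "exclusion", sigma_um=20.0, retention=0.1)],
        **common,
    )


def planted_interaction_check(
    n_reps: int = 200, radius_um: float = 20.0, seed: int = 17
) -> dict:
    """Fraction of replicates where planted interactions are recovered.

    Attraction (mean 3 extra CD8 T cells per Siglec-15+ TAM at sigma =
    10 um) should raise the CD8 disc density around flagged TAMs above
    that around unflagged TAMs; exclusion (thinning to 10% within 20 um)
    should reverse the sign.
    """
    out = {"n_reps": n_reps, "radius_um": radius_um}
    for kind in ("attraction", "exclusion"):
        cfg = _interaction_config(kind)
        rng = np.random.default_rng(seed)
        hits = 0
        for i in range(n_reps):
            cells, _ = generate_roi(cfg, rng, roi_id=f"{kind}{i}")
            tam = cells[cells["CD68_call"]]
            cd8 = cells[cells["CD8_call"]]
            flagged = tam[tam["Siglec15_call"]]
            unflagged = tam[~tam["Siglec15_call"]]
            if len(flagged) == 0 or len(unflagged) == 0:
                continue
            d_pos = spatial_density(neighbors_within(flagged, cd8, radius_um),
                                    radius_um)
            d_neg = spatial_density(neighbors_within(unflagged, cd8, radius_um),
                                    radius_um)
            if kind == "attraction":
                hits += d_pos > d_neg
            else:
                hits += d_pos < d_neg
        out[f"{kind}_recovery_rate"] = hits / n_reps
    return out


# ---------------------------------------------------------------------------
# survival machinery calibration
# ---------------------------------------------------------------------------

def logrank_rejection_rate(
    n_reps: int = 1000, n: int = 200, log_hr: float = 0.0,
    censor_rate: float = 0.3, alpha: float = 0.05, seed: int = 23,
) -> dict:
    """Log-rank rejection rate under a planted hazard ratio.

    ``log_hr = 0`` measures type-I error (should sit near alpha);
    a nonzero value measures power.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        df = simulate_ph_cohort(n, log_hr, rng, censor_rate=censor_rate)
        fit = km_logrank(df["time"], df["event"], df["x"], include_curves=False)
        rejections += fit.logrank_p < alpha
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps, "n": n,
            "hr_true": math.exp(log_hr), "alpha": alpha}


def cox_ci_coverage(
    n_reps: int = 200, n: int = 500, hr: float = 2.0,
    censor_rate: float = 0.3, seed: int = 29,
) -> dict:
    """95% CI coverage and mean HR estimate for a planted binary effect."""
    rng = np.random.default_rng(seed)
    covered = 0
    hrs = []
    for _ in range(n_reps):
        df = simulate_ph_cohort(n, math.log(hr), rng, censor_rate=censor_rate)
        fit = cox_regression(df, ["x"], duration_col="time", event_col="event")
        row = fit.cox.iloc[0]
        covered += row["ci_low"] <= hr <= row["ci_high"]
        hrs.append(row["hr"])
    return {"coverage": covered / n_reps, "hr_true": hr,
            "hr_mean_estimate": float(np.mean(hrs)), "n_reps": n_reps, "n": n}


# ---------------------------------------------------------------------------
# Youden oracle agreement
# ---------------------------------------------------------------------------

def _youden_exhaustive(values: np.ndarray, outcome: np.ndarray):
    """Naive scan over every observed threshold; smaller cutoff wins ties."""
    best_j, best_c = -2.0, None
    n_pos = outcome.sum()
    n_neg = len(outcome) - n_pos
    for c in np.sort(np.unique(values)):
        pred = values >= c
        sens = (pred & (outcome == 1)).sum() / n_pos
        spec = (~pred & (outcome == 0)).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_c, best_j


def youden_oracle_check(n_instances: int = 100, n: int = 20, seed: int = 31) -> dict:
    """Vectorized Youden cutoff vs exhaustive threshold search."""
    rng = np.random.default_rng(seed)
    n_exact = 0
    for _ in range(n_instances):
        y = np.zeros(n, dtype=int)
        while y.sum() in (0, n):
            y = (rng.random(n) < 0.4).astype(int)
        v = np.round(rng.normal(0, 1, n) + 0.8 * y, 2)  # ties are likely
        got = youden_cutoff(v, y)
        want_c, want_j = _youden_exhaustive(v, y)
        n_exact += (got.cutoff == want_c) and abs(got.youden_j - want_j) < 1e-12
    return {"agreement_rate": n_exact / n_instances, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# TMIT recovery
# ---------------------------------------------------------------------------

def tmit_recovery(n_patients: int = 200, seed: int = 0) -> dict:
    """Full-cohort TMIT partition and planted TAM-density-shift recovery.

    Simulates a cohort with the default planted TAM-intensity multiplier
    in the CD8-low / Siglec-15-high group, recomputes TMIT labels from
    the realized data (Siglec-15 percent in the tumor compartment at the
    5% cutoff; CD8 density at the cohort median) and tests the
    CD8L_S15H vs CD8L_S15L TAM-density contrast.
    """
    cohort = generate_cohort(SimConfig(n_patients=n_patients, seed=seed))
    cells = assign_phenotypes(cohort.cells)
    expr = compartment_percent(cells, cohort.rois, "Siglec15",
                               compartments=("TC",))
    dens = density_by_area(cells, cohort.rois, ["TAM", "CD8T"],
                           area_kinds=("total",))
    cd8 = dens[dens["phenotype"] == "CD8T"][["patient_id", "density"]]
    feats = expr[["patient_id", "percent_positive"]].rename(
        columns={"percent_positive": "s15_tc_pct"}
    ).merge(cd8.rename(columns={"density": "cd8_density"}), on="patient_id")
    tmit = assign_tmit(feats, "s15_tc_pct", "cd8_density", s15_cutoff=5.0)
    props = tmit_group_proportions(tmit)
    comp = tmit_group_comparison(tmit, dens, phenotype="TAM")
    return {
        "n_patients": int(len(tmit)),
        "labels_occupied": int((props["n"] > 0).sum()),
        "proportion_sum_pct": float(props["percent"].sum()),
        "proportions": dict(zip(props["label"], props["percent"])),
        "contrast_p": comp["contrast_p"],
        "contrast_medians": {k: comp["group_medians"].get(k) for k in comp["contrast"]},
        "kruskal_p": comp["kruskal_p"],
    }
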