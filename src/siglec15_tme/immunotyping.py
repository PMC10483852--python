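"""Tumor microenvironment immune typing (TMIT).

Patients are cross-classified by Siglec-15 status (high/low, per
compartment cutoff) and CD8 status (high/low CD8+ T-cell infiltration;
default cutoff: cohort median of CD8 T-cell density in total tissue
area), yielding four groups that partition the cohort:

    CD8H_S15H, CD8L_S15H, CD8H_S15L, CD8L_S15L

The group of interest is CD8L_S15H (checkpoint-high, effector-poor);
group-wise immune-cell densities are compared with Kruskal-Wallis across
the four groups plus designated pairwise contrasts (default
CD8L_S15H vs CD8L_S15L, Mann-Whitney), and survival across the four
groups with Kaplan-Meier / log-rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import SurvivalFit, classify_high, endpoint_columns, km_logrank
from .tables import ConfigurationError, TableValidationError

__all__ = [
    "TMIT_LABELS",
    "assign_tmit",
    "tmit_group_comparison",
    "tmit_survival",
    "s15_proportion_by_cd8",
]

TMIT_LABELS: tuple[str, ...] = ("CD8H_S15H", "CD8L_S15H", "CD8H_S15L", "CD8L_S15L")

#: Pairwise groups compared by default: Siglec-15 effect within CD8-low.
DEFAULT_CONTRAST: tuple[str, str] = ("CD8L_S15H", "CD8L_S15L")

_MIN_GROUP_N = 3  # below this a pairwise contrast is flagged underpowered


def assign_tmit(
    features: pd.DataFrame,
    s15_col: str,
    cd8_col: str,
    s15_cutoff: float,
    cd8_cutoff: float | str = "median",
    compartment: str = "TC",
) -> pd.DataFrame:
    """Assign each patient one of the four TMIT labels.

    Parameters
    ----------
    features:
        Per-patient frame with ``patient_id``, a Siglec-15 feature column
        (percent positive in the compartment) and a CD8 feature column
        (CD8 T-cell density).  Patients missing either feature are
        excluded with a warning.
    s15_cutoff:
        High/low cutoff for the Siglec-15 feature (cutoff-inclusive).
    cd8_cutoff:
        Numeric cutoff or ``'median'`` (cohort median of the CD8 feature
        over included patients).
    """
    df = features.copy()
    missing = df[s15_col].isna() | df[cd8_col].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} patient(s) lack {s15_col!r} or {cd8_col!r} "
            "and were excluded from TMIT assignment",
            stacklevel=2,
        )
        df = df[~missing]
    if df.empty:
        raise TableValidationError("no patients with both TMIT features defined")
    cd8_cut = float(df[cd8_col].median()) if cd8_cutoff == "median" else float(cd8_cutoff)
    s15_high = classify_high(df[s15_col], float(s15_cutoff))
    cd8_high = classify_high(df[cd8_col], cd8_cut)
    label = np.where(
        cd8_high,
        np.where(s15_high, "CD8H_S15H", "CD8H_S15L"),
        np.where(s15_high, "CD8L_S15H", "CD8L_S15L"),
    )
    return pd.DataFrame(
        {"patient_id": df["patient_id"].to_numpy(),
         "compartment": compartment,
         "s15_status": np.where(s15_high, "high", "low"),
         "cd8_status": np.where(cd8_high, "high", "low"),
         "label": label,
         "s15_cutoff": float(s15_cutoff), "cd8_cutoff": cd8_cut}
    )


def tmit_group_proportions(assignments: pd.DataFrame) -> pd.DataFrame:
    """Percent of patients per TMIT label (sums to 100)."""
    counts = assignments["label"].value_counts()
    total = int(counts.sum())
    return pd.DataFrame(
        [{"label": lab, "n": int(counts.get(lab, 0)),
          "percent": 100.0 * counts.get(lab, 0) / total}
         for lab in TMIT_LABELS]
    )


def tmit_group_comparison(
    assignments: pd.DataFrame,
    densities: pd.DataFrame,
    phenotype: str,
    area_kind: str = "total",
    contrast: tuple[str, str] = DEFAULT_CONTRAST,
) -> dict:
    """Compare a phenotype's density across TMIT groups.

    Kruskal-Wallis over all occupied groups plus a Mann-Whitney test for
    the designated pairwise contrast.  Contrasts with fewer than
    ``3`` patients in a group are flagged ``underpowered``.
    """
    for lab in contrast:
        if lab not in TMIT_LABELS:
            raise ConfigurationError(f"unknown TMIT label {lab!r} in contrast")
    dens = densities[
        (densities["phenotype"] == phenotype)
        & (densities["area_kind"] == area_kind)
    ][["patient_id", "density"]]
    merged = assignments.merge(dens, on="patient_id", how="inner").dropna(
        subset=["density"]
    )
    groups = {
        lab: merged.loc[merged["label"] == lab, "density"].to_numpy()
        for lab in TMIT_LABELS
    }
    occupied = {lab: v for lab, v in groups.items() if v.size > 0}
    if len(occupied) < 2:
        raise TableValidationError(
            "group comparison requires >= 2 occupied TMIT groups"
        )
    kw_stat, kw_p = stats.kruskal(*occupied.values())

    a, b = groups[contrast[0]], groups[contrast[1]]
    underpowered = a.size < _MIN_GROUP_N or b.size < _MIN_GROUP_N
    if a.size and b.size:
        mw = stats.mannwhitneyu(a, b, alternative="two-sided")
        c_stat, c_p = float(mw.statistic), float(mw.pvalue)
    else:
        c_stat, c_p = np.nan, np.nan
    return {
        "phenotype": phenotype,
        "area_kind": area_kind,
        "group_medians": {lab: float(np.median(v)) for lab, v in occupied.items()},
        "group_n": {lab: int(v.size) for lab, v in groups.items()},
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "contrast": contrast,
        "contrast_statistic": c_stat,
        "contrast_p": c_p,
        "contrast_underpowered": bool(underpowered),
    }


def tmit_survival(
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    endpoint: str = "DFS",
) -> SurvivalFit:
    """Four-curve Kaplan-Meier with overall log-rank across TMIT groups."""
    dur, ev = endpoint_columns(endpoint)
    merged = assignments.merge(patients, on="patient_id", how="inner").dropna(
        subset=[dur, ev]
    )
    if merged["label"].nunique() < 2:
        raise TableValidationError(
            "TMIT survival requires >= 2 occupied groups, got "
            f"{sorted(merged['label'].unique())}"
        )
    return km_logrank(merged[dur], merged[ev], merged["label"])


def s15_proportion_by_cd8(assignments: pd.DataFrame) -> dict:
    """Chi-square comparison of the S15-high proportion between CD8 groups."""
    tab = pd.crosstab(assignments["cd8_status"], assignments["s15_status"])
    tab = tab.reindex(index=["high", "low"], columns=["high", "low"], fill_value=0)
    chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    prop = (tab["high"] / tab.sum(axis=1)).to_dict()
    return {
        "table": tab,
        "s15_high_prop_by_cd8": {k: float(v) for k, v in prop.items()},
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
    }
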