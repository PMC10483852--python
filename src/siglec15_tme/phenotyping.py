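"""Marker-gate phenotyping and compartment quantification.

Cells are assigned exactly one *primary* phenotype by the first matching
rule in a configured priority order (multi-positive cells go to the
highest-priority match; cells matching no rule become ``other``), plus
boolean sub-flags carried by individual markers (Siglec-15, PD-L1, CD163).

Default gates
-------------
========  =================  =========================================
label     gate               meaning
========  =================  =========================================
tumor     CK+                epithelial tumor cell
TAM       CD68+              tumor-associated macrophage
Treg      CD4+ FoxP3+        regulatory T helper cell
Teff      CD4+ FoxP3-        effector T helper cell
CD8T      CD8+               cytotoxic T cell
other     (no rule matched)
========  =================  =========================================

Derived groups: ``CD4T`` = Treg | Teff, ``M2TAM`` = TAM & CD163+.

Expression compartments are marker-defined, independent of the primary
label: TC (tumor compartment) = CK+ cells, MC (macrophage compartment) =
CD68+ cells, SC (stroma compartment) = CK- cells.  Percent-positive
statistics pool a patient's cells over all ROIs; densities divide counts
by the realized tissue areas (cells per mm^2, in total / tumor / stroma
area).  Empty denominators propagate as NaN ("undefined"), never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import ConfigurationError, PanelConfig, TableValidationError

__all__ = [
    "PhenotypeRule",
    "DEFAULT_RULES",
    "PHENOTYPE_GROUPS",
    "COMPARTMENT_GATES",
    "assign_phenotypes",
    "phenotype_mask",
    "compartment_mask",
    "compartment_percent",
    "density_by_area",
    "m2_ratio_category",
    "joint_s15_classification",
]


@dataclass(frozen=True)
class PhenotypeRule:
    """One gate: required-positive and required-negative markers."""

    label: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        clash = set(self.positive) & set(self.negative)
        if clash:
            raise ConfigurationError(
                f"rule {self.label!r} requires marker(s) {sorted(clash)} both "
                "positive and negative"
            )


#: Priority order for multi-positive cells: tumor > TAM > T-cell lineages.
DEFAULT_RULES: tuple[PhenotypeRule, ...] = (
    PhenotypeRule("tumor", ("CK",)),
    PhenotypeRule("TAM", ("CD68",)),
    PhenotypeRule("Treg", ("CD4", "FoxP3")),
    PhenotypeRule("Teff", ("CD4",), ("FoxP3",)),
    PhenotypeRule("CD8T", ("CD8",)),
)

#: Composite phenotype groups selectable wherever a phenotype is expected.
PHENOTYPE_GROUPS: dict[str, tuple[str, ...]] = {
    "CD4T": ("Treg", "Teff"),
}

#: Expression compartments as (marker, required-sign) gates.
COMPARTMENT_GATES: dict[str, tuple[str, bool]] = {
    "TC": ("CK", True),
    "MC": ("CD68", True),
    "SC": ("CK", False),
}

_SUBFLAGS = {"s15_pos": "Siglec15", "pdl1_pos": "PDL1", "cd163_pos": "CD163"}


def assign_phenotypes(
    cells: pd.DataFrame,
    rules: Sequence[PhenotypeRule] = DEFAULT_RULES,
    panel: PanelConfig | None = None,
) -> pd.DataFrame:
    """Return a copy of ``cells`` with ``phenotype`` and sub-flag columns.

    Every cell receives exactly one primary label (first matching rule, or
    ``other``) plus boolean ``s15_pos`` / ``pdl1_pos`` / ``cd163_pos``
    columns, so labels partition the cell set by construction.
    """
    panel = panel or PanelConfig()
    known = set(panel.markers)
    for rule in rules:
        unknown = (set(rule.positive) | set(rule.negative)) - known
        if unknown:
            raise ConfigurationError(
                f"rule {rule.label!r} references marker(s) {sorted(unknown)} "
                "absent from the panel"
            )
    out = cells.copy()
    label = pd.Series("other", index=out.index, dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for rule in rules:
        m = unassigned.copy()
        for marker in rule.positive:
            m &= out[f"{marker}_call"].to_numpy(bool)
        for marker in rule.negative:
            m &= ~out[f"{marker}_call"].to_numpy(bool)
        label.iloc[m] = rule.label
        unassigned &= ~m
    out["phenotype"] = label
    for flag, marker in _SUBFLAGS.items():
        if f"{marker}_call" in out.columns:
            out[flag] = out[f"{marker}_call"].astype(bool)
    return out


def phenotype_mask(cells: pd.DataFrame, phenotype: str) -> np.ndarray:
    """Boolean mask for a primary phenotype or a composite group."""
    labels = PHENOTYPE_GROUPS.get(phenotype)
    if phenotype == "M2TAM":
        return (cells["phenotype"].eq("TAM") & cells["CD163_call"]).to_numpy(bool)
    if labels is not None:
        return cells["phenotype"].isin(labels).to_numpy(bool)
    return cells["phenotype"].eq(phenotype).to_numpy(bool)


def compartment_mask(cells: pd.DataFrame, compartment: str) -> np.ndarray:
    try:
        marker, sign = COMPARTMENT_GATES[compartment]
    except KeyError:
        raise ConfigurationError(
            f"unknown compartment {compartment!r}; expected one of "
            f"{sorted(COMPARTMENT_GATES)}"
        ) from None
    calls = cells[f"{marker}_call"].to_numpy(bool)
    return calls if sign else ~calls


def _roi_to_patient(rois: pd.DataFrame) -> pd.Series:
    return rois.set_index("roi_id")["patient_id"]


def compartment_percent(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    marker: str,
    compartments: Iterable[str] = ("TC", "MC", "SC"),
) -> pd.DataFrame:
    """Per-patient percent of compartment cells positive for ``marker``.

    Cells are pooled across each patient's ROIs before dividing.  A
    patient with an empty compartment gets ``percent_positive = NaN``
    (undefined), with ``n_cells = 0``.

    Returns a tidy frame: patient_id, compartment, marker,
    percent_positive, n_positive, n_cells.
    """
    pat = cells["roi_id"].map(_roi_to_patient(rois))
    if pat.isna().any():
        raise TableValidationError("cells reference roi_ids missing from ROI table")
    pos = cells[f"{marker}_call"].to_numpy(bool)
    rows = []
    patients = sorted(_roi_to_patient(rois).unique())
    for comp in compartments:
        mask = compartment_mask(cells, comp)
        grp = pd.DataFrame({"patient_id": pat[mask], "pos": pos[mask]})
        agg = grp.groupby("patient_id")["pos"].agg(["sum", "count"])
        for pid in patients:
            if pid in agg.index:
                n_pos, n = int(agg.loc[pid, "sum"]), int(agg.loc[pid, "count"])
                pct = 100.0 * n_pos / n
            else:
                n_pos, n, pct = 0, 0, np.nan
            rows.append(
                {"patient_id": pid, "compartment": comp, "marker": marker,
                 "percent_positive": pct, "n_positive": n_pos, "n_cells": n}
            )
    return pd.DataFrame(rows)


def density_by_area(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    phenotypes: Iterable[str],
    area_kinds: Iterable[str] = ("total", "tumor", "stroma"),
    level: str = "patient",
) -> pd.DataFrame:
    """Cell densities (per mm^2) per patient or ROI, by tissue area kind.

    ``tumor``/``stroma`` densities count only cells whose tissue class
    matches and divide by that compartment's area; ``total`` divides all
    cells of the phenotype by the summed tissue area.  Zero area yields
    NaN (undefined), not zero.
    """
    if level not in ("patient", "roi"):
        raise ConfigurationError(f"level must be 'patient' or 'roi', got {level!r}")
    key = "patient_id" if level == "patient" else "roi_id"
    areas = rois.copy()
    areas["area_total_mm2"] = areas["area_tumor_mm2"] + areas["area_stroma_mm2"]
    area_sum = areas.groupby(key if level == "patient" else "roi_id")[
        ["area_tumor_mm2", "area_stroma_mm2", "area_total_mm2"]
    ].sum()
    pat = cells["roi_id"].map(_roi_to_patient(rois))
    cell_key = pat if level == "patient" else cells["roi_id"]
    units = sorted(area_sum.index)

    rows = []
    for ph in phenotypes:
        ph_mask = phenotype_mask(cells, ph)
        for kind in area_kinds:
            if kind == "total":
                sel = ph_mask
            elif kind in ("tumor", "stroma"):
                sel = ph_mask & cells["tissue_class"].eq(kind).to_numpy()
            else:
                raise ConfigurationError(f"unknown area kind {kind!r}")
            counts = cell_key[sel].value_counts()
            for u in units:
                n = int(counts.get(u, 0))
                a = float(area_sum.loc[u, f"area_{kind}_mm2"])
                dens = n / a if a > 0 else np.nan
                rows.append(
                    {key: u, "phenotype": ph, "area_kind": kind,
                     "n_cells": n, "area_mm2": a, "density": dens}
                )
    return pd.DataFrame(rows)


M2_RATIO_BOUNDS = (0.5, 0.75)  # low < 0.5 <= intermediate < 0.75 <= high


def m2_ratio_category(
    cells: pd.DataFrame, rois: pd.DataFrame
) -> pd.DataFrame:
    """Per patient: fraction of Siglec-15+ TAMs that are CD163+ (M2-like).

    Categories split the fraction at 50% and 75%, both lower-bound
    inclusive: low < 0.5 <= intermediate < 0.75 <= high.  Patients with
    zero Siglec-15+ TAMs are undefined (NaN fraction, category ``NaN``).
    """
    pat = cells["roi_id"].map(_roi_to_patient(rois))
    tam = cells["phenotype"].eq("TAM").to_numpy()
    s15_tam = tam & cells["s15_pos"].to_numpy(bool)
    m2_s15 = s15_tam & cells["cd163_pos"].to_numpy(bool)
    denom = pd.Series(s15_tam, index=cells.index).groupby(pat).sum()
    numer = pd.Series(m2_s15, index=cells.index).groupby(pat).sum()
    rows = []
    for pid in sorted(_roi_to_patient(rois).unique()):
        d = int(denom.get(pid, 0))
        n = int(numer.get(pid, 0))
        if d == 0:
            frac, cat = np.nan, np.nan
        else:
            frac = n / d
            lo, hi = M2_RATIO_BOUNDS
            cat = "low" if frac < lo else ("intermediate" if frac < hi else "high")
        rows.append({"patient_id": pid, "n_s15_tam": d, "n_s15_m2tam": n,
                     "m2_fraction": frac, "category": cat})
    return pd.DataFrame(rows)


JOINT_S15_LABELS = ("both_high", "tc_only", "mc_only", "both_low")


def joint_s15_classification(status: pd.DataFrame) -> pd.DataFrame:
    """Cross-classify patients by Siglec-15 status in TC x MC.

    Parameters
    ----------
    status:
        Frame with ``patient_id``, ``tc_high`` and ``mc_high`` boolean (or
        NaN for unknown) columns.  Patients with a missing status are
        excluded with a warning.

    Returns
    -------
    One row per joint class (both_high, tc_only, mc_only, both_low) with
    ``n`` and ``percent`` of classified patients; percents sum to 100
    within rounding.
    """
    s = status.copy()
    missing = s["tc_high"].isna() | s["mc_high"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} patient(s) lack TC/MC Siglec-15 status and "
            "were excluded from the joint classification",
            stacklevel=2,
        )
        s = s[~missing]
    if s.empty:
        raise TableValidationError("no patients with complete TC/MC status")
    tc = s["tc_high"].astype(bool)
    mc = s["mc_high"].astype(bool)
    counts = {
        "both_high": int((tc & mc).sum()),
        "tc_only": int((tc & ~mc).sum()),
        "mc_only": int((~tc & mc).sum()),
        "both_low": int((~tc & ~mc).sum()),
    }
    total = len(s)
    return pd.DataFrame(
        [{"label": k, "n": v, "percent": 100.0 * v / total} for k, v in counts.items()]
    )
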