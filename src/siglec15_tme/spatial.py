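"""Radius-limited neighborhood statistics on marked point patterns.

Each ROI is treated as a bivariate planar marked point pattern: a set of
*reference* cells (a phenotype, optionally refined by marker sub-flags,
e.g. Siglec-15+ PD-L1- TAMs) and a set of *target* cells.  For a radius
``r`` (default grid 20/40/60/80 um) two statistics are computed from the
Euclidean centroid distances:

spatial density
    number of target cells within ``r`` of each reference cell,
    area-normalized to cells per mm^2.  ``disc`` mode (default) divides
    the per-reference count by the search-disc area ``pi r^2``, making
    values comparable across radii; ``tissue`` mode divides the mean
    per-reference count by the ROI's realized tissue area.
proximity distance
    mean distance over all (reference, target) pairs within ``r``,
    pooled over reference cells.

The radius comparison is inclusive (``<= r``); a cell belonging to both
sets never counts as its own neighbor.  No edge correction is applied; an
optional guard margin can exclude reference cells within ``r`` of the ROI
border (used e.g. to verify the disc-mode estimator is unbiased for
homogeneous targets).  Patient-level values pool reference cells across
the patient's ROIs (reference-cell-weighted), so ROIs with more reference
cells contribute proportionally.

Undefined values (no reference cells; no pairs within radius) propagate
as NaN, never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .tables import ConfigurationError, TableValidationError
from .phenotyping import phenotype_mask

__all__ = [
    "DEFAULT_RADII_UM",
    "CellSelector",
    "neighbors_within",
    "spatial_density",
    "proximity_distance",
    "neighborhood_stats",
    "stratified_spatial_comparison",
]

DEFAULT_RADII_UM: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)


@dataclass(frozen=True)
class CellSelector:
    """Select cells by primary phenotype plus marker sub-flag requirements.

    ``positive`` / ``negative`` name markers whose call must be +/-, e.g.
    ``CellSelector("TAM", positive=("Siglec15",))`` = Siglec-15+ TAMs and
    ``CellSelector("tumor", positive=("Siglec15",), negative=("PDL1",))``
    = Siglec-15+ PD-L1- tumor cells.
    """

    phenotype: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is None:
            parts = [f"{m}+" for m in self.positive] + [f"{m}-" for m in self.negative]
            object.__setattr__(
                self, "label", " ".join(parts + [self.phenotype]) or self.phenotype
            )

    def mask(self, cells: pd.DataFrame) -> np.ndarray:
        m = phenotype_mask(cells, self.phenotype)
        for marker in self.positive:
            m &= cells[f"{marker}_call"].to_numpy(bool)
        for marker in self.negative:
            m &= ~cells[f"{marker}_call"].to_numpy(bool)
        return m


def _as_selector(spec: CellSelector | str | Mapping) -> CellSelector:
    if isinstance(spec, CellSelector):
        return spec
    if isinstance(spec, str):
        return CellSelector(spec)
    return CellSelector(
        phenotype=spec["phenotype"],
        positive=tuple(spec.get("positive", ())),
        negative=tuple(spec.get("negative", ())),
        label=spec.get("label"),
    )


def neighbors_within(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    radius_um: float,
) -> list[np.ndarray]:
    """Distances from each reference cell to target cells within radius.

    Both frames must come from a single, common ROI.  Returns one sorted
    distance array per reference cell (possibly empty), with Euclidean
    distances ``<= radius_um``.  A cell present in both sets (same
    ``cell_id``) is excluded from its own neighborhood.
    """
    if radius_um <= 0:
        raise ConfigurationError(f"radius must be positive, got {radius_um}")
    for df, name in ((reference, "reference"), (target, "target")):
        if "roi_id" in df.columns and df["roi_id"].nunique() > 1:
            raise TableValidationError(
                f"{name} cells span multiple ROIs: {sorted(df['roi_id'].unique())}"
            )
    if (
        "roi_id" in reference.columns and "roi_id" in target.columns
        and len(reference) and len(target)
        and reference["roi_id"].iat[0] != target["roi_id"].iat[0]
    ):
        raise TableValidationError(
            "reference and target cells come from different ROIs"
        )

    n_ref = len(reference)
    if n_ref == 0 or len(target) == 0:
        return [np.empty(0)] * n_ref
    ref_xy = reference[["x_um", "y_um"]].to_numpy(float)
    tgt_xy = target[["x_um", "y_um"]].to_numpy(float)
    tgt_ids = target["cell_id"].to_numpy() if "cell_id" in target.columns else None
    ref_ids = reference["cell_id"].to_numpy() if "cell_id" in reference.columns else None

    tree = cKDTree(tgt_xy)
    hits = tree.query_ball_point(ref_xy, r=radius_um)
    out: list[np.ndarray] = []
    for i, idx in enumerate(hits):
        idx = np.asarray(idx, dtype=int)
        if ref_ids is not None and tgt_ids is not None and idx.size:
            idx = idx[tgt_ids[idx] != ref_ids[i]]
        if idx.size:
            d = np.hypot(
                tgt_xy[idx, 0] - ref_xy[i, 0], tgt_xy[idx, 1] - ref_xy[i, 1]
            )
            out.append(np.sort(d))
        else:
            out.append(np.empty(0))
    return out


def _disc_area_mm2(radius_um: float) -> float:
    return math.pi * radius_um**2 / 1e6


def spatial_density(
    neighbor_lists: Sequence[np.ndarray],
    radius_um: float,
    mode: str = "disc",
    tissue_area_mm2: float | None = None,
) -> float:
    """Area-normalized mean neighbor count (cells per mm^2).

    ``disc`` mode: mean over reference cells of count / (pi r^2 in mm^2).
    ``tissue`` mode: mean count / ROI tissue area in mm^2.  NaN when there
    are no reference cells.
    """
    n_ref = len(neighbor_lists)
    if n_ref == 0:
        return float("nan")
    counts = np.array([len(d) for d in neighbor_lists], dtype=float)
    if mode == "disc":
        return float(counts.mean() / _disc_area_mm2(radius_um))
    if mode == "tissue":
        if tissue_area_mm2 is None or tissue_area_mm2 <= 0:
            raise ConfigurationError(
                "tissue mode requires a positive tissue_area_mm2"
            )
        return float(counts.mean() / tissue_area_mm2)
    raise ConfigurationError(f"mode must be 'disc' or 'tissue', got {mode!r}")


def proximity_distance(neighbor_lists: Sequence[np.ndarray]) -> float:
    """Mean distance over all pairs within radius, pooled; NaN if none."""
    if not neighbor_lists:
        return float("nan")
    all_d = np.concatenate([np.asarray(d, float) for d in neighbor_lists]) \
        if neighbor_lists else np.empty(0)
    if all_d.size == 0:
        return float("nan")
    return float(all_d.mean())


def _guard_mask(cells: pd.DataFrame, rois: pd.DataFrame, radius_um: float) -> np.ndarray:
    geo = rois.set_index("roi_id")[["width_um", "height_um"]]
    w = cells["roi_id"].map(geo["width_um"]).to_numpy(float)
    h = cells["roi_id"].map(geo["height_um"]).to_numpy(float)
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    return (x >= radius_um) & (x <= w - radius_um) & (y >= radius_um) & (y <= h - radius_um)


def neighborhood_stats(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    reference: CellSelector | str | Mapping,
    target: CellSelector | str | Mapping,
    radii_um: Sequence[float] = DEFAULT_RADII_UM,
    mode: str = "disc",
    guard_margin: bool = False,
    level: str = "patient",
) -> pd.DataFrame:
    """Spatial density and proximity distance per patient (or ROI) and radius.

    Emits a record only where at least one reference cell exists.  At
    patient level, per-ROI neighbor lists are pooled over the patient's
    reference cells before normalizing (tissue mode weights per-ROI
    densities by reference-cell count).
    """
    if level not in ("patient", "roi"):
        raise ConfigurationError(f"level must be 'patient' or 'roi', got {level!r}")
    ref_sel = _as_selector(reference)
    tgt_sel = _as_selector(target)
    roi_pat = rois.set_index("roi_id")["patient_id"]

    ref_all = cells[ref_sel.mask(cells)]
    tgt_all = cells[tgt_sel.mask(cells)]
    area = rois.set_index("roi_id")
    area_total = area["area_tumor_mm2"] + area["area_stroma_mm2"]

    rows = []
    for roi_id, ref_roi in ref_all.groupby("roi_id", sort=True):
        tgt_roi = tgt_all[tgt_all["roi_id"] == roi_id]
        for r in radii_um:
            ref_use = ref_roi
            if guard_margin:
                ref_use = ref_roi[_guard_mask(ref_roi, rois, r)]
            if len(ref_use) == 0:
                continue
            lists = neighbors_within(ref_use, tgt_roi, r)
            counts = np.array([len(d) for d in lists], dtype=float)
            dens = spatial_density(
                lists, r, mode=mode, tissue_area_mm2=float(area_total.loc[roi_id])
                if mode == "tissue" else None,
            )
            dists = np.concatenate(lists) if lists else np.empty(0)
            rows.append(
                {"roi_id": roi_id, "patient_id": roi_pat.loc[roi_id],
                 "reference": ref_sel.label, "target": tgt_sel.label,
                 "radius_um": float(r), "mode": mode,
                 "n_reference": int(len(ref_use)), "n_pairs": int(counts.sum()),
                 "spatial_density": dens,
                 "proximity_um": float(dists.mean()) if dists.size else np.nan}
            )
    roi_stats = pd.DataFrame(
        rows, columns=["roi_id", "patient_id", "reference", "target", "radius_um",
                       "mode", "n_reference", "n_pairs", "spatial_density",
                       "proximity_um"],
    )
    if level == "roi":
        return roi_stats

    # pool reference cells across each patient's ROIs (reference-weighted)
    prows = []
    for (pid, r), grp in roi_stats.groupby(["patient_id", "radius_um"], sort=True):
        n_ref = int(grp["n_reference"].sum())
        n_pairs = int(grp["n_pairs"].sum())
        if mode == "disc":
            dens = n_pairs / n_ref / _disc_area_mm2(r)
        else:
            dens = float(
                np.average(grp["spatial_density"], weights=grp["n_reference"])
            )
        prox_num = (grp["proximity_um"] * grp["n_pairs"]).sum()
        prox = prox_num / n_pairs if n_pairs > 0 else np.nan
        prows.append(
            {"patient_id": pid, "reference": ref_sel.label, "target": tgt_sel.label,
             "radius_um": float(r), "mode": mode, "n_reference": n_ref,
             "n_pairs": n_pairs, "spatial_density": float(dens),
             "proximity_um": float(prox)}
        )
    return pd.DataFrame(
        prows, columns=["patient_id", "reference", "target", "radius_um", "mode",
                        "n_reference", "n_pairs", "spatial_density", "proximity_um"],
    )


def stratified_spatial_comparison(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    strata: Mapping[str, CellSelector | str | Mapping],
    target: CellSelector | str | Mapping,
    radii_um: Sequence[float] = DEFAULT_RADII_UM,
    mode: str = "disc",
    paired: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient neighborhood stats per stratum, plus two-group tests.

    ``strata`` maps stratum name -> reference-cell selector (e.g.
    ``{"S15+ TAM": ..., "S15- TAM": ...}``).  For each radius and each
    metric (spatial_density, proximity_um), the two strata are compared
    across patients: Wilcoxon signed-rank over patients where both strata
    are defined (``paired=True``, the default, matching within-patient
    reference stratification), otherwise Mann-Whitney.  With fewer than
    two usable patients the test is undefined (NaN p-value).

    Returns ``(per_patient_stats, tests)``.
    """
    names = list(strata)
    if len(names) != 2:
        raise ConfigurationError(
            f"exactly two strata required for comparison, got {len(names)}"
        )
    frames = []
    for name, sel in strata.items():
        st = neighborhood_stats(
            cells, rois, sel, target, radii_um=radii_um, mode=mode, level="patient"
        )
        st.insert(0, "stratum", name)
        frames.append(st)
    stats_df = pd.concat(frames, ignore_index=True)

    trows = []
    for r in radii_um:
        sub = stats_df[stats_df["radius_um"] == float(r)]
        wide = {
            name: sub[sub["stratum"] == name].set_index("patient_id") for name in names
        }
        for metric in ("spatial_density", "proximity_um"):
            a = wide[names[0]][metric].dropna()
            b = wide[names[1]][metric].dropna()
            if paired:
                common = a.index.intersection(b.index)
                x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
                n_used = len(common)
                if n_used < 2:
                    stat, p = np.nan, np.nan
                elif np.allclose(x, y):
                    stat, p = 0.0, 1.0
                else:
                    res = stats.wilcoxon(x, y, zero_method="wilcox")
                    stat, p = float(res.statistic), float(res.pvalue)
                method = "wilcoxon_signed_rank"
            else:
                n_used = min(len(a), len(b))
                if len(a) < 2 or len(b) < 2:
                    stat, p = np.nan, np.nan
                else:
                    res = stats.mannwhitneyu(a, b, alternative="two-sided")
                    stat, p = float(res.statistic), float(res.pvalue)
                method = "mann_whitney"
            trows.append(
                {"radius_um": float(r), "metric": metric,
                 "stratum_a": names[0], "stratum_b": names[1],
                 "median_a": float(a.median()) if len(a) else np.nan,
                 "median_b": float(b.median()) if len(b) else np.nan,
                 "n_patients": int(n_used), "statistic": stat, "p_value": p,
                 "method": method}
            )
    return stats_df, pd.DataFrame(trows)
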