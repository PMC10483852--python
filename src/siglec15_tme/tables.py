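"""Tabular data model for multiplexed-imaging cohorts.

Three table kinds circulate through the pipeline, mirroring what cell
phenotyping software (inForm-style) and a clinical database export:

``cells``
    one row per segmented cell: identifiers, centroid coordinates in
    micrometres (image convention: origin top-left, y increasing downward),
    tissue class (``tumor``/``stroma`` from tissue segmentation) and one
    ``<marker>_call`` column per panel marker holding ``positive`` /
    ``negative``.  Optional ``<marker>_intensity`` columns carry mean
    expression; binary calls are derived from them (threshold-inclusive)
    only when the call columns are absent.
``rois``
    one row per imaged region of interest: patient linkage, field geometry
    (default 931 x 698 um, ~0.65 mm^2) and per-compartment tissue areas in
    mm^2 (1 mm^2 = 1e6 um^2).
``patients``
    one row per patient: survival endpoints (OS/DFS months + event flags)
    and clinical covariates (T/N classification, age, sex, smoking).

In memory each table is a validated :class:`pandas.DataFrame`; the
dataclasses below are typed record views used for construction and
round-tripping.  Validation is total: malformed input raises a diagnostic
naming the offending rows and values, never a silent drop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MARKERS",
    "ROI_WIDTH_UM",
    "ROI_HEIGHT_UM",
    "ROI_AREA_MM2",
    "TableFormatError",
    "TableValidationError",
    "ConfigurationError",
    "PanelConfig",
    "CellRecord",
    "RoiRecord",
    "PatientRecord",
    "read_cell_table",
    "write_cell_table",
    "read_roi_table",
    "write_roi_table",
    "read_patient_table",
    "write_patient_table",
    "cells_to_records",
    "records_to_cells",
]

#: Eight-marker panel used throughout: epithelial (CK), T-cell lineage
#: (CD4, CD8, FoxP3), macrophage (CD68, CD163) and checkpoint markers
#: (Siglec15, PDL1).
DEFAULT_MARKERS: tuple[str, ...] = (
    "CK", "CD4", "CD8", "FoxP3", "CD68", "CD163", "Siglec15", "PDL1",
)

ROI_WIDTH_UM: float = 931.0
ROI_HEIGHT_UM: float = 698.0
#: Nominal imaged field area, mm^2.
ROI_AREA_MM2: float = ROI_WIDTH_UM * ROI_HEIGHT_UM / 1e6

TISSUE_CLASSES = ("tumor", "stroma")
T_CLASSES = ("T1", "T2_4")
N_CLASSES = ("N0", "N1_2")

_AREA_TOL_MM2 = 1e-6


class TableFormatError(ValueError):
    """A table is structurally malformed (missing/unknown columns)."""


class TableValidationError(ValueError):
    """A table parsed but violates a content invariant."""


class ConfigurationError(ValueError):
    """A panel / rule / pipeline configuration is inconsistent."""


@dataclass(frozen=True)
class PanelConfig:
    """Marker panel plus per-marker intensity thresholds.

    Thresholds are consulted only when a table ships intensities without
    binary calls; positivity is threshold-inclusive (``intensity >= t``).
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    thresholds: Mapping[str, float] | float = 1.0

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ConfigurationError(f"duplicate marker names in panel: {self.markers}")
        object.__setattr__(self, "markers", tuple(self.markers))

    def threshold(self, marker: str) -> float:
        if isinstance(self.thresholds, Mapping):
            return float(self.thresholds.get(marker, 1.0))
        return float(self.thresholds)


@dataclass
class CellRecord:
    cell_id: str
    roi_id: str
    x_um: float
    y_um: float
    tissue_class: str
    marker_calls: dict[str, bool]
    marker_intensity: dict[str, float] | None = None


@dataclass
class RoiRecord:
    roi_id: str
    patient_id: str
    area_tumor_mm2: float
    area_stroma_mm2: float
    width_um: float = ROI_WIDTH_UM
    height_um: float = ROI_HEIGHT_UM

    @property
    def area_total_mm2(self) -> float:
        return self.area_tumor_mm2 + self.area_stroma_mm2

    def validate(self) -> None:
        if self.area_tumor_mm2 < 0 or self.area_stroma_mm2 < 0:
            raise TableValidationError(
                f"ROI {self.roi_id}: negative compartment area"
            )
        frame_mm2 = self.width_um * self.height_um / 1e6
        if self.area_total_mm2 > frame_mm2 + _AREA_TOL_MM2:
            raise TableValidationError(
                f"ROI {self.roi_id}: total tissue area {self.area_total_mm2:.6f} mm^2 "
                f"exceeds the {self.width_um:g} x {self.height_um:g} um frame "
                f"({frame_mm2:.6f} mm^2)"
            )


@dataclass
class PatientRecord:
    patient_id: str
    os_months: float
    dfs_months: float
    os_event: int
    dfs_event: int
    t_class: str
    n_class: str
    age_years: float
    sex: str
    smoking: int
    derived_features: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

_CELL_BASE = ["cell_id", "roi_id", "x_um", "y_um", "tissue_class"]


def _call_col(marker: str) -> str:
    return f"{marker}_call"


def _int_col(marker: str) -> str:
    return f"{marker}_intensity"


def _parse_calls(series: pd.Series, column: str) -> pd.Series:
    norm = series.astype(str).str.strip().str.lower()
    ok = norm.isin(("positive", "negative"))
    if not ok.all():
        bad = series[~ok]
        rows = ", ".join(str(i) for i in bad.index[:10])
        vals = ", ".join(repr(v) for v in bad.unique()[:5])
        raise TableValidationError(
            f"column {column!r}: invalid call value(s) {vals} at row(s) {rows}; "
            "expected 'positive' or 'negative'"
        )
    return norm.eq("positive")


def read_cell_table(
    path: str | Path,
    panel: PanelConfig | None = None,
    rois: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read and validate a per-cell CSV export.

    Parameters
    ----------
    path:
        CSV with header ``cell_id,roi_id,x_um,y_um,tissue_class`` plus, per
        panel marker, a ``<marker>_call`` column and/or a
        ``<marker>_intensity`` column.
    panel:
        Marker panel; defaults to the eight-marker panel.  A marker with
        intensities but no call column is thresholded (``>=`` positive).
    rois:
        Optional ROI table; when given, cell coordinates are checked
        against each owning ROI's frame and offenders are reported.

    Returns
    -------
    DataFrame with the base columns, one boolean ``<marker>_call`` column
    per marker and any intensity columns present in the file.
    """
    panel = panel or PanelConfig()
    raw = pd.read_csv(path, dtype={"cell_id": str, "roi_id": str})
    missing = [c for c in _CELL_BASE if c not in raw.columns]
    if missing:
        raise TableFormatError(f"cell table {path}: missing required column(s) {missing}")

    df = raw[_CELL_BASE].copy()
    df["x_um"] = pd.to_numeric(df["x_um"], errors="raise")
    df["y_um"] = pd.to_numeric(df["y_um"], errors="raise")

    tc = df["tissue_class"].astype(str).str.strip().str.lower()
    bad = ~tc.isin(TISSUE_CLASSES)
    if bad.any():
        vals = ", ".join(repr(v) for v in tc[bad].unique()[:5])
        rows = ", ".join(str(i) for i in df.index[bad][:10])
        raise TableValidationError(
            f"cell table {path}: tissue_class value(s) {vals} at row(s) {rows} "
            f"are not in {TISSUE_CLASSES}"
        )
    df["tissue_class"] = tc

    for m in panel.markers:
        call, intens = _call_col(m), _int_col(m)
        if call in raw.columns:
            df[call] = _parse_calls(raw[call], call)
        elif intens in raw.columns:
            vals = pd.to_numeric(raw[intens], errors="raise")
            if (vals < 0).any():
                raise TableValidationError(
                    f"cell table {path}: negative intensities in {intens!r}"
                )
            df[call] = vals >= panel.threshold(m)
        else:
            raise TableFormatError(
                f"cell table {path}: marker {m!r} has neither a {call!r} nor a "
                f"{intens!r} column"
            )
        if intens in raw.columns:
            df[intens] = pd.to_numeric(raw[intens], errors="raise")

    if rois is not None:
        _check_bounds(df, rois, path)
    return df


def _check_bounds(cells: pd.DataFrame, rois: pd.DataFrame, path: object) -> None:
    geo = rois.set_index("roi_id")[["width_um", "height_um"]]
    unknown = set(cells["roi_id"]) - set(geo.index)
    if unknown:
        raise TableValidationError(
            f"cell table {path}: roi_id(s) {sorted(unknown)[:5]} not present in ROI table"
        )
    w = cells["roi_id"].map(geo["width_um"]).to_numpy(float)
    h = cells["roi_id"].map(geo["height_um"]).to_numpy(float)
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    out = (x < 0) | (x > w) | (y < 0) | (y > h)
    if out.any():
        offenders = cells.loc[out, "cell_id"].tolist()[:10]
        raise TableValidationError(
            f"cell table {path}: {int(out.sum())} cell(s) outside their ROI frame, "
            f"e.g. {offenders}"
        )


def write_cell_table(
    cells: pd.DataFrame | Iterable[CellRecord],
    path: str | Path,
    panel: PanelConfig | None = None,
) -> None:
    """Write cells as CSV; boolean calls serialize as positive/negative.

    Intensity columns are written only when present, so records without
    intensities round-trip without spurious columns.
    """
    panel = panel or PanelConfig()
    if not isinstance(cells, pd.DataFrame):
        cells = records_to_cells(list(cells), panel)
    out = cells[_CELL_BASE].copy()
    for m in panel.markers:
        call = _call_col(m)
        out[call] = np.where(cells[call], "positive", "negative")
    for m in panel.markers:
        intens = _int_col(m)
        if intens in cells.columns:
            out[intens] = cells[intens]
    out.to_csv(path, index=False)


def cells_to_records(cells: pd.DataFrame, panel: PanelConfig | None = None) -> list[CellRecord]:
    panel = panel or PanelConfig()
    has_intens = [m for m in panel.markers if _int_col(m) in cells.columns]
    records = []
    for row in cells.itertuples(index=False):
        d = row._asdict()
        records.append(
            CellRecord(
                cell_id=d["cell_id"],
                roi_id=d["roi_id"],
                x_um=float(d["x_um"]),
                y_um=float(d["y_um"]),
                tissue_class=d["tissue_class"],
                marker_calls={m: bool(d[_call_col(m)]) for m in panel.markers},
                marker_intensity=(
                    {m: float(d[_int_col(m)]) for m in has_intens} if has_intens else None
                ),
            )
        )
    return records


def records_to_cells(records: Sequence[CellRecord], panel: PanelConfig | None = None) -> pd.DataFrame:
    panel = panel or PanelConfig()
    cols: dict[str, list] = {c: [] for c in _CELL_BASE}
    for r in records:
        missing = set(panel.markers) - set(r.marker_calls)
        if missing:
            raise TableValidationError(
                f"cell {r.cell_id}: missing marker call(s) {sorted(missing)}"
            )
        cols["cell_id"].append(r.cell_id)
        cols["roi_id"].append(r.roi_id)
        cols["x_um"].append(r.x_um)
        cols["y_um"].append(r.y_um)
        cols["tissue_class"].append(r.tissue_class)
    df = pd.DataFrame(cols, columns=_CELL_BASE)
    if df.empty:
        df = pd.DataFrame(columns=_CELL_BASE)
    for m in panel.markers:
        df[_call_col(m)] = [r.marker_calls[m] for r in records]
    if any(r.marker_intensity for r in records):
        for m in panel.markers:
            if any(r.marker_intensity and m in r.marker_intensity for r in records):
                df[_int_col(m)] = [
                    (r.marker_intensity or {}).get(m, np.nan) for r in records
                ]
    return df


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

_ROI_COLS = ["roi_id", "patient_id", "width_um", "height_um",
             "area_tumor_mm2", "area_stroma_mm2"]


def read_roi_table(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"roi_id": str, "patient_id": str})
    missing = [c for c in _ROI_COLS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"ROI table {path}: missing required column(s) {missing}")
    df = raw[_ROI_COLS].copy()
    for c in _ROI_COLS[2:]:
        df[c] = pd.to_numeric(df[c], errors="raise")
    for rec in df.itertuples(index=False):
        RoiRecord(
            roi_id=rec.roi_id, patient_id=rec.patient_id,
            area_tumor_mm2=rec.area_tumor_mm2, area_stroma_mm2=rec.area_stroma_mm2,
            width_um=rec.width_um, height_um=rec.height_um,
        ).validate()
    df["area_total_mm2"] = df["area_tumor_mm2"] + df["area_stroma_mm2"]
    return df


def write_roi_table(rois: pd.DataFrame | Iterable[RoiRecord], path: str | Path) -> None:
    if not isinstance(rois, pd.DataFrame):
        rois = pd.DataFrame([dataclasses.asdict(r) for r in rois], columns=_ROI_COLS)
    rois[_ROI_COLS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# patients
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "os_months", "dfs_months", "os_event", "dfs_event",
                 "t_class", "n_class", "age_years", "sex", "smoking"]
_FEATURE_PREFIX = "feat_"


def read_patient_table(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    missing = [c for c in _PATIENT_COLS if c not in raw.columns]
    if missing:
        raise TableFormatError(
            f"patient table {path}: missing required column(s) {missing}"
        )
    keep = _PATIENT_COLS + [c for c in raw.columns if c.startswith(_FEATURE_PREFIX)]
    df = raw[keep].copy()
    for c in ("os_months", "dfs_months", "age_years"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    for c in ("os_event", "dfs_event", "smoking"):
        vals = pd.to_numeric(df[c], errors="raise")
        if not vals.isin((0, 1)).all():
            raise TableValidationError(f"patient table {path}: {c} must be 0/1")
        df[c] = vals.astype(int)
    if (df[["os_months", "dfs_months"]] < 0).any().any():
        raise TableValidationError(f"patient table {path}: negative survival time")
    for c, allowed in (("t_class", T_CLASSES), ("n_class", N_CLASSES)):
        bad = ~df[c].isin(allowed)
        if bad.any():
            vals = ", ".join(repr(v) for v in df.loc[bad, c].unique()[:5])
            raise TableValidationError(
                f"patient table {path}: {c} value(s) {vals} not in {allowed}"
            )
    return df


def write_patient_table(
    patients: pd.DataFrame | Iterable[PatientRecord], path: str | Path
) -> None:
    if not isinstance(patients, pd.DataFrame):
        rows = []
        for p in patients:
            d = dataclasses.asdict(p)
            feats = d.pop("derived_features")
            d.update({f"{_FEATURE_PREFIX}{k}": v for k, v in feats.items()})
            rows.append(d)
        patients = pd.DataFrame(rows)
    cols = _PATIENT_COLS + [
        c for c in patients.columns if c.startswith(_FEATURE_PREFIX)
    ]
    patients[cols].to_csv(path, index=False)
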