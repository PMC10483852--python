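import numpy as np
import pandas as pd
import pytest

from siglec15_tme.phenotyping import assign_phenotypes
from siglec15_tme.simulate import SimConfig, generate_cohort
from siglec15_tme.tables import DEFAULT_MARKERS


def make_cells(rows, roi_id="roi1"):
    """Build a cell frame from compact dicts.

    Each row: {"id", "x", "y", "tissue", "pos": [markers...]}; unlisted
    markers are negative.
    """
    out = {
        "cell_id": [r.get("id", f"c{i}") for i, r in enumerate(rows)],
        "roi_id": [r.get("roi", roi_id) for r in rows],
        "x_um": [float(r["x"]) for r in rows],
        "y_um": [float(r["y"]) for r in rows],
        "tissue_class": [r.get("tissue", "stroma") for r in rows],
    }
    df = pd.DataFrame(out)
    for m in DEFAULT_MARKERS:
        df[f"{m}_call"] = [m in r.get("pos", ()) for r in rows]
    return df


def make_rois(roi_ids, patient_ids=None, area_tumor=0.3, area_stroma=0.349838):
    patient_ids = patient_ids or ["P0"] * len(roi_ids)
    return pd.DataFrame(
        {
            "roi_id": roi_ids,
            "patient_id": patient_ids,
            "width_um": 931.0,
            "height_um": 698.0,
            "area_tumor_mm2": area_tumor,
            "area_stroma_mm2": area_stroma,
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient synthetic cohort shared across read-only tests."""
    return generate_cohort(SimConfig(n_patients=12, seed=42))


@pytest.fixture(scope="session")
def pheno_cells(small_cohort):
    return assign_phenotypes(small_cohort.cells)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
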