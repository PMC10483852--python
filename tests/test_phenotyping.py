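import numpy as np
import pandas as pd
import pytest

from siglec15_tme.phenotyping import (
    DEFAULT_RULES,
    PhenotypeRule,
    assign_phenotypes,
    compartment_percent,
    density_by_area,
    joint_s15_classification,
    m2_ratio_category,
)
from siglec15_tme.tables import ConfigurationError

from conftest import make_cells, make_rois


@pytest.mark.parametrize(
    "positives, expected",
    [
        (["CK"], "tumor"),
        (["CD4", "FoxP3"], "Treg"),
        (["CD4"], "Teff"),
        (["CD8"], "CD8T"),
        (["CD68"], "TAM"),
        ([], "other"),
        (["CK", "CD68"], "tumor"),   # priority: tumor > TAM
        (["CD68", "CD4"], "TAM"),    # priority: TAM > T-cell lineages
    ],
)
def test_gate_assignment(positives, expected):
    cells = make_cells([{"x": 1, "y": 1, "pos": positives}])
    out = assign_phenotypes(cells)
    assert out["phenotype"].iloc[0] == expected


def test_subflags_follow_marker_calls():
    cells = make_cells([{"x": 1, "y": 1, "pos": ["CD68", "CD163", "Siglec15"]}])
    out = assign_phenotypes(cells)
    assert bool(out["s15_pos"].iloc[0]) and bool(out["cd163_pos"].iloc[0])
    assert not bool(out["pdl1_pos"].iloc[0])


def test_labels_partition_cells(pheno_cells):
    counts = pheno_cells["phenotype"].value_counts()
    assert counts.sum() == len(pheno_cells)
    assert set(counts.index) <= {"tumor", "TAM", "Treg", "Teff", "CD8T", "other"}


def test_rule_conflicts_rejected():
    with pytest.raises(ConfigurationError):
        PhenotypeRule("bad", ("CD4",), ("CD4",))
    with pytest.raises(ConfigurationError, match="absent from the panel"):
        assign_phenotypes(
            make_cells([{"x": 1, "y": 1}]),
            rules=(PhenotypeRule("x", ("NotAMarker",)),),
        )


def test_compartment_percent_arithmetic():
    rows = [{"x": i, "y": 1, "pos": ["CK", "Siglec15"] if i < 7 else ["CK"]}
            for i in range(40)]
    cells = assign_phenotypes(make_cells(rows))
    rois = make_rois(["roi1"])
    res = compartment_percent(cells, rois, "Siglec15")
    tc = res[res["compartment"] == "TC"].iloc[0]
    assert tc["percent_positive"] == pytest.approx(17.5)  # 7 of 40
    assert tc["n_cells"] == 40
    # MC empty -> undefined, not zero
    mc = res[res["compartment"] == "MC"].iloc[0]
    assert np.isnan(mc["percent_positive"]) and mc["n_cells"] == 0


def test_compartment_percent_pools_across_rois():
    rows = [{"roi": f"roi{1 + (i % 3)}", "x": i, "y": 1,
             "pos": ["CK", "Siglec15"] if i % 5 == 0 else ["CK"]}
            for i in range(60)]
    cells = assign_phenotypes(make_cells(rows))
    rois3 = make_rois(["roi1", "roi2", "roi3"])
    pooled = compartment_percent(cells, rois3, "Siglec15")
    # same cells all attributed to a single ROI must give the same answer
    cells1 = cells.assign(roi_id="roi1")
    single = compartment_percent(cells1, make_rois(["roi1"]), "Siglec15")
    a = pooled[pooled["compartment"] == "TC"]["percent_positive"].iloc[0]
    b = single[single["compartment"] == "TC"]["percent_positive"].iloc[0]
    assert a == pytest.approx(b)


def test_density_arithmetic():
    rows = [{"x": i, "y": 1, "tissue": "tumor" if i < 20 else "stroma",
             "pos": ["CD68"]} for i in range(26)]
    cells = assign_phenotypes(make_cells(rows))
    rois = make_rois(["roi1"], area_tumor=0.4, area_stroma=0.25)
    res = density_by_area(cells, rois, ["TAM"])
    by_kind = res.set_index("area_kind")["density"]
    assert by_kind["total"] == pytest.approx(26 / 0.65)  # 40.0
    assert by_kind["tumor"] == pytest.approx(20 / 0.4)
    assert by_kind["stroma"] == pytest.approx(6 / 0.25)


def test_density_046_15_example():
    # 30 TAMs in one 0.65 mm^2 field
    rows = [{"x": i, "y": 1, "pos": ["CD68"]} for i in range(30)]
    cells = assign_phenotypes(make_cells(rows))
    rois = make_rois(["roi1"], area_tumor=0.3, area_stroma=0.35)
    res = density_by_area(cells, rois, ["TAM"], area_kinds=["total"])
    assert res["density"].iloc[0] == pytest.approx(30 / 0.65, rel=1e-6)  # 46.15


def test_total_density_is_area_weighted_combination(pheno_cells, small_cohort):
    res = density_by_area(pheno_cells, small_cohort.rois, ["CD8T", "TAM"])
    pid = res["patient_id"].iloc[0]
    for ph in ("CD8T", "TAM"):
        sub = res[(res["phenotype"] == ph)
                  & (res["patient_id"] == pid)].set_index("area_kind")
        lhs = sub.loc["total", "density"] * sub.loc["total", "area_mm2"]
        rhs = (sub.loc["tumor", "density"] * sub.loc["tumor", "area_mm2"]
               + sub.loc["stroma", "density"] * sub.loc["stroma", "area_mm2"])
        assert lhs == pytest.approx(rhs)


def test_zero_area_density_undefined():
    cells = assign_phenotypes(make_cells([{"x": 1, "y": 1, "pos": ["CD68"]}]))
    rois = make_rois(["roi1"], area_tumor=0.0, area_stroma=0.65)
    res = density_by_area(cells, rois, ["TAM"], area_kinds=["tumor"])
    assert np.isnan(res["density"].iloc[0])


@pytest.mark.parametrize(
    "frac, expected",
    [(0.8, "high"), (0.75, "high"), (0.5, "intermediate"), (0.49, "low")],
)
def test_m2_ratio_categories(frac, expected):
    n = 100
    n_m2 = int(round(frac * n))
    rows = [{"x": i, "y": 1,
             "pos": ["CD68", "Siglec15"] + (["CD163"] if i < n_m2 else [])}
            for i in range(n)]
    cells = assign_phenotypes(make_cells(rows))
    res = m2_ratio_category(cells, make_rois(["roi1"]))
    assert res["category"].iloc[0] == expected
    assert res["m2_fraction"].iloc[0] == pytest.approx(frac)


def test_m2_ratio_undefined_without_s15_tams():
    cells = assign_phenotypes(make_cells([{"x": 1, "y": 1, "pos": ["CD68"]}]))
    res = m2_ratio_category(cells, make_rois(["roi1"]))
    assert np.isnan(res["m2_fraction"].iloc[0])


def test_joint_classification_proportions_and_marginals():
    # 213 patients with counts 31 / 3 / 26 / 153
    n = [31, 3, 26, 153]
    tc = [True] * 31 + [True] * 3 + [False] * 26 + [False] * 153
    mc = [True] * 31 + [False] * 3 + [True] * 26 + [False] * 153
    status = pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(213)], "tc_high": tc, "mc_high": mc}
    )
    res = joint_s15_classification(status).set_index("label")
    assert res["n"].tolist() == n
    assert res["percent"].sum() == pytest.approx(100.0)
    rounded = res["percent"].round(1)
    assert rounded.tolist() == [14.6, 1.4, 12.2, 71.8]
    # marginal TC-high = both_high + tc_only
    assert res.loc["both_high", "n"] + res.loc["tc_only", "n"] == sum(tc)


def test_joint_classification_excludes_missing_with_warning():
    status = pd.DataFrame(
        {"patient_id": ["a", "b", "c"], "tc_high": [True, np.nan, False],
         "mc_high": [True, True, False]}
    )
    with pytest.warns(UserWarning, match="excluded"):
        res = joint_s15_classification(status)
    assert res["n"].sum() == 2


def test_all_low_cohort():
    status = pd.DataFrame(
        {"patient_id": ["a", "b"], "tc_high": [False, False],
         "mc_high": [False, False]}
    )
    res = joint_s15_classification(status).set_index("label")
    assert res.loc["both_low", "percent"] == 100.0
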