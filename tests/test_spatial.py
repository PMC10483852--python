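import math

import numpy as np
import pandas as pd
import pytest

from siglec15_tme.phenotyping import assign_phenotypes
from siglec15_tme.spatial import (
    CellSelector,
    neighborhood_stats,
    neighbors_within,
    proximity_distance,
    spatial_density,
    stratified_spatial_comparison,
)
from siglec15_tme.tables import TableValidationError

from conftest import make_cells, make_rois


def _frame(xy, roi="roi1", prefix="t"):
    return pd.DataFrame(
        {"cell_id": [f"{prefix}{i}" for i in range(len(xy))], "roi_id": roi,
         "x_um": [p[0] for p in xy], "y_um": [p[1] for p in xy]}
    )


def brute_force_neighbors(ref, tgt, r):
    """All-pairs oracle: full distance matrix, inclusive radius."""
    out = []
    rx = ref[["x_um", "y_um"]].to_numpy(float)
    tx = tgt[["x_um", "y_um"]].to_numpy(float)
    rid = ref["cell_id"].to_numpy()
    tid = tgt["cell_id"].to_numpy()
    for i in range(len(rx)):
        d = np.hypot(tx[:, 0] - rx[i, 0], tx[:, 1] - rx[i, 1])
        keep = (d <= r) & (tid != rid[i])
        out.append(np.sort(d[keep]))
    return out


def test_three_four_five_triangle():
    ref = _frame([(0.0, 0.0)], prefix="r")
    tgt = _frame([(3.0, 4.0), (30.0, 40.0)])
    lists = neighbors_within(ref, tgt, 20.0)
    assert len(lists) == 1
    assert lists[0].tolist() == [5.0]


def test_no_targets_gives_empty_lists():
    ref = _frame([(0, 0), (10, 10)], prefix="r")
    tgt = _frame([])
    lists = neighbors_within(ref, tgt, 20.0)
    assert [len(x) for x in lists] == [0, 0]


def test_self_neighbor_excluded():
    cells = _frame([(0.0, 0.0), (5.0, 0.0)])
    lists = neighbors_within(cells, cells, 20.0)
    assert all(d.tolist() == [5.0] for d in lists)


def test_cross_roi_mixing_rejected():
    ref = _frame([(0, 0)], roi="roiA", prefix="r")
    tgt = _frame([(1, 1)], roi="roiB")
    with pytest.raises(TableValidationError, match="different ROIs"):
        neighbors_within(ref, tgt, 20.0)


@pytest.mark.parametrize("n,r", [(50, 25.0), (200, 40.0), (500, 15.0)])
def test_tree_search_equals_all_pairs_oracle(rng, n, r):
    xy = rng.uniform(0, 900, size=(n, 2))
    ref = _frame(list(map(tuple, xy[: n // 2])), prefix="r")
    tgt = _frame(list(map(tuple, xy[n // 2:])))
    got = neighbors_within(ref, tgt, r)
    want = brute_force_neighbors(ref, tgt, r)
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert np.array_equal(g, w)


def test_counts_monotone_in_radius_and_proximity_bounded(rng):
    xy = rng.uniform(0, 500, size=(300, 2))
    ref = _frame(list(map(tuple, xy[:100])), prefix="r")
    tgt = _frame(list(map(tuple, xy[100:])))
    prev = None
    for r in (20.0, 40.0, 60.0, 80.0):
        lists = neighbors_within(ref, tgt, r)
        counts = np.array([len(d) for d in lists])
        if prev is not None:
            assert (counts >= prev).all()
        prev = counts
        prox = proximity_distance(lists)
        assert 0.0 <= prox <= r


def test_pair_symmetry(rng):
    xy = rng.uniform(0, 400, size=(150, 2))
    a = _frame(list(map(tuple, xy[:70])), prefix="a")
    b = _frame(list(map(tuple, xy[70:])), prefix="b")
    r = 35.0
    ab = sum(len(d) for d in neighbors_within(a, b, r))
    ba = sum(len(d) for d in neighbors_within(b, a, r))
    assert ab == ba


def test_translation_rotation_invariance(rng):
    xy = rng.uniform(100, 300, size=(120, 2))
    a = _frame(list(map(tuple, xy[:60])), prefix="a")
    b = _frame(list(map(tuple, xy[60:])), prefix="b")
    r = 30.0
    base = neighbors_within(a, b, r)
    theta = 0.7
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    xy2 = xy @ rot.T + np.array([50.0, -20.0])
    a2 = _frame(list(map(tuple, xy2[:60])), prefix="a")
    b2 = _frame(list(map(tuple, xy2[60:])), prefix="b")
    moved = neighbors_within(a2, b2, r)
    d0 = spatial_density(base, r)
    d1 = spatial_density(moved, r)
    assert d1 == pytest.approx(d0, rel=1e-9)
    assert proximity_distance(moved) == pytest.approx(proximity_distance(base),
                                                      rel=1e-9)


def test_disc_density_closed_form():
    # 1 reference with 2 neighbors at r=20: 2 / (pi * 400e-6) per mm^2
    lists = [np.array([5.0, 15.0])]
    want = 2 / (math.pi * 400e-6)
    assert spatial_density(lists, 20.0) == pytest.approx(want)  # ~1591.5 per mm2
    assert spatial_density([np.empty(0)] * 5, 20.0) == 0.0
    assert math.isnan(spatial_density([], 20.0))


def test_tissue_mode_density():
    lists = [np.array([5.0]), np.array([1.0, 2.0, 3.0])]
    assert spatial_density(lists, 20.0, mode="tissue", tissue_area_mm2=0.5) == \
        pytest.approx((1 + 3) / 2 / 0.5)


def test_proximity_examples():
    assert proximity_distance([np.array([5.0])]) == 5.0
    assert proximity_distance([np.array([5.0]), np.array([15.0])]) == 10.0
    assert math.isnan(proximity_distance([np.empty(0)]))


def test_pooled_proximity_equals_distance_matrix_oracle(rng):
    xy = rng.uniform(0, 600, size=(250, 2))
    ref = _frame(list(map(tuple, xy[:100])), prefix="r")
    tgt = _frame(list(map(tuple, xy[100:])))
    r = 45.0
    got = proximity_distance(neighbors_within(ref, tgt, r))
    want = np.concatenate(brute_force_neighbors(ref, tgt, r)).mean()
    assert got == pytest.approx(want, rel=1e-12)


def _stratified_cells():
    rows = []
    # two patients, one ROI each; S15+ TAMs each have a CD8 cell at 5 um,
    # S15- TAMs have none nearby
    for p, roi in (("P0", "roiA"), ("P1", "roiB")):
        for i in range(6):
            s15 = i < 3
            x = 100.0 + 120 * i
            rows.append({"roi": roi, "id": f"{roi}tam{i}", "x": x, "y": 100,
                         "pos": ["CD68"] + (["Siglec15"] if s15 else [])})
            if s15:
                rows.append({"roi": roi, "id": f"{roi}cd8{i}", "x": x + 5,
                             "y": 100, "pos": ["CD8"]})
    return assign_phenotypes(make_cells(rows))


def test_stratified_comparison_detects_planted_difference():
    cells = _stratified_cells()
    rois = make_rois(["roiA", "roiB"], ["P0", "P1"])
    strata = {
        "S15+ TAM": CellSelector("TAM", positive=("Siglec15",)),
        "S15- TAM": CellSelector("TAM", negative=("Siglec15",)),
    }
    stats_df, tests = stratified_spatial_comparison(
        cells, rois, strata, CellSelector("CD8T"), radii_um=(20.0,)
    )
    dens = stats_df.pivot(index="patient_id", columns="stratum",
                          values="spatial_density")
    assert (dens["S15+ TAM"] > dens["S15- TAM"]).all()
    row = tests[tests["metric"] == "spatial_density"].iloc[0]
    assert row["median_a"] > row["median_b"]
    assert row["n_patients"] == 2


def test_identical_strata_p_is_one():
    cells = _stratified_cells()
    rois = make_rois(["roiA", "roiB"], ["P0", "P1"])
    strata = {
        "all TAM": CellSelector("TAM", label="a"),
        "all TAM again": CellSelector("TAM", label="b"),
    }
    _, tests = stratified_spatial_comparison(
        cells, rois, strata, CellSelector("CD8T"), radii_um=(20.0,)
    )
    row = tests[tests["metric"] == "spatial_density"].iloc[0]
    assert row["statistic"] == 0.0 and row["p_value"] == 1.0


def test_single_patient_comparison_undefined():
    cells = _stratified_cells()
    cells = cells[cells["roi_id"] == "roiA"]
    rois = make_rois(["roiA"], ["P0"])
    strata = {
        "S15+ TAM": CellSelector("TAM", positive=("Siglec15",)),
        "S15- TAM": CellSelector("TAM", negative=("Siglec15",)),
    }
    _, tests = stratified_spatial_comparison(
        cells, rois, strata, CellSelector("CD8T"), radii_um=(20.0,)
    )
    assert tests["p_value"].isna().all()


def test_patient_pooling_is_reference_weighted(pheno_cells, small_cohort):
    ref = CellSelector("TAM")
    tgt = CellSelector("CD8T")
    by_roi = neighborhood_stats(pheno_cells, small_cohort.rois, ref, tgt,
                                radii_um=(40.0,), level="roi")
    by_pat = neighborhood_stats(pheno_cells, small_cohort.rois, ref, tgt,
                                radii_um=(40.0,), level="patient")
    merged = by_roi.groupby("patient_id").agg(
        n_ref=("n_reference", "sum"), n_pairs=("n_pairs", "sum")
    )
    for rec in by_pat.itertuples(index=False):
        want = merged.loc[rec.patient_id, "n_pairs"] / \
            merged.loc[rec.patient_id, "n_ref"] / (math.pi * 1600e-6)
        assert rec.spatial_density == pytest.approx(want)
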