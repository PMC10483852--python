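import numpy as np
import pytest

from siglec15_tme.simulate import (
    Interaction,
    SimConfig,
    generate_cohort,
    generate_roi,
    sample_poisson_points,
    simulate_ph_cohort,
    write_cohort,
)
from siglec15_tme.tables import ConfigurationError


def test_same_seed_byte_identical(tmp_path):
    cfg = SimConfig(n_patients=3, seed=123)
    a = write_cohort(generate_cohort(cfg), tmp_path / "a")
    b = write_cohort(generate_cohort(SimConfig(n_patients=3, seed=123)),
                     tmp_path / "b")
    for key in a:
        assert a[key].read_bytes() == b[key].read_bytes()


def test_different_seed_differs(tmp_path):
    a = generate_cohort(SimConfig(n_patients=2, seed=1))
    b = generate_cohort(SimConfig(n_patients=2, seed=2))
    assert not a.cells.equals(b.cells)


def test_areas_partition_frame_exactly(small_cohort):
    rois = small_cohort.rois
    frame = rois["width_um"] * rois["height_um"] / 1e6
    total = rois["area_tumor_mm2"] + rois["area_stroma_mm2"]
    assert np.allclose(total, frame, rtol=0, atol=1e-12)
    assert (rois["area_tumor_mm2"] > 0).all()


def test_zero_intensities_give_empty_roi():
    cfg = SimConfig(intensities={"CD8T": (0.0, 0.0)}, interactions=[])
    cells, roi = generate_roi(cfg, 0)
    assert len(cells) == 0
    assert roi.area_total_mm2 == pytest.approx(0.649838)


def test_cells_lie_inside_frame(small_cohort):
    c = small_cohort.cells
    assert ((c["x_um"] >= 0) & (c["x_um"] <= 931)).all()
    assert ((c["y_um"] >= 0) & (c["y_um"] <= 698)).all()


def test_tissue_class_matches_phenotype_layout(small_cohort):
    # epithelial tumor cells are only generated inside tumor nests
    tum = small_cohort.cells[small_cohort.cells["CK_call"]]
    assert (tum["tissue_class"] == "tumor").all()


def test_poisson_count_calibration():
    # homogeneous 100 cells/mm^2 on a 0.65 mm^2 frame: mean count 65
    rng = np.random.default_rng(2)
    counts = [
        len(sample_poisson_points(100.0, 931.0, 698.0, rng)) for _ in range(500)
    ]
    mean = np.mean(counts)
    expected = 100.0 * 0.649838
    se = np.sqrt(expected / 500)  # Poisson variance = mean
    assert abs(mean - expected) <= 3 * se


def test_intensity_overflow_refused():
    cfg = SimConfig(intensities={"other": (1e8, 1e8)}, interactions=[])
    with pytest.raises(ConfigurationError, match="refusing"):
        generate_roi(cfg, 0)


def test_invalid_interaction_rejected():
    with pytest.raises(ConfigurationError):
        Interaction("TAM", {}, "CD8T", "teleport")
    with pytest.raises(ConfigurationError):
        Interaction("TAM", {}, "CD8T", "exclusion", retention=1.5)


def _pinned_marker_model():
    mm = {k: dict(v) for k, v in SimConfig().marker_model.items()}
    mm["s15_mc"] = {"mu": 0.0, "sigma": 0.0, "load": 0.0}  # P(S15+ TAM) = 0.5
    return mm


def test_attraction_adds_targets_near_flagged_references():
    base = dict(
        intensities={"TAM": (150.0, 150.0), "CD8T": (100.0, 100.0)},
        patient_sd_log=0.0, cd8_high_prob=0.0, tmit_tam_multiplier=1.0,
        marker_model=_pinned_marker_model(),
    )
    quiet = SimConfig(interactions=[], seed=0, **base)
    planted = SimConfig(
        interactions=[Interaction("TAM", {"Siglec15": True}, "CD8T",
                                  "attraction", strength=3.0, sigma_um=10.0)],
        seed=0, **base,
    )
    n_quiet = len(generate_roi(quiet, 5)[0].query("CD8_call"))
    n_planted = len(generate_roi(planted, 5)[0].query("CD8_call"))
    assert n_planted > n_quiet


def test_exclusion_removes_targets_near_flagged_references():
    base = dict(
        intensities={"TAM": (150.0, 150.0), "CD8T": (300.0, 300.0)},
        patient_sd_log=0.0, cd8_high_prob=0.0, tmit_tam_multiplier=1.0,
        marker_model=_pinned_marker_model(),
    )
    quiet = SimConfig(interactions=[], seed=0, **base)
    planted = SimConfig(
        interactions=[Interaction("TAM", {"Siglec15": True}, "CD8T",
                                  "exclusion", sigma_um=20.0, retention=0.0)],
        seed=0, **base,
    )
    n_quiet = len(generate_roi(quiet, 5)[0].query("CD8_call"))
    n_planted = len(generate_roi(planted, 5)[0].query("CD8_call"))
    assert n_planted < n_quiet


def test_survival_plan_censoring_rate_achieved(rng):
    df = simulate_ph_cohort(4000, 0.0, rng, censor_rate=0.45)
    assert abs(1 - df["event"].mean() - 0.45) < 0.03
    assert (df["time"] > 0).all()


def test_event_flags_and_enums_valid(small_cohort):
    p = small_cohort.patients
    assert p["dfs_event"].isin([0, 1]).all() and p["os_event"].isin([0, 1]).all()
    assert p["t_class"].isin(["T1", "T2_4"]).all()
    assert p["n_class"].isin(["N0", "N1_2"]).all()
    assert (p[["os_months", "dfs_months"]] > 0).all().all()


def test_truth_manifest_recomputes_planted_statuses(small_cohort):
    truth = small_cohort.truth
    assert len(truth.patients) == 12
    for tp in truth.patients:
        assert tp["s15_tc_high"] == (tp["probs"]["s15_tc"] >= 0.05)
        assert tp["s15_mc_high"] == (tp["probs"]["s15_mc"] >= 0.16)
    assert truth.config["n_patients"] == 12


def test_yaml_round_trip(tmp_path):
    cfg = SimConfig(n_patients=7, seed=9)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    back = SimConfig.from_yaml(p)
    assert back == cfg
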