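import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siglec15_tme.simulate import simulate_ph_cohort
from siglec15_tme.survival import (
    CutoffResult,
    benjamini_hochberg,
    classify_high,
    cox_regression,
    fixed_cutoff,
    km_logrank,
    stratify_by_spatial_feature,
    youden_cutoff,
)
from siglec15_tme.tables import TableValidationError


def test_youden_perfect_separation():
    res = youden_cutoff([1, 2, 9, 10], [0, 0, 1, 1])
    assert res.cutoff == 9  # smallest value achieving J = 1
    assert res.youden_j == pytest.approx(1.0)


def test_youden_single_class_is_error():
    with pytest.raises(TableValidationError, match="single class"):
        youden_cutoff([1, 2, 3], [0, 0, 0])


def test_youden_tie_breaks_toward_smaller_cutoff():
    # both cutoffs 2 and 3 give J = 0.5; the smaller must win
    res = youden_cutoff([1, 2, 3, 4], [0, 1, 0, 1])
    exhaustive = {}
    v = np.array([1, 2, 3, 4]); y = np.array([0, 1, 0, 1])
    for c in v:
        pred = v >= c
        exhaustive[c] = (pred & (y == 1)).sum() / 2 + (~pred & (y == 0)).sum() / 2 - 1
    best = max(exhaustive.values())
    assert exhaustive[res.cutoff] == pytest.approx(best)
    assert res.cutoff == min(c for c, j in exhaustive.items() if j == best)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    values=st.lists(st.integers(-5, 5).map(float), min_size=4, max_size=25),
    bits=st.lists(st.booleans(), min_size=4, max_size=25),
)
def test_youden_matches_exhaustive_scan_property(values, bits):
    """On arbitrary (tied, discrete) inputs the vectorized scan equals the
    naive per-threshold computation, including the tie-break."""
    n = min(len(values), len(bits))
    v = np.array(values[:n])
    y = np.array(bits[:n], dtype=int)
    if y.sum() in (0, n):
        return
    res = youden_cutoff(v, y)
    best_j, best_c = -2.0, None
    for c in np.sort(np.unique(v)):
        pred = v >= c
        sens = (pred & (y == 1)).sum() / y.sum()
        spec = (~pred & (y == 0)).sum() / (n - y.sum())
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    assert res.cutoff == best_c
    assert res.youden_j == pytest.approx(best_j)


def test_classification_is_cutoff_inclusive():
    assert classify_high([4.9, 5.0, 5.1], 5.0).tolist() == [False, True, True]
    assert fixed_cutoff("f", "fixed_5").cutoff == 5.0


def _km_survival(fit, group):
    sub = fit.curves[fit.curves["group"] == group]
    return sub.set_index("time")["survival"]


def test_km_without_censoring_is_empirical_survival():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 20.0, 30.0])
    e = np.ones(8, int)
    g = np.array(["A"] * 5 + ["B"] * 3)
    fit = km_logrank(t, e, g)
    s = _km_survival(fit, "A")
    # S(t) = fraction of group A still event-free
    assert s.loc[1.0] == pytest.approx(4 / 5)
    assert s.loc[3.0] == pytest.approx(2 / 5)
    assert s.loc[5.0] == pytest.approx(0.0)
    # curve non-increasing, starts at 1
    assert s.iloc[0] <= 1.0 and (np.diff(s.to_numpy()) <= 1e-12).all()


def test_identical_groups_logrank_is_null():
    t = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
    e = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0])
    g = np.array(["A"] * 5 + ["B"] * 5)
    fit = km_logrank(t, e, g)
    assert fit.logrank_statistic == pytest.approx(0.0, abs=1e-9)
    assert fit.logrank_p == pytest.approx(1.0)


def _logrank_oracle(t1, e1, t2, e2):
    """Textbook two-group log-rank: (sum(O-E))^2 / sum(V)."""
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    u = v = 0.0
    for tt in times:
        n1 = (t1 >= tt).sum(); n2 = (t2 >= tt).sum()
        d1 = ((t1 == tt) & (e1 == 1)).sum(); d2 = ((t2 == tt) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        if n <= 1 or d == 0:
            continue
        u += d1 - d * n1 / n
        v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return u * u / v


def test_logrank_matches_hand_formula():
    t1 = np.array([1.0, 3.0, 5.0]); e1 = np.array([1, 1, 0])
    t2 = np.array([2.0, 4.0, 6.0]); e2 = np.array([1, 1, 1])
    fit = km_logrank(np.concatenate([t1, t2]), np.concatenate([e1, e2]),
                     np.array(["A"] * 3 + ["B"] * 3))
    want = _logrank_oracle(t1, e1, t2, e2)
    assert fit.logrank_statistic == pytest.approx(want, rel=1e-9)


def test_empty_group_rejected():
    with pytest.raises(TableValidationError):
        km_logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array(["A", "A"]))


def _breslow_loglik(beta, t, e, x):
    order = np.argsort(-t)  # descending: risk set is a prefix
    t, e, x = t[order], e[order], x[order]
    ll = 0.0
    risk = 0.0
    for i in range(len(t)):
        risk += math.exp(beta * x[i])
        if e[i] == 1:
            ll += beta * x[i] - math.log(risk)
    return ll


def test_cox_matches_grid_search_oracle(rng):
    n = 60
    x = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x)))  # continuous, no ties
    e = np.ones(n, int)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    fit = cox_regression(df, ["x"], duration_col="time", event_col="event")
    beta_hat = math.log(fit.cox["hr"].iloc[0])
    grid = np.arange(-3, 3, 0.001)
    ll = [_breslow_loglik(b, t, e, x) for b in grid]
    beta_grid = grid[int(np.argmax(ll))]
    assert beta_hat == pytest.approx(beta_grid, abs=2e-3)


def test_constant_covariate_dropped_with_warning(rng):
    df = simulate_ph_cohort(80, math.log(2), rng)
    df["const"] = 1.0
    with pytest.warns(UserWarning, match="constant"):
        fit = cox_regression(df, ["x", "const"], duration_col="time",
                             event_col="event")
    assert set(fit.cox["covariate"]) == {"x"}


def test_stepwise_enters_only_univariate_significant(rng):
    df = simulate_ph_cohort(300, math.log(2.5), rng)
    df["noise"] = rng.normal(size=len(df))
    fit = cox_regression(df, ["x", "noise"], duration_col="time",
                         event_col="event", mode="multivariate_stepwise")
    uni = fit.cox[fit.cox["mode"] == "univariate"].set_index("covariate")
    multi = fit.cox[fit.cox["mode"] == "multivariate_stepwise"]
    want = {c for c in ("x", "noise") if uni.loc[c, "p"] < 0.05}
    assert set(multi["covariate"]) == want
    assert "x" in want  # planted HR 2.5 at n=300 is essentially always entered
    # CI contains the point estimate
    assert ((fit.cox["ci_low"] <= fit.cox["hr"])
            & (fit.cox["hr"] <= fit.cox["ci_high"])).all()


def test_median_split_stratification_detects_planted_hazard(rng):
    # feature tied to hazard across the median split (HR 2)
    n = 200
    feat = rng.normal(size=n)
    high = feat >= np.median(feat)
    hazards = 0.02 * np.exp(math.log(2) * high)
    t = rng.exponential(1 / hazards)
    df = pd.DataFrame({"patient_id": range(n), "feat": feat,
                       "dfs_months": t, "dfs_event": 1})
    fit = stratify_by_spatial_feature(df, "feat", "DFS")
    assert fit.logrank_p < 0.05
    assert set(fit.groups) == {"feat high", "feat low"}


def test_stratification_power_at_planted_hr(rng):
    hits = 0
    reps = 50
    for _ in range(reps):
        df = simulate_ph_cohort(200, math.log(2), rng)
        df = df.rename(columns={"time": "dfs_months", "event": "dfs_event",
                                "x": "f"})
        fit = stratify_by_spatial_feature(df, "f", "DFS", cutoff=0.5)
        hits += fit.logrank_p < 0.05
    assert hits / reps >= 0.8


def test_constant_feature_is_error():
    df = pd.DataFrame({"patient_id": [1, 2, 3], "f": [1.0, 1.0, 1.0],
                       "dfs_months": [1.0, 2.0, 3.0], "dfs_event": [1, 1, 1]})
    with pytest.raises(TableValidationError, match="single group"):
        stratify_by_spatial_feature(df, "f", "DFS")
    df["g"] = np.nan
    with pytest.raises(TableValidationError, match="missing"):
        stratify_by_spatial_feature(df, "g", "DFS")


def test_benjamini_hochberg_known_case():
    adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert benjamini_hochberg([0.5]) == pytest.approx([0.5])
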