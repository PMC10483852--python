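"""Cutoff determination and survival stratification.

Expression and density features are dichotomized into high/low either at
fixed percentages (>= 1%, >= 5%, >= 25%) or at the Youden-optimal cutoff
(the observed value maximizing J = sensitivity + specificity - 1 for
predicting a binary outcome; ties broken toward the smaller cutoff).
"High" is always cutoff-inclusive (value >= cutoff).

Stratified groups are compared with Kaplan-Meier product-limit curves and
the two-sided log-rank test; hazard ratios come from Cox proportional-
hazards regression, either univariate per covariate or multivariate with
forward-stepwise entry (covariates with univariate p < 0.05 enter; no
removal step).  Spatial features (e.g. CD8 T-cell density around
Siglec-15+ tumor cells) are dichotomized at the cohort median by default
before Kaplan-Meier analysis.  All tests are two-sided at alpha = 0.05;
no multiple-testing correction is applied across radii or features
(Benjamini-Hochberg is available as an opt-in helper).

Kaplan-Meier, log-rank and Cox fitting delegate to :mod:`lifelines`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .tables import ConfigurationError, TableValidationError

__all__ = [
    "FIXED_CUTOFFS",
    "CutoffResult",
    "SurvivalFit",
    "classify_high",
    "youden_cutoff",
    "fixed_cutoff",
    "km_logrank",
    "cox_regression",
    "stratify_by_spatial_feature",
    "benjamini_hochberg",
    "endpoint_columns",
]

#: Fixed dichotomization family for percent-positive features.
FIXED_CUTOFFS: dict[str, float] = {"fixed_1": 1.0, "fixed_5": 5.0, "fixed_25": 25.0}


@dataclass(frozen=True)
class CutoffResult:
    feature: str
    cutoff: float
    method: str
    youden_j: float = float("nan")


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves with a log-rank test, and/or Cox estimates."""

    groups: list[str]
    curves: pd.DataFrame | None = None      # group, time, survival, n_at_risk
    logrank_statistic: float = float("nan")
    logrank_p: float = float("nan")
    cox: pd.DataFrame | None = None         # covariate, hr, ci_low, ci_high, p
    warnings: list[str] = field(default_factory=list)


def classify_high(values: np.ndarray | pd.Series, cutoff: float) -> np.ndarray:
    """Cutoff-inclusive dichotomization: high means value >= cutoff."""
    return np.asarray(values, float) >= cutoff


def fixed_cutoff(feature: str, method: str) -> CutoffResult:
    try:
        return CutoffResult(feature, FIXED_CUTOFFS[method], method)
    except KeyError:
        raise ConfigurationError(
            f"unknown fixed cutoff {method!r}; expected one of {sorted(FIXED_CUTOFFS)}"
        ) from None


def youden_cutoff(
    values: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    feature: str = "",
) -> CutoffResult:
    """Observed value maximizing J = sensitivity + specificity - 1.

    ``values >= cutoff`` predicts ``outcome == 1``.  Candidate cutoffs are
    the observed values; ties in J are broken toward the smaller cutoff.
    Requires both outcome classes to be present.
    """
    v = np.asarray(values, float)
    y = np.asarray(outcome, int)
    if v.shape != y.shape or v.ndim != 1:
        raise ConfigurationError("values and outcome must be 1-d of equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise TableValidationError(
            "Youden cutoff undefined: outcome has a single class "
            f"({n_pos} events / {n_neg} non-events)"
        )
    # sort descending; sweeping the cutoff down adds points to the
    # predicted-positive side in order
    order = np.argsort(-v, kind="stable")
    vs, ys = v[order], y[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    # candidate cutoff = vs[i]: predicted positive are all with value >= vs[i],
    # i.e. through the last index j with vs[j] == vs[i]
    last = np.searchsorted(-vs, -vs, side="right") - 1
    sens = tp[last] / n_pos
    spec = 1.0 - fp[last] / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    # among maximizers choose the smallest cutoff value
    best_cut = vs[j >= best_j - 1e-12].min()
    return CutoffResult(feature, float(best_cut), "youden", float(best_j))


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    ep = endpoint.strip().upper()
    if ep == "DFS":
        return "dfs_months", "dfs_event"
    if ep == "OS":
        return "os_months", "os_event"
    raise ConfigurationError(f"endpoint must be 'DFS' or 'OS', got {endpoint!r}")


def km_logrank(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    include_curves: bool = True,
) -> SurvivalFit:
    """Per-group Kaplan-Meier curves and a two-sided log-rank test.

    ``include_curves=False`` skips the product-limit curves (used in
    simulation loops where only the log-rank test is needed).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g = np.asarray(groups)
    if np.any(t < 0):
        raise TableValidationError("negative survival times")
    labels = [str(x) for x in pd.unique(g)]
    if len(labels) < 2:
        raise TableValidationError(
            f"log-rank requires >= 2 non-empty groups, got {labels}"
        )
    curves = []
    for lab in labels:
        mask = g.astype(str) == lab
        if mask.sum() == 0:
            raise TableValidationError(f"group {lab!r} is empty")
        if not include_curves:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=lab)
        at_risk = kmf.event_table["at_risk"]
        surv = kmf.survival_function_[lab]
        curves.append(
            pd.DataFrame(
                {"group": lab, "time": surv.index.to_numpy(float),
                 "survival": surv.to_numpy(float),
                 "n_at_risk": at_risk.reindex(surv.index).ffill().to_numpy(float)}
            )
        )
    res = multivariate_logrank_test(t, g.astype(str), e)
    return SurvivalFit(
        groups=labels,
        curves=pd.concat(curves, ignore_index=True) if curves else None,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             covariates: list[str]) -> pd.DataFrame:
    cph = CoxPHFitter()
    cph.fit(df[[duration_col, event_col] + covariates],
            duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return pd.DataFrame(
        {"covariate": s.index,
         "hr": s["exp(coef)"].to_numpy(float),
         "ci_low": s["exp(coef) lower 95%"].to_numpy(float),
         "ci_high": s["exp(coef) upper 95%"].to_numpy(float),
         "p": s["p"].to_numpy(float)}
    ).reset_index(drop=True)


def cox_regression(
    patients: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "dfs_months",
    event_col: str = "dfs_event",
    mode: str = "univariate",
    entry_p: float = 0.05,
) -> SurvivalFit:
    """Cox proportional-hazards regression (Wald HR, 95% CI, p).

    ``univariate`` fits each covariate alone; ``multivariate_stepwise``
    enters every covariate whose univariate p < ``entry_p`` into one
    joint model (forward entry, no removal).  Constant covariates are
    dropped with a warning.
    """
    if mode not in ("univariate", "multivariate_stepwise"):
        raise ConfigurationError(f"unknown Cox mode {mode!r}")
    df = patients.dropna(subset=[duration_col, event_col] + covariates).copy()
    notes: list[str] = []
    usable = []
    for c in covariates:
        if df[c].nunique() <= 1:
            msg = f"covariate {c!r} is constant and was dropped"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        else:
            usable.append(c)
    if not usable:
        raise TableValidationError("no non-constant covariates to fit")

    uni_rows = []
    for c in usable:
        row = _fit_cox(df, duration_col, event_col, [c])
        row["mode"] = "univariate"
        uni_rows.append(row)
    uni = pd.concat(uni_rows, ignore_index=True)

    if mode == "univariate":
        return SurvivalFit(groups=usable, cox=uni, warnings=notes)

    selected = [
        c for c in usable if float(uni.loc[uni["covariate"] == c, "p"].iloc[0]) < entry_p
    ]
    if not selected:
        notes.append(f"no covariate reached univariate p < {entry_p}; "
                     "multivariate model not fitted")
        return SurvivalFit(groups=usable, cox=uni, warnings=notes)
    multi = _fit_cox(df, duration_col, event_col, selected)
    multi["mode"] = "multivariate_stepwise"
    return SurvivalFit(
        groups=usable, cox=pd.concat([uni, multi], ignore_index=True), warnings=notes
    )


def stratify_by_spatial_feature(
    patients: pd.DataFrame,
    feature: str,
    endpoint: str = "DFS",
    cutoff: float | str = "median",
) -> SurvivalFit:
    """Dichotomize a per-patient feature and run KM + log-rank.

    ``cutoff='median'`` (default) splits at the cohort median; a numeric
    cutoff is used as-is; high means value >= cutoff.  Raises if the
    feature is missing for all patients or the split leaves one group.
    """
    dur, ev = endpoint_columns(endpoint)
    df = patients.dropna(subset=[feature, dur, ev])
    if df.empty:
        raise TableValidationError(f"feature {feature!r} is missing for all patients")
    cut = float(df[feature].median()) if cutoff == "median" else float(cutoff)
    high = classify_high(df[feature], cut)
    if high.all() or (~high).all():
        raise TableValidationError(
            f"feature {feature!r} does not split the cohort at cutoff {cut:g} "
            "(single group)"
        )
    groups = np.where(high, f"{feature} high", f"{feature} low")
    fit = km_logrank(df[dur], df[ev], groups)
    fit.warnings.append(f"cutoff={cut:g}")
    return fit


def benjamini_hochberg(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """BH-adjusted p-values (opt-in extension; not applied by default)."""
    p = np.asarray(p_values, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
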