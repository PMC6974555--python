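"""Survival analysis for the cohort stage.

Kaplan-Meier product-limit curves with Greenwood variance and log-log
95% confidence bands, log-rank group comparisons, Cox proportional-
hazards fits (Efron tie handling, Wald CIs), the CVHR-threshold
mortality scan, and Pearson correlation.  All estimators are delegated
to lifelines / scipy behind a thin result layer; tests cross-check them
against brute-force product-limit and risk-set enumeration oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

HORIZON_YEARS = 5.0
MIN_SUBGROUP = 20


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve with log-log Greenwood 95% CI."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0

    def mortality_at(self, t: float = HORIZON_YEARS) -> float:
        return 1.0 - self.survival_at(t)

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return (float(self.ci_low[idx]), float(self.ci_high[idx]))


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate hazard ratios with Wald 95% CIs and p-values."""

    summary: pd.DataFrame  # index = covariate; columns hr, ci_low, ci_high, p, coef, se
    log_likelihood: float
    n: int
    n_events: int
    converged: bool

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci95(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return (float(row["ci_low"]), float(row["ci_high"]))

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


class CoxConvergenceError(RuntimeError):
    """Cox partial-likelihood maximisation failed (or data are separated)."""


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    CIs are Greenwood on the log(-log S) scale, which keeps the bands
    inside [0, 1].
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no subjects")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    ts = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy()
    low = ci.iloc[:, 0].to_numpy()
    high = ci.iloc[:, 1].to_numpy()
    sorted_times = np.sort(times)
    at_risk = len(times) - np.searchsorted(sorted_times, ts, side="left")
    return KMCurve(
        event_times=ts, survival=surv, ci_low=low, ci_high=high, n_at_risk=at_risk, n=len(times)
    )


def logrank_test(
    group_labels: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float]:
    """Log-rank comparison of >= 2 groups; returns (chi2, p)."""
    group_labels = np.asarray(group_labels)
    groups, counts = np.unique(group_labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts == 0):
        raise ValueError("empty group")
    res = multivariate_logrank_test(np.asarray(times, float), group_labels, np.asarray(events, bool))
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    design: pd.DataFrame, times: np.ndarray, events: np.ndarray
) -> CoxFit:
    """Multivariable Cox proportional-hazards fit (Efron ties).

    ``design`` holds one column per covariate (binary covariates as 0/1).
    Raises :class:`CoxConvergenceError` instead of returning silent
    estimates when the partial likelihood cannot be maximised.
    """
    design = pd.DataFrame(design).astype(float).reset_index(drop=True)
    if design.shape[0] != len(times):
        raise ValueError("design and times length mismatch")
    variances = design.var(axis=0)
    if np.any(variances == 0):
        raise ValueError(f"constant covariate(s): {list(variances.index[variances == 0])}")
    n_events = int(np.sum(events))
    if n_events < design.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")
    df = design.copy()
    df["__time"] = np.asarray(times, dtype=float)
    df["__event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__time", event_col="__event")
    except Exception as exc:  # convergence / separation
        raise CoxConvergenceError(str(exc)) from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        converged=True,
    )


def threshold_mortality_scan(
    cvhr_minutes: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    thresholds: np.ndarray | None = None,
    min_subgroup: int = MIN_SUBGROUP,
    horizon: float = HORIZON_YEARS,
) -> pd.DataFrame:
    """Mortality as a function of a CVHR-duration ceiling.

    For each threshold tau, the KM ``horizon``-year mortality (with 95%
    CI) of the subgroup with cvhr_minutes <= tau.  Intended for non-flat
    patients only.  Subgroups smaller than ``min_subgroup`` are
    suppressed.  Default threshold grid: every observed CVHR value.
    """
    cvhr_minutes = np.asarray(cvhr_minutes, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if thresholds is None:
        thresholds = np.unique(cvhr_minutes)
    rows = []
    for tau in np.asarray(thresholds, dtype=float):
        mask = cvhr_minutes <= tau
        n = int(mask.sum())
        if n < min_subgroup:
            continue
        curve = km_estimate(times[mask], events[mask])
        lo, hi = curve.ci_at(horizon)
        rows.append(
            {
                "threshold_min": float(tau),
                "n": n,
                "mortality": curve.mortality_at(horizon),
                "ci_low": 1.0 - hi,
                "ci_high": 1.0 - lo,
            }
        )
    return pd.DataFrame(rows, columns=["threshold_min", "n", "mortality", "ci_low", "ci_high"])


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN-safe precondition checks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)
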