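"""Kaplan-Meier estimation, log-rank testing and Cox modelling.

The two-group log-rank statistic is computed in-package from the pooled
risk table (vectorized; it is evaluated at every candidate threshold inside
the minimum-p cut-point scan, so it has to be cheap).  Cox fits go through
lifelines with Efron tie handling.  A hand-written Efron partial-likelihood
score test is provided to check the classical identity that the Cox score
test for a binary covariate equals the log-rank test.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SurvivalCurve:
    """Product-limit estimate: step times, survival probabilities, risk set."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclasses.dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs and p-values."""

    table: pd.DataFrame  # columns: covariate, hr, ci_low, ci_high, p
    converged: bool
    selection_trace: list[str] = dataclasses.field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "p"])


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator (censoring shrinks the risk set
    without a step)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    # drop the t=0 anchor row; keep distinct observed times
    sf = fitter.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [int((times >= t).sum()) for t in grid], dtype=int
    )
    keep = grid > 0
    return SurvivalCurve(times=grid[keep], survival=surv[keep], at_risk=at_risk[keep])


def _risk_table(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per distinct event time: (n at risk, n at risk in group A, total
    deaths, deaths in group A)."""
    event_times = np.unique(times[events])
    n_at_risk = (times[None, :] >= event_times[:, None]).sum(axis=1)
    in_a = group.astype(float)
    n_at_risk_a = ((times[None, :] >= event_times[:, None]) * in_a[None, :]).sum(axis=1)
    is_event_at = (times[None, :] == event_times[:, None]) & events[None, :]
    deaths = is_event_at.sum(axis=1)
    deaths_a = (is_event_at * in_a[None, :]).sum(axis=1)
    return n_at_risk, n_at_risk_a, deaths, deaths_a


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p), df=1.

    With no events at all the test carries no information: returns
    (0, 1) with a logged warning.
    """
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a, bool)
    events_b = np.asarray(events_b, bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.ones(len(times_a)), np.zeros(len(times_b))]).astype(bool)
    return _logrank_pooled(times, events, group)


def _logrank_pooled(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    if not events.any():
        logger.warning("log-rank with zero events: returning p = 1")
        return 0.0, 1.0
    n, na, d, da = _risk_table(times, events, group)
    expected = d * na / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (na / n) * (1 - na / n) * (n - d) / np.maximum(n - 1, 1)
    observed_minus_expected = (da - expected).sum()
    variance = var.sum()
    if variance <= 0:
        return 0.0, 1.0
    chi2 = observed_minus_expected**2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_score_test(
    times: Sequence[float], events: Sequence[bool], covariate: Sequence[float]
) -> tuple[float, float]:
    """Cox partial-likelihood score test at beta = 0 (Efron ties).

    Independent of :func:`logrank`: the statistic is U(0)^2 / I(0) computed
    from the Efron partial likelihood's analytic first and second
    derivatives.  On a binary covariate it coincides with the log-rank test.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(covariate, float)
    score = 0.0
    information = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        dead = (times == t) & events
        d = int(dead.sum())
        x_risk = x[at_risk]
        x_dead = x[dead]
        sum_risk = x_risk.sum()
        sum_sq_risk = (x_risk**2).sum()
        n_risk = at_risk.sum()
        sum_dead = x_dead.sum()
        sum_sq_dead = (x_dead**2).sum()
        for l in range(d):  # Efron: interpolate the tied deaths out of the risk set
            frac = l / d
            denom = n_risk - frac * d
            mean = (sum_risk - frac * sum_dead) / denom
            mean_sq = (sum_sq_risk - frac * sum_sq_dead) / denom
            score += sum_dead / d - mean
            information += mean_sq - mean**2
    if information <= 0:
        return 0.0, 1.0
    chi2 = score**2 / information
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs.

    Constant covariates are rejected; non-convergence is flagged on the
    returned fit rather than silently reported.
    """
    covariates = covariates.reset_index(drop=True)
    for column in covariates.columns:
        if covariates[column].nunique() < 2:
            raise ValueError(f"covariate {column!r} is constant")
    frame = covariates.copy()
    frame["_time"] = np.asarray(times, float)
    frame["_event"] = np.asarray(events, bool).astype(int)
    if frame["_event"].sum() < len(covariates.columns):
        raise ValueError("fewer events than covariates")
    fitter = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fitter.fit(frame, duration_col="_time", event_col="_event")
        except Exception as err:  # convergence failure / separation
            logger.warning("Cox fit failed to converge: %s", err)
            fitter = CoxPHFitter(penalizer=0.1)
            fitter.fit(frame, duration_col="_time", event_col="_event")
            converged = False
    summary = fitter.summary
    with np.errstate(over="ignore"):  # separated fits can push coef -> inf
        table = pd.DataFrame(
            {
                "covariate": summary.index,
                "hr": np.exp(summary["coef"]).to_numpy(),
                "ci_low": np.exp(summary["coef lower 95%"]).to_numpy(),
                "ci_high": np.exp(summary["coef upper 95%"]).to_numpy(),
                "p": summary["p"].to_numpy(),
            }
        ).reset_index(drop=True)
    return CoxFit(table=table, converged=converged)


_TNM_COMPONENTS = ("depth_T", "node_N", "metastasis_M")


def prognostic_workflow(
    factors: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    alpha: float = 0.05,
) -> CoxFit:
    """Univariate screen (p < alpha) followed by a multivariate Cox model.

    ``factors`` columns must be numeric (binary indicators for categorical
    factors).  Individual T/N/M component factors are excluded from the
    multivariate model whenever composite ``stage`` passes the screen, to
    avoid refitting the stage's own components alongside it.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    trace: list[str] = []
    survivors: list[str] = []
    for column in factors.columns:
        x = factors[column].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            trace.append(f"{column}: constant, skipped")
            continue
        if set(np.unique(x)) <= {0.0, 1.0}:
            chi2, p = _logrank_pooled(times, events, x.astype(bool))
            test = "logrank"
        else:
            fit = cox_fit(times, events, factors[[column]])
            p = fit.p(column)
            test = "cox"
        if p < alpha:
            survivors.append(column)
            trace.append(f"{column}: univariate {test} p={p:.4g} < {alpha}, kept")
        else:
            trace.append(f"{column}: univariate {test} p={p:.4g} >= {alpha}, dropped")
    if "stage" in survivors:
        for component in _TNM_COMPONENTS:
            if component in survivors:
                survivors.remove(component)
                trace.append(f"{component}: excluded (composite stage retained)")
    if not survivors:
        trace.append("no factor passed the univariate screen; report only")
        return CoxFit(
            table=pd.DataFrame(columns=["covariate", "hr", "ci_low", "ci_high", "p"]),
            converged=True,
            selection_trace=trace,
        )
    fit = cox_fit(times, events, factors[survivors])
    fit.selection_trace = trace
    return fit
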