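"""Cut-off discovery: ROC/Youden, minimum-p log-rank, minimum-p t-test.

Conventions shared by all three procedures:

* candidate thresholds are the unique observed values (the published
  thresholds look like observed measurements, not midpoints);
* a value >= theta is a positive call, matching the scoring rule "equal to
  or higher than the cut-off scores 1 point";
* ties in the objective break toward the larger theta (higher specificity).

The minimum-p scans perform no multiple-testing correction by default —
faithful to common practice, and known to be anti-conservative; an optional
permutation-adjusted p is available and a warning is logged once per scan.
"""
from __future__ import annotations

import dataclasses
import enum
import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .survival_stats import _logrank_pooled, cox_fit

logger = logging.getLogger(__name__)


class CutoffPurpose(str, enum.Enum):
    DIAGNOSTIC = "DIAGNOSTIC"
    SURVIVAL_OS = "SURVIVAL_OS"
    SURVIVAL_RFS = "SURVIVAL_RFS"
    TERM_SPLIT = "TERM_SPLIT"


@dataclasses.dataclass
class CutoffResult:
    """A gene's discovered threshold together with how it was found."""

    gene: str | None
    purpose: CutoffPurpose
    found: bool
    threshold: float | None = None
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    scan_p: float | None = None
    scan_p_adjusted: float | None = None
    relative_risk: float | None = None
    group_high: dict | None = None  # n/mean/sd of the >= theta group
    group_low: dict | None = None


def roc_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney all-pairs identity,
    ties counted 1/2."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _sens_spec(pos: np.ndarray, neg: np.ndarray, theta: float) -> tuple[float, float]:
    sens = float((pos >= theta).mean())
    spec = float((neg < theta).mean())
    return sens, spec


def youden_cutoff(
    pos: Sequence[float], neg: Sequence[float], gene: str | None = None
) -> CutoffResult:
    """ROC-optimal diagnostic threshold maximizing Youden J = sens + spec - 1.

    Candidates are the unique observed values of both classes; ties in J
    break toward the larger threshold.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    candidates = np.unique(np.concatenate([pos, neg]))
    best_theta, best_j, best = None, -math.inf, (None, None)
    for theta in candidates:  # ascending, so >= keeps the largest tied theta
        sens, spec = _sens_spec(pos, neg, theta)
        j = sens + spec - 1.0
        if j >= best_j:
            best_theta, best_j, best = float(theta), j, (sens, spec)
    return CutoffResult(
        gene=gene,
        purpose=CutoffPurpose.DIAGNOSTIC,
        found=True,
        threshold=best_theta,
        auc=roc_auc(pos, neg),
        sensitivity=best[0],
        specificity=best[1],
    )


def proportion_above(values: Sequence[float], theta: float) -> float:
    """Percent of values >= theta, rounded to one decimal
    (half away from zero)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    from .risk_score import round_percent

    return round_percent(100.0 * float((values >= theta).sum()) / len(values))


def _eligible_candidates(
    values: np.ndarray, min_group_frac: float
) -> list[float]:
    """Unique observed thresholds leaving both split groups with at least
    ceil(min_group_frac * n) members."""
    n = len(values)
    min_size = math.ceil(min_group_frac * n)
    eligible = []
    for theta in np.unique(values):
        n_high = int((values >= theta).sum())
        if n_high >= min_size and (n - n_high) >= min_size:
            eligible.append(float(theta))
    return eligible


def minp_logrank_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
    min_group_frac: float = 0.1,
    alpha: float = 0.05,
    purpose: CutoffPurpose = CutoffPurpose.SURVIVAL_OS,
    gene: str | None = None,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutoffResult:
    """Survival cut-point by minimum-p log-rank scan.

    Scans eligible observed thresholds, splits at value >= theta, and keeps
    the split with the smallest log-rank p.  ``found`` is False when no
    eligible threshold reaches p < alpha ("no optimal cut-off obtained").
    The relative risk is the univariate Cox hazard ratio of the >=-theta
    indicator at the selected threshold.  ``n_permutations > 0`` adds a
    permutation-adjusted p for the selection-inflated minimum.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not (len(values) == len(times) == len(events)):
        raise ValueError("values, times and events must be aligned")
    if not events.any():
        raise ValueError("no events observed; survival scan is undefined")
    if not 0 < min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in (0, 0.5)")
    logger.warning(
        "minimum-p log-rank scan: the selected p-value is anti-conservative "
        "(no multiplicity correction by default)"
    )
    best = _scan_minimum_p(
        values, _eligible_candidates(values, min_group_frac),
        lambda theta: _logrank_pooled(times, events, values >= theta)[1],
    )
    if best is None:
        return CutoffResult(gene=gene, purpose=purpose, found=False)
    theta, p = best
    if p >= alpha:
        return CutoffResult(gene=gene, purpose=purpose, found=False, scan_p=p)
    indicator = (values >= theta).astype(float)
    import pandas as pd

    try:
        fit = cox_fit(times, events, pd.DataFrame({"high": indicator}))
        relative_risk = fit.hr("high")
    except Exception:
        relative_risk = None
    result = CutoffResult(
        gene=gene,
        purpose=purpose,
        found=True,
        threshold=theta,
        scan_p=p,
        relative_risk=relative_risk,
    )
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)
        result.scan_p_adjusted = _permutation_adjust(
            p,
            n_permutations,
            lambda perm: _best_p(
                values,
                _eligible_candidates(values, min_group_frac),
                lambda theta: _logrank_pooled(times[perm], events[perm], values >= theta)[1],
            ),
            len(values),
            rng,
        )
    return result


def minp_ttest_cutoff(
    values: Sequence[float],
    terms: Sequence[float],
    min_group_frac: float = 0.1,
    gene: str | None = None,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutoffResult:
    """Time-to-onset cut-point by minimum-p pooled t-test scan.

    For each eligible threshold the onset terms of the >=-theta group are
    compared with the <-theta group by a two-sided pooled-variance Student
    t-test; the threshold minimizing p is returned with the two groups'
    summaries.  Sensitivity/specificity are reported descriptively against
    the label "term <= cohort median term", calling value >= theta positive.
    """
    values = np.asarray(values, dtype=float)
    terms = np.asarray(terms, dtype=float)
    if len(values) != len(terms):
        raise ValueError("values and terms must be aligned")
    if len(values) < 4:
        raise ValueError("need n >= 4")
    if np.ptp(values) == 0:
        return CutoffResult(gene=gene, purpose=CutoffPurpose.TERM_SPLIT, found=False)
    logger.warning(
        "minimum-p t-test scan: the selected p-value is anti-conservative "
        "(no multiplicity correction by default)"
    )

    def split_p(theta: float) -> float:
        high = terms[values >= theta]
        low = terms[values < theta]
        if len(high) < 2 or len(low) < 2:
            return 1.0
        if np.ptp(high) == 0 and np.ptp(low) == 0:
            return 1.0 if high.mean() == low.mean() else 0.0
        t, p = stats.ttest_ind(high, low, equal_var=True)
        return float(p)

    best = _scan_minimum_p(
        values, _eligible_candidates(values, min_group_frac), split_p
    )
    if best is None:
        return CutoffResult(gene=gene, purpose=CutoffPurpose.TERM_SPLIT, found=False)
    theta, p = best
    high = terms[values >= theta]
    low = terms[values < theta]
    short_term = terms <= np.median(terms)
    sens = float(((values >= theta) & short_term).sum() / max(short_term.sum(), 1))
    spec = float(((values < theta) & ~short_term).sum() / max((~short_term).sum(), 1))
    result = CutoffResult(
        gene=gene,
        purpose=CutoffPurpose.TERM_SPLIT,
        found=True,
        threshold=theta,
        scan_p=p,
        sensitivity=sens,
        specificity=spec,
        group_high={"n": len(high), "mean": float(high.mean()),
                    "sd": float(high.std(ddof=1))},
        group_low={"n": len(low), "mean": float(low.mean()),
                   "sd": float(low.std(ddof=1))},
    )
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)

        def split_p_perm(theta: float, perm: np.ndarray) -> float:
            permuted = terms[perm]
            high = permuted[values >= theta]
            low = permuted[values < theta]
            if len(high) < 2 or len(low) < 2:
                return 1.0
            return float(stats.ttest_ind(high, low, equal_var=True)[1])

        result.scan_p_adjusted = _permutation_adjust(
            p,
            n_permutations,
            lambda perm: _best_p(
                values,
                _eligible_candidates(values, min_group_frac),
                lambda theta: split_p_perm(theta, perm),
            ),
            len(values),
            rng,
        )

    return result


def _scan_minimum_p(values, candidates, p_of_theta) -> tuple[float, float] | None:
    best = None
    for theta in candidates:  # ascending: >= keeps the largest theta on ties
        p = p_of_theta(theta)
        if best is None or p <= best[1]:
            best = (float(theta), float(p))
    return best


def _best_p(values, candidates, p_of_theta) -> float:
    best = _scan_minimum_p(values, candidates, p_of_theta)
    return 1.0 if best is None else best[1]


def _permutation_adjust(observed_p, n_permutations, best_p_of_perm, n, rng) -> float:
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if best_p_of_perm(perm) <= observed_p:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
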