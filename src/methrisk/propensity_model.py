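"""Logistic propensity model for the initial diagnosis.

The fitted probability of an initially malignant diagnosis — from
remnant-mucosa methylation alone, or together with age, sex and the months
from initial surgery to RGC onset — is used purely as a discrimination
summary: its in-sample (apparent) ROC AUC, and a pooled t comparison of the
scores between the diagnosis groups.  The apparent AUC mirrors the
original single-sample design (no validation split); a k-fold
cross-validated AUC is emitted alongside as an honesty check.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cutoff_finder import roc_auc
from .inference_stats import student_t

MAX_ABS_COEF = 30.0  # |coef| beyond this on standardized-scale data flags separation


@dataclasses.dataclass
class PropensityFit:
    covariates: tuple[str, ...]
    coefficients: pd.Series
    scores: np.ndarray
    auc: float
    group_p: float
    converged: bool
    separation: bool
    cv_auc: float | None = None


def fit_propensity(
    covariates: pd.DataFrame,
    labels: Sequence[int],
    cross_validate: int = 0,
    seed: int = 0,
) -> PropensityFit:
    """Maximum-likelihood logistic fit (unregularized) of label on covariates.

    Complete separation is detected and flagged; scores then come from the
    iteration-capped fit.  ``cross_validate=k`` adds a stratified k-fold
    out-of-sample AUC.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if len(covariates) <= covariates.shape[1]:
        raise ValueError("need more observations than covariates")
    x = sm.add_constant(covariates.astype(float), has_constant="add")
    scores, params, converged, separation = _fit_scores(x, labels)
    auc = roc_auc(scores[labels == 1], scores[labels == 0])
    if np.ptp(scores) == 0:
        group_p = 1.0
    else:
        _, _, group_p = student_t(scores[labels == 1], scores[labels == 0])
    cv_auc = None
    if cross_validate > 1:
        cv_auc = _cv_auc(x, labels, cross_validate, seed)
    return PropensityFit(
        covariates=tuple(covariates.columns),
        coefficients=params,
        scores=scores,
        auc=auc,
        group_p=group_p,
        converged=converged,
        separation=separation,
        cv_auc=cv_auc,
    )


def compare_scores(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Two-sided pooled-t p for score differences between the two classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if np.ptp(scores) == 0:
        warnings.warn("degenerate scores (all equal): p = 1")
        return 1.0
    _, _, p = student_t(scores[labels == 1], scores[labels == 0])
    return p


def replicate_auc_study(
    n_cohorts: int,
    base_seed: int = 1,
    model: str = "genes+clinical",
) -> np.ndarray:
    """In-sample AUC of the propensity model over repeated synthetic cohorts.

    Each replicate draws a fresh default cohort (35 malignant / 23 benign,
    printed term distributions, pooled remnant-mucosa methylation margins),
    fits the unregularized logistic model — remnant-mucosa gene values
    alone (``model="genes"``) or together with age, sex and term
    (``model="genes+clinical"``) — and records the apparent AUC.  Seeds run
    ``base_seed .. base_seed + n_cohorts - 1``.
    """
    from .cohort_io import GENES, Compartment, InitialDiagnosis
    from .synthetic_cohort import GeneratorConfig, generate_cohort

    if model not in ("genes", "genes+clinical"):
        raise ValueError("model must be 'genes' or 'genes+clinical'")
    aucs = np.empty(n_cohorts)
    for k in range(n_cohorts):
        config = GeneratorConfig(
            seed=base_seed + k, n_in_malignant=0, n_in_benign=0
        )
        patients, samples = generate_cohort(config)
        rn = {
            s.patient_id: s for s in samples if s.compartment is Compartment.RN
        }
        rows, labels = [], []
        for p in patients:
            sample = rn[p.patient_id]
            row = {g: sample.gene_values[g] for g in GENES}
            if model == "genes+clinical":
                row["age"] = p.age
                row["sex_male"] = int(p.sex == "M")
                row["term"] = p.term_to_rgc
            rows.append(row)
            labels.append(
                int(p.initial_diagnosis is InitialDiagnosis.MALIGNANT)
            )
        fit = fit_propensity(pd.DataFrame(rows), labels)
        aucs[k] = fit.auc
    return aucs


def _fit_scores(
    x: pd.DataFrame, labels: np.ndarray
) -> tuple[np.ndarray, pd.Series, bool, bool]:
    model = sm.Logit(labels, x)
    converged = True
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:  # PerfectSeparationError and friends
            separation = True
            fit = model.fit(disp=0, method="bfgs", maxiter=100, skip_hessian=True)
            converged = False
    scale = x.std(ddof=0).replace(0, 1.0)
    if (np.abs(fit.params * scale) > MAX_ABS_COEF).any():
        separation = True
    with np.errstate(over="ignore"):  # saturated logits under separation
        scores = np.asarray(fit.predict(x), dtype=float)
    return scores, fit.params, converged, separation


def _cv_auc(x: pd.DataFrame, labels: np.ndarray, k: int, seed: int) -> float:
    """Stratified k-fold out-of-sample AUC on pooled held-out scores."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    held_out = np.empty(len(labels), dtype=float)
    for fold in range(k):
        train = folds != fold
        test = ~train
        model = sm.Logit(labels[train], x.loc[train])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(disp=0, maxiter=200)
            except Exception:
                fit = model.fit(disp=0, method="bfgs", maxiter=100, skip_hessian=True)
            with np.errstate(over="ignore"):
                held_out[test] = np.asarray(fit.predict(x.loc[test]), dtype=float)
    return roc_auc(held_out[labels == 1], held_out[labels == 0])
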