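"""Association and comparison statistics shared across the analyses.

Conventions follow the source analyses: pooled-variance (not Welch)
Student t throughout — it is the form that reproduces the printed p-values
from group summaries; Pearson chi-squared without continuity correction;
Spearman rank correlation for gene-gene association because TaqMeth V is
zero-inflated and right-skewed.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Compartment, MethylationSample


@dataclasses.dataclass(frozen=True)
class SummaryGroup:
    """A group described only by its size, mean and SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("SummaryGroup requires n >= 2")
        if not self.sd > 0:
            raise ValueError("SummaryGroup requires sd > 0")


def student_t_from_summary(
    a: SummaryGroup | tuple, b: SummaryGroup | tuple
) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student t-test from group summaries.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    a = a if isinstance(a, SummaryGroup) else SummaryGroup(*a)
    b = b if isinstance(b, SummaryGroup) else SummaryGroup(*b)
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = math.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    if se == 0:
        return 0.0, df, 1.0
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


def student_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pooled-variance Student t on raw samples (ddof-1 summaries)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 and sy == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf
        return t, len(x) + len(y) - 2, 1.0 if t == 0 else 0.0
    df = len(x) + len(y) - 2
    pooled_var = ((len(x) - 1) * sx**2 + (len(y) - 1) * sy**2) / df
    se = math.sqrt(pooled_var * (1.0 / len(x) + 1.0 / len(y)))
    t = (x.mean() - y.mean()) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def anova_tukey(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with all-pairs Tukey HSD.

    Returns (F, p, tukey) where ``tukey`` is a DataFrame with columns
    (group_i, group_j, p_adj).  Accepts 2+ groups (with 2 groups the F test
    coincides with the squared pooled t).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("every group needs n >= 2")
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if math.isnan(f_stat):  # zero within-group variance everywhere
            f_stat, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {"group_i": i, "group_j": j, "p_adj": float(hsd.pvalue[i, j])}
            )
    return float(f_stat), float(p), pd.DataFrame(rows)


def chi_squared(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("chi_squared expects a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi_squared requires non-zero margins")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def linear_r2(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, float]:
    """OLS of y on x: returns (r_squared, slope_sign, p_slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    fit = stats.linregress(x, y)
    sign = int(np.sign(fit.slope))
    return float(fit.rvalue**2), sign, float(fit.pvalue)


def pairwise_correlation(
    samples: Iterable[MethylationSample],
    genes: Sequence[str],
    compartment: Compartment | str,
) -> pd.DataFrame:
    """Spearman correlation per gene pair within one tissue compartment.

    Pairwise-complete: a pair uses only samples where both genes were
    measured; fewer than 3 complete pairs leaves the entry missing (NaN).
    """
    compartment = Compartment(compartment)
    columns: dict[str, list[float]] = {g: [] for g in genes}
    for sample in samples:
        if sample.compartment is not compartment:
            continue
        for g in genes:
            value = sample.value(g)
            columns[g].append(math.nan if value is None else value)
    frame = pd.DataFrame(columns)
    rows = []
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            pair = frame[[gi, gj]].dropna()
            if len(pair) < 3:
                rho, p = math.nan, math.nan
            else:
                rho, p = stats.spearmanr(pair[gi], pair[gj])
            rows.append(
                {
                    "compartment": compartment.value,
                    "gene_a": gi,
                    "gene_b": gj,
                    "n": len(pair),
                    "spearman_rho": float(rho) if rho == rho else math.nan,
                    "p_value": float(p) if p == p else math.nan,
                }
            )
    return pd.DataFrame(rows)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (supplementary output only)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def association_table(
    values_by_factor: Mapping[str, Mapping[str, Sequence[float]]],
) -> pd.DataFrame:
    """Per-factor association p-values, in the style of a clinicopathological
    factor table.

    ``values_by_factor`` maps factor name -> level -> measured values; a
    2-level factor gets a pooled Student t, 3+ levels one-way ANOVA.  A BH
    FDR column is appended as supplementary output.
    """
    rows = []
    for factor, level_map in values_by_factor.items():
        groups = [np.asarray(v, float) for v in level_map.values() if len(v) >= 2]
        if len(groups) < 2:
            rows.append({"factor": factor, "test": "NA", "p_value": math.nan})
            continue
        if len(groups) == 2:
            _, _, p = student_t(groups[0], groups[1])
            test = "student_t"
        else:
            _, p, _ = anova_tukey(groups)
            test = "anova"
        rows.append({"factor": factor, "test": test, "p_value": p})
    frame = pd.DataFrame(rows)
    mask = frame["p_value"].notna()
    frame["p_bh_fdr"] = math.nan
    if mask.any():
        frame.loc[mask, "p_bh_fdr"] = bh_fdr(frame.loc[mask, "p_value"].to_numpy())
    return frame
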