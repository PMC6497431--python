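"""The 0-4 methylation risk score and its evaluation.

Each gene contributes one binary point: TaqMeth V below the gene's cut-off
scores 0, equal to or above it scores 1.  The total over the scored gene
subset is the methylation risk score.  A missing measurement propagates as
MISSING — never as 0 — and makes the total a lower bound; incomplete panels
are excluded from score distributions rather than zero-filled, because
zero-filling would deflate scores asymmetrically.
"""
from __future__ import annotations

import dataclasses
import decimal
import itertools
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import GENES, MethylationSample
from .inference_stats import anova_tukey, student_t

logger = logging.getLogger(__name__)

MISSING = "MISSING"

#: the trio whose methylation tracks time-to-onset most strongly
TRIO = ("CDO1", "HOPX", "Reprimo")


def round_percent(x: float) -> float:
    """One-decimal percent, half rounded away from zero (77.15 -> 77.2)."""
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclasses.dataclass
class RiskScore:
    """Per-gene points and their sum for one specimen."""

    patient_id: str
    points: dict[str, object]  # gene -> 0 | 1 | MISSING
    total: int
    complete: bool

    def __post_init__(self) -> None:
        numeric = [p for p in self.points.values() if p != MISSING]
        if self.total != sum(numeric):
            raise ValueError("total must equal the sum of non-missing points")


@dataclasses.dataclass
class SplitComparison:
    """One row of a subset x split evaluation of the score against terms."""

    genes: tuple[str, ...]
    split: str
    group_sizes: tuple[int, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    p_value: float | None
    test: str
    evaluable: bool = True


def gene_point(value: float | None, theta: float):
    """1 iff value >= theta; a missing value propagates as MISSING."""
    if theta <= 0:
        raise ValueError("cut-off must be > 0")
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING
    if value < 0:
        raise ValueError("TaqMeth V must be >= 0")
    return 1 if value >= theta else 0


def total_score(
    sample: MethylationSample,
    cutoffs: Mapping[str, float],
    genes: Sequence[str] = GENES,
) -> RiskScore:
    """Sum the per-gene points of ``sample`` over the requested gene subset."""
    unknown = set(genes) - set(GENES)
    if unknown:
        raise ValueError(f"unknown genes {sorted(unknown)}")
    missing_cutoffs = [g for g in genes if g not in cutoffs]
    if missing_cutoffs:
        raise ValueError(f"no cut-off provided for {missing_cutoffs}")
    points = {g: gene_point(sample.value(g), cutoffs[g]) for g in genes}
    numeric = [p for p in points.values() if p != MISSING]
    return RiskScore(
        patient_id=sample.patient_id,
        points=points,
        total=int(sum(numeric)),
        complete=len(numeric) == len(genes),
    )


def score_distribution(scores: Sequence[RiskScore], k: int) -> pd.DataFrame:
    """Counts, one-decimal percents and cumulative >=s fractions per score.

    Incomplete scores are excluded (with a logged count); an empty list
    after exclusion is an error.
    """
    complete = [s for s in scores if s.complete]
    excluded = len(scores) - len(complete)
    if excluded:
        logger.info("score_distribution: excluded %d incomplete panels", excluded)
    if not complete:
        raise ValueError("no complete scores to summarize")
    totals = np.array([s.total for s in complete])
    if (totals > k).any():
        raise ValueError("a score exceeds the declared maximum k")
    n = len(totals)
    rows = []
    for s in range(k + 1):
        count = int((totals == s).sum())
        rows.append(
            {
                "score": s,
                "count": count,
                "percent": round_percent(100.0 * count / n),
                "frac_ge": float((totals >= s).sum() / n),
                "percent_ge": round_percent(100.0 * (totals >= s).sum() / n),
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["n"] = n
    frame.attrs["excluded"] = excluded
    return frame


def _parse_split(split: str, k: int) -> list[tuple[int, int]] | None:
    """Parse a split label like "0-1 vs 2-4" or "0,1,2" into score ranges.

    Returns a list of inclusive (lo, hi) ranges, or None for the all-levels
    (one group per score) grouping.
    """
    if "vs" not in split:
        return None
    ranges = []
    for part in split.split("vs"):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(part), int(part)))
    return ranges


def standard_splits(k: int) -> list[str]:
    """The canonical split ladder for a k-gene subset: the all-levels
    grouping plus every contiguous binary split."""
    labels = [",".join(str(s) for s in range(k + 1))]
    for cut in range(k):
        left = str(cut) if cut == 0 else f"0-{cut}"
        right = str(cut + 1) if cut + 1 == k else f"{cut + 1}-{k}"
        labels.append(f"{left} vs {right}")
    return labels


def enumerate_combinations(
    samples: Sequence[MethylationSample],
    terms: Sequence[float],
    cutoffs: Mapping[str, float],
    subsets: Sequence[Sequence[str]] | None = None,
    splits_by_k: Mapping[int, Sequence[str]] | None = None,
) -> list[SplitComparison]:
    """Evaluate score-vs-term comparisons over gene subsets and splits.

    Default subsets: the three pairs of the trio, the trio itself, and all
    four genes.  Binary splits are tested with a pooled Student t; the
    all-levels grouping with one-way ANOVA.  A split producing an empty (or
    single-member) group is reported as not evaluable rather than an error.
    """
    if len(samples) != len(terms):
        raise ValueError("samples and terms must be aligned")
    if subsets is None:
        subsets = [list(pair) for pair in itertools.combinations(TRIO, 2)]
        subsets.append(list(TRIO))
        subsets.append(list(GENES))
    results: list[SplitComparison] = []
    terms = np.asarray(terms, dtype=float)
    for subset in subsets:
        k = len(subset)
        scores = [total_score(s, cutoffs, subset) for s in samples]
        keep = np.array([s.complete for s in scores])
        totals = np.array([s.total for s in scores])[keep]
        subset_terms = terms[keep]
        labels = (
            splits_by_k[k] if splits_by_k is not None else standard_splits(k)
        )
        for label in labels:
            ranges = _parse_split(label, k)
            if ranges is None:
                groups = [subset_terms[totals == s] for s in range(k + 1)]
                test = "anova"
            else:
                groups = [
                    subset_terms[(totals >= lo) & (totals <= hi)]
                    for lo, hi in ranges
                ]
                test = "student_t"
            if any(len(g) < 2 for g in groups):
                results.append(
                    SplitComparison(
                        genes=tuple(subset),
                        split=label,
                        group_sizes=tuple(len(g) for g in groups),
                        group_means=(),
                        group_sds=(),
                        p_value=None,
                        test=test,
                        evaluable=False,
                    )
                )
                continue
            if all(np.ptp(g) == 0 for g in groups) and len(
                {g[0] for g in groups}
            ) == 1:
                p = 1.0
            elif test == "anova":
                _, p, _ = anova_tukey(groups)
            else:
                _, _, p = student_t(groups[0], groups[1])
            results.append(
                SplitComparison(
                    genes=tuple(subset),
                    split=label,
                    group_sizes=tuple(len(g) for g in groups),
                    group_means=tuple(float(g.mean()) for g in groups),
                    group_sds=tuple(float(g.std(ddof=1)) for g in groups),
                    p_value=float(p),
                    test=test,
                )
            )
    return results


def split_table(results: Sequence[SplitComparison]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "genes": "+".join(r.genes),
                "split": r.split,
                "test": r.test,
                "evaluable": r.evaluable,
                "group_sizes": "/".join(str(n) for n in r.group_sizes),
                "group_means": "/".join(f"{m:.6g}" for m in r.group_means),
                "p_value": r.p_value if r.p_value is not None else math.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genes", "split", "test", "evaluable",
            "group_sizes", "group_means", "p_value",
        ],
    )
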