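#!/usr/bin/env python
"""Predicting how soon remnant cancer develops: biopsy cut-offs and the
0-4 methylation risk score.

Regresses each gene's biopsy TaqMeth V on the remaining time to onset,
scans for the minimum-p t-test threshold splitting short- from long-term
developers, evaluates every gene-subset/score-split combination, and
applies the published cut-offs as the scoring rule to the remnant-mucosa
specimens of both diagnosis groups.
"""
import logging
import pathlib
import sys

import numpy as np
import pandas as pd

from methrisk.cohort_io import (
    Compartment,
    InitialDiagnosis,
    read_measurements,
    read_patients,
    write_table,
)
from methrisk.cutoff_finder import minp_ttest_cutoff
from methrisk.inference_stats import linear_r2
from methrisk.pipeline import PUBLISHED_TERM_CUTOFFS
from methrisk.risk_score import enumerate_combinations, score_distribution, split_table, total_score

logging.getLogger("methrisk").setLevel(logging.ERROR)
COHORT = pathlib.Path("results/cohort")
GENES = ("CDO1", "HOPX", "Reprimo", "ECAD")


def main() -> None:
    if not COHORT.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    patients = {p.patient_id: p for p in read_patients(COHORT / "patients.tsv")}
    samples = read_measurements(COHORT / "measurements.tsv")
    biopsies = [s for s in samples if s.compartment is Compartment.BIOPSY]
    # "time to development": the biopsy's lead time before cancer onset
    terms = [s.months_before_onset for s in biopsies]

    rows = []
    for gene in GENES:
        values = np.array([s.value(gene) for s in biopsies])
        r2, sign, p_slope = linear_r2(terms, values)
        scan = minp_ttest_cutoff(values, np.asarray(terms), gene=gene)
        rows.append({
            "gene": gene, "r2_vs_term": r2, "slope_sign": sign,
            "p_slope": p_slope, "threshold": scan.threshold,
            "scan_p": scan.scan_p, "sensitivity": scan.sensitivity,
            "specificity": scan.specificity,
        })
    biopsy_table = pd.DataFrame(rows)
    write_table(biopsy_table, pathlib.Path("results/term_cutoffs.tsv"))
    print("biopsy term cut-offs -> results/term_cutoffs.tsv")
    print(biopsy_table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    splits = enumerate_combinations(biopsies, terms, PUBLISHED_TERM_CUTOFFS)
    write_table(split_table(splits), pathlib.Path("results/score_splits.tsv"))
    best = min((r for r in splits if r.evaluable), key=lambda r: r.p_value)
    print(f"best split: {'+'.join(best.genes)} {best.split} "
          f"(p = {best.p_value:.2g})")

    print("risk score on remnant mucosa (published cut-offs):")
    for diagnosis in (InitialDiagnosis.MALIGNANT, InitialDiagnosis.BENIGN):
        scores = [
            total_score(s, PUBLISHED_TERM_CUTOFFS)
            for s in samples
            if s.compartment is Compartment.RN
            and patients[s.patient_id].initial_diagnosis is diagnosis
        ]
        frame = score_distribution(scores, k=4)
        ge2 = frame.loc[frame["score"] == 2, "percent_ge"].item()
        name = diagnosis.value.lower()
        write_table(frame, pathlib.Path(f"results/score_distribution_{name}.tsv"))
        print(f"  {name}-initial: {ge2:.1f}% of patients score >= 2")


if __name__ == "__main__":
    main()
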