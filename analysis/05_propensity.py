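#!/usr/bin/env python
"""Can remnant-mucosa methylation recognise the initial diagnosis?

Fits the logistic propensity model for an initially malignant diagnosis
from the four RN TaqMeth Vs alone, then with age, sex and the term to
onset added, reporting apparent and cross-validated AUC; finally replicates
the 7-covariate apparent AUC over 200 fresh synthetic cohorts.
"""
import pathlib
import sys

import numpy as np
import pandas as pd

from methrisk.cohort_io import Compartment, InitialDiagnosis, read_measurements, read_patients, write_table
from methrisk.propensity_model import fit_propensity, replicate_auc_study

COHORT = pathlib.Path("results/cohort")
GENES = ("CDO1", "HOPX", "Reprimo", "ECAD")


def main() -> None:
    if not COHORT.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    patients = read_patients(COHORT / "patients.tsv")
    rn = {
        s.patient_id: s
        for s in read_measurements(COHORT / "measurements.tsv")
        if s.compartment is Compartment.RN
    }
    frame = pd.DataFrame([
        {
            **{g: rn[p.patient_id].value(g) for g in GENES},
            "age": p.age,
            "sex_male": int(p.sex == "M"),
            "term": p.term_to_rgc,
        }
        for p in patients
    ])
    labels = np.array([
        int(p.initial_diagnosis is InitialDiagnosis.MALIGNANT) for p in patients
    ])

    gene_fit = fit_propensity(frame[list(GENES)], labels, cross_validate=5, seed=0)
    full_fit = fit_propensity(frame, labels, cross_validate=5, seed=0)
    table = pd.DataFrame([
        {"model": "genes", "auc_apparent": gene_fit.auc,
         "auc_cv5": gene_fit.cv_auc, "group_p": gene_fit.group_p},
        {"model": "genes+clinical", "auc_apparent": full_fit.auc,
         "auc_cv5": full_fit.cv_auc, "group_p": full_fit.group_p},
    ])
    write_table(table, pathlib.Path("results/propensity.tsv"))
    print("propensity discrimination -> results/propensity.tsv")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    aucs = replicate_auc_study(200, base_seed=1)
    print(f"replicated 7-covariate apparent AUC over 200 cohorts: "
          f"median {np.median(aucs):.3f} (IQR {np.quantile(aucs, .25):.3f}-"
          f"{np.quantile(aucs, .75):.3f})")
    print("methylation alone discriminates weakly; adding age, sex and the "
          "term to onset makes the groups nearly separable in-sample.")


if __name__ == "__main__":
    main()
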