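"""End-to-end orchestration: simulate/load -> cut-offs -> score ->
associations -> survival -> propensity, with a provenance manifest.

Every stage writes a plain TSV under the configured output directory and
records its SHA-256 digest in ``manifest.json``, so a run is byte-for-byte
reproducible from (config, seed) and any stage can be re-run in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import (
    Compartment,
    InitialDiagnosis,
    MethylationSample,
    PatientRecord,
    RunConfig,
    config_digest,
    read_measurements,
    read_patients,
    samples_by_compartment,
    write_measurements,
    write_patients,
    write_table,
)
from .cutoff_finder import (
    CutoffPurpose,
    minp_logrank_cutoff,
    minp_ttest_cutoff,
    proportion_above,
    youden_cutoff,
)
from .inference_stats import anova_tukey, pairwise_correlation
from .propensity_model import fit_propensity
from .risk_score import (
    RiskScore,
    enumerate_combinations,
    score_distribution,
    split_table,
    total_score,
)
from .survival_stats import prognostic_workflow
from .synthetic_cohort import (
    GeneratorConfig,
    generate_biopsy_series,
    generate_cohort,
)

logger = logging.getLogger(__name__)

#: the published cut-offs, injectable via reproduce_published_mode
PUBLISHED_DIAGNOSTIC_CUTOFFS = {
    "CDO1": 6.49, "HOPX": 4.14, "Reprimo": 2.59, "ECAD": 1.09,
}
PUBLISHED_TERM_CUTOFFS = {
    "CDO1": 1.2, "HOPX": 0.60, "Reprimo": 0.15, "ECAD": 0.07,
}


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    version: str
    file_digests: dict[str, str]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_simulate(
    config: RunConfig,
) -> tuple[list[PatientRecord], list[MethylationSample], list[str]]:
    warnings: list[str] = []
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed if config.seed is not None else 0)
        gen_config = GeneratorConfig(**sim_kwargs)
        patients, samples = generate_cohort(gen_config)
        samples = samples + generate_biopsy_series(patients, gen_config)
        logger.info("simulated cohort: %d patients, %d samples",
                    len(patients), len(samples))
        return patients, samples, warnings
    if not config.patients_path or not config.measurements_path:
        raise ValueError(
            "config must provide either a simulate block or both "
            "patients_path and measurements_path"
        )
    patients = read_patients(config.patients_path)
    samples = read_measurements(config.measurements_path)
    return patients, samples, warnings


def _gene_vector(
    samples: Sequence[MethylationSample], gene: str
) -> tuple[list[str], np.ndarray]:
    ids, values = [], []
    for s in samples:
        value = s.value(gene)
        if value is not None:
            ids.append(s.patient_id)
            values.append(value)
    return ids, np.asarray(values)


def run_full(config: RunConfig) -> RunManifest:
    """Run every analysis stage and write the report directory.

    Stages (mirroring the published analysis order): diagnostic cut-offs on
    tumor vs remnant mucosa, compartment ANOVA, gene-gene correlations,
    prognostic cut-offs + univariate->multivariate Cox, propensity
    discrimination of the initial diagnosis, biopsy term cut-offs and the
    0-4 risk score.
    """
    out_dir = pathlib.Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []
    patients, samples, stage_warnings = _load_or_simulate(config)
    run_warnings.extend(stage_warnings)
    written: dict[str, pathlib.Path] = {}
    written["patients"] = write_patients(patients, out_dir / "patients.tsv")
    written["measurements"] = write_measurements(
        samples, out_dir / "measurements.tsv"
    )
    by_id = {p.patient_id: p for p in patients}
    rt = samples_by_compartment(samples, Compartment.RT)
    rn = samples_by_compartment(samples, Compartment.RN)
    biopsies = samples_by_compartment(samples, Compartment.BIOPSY)

    # --- stage 1: diagnostic cut-offs (tumor vs remnant mucosa) ----------
    diag_rows = []
    diag_cutoffs: dict[str, float] = {}
    overrides = config.cutoff_overrides.get("diagnostic", {})
    for gene in config.genes:
        _, pos = _gene_vector(rt, gene)
        _, neg = _gene_vector(rn, gene)
        if gene in overrides:
            theta = overrides[gene]
            from .cutoff_finder import CutoffResult, roc_auc, _sens_spec

            sens, spec = _sens_spec(pos, neg, theta)
            result = CutoffResult(
                gene=gene, purpose=CutoffPurpose.DIAGNOSTIC, found=True,
                threshold=theta, auc=roc_auc(pos, neg),
                sensitivity=sens, specificity=spec,
            )
        else:
            result = youden_cutoff(pos, neg, gene=gene)
        diag_cutoffs[gene] = result.threshold
        diag_rows.append({
            "gene": gene,
            "purpose": "DIAGNOSTIC",
            "threshold": result.threshold,
            "auc": result.auc,
            "sensitivity": result.sensitivity,
            "specificity": result.specificity,
            "pct_tumor_above": proportion_above(pos, result.threshold),
            "pct_mucosa_above": proportion_above(neg, result.threshold),
        })

    # --- stage 2: compartment ANOVA and correlations ---------------------
    anova_rows = []
    for gene in config.genes:
        groups = _compartment_groups(samples, by_id, gene)
        if all(len(g) >= 2 for g in groups.values()):
            f_stat, p, _ = anova_tukey(list(groups.values()))
            anova_rows.append({
                "gene": gene, "F": f_stat, "p_value": p,
                **{f"n_{k}": len(v) for k, v in groups.items()},
            })
    written["anova"] = write_table(pd.DataFrame(anova_rows), out_dir / "anova.tsv")
    corr_frames = [
        pairwise_correlation(samples, config.genes, comp)
        for comp in (Compartment.RT, Compartment.RN, Compartment.BIOPSY)
    ]
    written["correlations"] = write_table(
        pd.concat(corr_frames, ignore_index=True), out_dir / "correlations.tsv"
    )

    # --- stage 3: prognostic cut-offs and Cox workflow -------------------
    run_warnings.append(
        "minimum-p cut-point scans are anti-conservative without correction"
    )
    survival_rows = []
    rn_by_patient = {s.patient_id: s for s in rn}
    rt_by_patient = {s.patient_id: s for s in rt}
    for endpoint, purpose in (("os", CutoffPurpose.SURVIVAL_OS),
                              ("rfs", CutoffPurpose.SURVIVAL_RFS)):
        for gene in config.genes:
            ids, values = _gene_vector(rt, gene)
            times = np.array([getattr(by_id[i], f"{endpoint}_time") for i in ids])
            events = np.array([getattr(by_id[i], f"{endpoint}_event") for i in ids])
            if not events.any():
                continue
            result = minp_logrank_cutoff(
                values, times, events,
                min_group_frac=config.min_group_frac, alpha=config.alpha,
                purpose=purpose, gene=gene,
            )
            survival_rows.append({
                "gene": gene, "endpoint": endpoint.upper(),
                "found": result.found, "threshold": result.threshold,
                "scan_p": result.scan_p, "relative_risk": result.relative_risk,
            })
    prognostic = _prognostic_factors(patients, rt_by_patient, config)
    written["survival"] = write_table(
        pd.DataFrame(survival_rows), out_dir / "survival.tsv"
    )
    written["multivariate"] = write_table(prognostic, out_dir / "multivariate.tsv")

    # --- stage 4: propensity discrimination ------------------------------
    run_warnings.append("propensity AUC is in-sample (apparent), no validation split")
    written["propensity"] = write_table(
        _propensity_table(patients, rn_by_patient, config),
        out_dir / "propensity.tsv",
    )

    # --- stage 5: biopsy term cut-offs and the risk score ----------------
    term_rows = []
    term_cutoffs: dict[str, float] = {}
    term_overrides = config.cutoff_overrides.get("term", {})
    for gene in config.genes:
        # "time to development" of a biopsy is its lead time before onset
        pairs = [
            (s.value(gene), s.months_before_onset)
            for s in biopsies
            if s.value(gene) is not None and s.patient_id in by_id
        ]
        if gene in term_overrides:
            term_cutoffs[gene] = term_overrides[gene]
            term_rows.append({"gene": gene, "found": True,
                              "threshold": term_overrides[gene],
                              "scan_p": None, "source": "override"})
            continue
        if len(pairs) >= 4:
            values = np.array([v for v, _ in pairs])
            terms = np.array([max(t, 0.0) for _, t in pairs])
            result = minp_ttest_cutoff(
                values, terms, min_group_frac=config.min_group_frac, gene=gene
            )
            if result.found:
                term_cutoffs[gene] = result.threshold
            term_rows.append({"gene": gene, "found": result.found,
                              "threshold": result.threshold,
                              "scan_p": result.scan_p, "source": "scan"})
    written["cutoffs"] = write_table(
        pd.DataFrame(diag_rows + term_rows), out_dir / "cutoffs.tsv"
    )

    score_cutoffs = {**PUBLISHED_TERM_CUTOFFS, **term_cutoffs,
                     **term_overrides}
    scores = [total_score(s, score_cutoffs, config.genes) for s in rn]
    distribution = score_distribution(scores, k=len(config.genes))
    written["scores"] = write_table(_score_rows(scores), out_dir / "scores.tsv")
    written["score_distribution"] = write_table(
        distribution, out_dir / "score_distribution.tsv"
    )
    if biopsies:
        usable = [s for s in biopsies if s.patient_id in by_id]
        terms = [s.months_before_onset for s in usable]
        splits = enumerate_combinations(usable, terms, score_cutoffs)
        written["splits"] = write_table(split_table(splits), out_dir / "splits.tsv")

    digests = {name: _digest(path) for name, path in sorted(written.items())}
    manifest = RunManifest(
        config_hash=config_digest(config),
        seed=config.seed,
        version=__version__,
        file_digests=digests,
        warnings=sorted(set(run_warnings)),
    )
    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def reproduce_published_mode(config: RunConfig) -> RunManifest:
    """Run the pipeline with the published cut-offs injected (no discovery)."""
    overrides = {
        "diagnostic": dict(PUBLISHED_DIAGNOSTIC_CUTOFFS),
        "term": dict(PUBLISHED_TERM_CUTOFFS),
    }
    merged = dataclasses.replace(
        config, cutoff_overrides={**overrides, **config.cutoff_overrides}
    )
    if not merged.genes:
        raise ValueError("empty gene subset")
    return run_full(merged)


def _compartment_groups(samples, by_id, gene):
    """TaqMeth vectors for RN-IM, RN-IB, IN-IM, IN-IB."""
    groups: dict[str, list[float]] = {
        "RN_IM": [], "RN_IB": [], "IN_IM": [], "IN_IB": [],
    }
    for s in samples:
        if s.compartment not in (Compartment.RN, Compartment.IN):
            continue
        value = s.value(gene)
        patient = by_id.get(s.patient_id)
        if value is None or patient is None:
            continue
        suffix = (
            "IM" if patient.initial_diagnosis is InitialDiagnosis.MALIGNANT else "IB"
        )
        groups[f"{s.compartment.value}_{suffix}"].append(value)
    return groups


def _prognostic_factors(patients, rt_by_patient, config: RunConfig) -> pd.DataFrame:
    rows = []
    for p in patients:
        rt = rt_by_patient.get(p.patient_id)
        row = {
            "initial_malignant": int(p.initial_diagnosis is InitialDiagnosis.MALIGNANT),
            "depth_T": int(p.depth_T == "ge_mp"),
            "node_N": int(p.node_N == "POS"),
            "metastasis_M": int(p.metastasis_M == "POS"),
            "stage": int(p.stage in ("III", "IV")),
            "ly": int(p.ly == "POS"),
            "v": int(p.v == "POS"),
        }
        for gene in config.genes:
            value = rt.value(gene) if rt is not None else None
            row[f"{gene}_rt"] = value if value is not None else np.nan
        row["_os_time"] = p.os_time
        row["_os_event"] = p.os_event
        rows.append(row)
    frame = pd.DataFrame(rows).dropna()
    times = frame.pop("_os_time").to_numpy()
    events = frame.pop("_os_event").to_numpy(dtype=bool)
    if events.sum() < 3:
        return pd.DataFrame(
            columns=["covariate", "hr", "ci_low", "ci_high", "p"]
        )
    fit = prognostic_workflow(frame, times, events, alpha=config.alpha)
    table = fit.table.copy()
    table.attrs["trace"] = fit.selection_trace
    return table


def _propensity_table(patients, rn_by_patient, config: RunConfig) -> pd.DataFrame:
    rows, labels = [], []
    for p in patients:
        rn = rn_by_patient.get(p.patient_id)
        if rn is None:
            continue
        row = {}
        for gene in config.genes:
            value = rn.value(gene)
            row[gene] = value if value is not None else np.nan
        row["age"] = p.age
        row["sex_male"] = int(p.sex == "M")
        row["term"] = p.term_to_rgc
        rows.append(row)
        labels.append(int(p.initial_diagnosis is InitialDiagnosis.MALIGNANT))
    frame = pd.DataFrame(rows)
    labels = np.asarray(labels)
    keep = frame.notna().all(axis=1).to_numpy()
    frame, labels = frame.loc[keep].reset_index(drop=True), labels[keep]
    gene_fit = fit_propensity(frame[list(config.genes)], labels, cross_validate=5,
                              seed=config.seed or 0)
    full_fit = fit_propensity(frame, labels, cross_validate=5,
                              seed=config.seed or 0)
    return pd.DataFrame([
        {"model": "genes", "n_covariates": len(config.genes),
         "auc_in_sample": gene_fit.auc, "auc_cv": gene_fit.cv_auc,
         "group_p": gene_fit.group_p, "separation": gene_fit.separation},
        {"model": "genes+clinical", "n_covariates": frame.shape[1],
         "auc_in_sample": full_fit.auc, "auc_cv": full_fit.cv_auc,
         "group_p": full_fit.group_p, "separation": full_fit.separation},
    ])


def _score_rows(scores: Sequence[RiskScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"patient_id": s.patient_id, "total": s.total,
               "complete": s.complete}
        for gene, point in s.points.items():
            row[f"point_{gene}"] = point
        rows.append(row)
    return pd.DataFrame(rows)
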