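"""Shared data model and tabular I/O.

All tables are TSV (header row, UTF-8, '.' decimal).  A TaqMeth V that was
never measured is a first-class missing state, distinct from 0.0 — an
undetected-methylation result is a legitimate 0.0, so nothing downstream
may impute zeros for absent measurements.
"""
from __future__ import annotations

import dataclasses
import enum
import json
import math
import pathlib
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

GENES: tuple[str, ...] = ("CDO1", "HOPX", "Reprimo", "ECAD")

UNKNOWN = "UNKNOWN"


class SchemaError(ValueError):
    """A table is structurally unusable (missing column, unknown symbol)."""


class RowError(ValueError):
    """A single row violates an invariant; the message names the row."""


class ConflictError(ValueError):
    """Duplicate measurements for the same (patient, compartment, gene, time)."""


class InitialDiagnosis(str, enum.Enum):
    MALIGNANT = "MALIGNANT"
    BENIGN = "BENIGN"


class Compartment(str, enum.Enum):
    RT = "RT"          # remnant gastric cancer tissue
    RN = "RN"          # remnant non-cancerous mucosa (at RGC surgery)
    IN = "IN"          # non-cancerous mucosa from the initial surgery
    BIOPSY = "BIOPSY"  # endoscopic biopsy between initial surgery and onset


#: declared label sets for the clinicopathological categoricals; UNKNOWN is
#: always admissible in addition.
CATEGORICAL_LEVELS: dict[str, frozenset[str]] = {
    "sex": frozenset({"M", "F"}),
    "hp_status": frozenset({"POS", "NEG"}),
    "reconstruction": frozenset({"BI", "BII", "OTHER"}),
    "site": frozenset({"ANASTOMOTIC", "NON_ANASTOMOTIC"}),
    "depth_T": frozenset({"le_sm", "ge_mp"}),
    "node_N": frozenset({"POS", "NEG"}),
    "metastasis_M": frozenset({"POS", "NEG"}),
    "stage": frozenset({"I", "II", "III", "IV"}),
    "ly": frozenset({"POS", "NEG"}),
    "v": frozenset({"POS", "NEG"}),
    "inf_pattern": frozenset({"a", "b", "c"}),
    "lauren": frozenset({"intestinal", "diffuse"}),
}

_MANDATORY_PATIENT_COLUMNS = (
    "patient_id",
    "initial_diagnosis",
    "age",
    "sex",
    "term_to_rgc",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
)

_CATEGORICAL_COLUMNS = (
    "hp_status",
    "reconstruction",
    "site",
    "depth_T",
    "node_N",
    "metastasis_M",
    "stage",
    "ly",
    "v",
    "inf_pattern",
    "lauren",
)

_MEASUREMENT_COLUMNS = (
    "patient_id",
    "compartment",
    "gene",
    "taqmeth_v",
    "months_before_onset",
)


@dataclasses.dataclass
class PatientRecord:
    """Clinical covariates and outcomes for one RGC patient.

    Times are months.  ``term_to_rgc`` runs from the initial gastrectomy to
    RGC onset; ``os_time``/``rfs_time`` are clocked from the RGC surgery.
    """

    patient_id: str
    initial_diagnosis: InitialDiagnosis
    age: int
    sex: str
    term_to_rgc: float
    os_time: float
    os_event: bool
    rfs_time: float
    rfs_event: bool
    hp_status: str = UNKNOWN
    reconstruction: str = UNKNOWN
    site: str = UNKNOWN
    depth_T: str = UNKNOWN
    node_N: str = UNKNOWN
    metastasis_M: str = UNKNOWN
    stage: str = UNKNOWN
    ly: str = UNKNOWN
    v: str = UNKNOWN
    inf_pattern: str = UNKNOWN
    lauren: str = UNKNOWN

    def __post_init__(self) -> None:
        self.initial_diagnosis = InitialDiagnosis(self.initial_diagnosis)
        if not self.age > 0:
            raise RowError(f"patient {self.patient_id}: age must be > 0")
        if not self.term_to_rgc > 0:
            raise RowError(
                f"patient {self.patient_id}: term_to_rgc must be > 0 months"
            )
        if self.os_time < 0 or self.rfs_time < 0:
            raise RowError(f"patient {self.patient_id}: survival times must be >= 0")
        if self.rfs_time > self.os_time + 1e-9:
            raise RowError(
                f"patient {self.patient_id}: rfs_time exceeds os_time"
            )
        for field, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, field)
            if value != UNKNOWN and value not in levels:
                raise RowError(
                    f"patient {self.patient_id}: {field}={value!r} not in "
                    f"{sorted(levels)} or {UNKNOWN}"
                )


@dataclasses.dataclass
class MethylationSample:
    """One specimen's per-gene TaqMeth V values.

    ``gene_values`` holds only the genes actually measured; an absent key is
    a missing measurement, never zero.  ``months_before_onset`` is required
    for (and only meaningful on) BIOPSY specimens.
    """

    patient_id: str
    compartment: Compartment
    gene_values: dict[str, float] = dataclasses.field(default_factory=dict)
    months_before_onset: float | None = None

    def __post_init__(self) -> None:
        self.compartment = Compartment(self.compartment)
        for gene, value in self.gene_values.items():
            if gene not in GENES:
                raise SchemaError(f"unknown gene symbol {gene!r}")
            if value < 0 or math.isnan(value):
                raise RowError(
                    f"patient {self.patient_id}: TaqMeth V for {gene} must be >= 0"
                )
        if self.compartment is Compartment.BIOPSY:
            if self.months_before_onset is None or self.months_before_onset < 0:
                raise RowError(
                    f"patient {self.patient_id}: BIOPSY sample requires "
                    "months_before_onset >= 0"
                )

    def value(self, gene: str) -> float | None:
        """Measured TaqMeth V for ``gene``, or None when not measured."""
        return self.gene_values.get(gene)


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration for the pipeline."""

    genes: tuple[str, ...] = GENES
    #: optional fixed thresholds, keyed purpose -> gene -> theta; a purpose
    #: present here skips cut-off discovery for the listed genes.
    cutoff_overrides: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=dict
    )
    min_group_frac: float = 0.1
    alpha: float = 0.05
    seed: int | None = None
    patients_path: str | None = None
    measurements_path: str | None = None
    out_dir: str = "results"
    simulate: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_group_frac < 0.5:
            raise SchemaError("min_group_frac must lie in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise SchemaError("alpha must lie in (0, 1)")
        unknown = set(self.genes) - set(GENES)
        if unknown:
            raise SchemaError(f"unknown genes in config: {sorted(unknown)}")
        for purpose, table in self.cutoff_overrides.items():
            for gene, theta in table.items():
                if gene not in GENES:
                    raise SchemaError(
                        f"cutoff override for unknown gene {gene!r} ({purpose})"
                    )
                if theta <= 0:
                    raise SchemaError(f"cutoff override {gene}/{purpose} must be > 0")


def load_config(path: str | pathlib.Path) -> RunConfig:
    """Load and validate a YAML/JSON key-value run configuration."""
    raw = yaml.safe_load(pathlib.Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    if "genes" in raw:
        raw["genes"] = tuple(raw["genes"])
    return RunConfig(**raw)


def _parse_bool(raw: object, where: str) -> bool:
    text = str(raw).strip().lower()
    if text in {"1", "true", "t", "yes"}:
        return True
    if text in {"0", "false", "f", "no"}:
        return False
    raise RowError(f"{where}: cannot parse boolean from {raw!r}")


def _parse_float(raw: object, where: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowError(f"{where}: cannot parse number from {raw!r}") from None


def read_patients(path: str | pathlib.Path) -> list[PatientRecord]:
    """Read ``patients.tsv`` into validated :class:`PatientRecord` objects.

    Blank categorical cells become UNKNOWN; a missing mandatory column is a
    :class:`SchemaError`, an invalid row a :class:`RowError` naming the row.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _MANDATORY_PATIENT_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"patients table is missing mandatory column {column!r}")
    records: list[PatientRecord] = []
    for index, row in frame.iterrows():
        where = f"row {index + 2}"  # 1-based, counting the header line
        kwargs: dict[str, object] = {
            "patient_id": row["patient_id"],
            "sex": row["sex"],
        }
        try:
            kwargs["initial_diagnosis"] = InitialDiagnosis(row["initial_diagnosis"])
        except ValueError:
            raise RowError(
                f"{where}: initial_diagnosis must be MALIGNANT or BENIGN, "
                f"got {row['initial_diagnosis']!r}"
            ) from None
        kwargs["age"] = int(_parse_float(row["age"], where))
        kwargs["term_to_rgc"] = _parse_float(row["term_to_rgc"], where)
        kwargs["os_time"] = _parse_float(row["os_time"], where)
        kwargs["rfs_time"] = _parse_float(row["rfs_time"], where)
        kwargs["os_event"] = _parse_bool(row["os_event"], where)
        kwargs["rfs_event"] = _parse_bool(row["rfs_event"], where)
        for column in _CATEGORICAL_COLUMNS:
            raw = row[column].strip() if column in frame.columns else ""
            kwargs[column] = raw if raw else UNKNOWN
        try:
            records.append(PatientRecord(**kwargs))
        except RowError as err:
            raise RowError(f"{where}: {err}") from None
    return records


def read_measurements(path: str | pathlib.Path) -> list[MethylationSample]:
    """Read the long-format measurement table and pivot it into samples.

    One :class:`MethylationSample` is produced per distinct
    (patient, compartment, months_before_onset); genes never reported for a
    sample stay missing.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _MEASUREMENT_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(
                f"measurements table is missing mandatory column {column!r}"
            )
    grouped: dict[tuple[str, str, float | None], dict[str, float]] = {}
    order: list[tuple[str, str, float | None]] = []
    for index, row in frame.iterrows():
        where = f"row {index + 2}"
        gene = row["gene"]
        if gene not in GENES:
            raise SchemaError(f"{where}: unknown gene symbol {gene!r}")
        months_raw = row["months_before_onset"].strip()
        months = _parse_float(months_raw, where) if months_raw else None
        key = (row["patient_id"], row["compartment"], months)
        values = grouped.get(key)
        if values is None:
            values = grouped[key] = {}
            order.append(key)
        if gene in values:
            raise ConflictError(
                f"{where}: duplicate measurement for "
                f"({key[0]}, {key[1]}, {gene}, {months})"
            )
        values[gene] = _parse_float(row["taqmeth_v"], where)
    samples = []
    for patient_id, compartment, months in order:
        try:
            comp = Compartment(compartment)
        except ValueError:
            raise SchemaError(f"unknown compartment {compartment!r}") from None
        samples.append(
            MethylationSample(
                patient_id=patient_id,
                compartment=comp,
                gene_values=grouped[(patient_id, compartment, months)],
                months_before_onset=months,
            )
        )
    return samples


def patients_frame(patients: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = dataclasses.asdict(p)
        row["initial_diagnosis"] = p.initial_diagnosis.value
        rows.append(row)
    columns = [f.name for f in dataclasses.fields(PatientRecord)]
    return pd.DataFrame(rows, columns=columns)


def measurements_frame(samples: Iterable[MethylationSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for gene in GENES:
            if gene in s.gene_values:
                rows.append(
                    {
                        "patient_id": s.patient_id,
                        "compartment": s.compartment.value,
                        "gene": gene,
                        "taqmeth_v": s.gene_values[gene],
                        "months_before_onset": s.months_before_onset,
                    }
                )
    return pd.DataFrame(rows, columns=list(_MEASUREMENT_COLUMNS))


def write_table(frame: pd.DataFrame, path: str | pathlib.Path) -> pathlib.Path:
    """Write a TSV with deterministic column order and shortest
    round-trippable float representation, so re-reading reproduces integers
    and strings bit-for-bit and floats exactly."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False,
                 float_format=lambda v: repr(float(v)))
    return path


def write_patients(patients: Sequence[PatientRecord], path) -> pathlib.Path:
    return write_table(patients_frame(patients), path)


def write_measurements(samples: Sequence[MethylationSample], path) -> pathlib.Path:
    return write_table(measurements_frame(samples), path)


def write_report_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | pathlib.Path
) -> dict[str, pathlib.Path]:
    """Write every result DataFrame as ``<name>.tsv`` under ``out_dir``.

    An empty DataFrame still yields a header-only file.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame in results.items():
        written[name] = write_table(frame, out_dir / f"{name}.tsv")
    return written


def samples_by_compartment(
    samples: Iterable[MethylationSample], compartment: Compartment
) -> list[MethylationSample]:
    return [s for s in samples if s.compartment is compartment]


def config_digest(config: RunConfig) -> str:
    """Stable SHA-256 of the configuration for the run manifest."""
    import hashlib

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
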