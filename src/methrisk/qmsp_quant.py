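"""TaqMeth V computation from Q-MSP replicate quantities.

The methylation value of a specimen is the amplification quantity of the
methylated target promoter divided by the beta-actin reference quantity,
times 100.  Replicates (assays run in triplicate) are aggregated by the
arithmetic mean of quantities before the ratio is taken; a failed
beta-actin reference (quantity <= 0) invalidates the specimen rather than
scoring it 0, because conflating reference failure with undetected
methylation would bias every downstream cut-off.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .cohort_io import GENES, SchemaError


class InvalidSampleError(ValueError):
    """The beta-actin reference failed; the specimen must be excluded."""


@dataclasses.dataclass
class QmspWell:
    """Per-replicate quantities for one gene on one specimen."""

    gene: str
    target_quantities: Sequence[float]
    actin_quantities: Sequence[float]

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise SchemaError(f"unknown gene symbol {self.gene!r}")
        for qs in (self.target_quantities, self.actin_quantities):
            if len(qs) == 0:
                raise ValueError("at least one replicate is required")
            if any(q < 0 for q in qs):
                raise ValueError("replicate quantities must be >= 0")

    def taqmeth(self) -> float:
        return taqmeth_value(
            aggregate_replicates(self.target_quantities),
            aggregate_replicates(self.actin_quantities),
        )


def aggregate_replicates(quantities: Sequence[float]) -> float:
    """Arithmetic mean of replicate quantities."""
    if len(quantities) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    return float(sum(quantities)) / len(quantities)


def taqmeth_value(target_q: float, actin_q: float) -> float:
    """100 x target quantity / beta-actin quantity.

    Raises :class:`InvalidSampleError` when the reference quantity is not
    positive.
    """
    if target_q < 0:
        raise ValueError("target quantity must be >= 0")
    if actin_q <= 0:
        raise InvalidSampleError(
            "beta-actin reference quantity <= 0: specimen must be excluded, "
            "not scored 0"
        )
    return 100.0 * target_q / actin_q


def compile_raw_quantities(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse a raw-quantity table into long-format TaqMeth V rows.

    Expects columns (patient_id, compartment, gene, replicate, target_q,
    actin_q); replicates are averaged per (patient, compartment, gene) and
    converted with :func:`taqmeth_value`.  Specimens whose reference failed
    are dropped (excluded, not zeroed) and reported in the second return
    value.
    """
    required = {"patient_id", "compartment", "gene", "target_q", "actin_q"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"raw quantity table is missing columns {sorted(missing)}")
    rows = []
    excluded = []
    keys = ["patient_id", "compartment", "gene"]
    if "months_before_onset" in frame.columns:
        keys.append("months_before_onset")
    for key, group in frame.groupby(keys, dropna=False, sort=False):
        target = aggregate_replicates(list(group["target_q"].astype(float)))
        actin = aggregate_replicates(list(group["actin_q"].astype(float)))
        record = dict(zip(keys, key))
        try:
            record["taqmeth_v"] = taqmeth_value(target, actin)
        except InvalidSampleError:
            excluded.append(record)
            continue
        rows.append(record)
    compiled = pd.DataFrame(rows, columns=keys + ["taqmeth_v"])
    compiled.attrs["excluded"] = excluded
    return compiled
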