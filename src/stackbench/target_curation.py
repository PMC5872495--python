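"""Curation of multi-valued drug-target potency assays into a binary
target-inhibition matrix.

Public potency databases report multiple K_d / EC50 values per (drug,
target) pair, occasionally off by several orders of magnitude when units
are misreported (nanomolar instead of the standard micromolar).  Curation
proceeds per pair:

1. compute the order of magnitude ``m = floor(log10(t))`` of each value;
2. drop any value whose magnitude deviates from the modal magnitude by
   more than 3;
3. summarize the survivors by their median.

The curated value is then binarized against half the drug's maximum tested
dose: the target counts as inhibited (1) when the curated potency is
strictly below ``max_dose / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetAssayRecord",
    "curate_values",
    "binarize_target",
    "build_target_matrix",
]


@dataclass(frozen=True)
class TargetAssayRecord:
    """Reported potency values (micromolar) for one drug-target pair."""

    drug_id: str
    target_id: str
    values: tuple[float, ...]
    max_dose: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if not self.values:
            raise ValueError("values must be nonempty")
        if any(v <= 0 for v in self.values):
            raise ValueError("potency values must be positive")
        if self.max_dose <= 0:
            raise ValueError("max_dose must be positive")


def _modal_magnitude(magnitudes: np.ndarray) -> int:
    """Most common magnitude; ties resolved toward the smallest (most
    potent) magnitude."""
    values, counts = np.unique(magnitudes, return_counts=True)
    return int(values[np.argmax(counts)])  # np.unique sorts ascending


def curate_values(values: Sequence[float]) -> float:
    """Outlier-filtered median of reported potency values.

    Values whose floor-log10 magnitude deviates from the modal magnitude by
    more than 3 are removed; the median of the survivors is returned.  The
    modal-magnitude values always survive, so the survivor set is never
    empty.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be nonempty")
    if (arr <= 0).any():
        raise ValueError("potency values must be positive")
    mags = np.floor(np.log10(arr)).astype(int)
    mode = _modal_magnitude(mags)
    survivors = arr[np.abs(mags - mode) <= 3]
    return float(np.median(survivors))


def binarize_target(curated_value: float, max_dose: float) -> int:
    """1 if the curated potency is strictly below half the max dose, else 0."""
    if curated_value <= 0 or max_dose <= 0:
        raise ValueError("curated_value and max_dose must be positive")
    return int(curated_value < max_dose / 2.0)


def build_target_matrix(
    records: Iterable[TargetAssayRecord],
    drugs: Sequence[str],
    targets: Sequence[str],
) -> pd.DataFrame:
    """Assemble the binary drug x target inhibition matrix.

    Duplicate records for the same (drug, target) pair are merged (their
    value lists concatenated) before curation; pairs with no record are 0.
    """
    drugs = list(drugs)
    targets = list(targets)
    drug_set, target_set = set(drugs), set(targets)

    merged: dict[tuple[str, str], tuple[list[float], float]] = {}
    for rec in records:
        if rec.drug_id not in drug_set:
            raise KeyError(f"record references unknown drug {rec.drug_id!r}")
        if rec.target_id not in target_set:
            raise KeyError(f"record references unknown target {rec.target_id!r}")
        key = (rec.drug_id, rec.target_id)
        if key in merged:
            vals, dose = merged[key]
            if dose != rec.max_dose:
                raise ValueError(
                    f"conflicting max_dose for {key}: {dose} vs {rec.max_dose}"
                )
            vals.extend(rec.values)
        else:
            merged[key] = (list(rec.values), rec.max_dose)

    matrix = pd.DataFrame(0, index=drugs, columns=targets, dtype=int)
    for (drug, target), (vals, dose) in merged.items():
        matrix.loc[drug, target] = binarize_target(curate_values(vals), dose)
    return matrix
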