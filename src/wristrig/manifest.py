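"""Manifest of the surgical-evaluation cohorts the calibrations were built on.

The recordings themselves are not deposited; the manifest records the
bookkeeping only — how many patients and how many classified flexion
signals each cohort contributed to training and testing, and how the
second cohort's training signals split into the two baseline-rigidity
regimes of the gated model.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CohortDataset",
    "STUDY_DATASETS",
    "BASELINE_CLUSTER_SIZES",
    "total_signals",
    "total_patients",
]


@dataclass(frozen=True)
class CohortDataset:
    name: str
    patients_train: int
    signals_train: int
    patients_test: int
    signals_test: int
    models: tuple[str, ...]


STUDY_DATASETS: tuple[CohortDataset, ...] = (
    CohortDataset("I", 6, 48, 4, 156, ("first",)),
    CohortDataset("II", 17, 237, 2, 38, ("multi",)),
    CohortDataset("III", 22, 118, 8, 150, ("cogwheel", "3-axis", "reduced")),
)

#: Training-signal split of the baseline-gated model (Dataset II):
#: low baseline rigidity = UPDRS 1-2, high = UPDRS 3.
BASELINE_CLUSTER_SIZES: dict[str, int] = {"low": 98, "high": 139}


def total_signals(split: str) -> int:
    """Total signals over all cohorts for ``split`` in {'train', 'test'}."""
    if split == "train":
        return sum(d.signals_train for d in STUDY_DATASETS)
    if split == "test":
        return sum(d.signals_test for d in STUDY_DATASETS)
    raise ValueError(f"unknown split {split!r}")


def total_patients(split: str) -> int:
    if split == "train":
        return sum(d.patients_train for d in STUDY_DATASETS)
    if split == "test":
        return sum(d.patients_test for d in STUDY_DATASETS)
    raise ValueError(f"unknown split {split!r}")
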