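"""Binder labeling from binding measurements and stratified splitting.

A compound is a binder iff its measured Ki is strictly below the threshold
(default 25 nM). Measurements where no curve could be fit below the censor
limit (default 1 µM) are "no binding" records and label as non-binders; a
Ki exactly at the threshold is a non-binder (conservative hit calling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

BINDER = "binder"
NON_BINDER = "non-binder"

CHEMOTYPES = ("V", "M", "Z", "A")


@dataclass(frozen=True)
class LabelingConfig:
    binder_threshold_nM: float = 25.0
    censor_limit_nM: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.binder_threshold_nM < self.censor_limit_nM):
            raise ValueError("require 0 < binder_threshold_nM < censor_limit_nM")


@dataclass(frozen=True)
class BindingMeasurement:
    """A fitted Ki (nM) or a censored 'no binding' outcome.

    Either ``ki_nM`` is present, or ``censored_no_binding`` is True; both
    may be present only when the fitted Ki exceeds the censor limit.
    """

    ki_nM: Optional[float] = None
    censored_no_binding: bool = False

    def validate(self, cfg: LabelingConfig = LabelingConfig()) -> None:
        if self.ki_nM is None and not self.censored_no_binding:
            raise ValueError("measurement has neither a Ki nor a censoring flag")
        if self.ki_nM is not None:
            if not (self.ki_nM > 0):
                raise ValueError(f"ki_nM must be positive, got {self.ki_nM}")
            if self.censored_no_binding and self.ki_nM <= cfg.censor_limit_nM:
                raise ValueError(
                    "censored measurement carries a Ki at or below the censor limit"
                )


def label_from_ki(m: BindingMeasurement, cfg: LabelingConfig = LabelingConfig()) -> str:
    """Binder iff Ki strictly below the threshold; censored → non-binder."""
    m.validate(cfg)
    if m.censored_no_binding and m.ki_nM is None:
        return NON_BINDER
    return BINDER if m.ki_nM < cfg.binder_threshold_nM else NON_BINDER


@dataclass
class CompoundRecord:
    """One compound: structure, measurement, chemotype tag, binder label."""

    molecule: "object"  # fibrilscreen.chem.Molecule; kept loose for plumbing
    measurement: BindingMeasurement
    chemotype_tag: Optional[str] = None
    binder_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chemotype_tag is not None and self.chemotype_tag not in CHEMOTYPES:
            raise ValueError(f"unknown chemotype tag {self.chemotype_tag!r}")

    @property
    def id(self) -> str:
        return self.molecule.id

    def with_label(self, cfg: LabelingConfig = LabelingConfig()) -> "CompoundRecord":
        return CompoundRecord(
            molecule=self.molecule,
            measurement=self.measurement,
            chemotype_tag=self.chemotype_tag,
            binder_label=label_from_ki(self.measurement, cfg),
        )


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def _largest_remainder(quotas: Sequence[float], total: int) -> list[int]:
    """Integer allocation matching `total` with per-cell quotas, rounding by
    largest fractional remainder (ties: earlier cell first)."""
    floors = [int(np.floor(q)) for q in quotas]
    leftover = total - sum(floors)
    order = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    out = list(floors)
    for i in order[:leftover]:
        out[i] += 1
    return out


def stratified_split(
    records: Sequence[CompoundRecord],
    test_fraction: float = 44 / 315,
    seed: int = 0,
) -> DatasetSplit:
    """Label-stratified train/test partition.

    Test-set size is ``round(n * test_fraction)``; each label class
    contributes its proportional share with largest-remainder rounding.
    Records are shuffled within class (seeded) before allocation, so the
    split is deterministic given the seed.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for r in records:
        if r.binder_label is None:
            raise ValueError(f"record {r.id!r} is unlabeled")
        by_class.setdefault(r.binder_label, []).append(r.id)
    for cls, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 records")

    n = len(records)
    n_test = int(round(n * test_fraction))
    classes = sorted(by_class)  # fixed order for deterministic rounding
    quotas = [len(by_class[c]) * n_test / n for c in classes]
    takes = _largest_remainder(quotas, n_test)

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    train_ids: list[str] = []
    for cls, k in zip(classes, takes):
        ids = list(by_class[cls])
        rng.shuffle(ids)
        test_ids.extend(ids[:k])
        train_ids.extend(ids[k:])
    return DatasetSplit(
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        seed=seed,
        test_fraction=test_fraction,
    )
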