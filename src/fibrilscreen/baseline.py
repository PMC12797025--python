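"""Similarity baseline: binder iff max Tanimoto to a training binder > τ."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from fibrilscreen.chem import FingerprintBits, FingerprintConfig, morgan_fingerprint, tanimoto
from fibrilscreen.labeling import BINDER, NON_BINDER, CompoundRecord, LabelingConfig
from fibrilscreen.models import ClassReport, classification_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineConfig:
    tau: float = 0.5
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must be in [0, 1]")


def baseline_predict(
    query: FingerprintBits,
    train_binders: Sequence[FingerprintBits],
    cfg: BaselineConfig = BaselineConfig(),
) -> tuple[str, float]:
    """Label a query by its maximum Tanimoto similarity to training binders.

    Strictly greater than τ ("exceeded") counts as a binder. An empty
    training-binder set predicts non-binder with max_similarity 0.
    """
    if not train_binders:
        logger.warning("baseline_predict called with no training binders")
        return NON_BINDER, 0.0
    max_sim = max(tanimoto(query, b) for b in train_binders)
    return (BINDER if max_sim > cfg.tau else NON_BINDER), max_sim


def baseline_evaluate(
    train_records: Sequence[CompoundRecord],
    test_records: Sequence[CompoundRecord],
    cfg: BaselineConfig = BaselineConfig(),
) -> ClassReport:
    """Score the baseline on labeled test records using training binders only."""
    binder_fps = [
        morgan_fingerprint(r.molecule, cfg.fingerprint)
        for r in train_records
        if r.binder_label == BINDER
    ]
    y_true, y_pred = [], []
    for r in test_records:
        if r.binder_label is None:
            raise ValueError(f"test record {r.id!r} is unlabeled")
        fp = morgan_fingerprint(r.molecule, cfg.fingerprint)
        label, _ = baseline_predict(fp, binder_fps, cfg)
        y_true.append(r.binder_label)
        y_pred.append(label)
    return classification_report(y_true, y_pred)
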