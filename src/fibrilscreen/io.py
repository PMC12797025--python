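"""Readers and writers for the pipeline's delimited-text formats.

Compound tables are CSV with header ``id,smiles,ki_nM,no_binding,chemotype``
(``ki_nM`` empty for censored records; ``no_binding`` is 0/1; ``chemotype``
optional). SMILES library files are one ``SMILES [whitespace] id`` per
line. Split manifests are two id lists plus the seed and fraction.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from fibrilscreen.chem import FeatureMatrix, Molecule, canonicalize
from fibrilscreen.labeling import (
    BindingMeasurement,
    CompoundRecord,
    DatasetSplit,
    LabelingConfig,
)

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["id", "smiles", "ki_nM", "no_binding", "chemotype"]


def read_compound_table(
    path: str | Path,
    labeling: LabelingConfig | None = None,
) -> tuple[list[CompoundRecord], int]:
    """Load a labeled compound table; returns (records, n_skipped).

    Unparsable SMILES are skipped with a warning and counted, per the
    parsing contract. Labels are assigned from the measurement.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    labeling = labeling or LabelingConfig()
    records: list[CompoundRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        mol = canonicalize(str(row.smiles), id=str(row.id))
        if not mol.parse_ok:
            n_skipped += 1
            continue
        ki = getattr(row, "ki_nM", None)
        ki = None if ki is None or pd.isna(ki) else float(ki)
        censored = bool(int(getattr(row, "no_binding", 0) or 0))
        chemotype = getattr(row, "chemotype", None)
        if chemotype is not None and (pd.isna(chemotype) or chemotype == ""):
            chemotype = None
        rec = CompoundRecord(
            molecule=mol,
            measurement=BindingMeasurement(ki_nM=ki, censored_no_binding=censored),
            chemotype_tag=chemotype,
        ).with_label(labeling)
        records.append(rec)
    if n_skipped:
        logger.warning("skipped %d unparsable records in %s", n_skipped, path)
    return records, n_skipped


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "smiles": r.molecule.smiles_canonical,
                "ki_nM": "" if r.measurement.ki_nM is None else repr(r.measurement.ki_nM),
                "no_binding": int(r.measurement.censored_no_binding),
                "chemotype": r.chemotype_tag or "",
            }
        )
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=TABLE_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)


def read_smiles_file(path: str | Path) -> tuple[list[Molecule], int]:
    """Load a SMILES-per-line library file; returns (molecules, n_skipped)."""
    mols: list[Molecule] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
            mol = canonicalize(smi, id=mol_id)
            if mol.parse_ok:
                mols.append(mol)
            else:
                n_skipped += 1
    if n_skipped:
        logger.warning("skipped %d unparsable SMILES in %s", n_skipped, path)
    return mols, n_skipped


def write_smiles_file(
    molecules: Iterable[Molecule], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for m in molecules:
            fh.write(f"{m.smiles_canonical}\t{m.id}\n")


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "seed": split.seed,
                "test_fraction": split.test_fraction,
                "train_ids": list(split.train_ids),
                "test_ids": list(split.test_ids),
            },
            fh,
            indent=2,
        )


def read_split_manifest(path: str | Path) -> DatasetSplit:
    with open(path) as fh:
        d = json.load(fh)
    return DatasetSplit(
        train_ids=tuple(d["train_ids"]),
        test_ids=tuple(d["test_ids"]),
        seed=int(d["seed"]),
        test_fraction=float(d["test_fraction"]),
    )


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV plus a ``.provenance.json`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.X, columns=matrix.feature_ids)
    df.insert(0, "id", matrix.ids)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "feature_ids": matrix.feature_ids,
                "dropped_descriptors": matrix.dropped_descriptors,
            },
            fh,
            indent=2,
        )
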