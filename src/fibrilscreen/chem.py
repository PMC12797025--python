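"""Molecular structure handling: canonicalization, fingerprints, descriptors.

All structure parsing goes through :func:`canonicalize`, which normalises a
SMILES string to the canonical form of its largest covalent fragment (salt
stripping; no charge neutralisation). Fingerprints are binary Morgan
(circular) fingerprints, default radius 3 / 1024 bits. Descriptors are the
RDKit 2D descriptor set — deterministic, conformer-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

# RDKit is chatty about malformed SMILES; we report parse failures ourselves.
RDLogger.DisableLog("rdApp.error")


class RejectedInputError(ValueError):
    """Raised when an operation receives an unparsed molecule."""


@dataclass(frozen=True)
class Molecule:
    """A parsed (or unparsable) molecule.

    ``smiles_canonical`` is the canonical SMILES of the largest covalently
    connected fragment of the input; empty when ``parse_ok`` is False.
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    parse_ok: bool

    def to_rdkit(self) -> Chem.Mol:
        if not self.parse_ok:
            raise RejectedInputError(f"molecule {self.id!r} did not parse")
        return Chem.MolFromSmiles(self.smiles_canonical)


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan fingerprint parameters (radius 3, 1024 bits by default)."""

    radius: int = 3
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")


@dataclass(frozen=True)
class FingerprintBits:
    """Fixed-length binary fingerprint with a cached popcount."""

    bits: np.ndarray  # uint8, shape (n_bits,)
    popcount: int = field(default=-1)

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("bits must be a 1-D binary vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", arr)
        object.__setattr__(self, "popcount", int(arr.sum()))

    def __len__(self) -> int:
        return self.bits.shape[0]

    def on_bits(self) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.bits))


@dataclass(frozen=True)
class DescriptorVector:
    """Named 2D descriptor values with a per-entry validity mask."""

    names: tuple[str, ...]
    values: np.ndarray  # float64; NaN where missing
    missing_mask: np.ndarray  # bool; True where not computable/finite

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def canonicalize(smiles: str, id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    On success the canonical SMILES of the largest covalent fragment is
    stored (counted by heavy atoms; ties broken by canonical-SMILES order
    for determinism). Unparsable input yields ``parse_ok=False`` and a
    logged warning — never an exception — so batch loaders can count and
    skip bad records.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("smiles must be a non-empty string")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        logger.warning("unparsable SMILES%s: %r", f" for {id!r}" if id else "", smiles)
        return Molecule(id=id, smiles_input=smiles, smiles_canonical="", parse_ok=False)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        frags = sorted(
            frags,
            key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
            reverse=True,
        )
        mol = frags[0]
    return Molecule(
        id=id,
        smiles_input=smiles,
        smiles_canonical=Chem.MolToSmiles(mol),
        parse_ok=True,
    )


def parse_all(
    smiles_list: Iterable[tuple[str, str]],
) -> tuple[list[Molecule], int]:
    """Canonicalize ``(id, smiles)`` pairs; return parsed molecules and the
    count of records skipped because they failed to parse."""
    parsed: list[Molecule] = []
    n_failed = 0
    for mol_id, smi in smiles_list:
        m = canonicalize(smi, id=mol_id)
        if m.parse_ok:
            parsed.append(m)
        else:
            n_failed += 1
    if n_failed:
        logger.warning("skipped %d unparsable record(s)", n_failed)
    return parsed, n_failed


@lru_cache(maxsize=200_000)
def _fp_onbits(smiles_canonical: str, radius: int, n_bits: int) -> tuple[int, ...]:
    gen = _morgan_generator(radius, n_bits)
    mol = Chem.MolFromSmiles(smiles_canonical)
    bv = gen.GetFingerprint(mol)
    return tuple(bv.GetOnBits())


@lru_cache(maxsize=32)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def morgan_fingerprint(
    mol: Molecule, cfg: FingerprintConfig = FingerprintConfig()
) -> FingerprintBits:
    """Binary Morgan fingerprint of a parsed molecule.

    Deterministic: identical canonical structures give bitwise-identical
    fingerprints regardless of input SMILES spelling.
    """
    if not mol.parse_ok:
        raise RejectedInputError(f"molecule {mol.id!r} did not parse")
    bits = np.zeros(cfg.n_bits, dtype=np.uint8)
    on = _fp_onbits(mol.smiles_canonical, cfg.radius, cfg.n_bits)
    bits[list(on)] = 1
    return FingerprintBits(bits=bits)


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b|.

    Defined as 0.0 for two all-zero vectors (maximal dissimilarity is the
    conservative screening convention). Symmetric by construction.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = a.popcount + b.popcount - inter
    if union == 0:
        return 0.0
    return inter / union


_DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in Descriptors._descList)


def descriptor_names() -> tuple[str, ...]:
    """Names of the 2D descriptor set, in fixed computation order."""
    return _DESCRIPTOR_NAMES


@lru_cache(maxsize=100_000)
def _descriptor_values(smiles_canonical: str) -> tuple[float, ...]:
    mol = Chem.MolFromSmiles(smiles_canonical)
    vals = []
    for _name, fn in Descriptors._descList:
        try:
            v = fn(mol)
        except Exception:  # descriptor undefined for this molecule
            v = math.nan
        if v is None or not isinstance(v, (int, float)) or not math.isfinite(v):
            v = math.nan
        vals.append(float(v))
    return tuple(vals)


def compute_descriptors(mol: Molecule) -> DescriptorVector:
    """2D physicochemical/topological descriptors for a parsed molecule.

    Non-computable or non-finite entries are flagged missing (NaN), never
    silently zeroed. The name set is identical for every molecule.
    """
    if not mol.parse_ok:
        raise RejectedInputError(f"molecule {mol.id!r} did not parse")
    values = np.array(_descriptor_values(mol.smiles_canonical), dtype=np.float64)
    return DescriptorVector(
        names=_DESCRIPTOR_NAMES,
        values=values,
        missing_mask=~np.isfinite(values),
    )


@dataclass
class FeatureMatrix:
    """Compounds × features with per-column provenance.

    Columns are a fingerprint-bit block (``fp:<index>``, binary, unscaled)
    followed by surviving descriptor columns (``desc:<name>``, z-scored
    with training-row statistics).
    """

    ids: list[str]
    X: np.ndarray  # float64, shape (n, n_features)
    feature_ids: list[str]
    dropped_descriptors: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def column_block(self, prefix: str) -> np.ndarray:
        cols = [i for i, f in enumerate(self.feature_ids) if f.startswith(prefix)]
        return self.X[:, cols]


class Featurizer:
    """Fingerprint + descriptor featurization with train-only statistics.

    ``fit`` decides which descriptor columns survive (no missing/non-finite
    value across the fitting set, non-zero variance not required) and
    records their mean/sd; ``transform`` builds the combined matrix for any
    molecule list. Fingerprint bits are left unscaled.
    """

    def __init__(self, cfg: FingerprintConfig = FingerprintConfig()):
        self.cfg = cfg
        self.kept_descriptors_: list[str] | None = None
        self.dropped_descriptors_: list[str] = []
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    def _raw_blocks(self, mols: Sequence[Molecule]) -> tuple[np.ndarray, np.ndarray]:
        if not mols:
            raise ValueError("empty compound list")
        fps = np.stack([morgan_fingerprint(m, self.cfg).bits for m in mols]).astype(
            np.float64
        )
        desc = np.stack([compute_descriptors(m).values for m in mols])
        return fps, desc

    def fit(self, mols: Sequence[Molecule]) -> "Featurizer":
        _fps, desc = self._raw_blocks(mols)
        finite = np.isfinite(desc).all(axis=0)
        names = descriptor_names()
        self.kept_descriptors_ = [n for n, ok in zip(names, finite) if ok]
        self.dropped_descriptors_ = [n for n, ok in zip(names, finite) if not ok]
        kept = desc[:, finite]
        self.means_ = kept.mean(axis=0)
        sds = kept.std(axis=0, ddof=0)
        # constant columns: sd 1 so z-scoring maps them to exactly 0
        self.sds_ = np.where(sds > 0, sds, 1.0)
        self._kept_index = np.flatnonzero(finite)
        return self

    def transform(self, mols: Sequence[Molecule]) -> FeatureMatrix:
        if self.kept_descriptors_ is None:
            raise RuntimeError("Featurizer.fit must be called before transform")
        fps, desc = self._raw_blocks(mols)
        kept = desc[:, self._kept_index]
        z = (kept - self.means_) / self.sds_
        # entries missing at transform time (column survived fit) -> 0 after
        # scaling, i.e. imputed at the training mean
        z = np.where(np.isfinite(z), z, 0.0)
        X = np.hstack([fps, z])
        feature_ids = [f"fp:{i}" for i in range(self.cfg.n_bits)] + [
            f"desc:{n}" for n in self.kept_descriptors_
        ]
        return FeatureMatrix(
            ids=[m.id for m in mols],
            X=X,
            feature_ids=feature_ids,
            dropped_descriptors=list(self.dropped_descriptors_),
        )


def build_feature_matrix(
    compounds: Sequence[Molecule],
    cfg: FingerprintConfig = FingerprintConfig(),
    fit_rows: Sequence[int] | None = None,
) -> FeatureMatrix:
    """One-shot featurization.

    Descriptor survival and standardisation statistics are computed from
    ``fit_rows`` (default: all rows); the returned matrix covers all
    compounds. For leak-free train/test work use :class:`Featurizer`
    directly with separate fit/transform calls.
    """
    if not compounds:
        raise ValueError("empty compound list")
    bad = [m.id for m in compounds if not m.parse_ok]
    if bad:
        raise RejectedInputError(f"unparsed molecules in input: {bad[:5]}")
    featurizer = Featurizer(cfg)
    fit_mols = compounds if fit_rows is None else [compounds[i] for i in fit_rows]
    featurizer.fit(fit_mols)
    return featurizer.transform(compounds)
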