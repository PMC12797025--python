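"""Synthetic scaffold-decorated compound libraries with latent affinity.

Three chemotype streams (V, M, Z) are built by decorating per-chemotype
core scaffold templates with substituents at two attachment points; an
"alternative" stream (A) uses unrelated aliphatic/heterocyclic templates.
A hidden per-chemotype pharmacophore fingerprint drives affinity:

    log10(Ki / nM) = intercept − slope · Tanimoto(fp(mol), pharmacophore) + ε

with ε ~ Normal(0, noise_sd). Records whose Ki exceeds the censor limit
are recorded as censored "no binding" outcomes. Study datasets are
calibrated so the realized binder fraction at the labeling threshold
matches the configured target (per chemotype, by a deterministic quantile
shift of the raw log-affinities).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from fibrilscreen.chem import (
    FingerprintBits,
    FingerprintConfig,
    Molecule,
    canonicalize,
    morgan_fingerprint,
    tanimoto,
)
from fibrilscreen.labeling import (
    BindingMeasurement,
    CompoundRecord,
    LabelingConfig,
)
from fibrilscreen.labeling import _largest_remainder  # shared rounding rule

# Core scaffold templates per chemotype. Slots {R0}/{R1} take substituent
# SMILES fragments. Chemically valid decoration is the only claim made for
# these structures; they resemble aryl-heteroaryl cores without being any
# particular published ligand.
SCAFFOLD_TEMPLATES: dict[str, tuple[str, ...]] = {
    "V": (
        "c1cc({R0})ccc1-c1nc2ccc({R1})cc2s1",
        "c1cc({R0})ccc1C(=O)Nc1ccc({R1})cc1",
        "c1cc({R0})ccc1-c1noc(-c2ccc({R1})cc2)n1",
    ),
    "M": (
        "c1cc({R0})ccc1/C=C/c1cc2cc({R1})ccc2o1",
        "c1cc({R0})ccc1/C=C/c1ccc({R1})cn1",
        "c1cc({R0})ccc1CCc1ccc({R1})cc1",
    ),
    "Z": (
        "c1cc({R0})ccc1-c1nc2cc({R1})ccc2o1",
        "c1cc({R0})ccc1-c1cc2cc({R1})ccc2[nH]1",
        "c1cc({R0})ccc1N1CCN(c2ccc({R1})cc2)CC1",
    ),
    "A": (
        "C1CCN(C(=O)C({R0})CC{R1})CC1",
        "O=C(NC1CCCCC1)C({R0})N({R1})C",
        "OC1CCC(N({R0})CC{R1})CC1",
        "O=S(=O)(N1CCOCC1)C({R0})C{R1}",
    ),
}

SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "F", "Cl", "Br", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "C#N", "C(F)(F)F", "CO", "CCO", "SC", "C=C", "OC(C)C", "CN",
    "CCN", "I", "CF", "[H]",
)

# Decorations used for the hidden pharmacophore parent of each chemotype.
PARENT_DECORATIONS: dict[str, tuple[str, str]] = {
    "V": ("N(C)C", "O"),
    "M": ("N(C)C", "O"),
    "Z": ("N(C)C", "O"),
}

# The latent pharmacophore is a shared substituent environment (a
# dimethylaniline moiety), not any whole parent molecule. Compounds
# carrying it span all core templates of a chemotype, so actives are
# mutually diverse in whole-molecule similarity — the property that makes
# a max-similarity baseline beatable — while the fragment's fingerprint
# bits remain a learnable signal.
PHARMACOPHORE_R0 = "N(C)C"
PHARMACOPHORE_FRAGMENT_SMILES = "CN(C)c1ccccc1"

STUDY_CLASSES = ("V", "M", "Z")


def reference_smiles() -> dict[str, str]:
    """Documented placeholder reference structures, one per chemotype.

    These stand in for user-supplied reference ligand SMILES in tests and
    demonstrations.
    """
    return {
        c: SCAFFOLD_TEMPLATES[c][0].format(
            R0=PARENT_DECORATIONS[c][0], R1=PARENT_DECORATIONS[c][1]
        )
        for c in STUDY_CLASSES
    }


@dataclass(frozen=True)
class LatentAffinityModel:
    """Hidden structure→affinity map for one chemotype."""

    pharmacophore_fp: Optional[FingerprintBits] = None
    intercept_log10Ki: float = 3.0
    slope_per_similarity: float = 2.5
    noise_sd_log10: float = 0.05

    def __post_init__(self) -> None:
        if self.slope_per_similarity < 0:
            raise ValueError("slope must be non-negative")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    n_compounds: int = 315
    class_proportions: tuple[float, float, float] = (138 / 315, 121 / 315, 56 / 315)
    target_binder_fraction: float = 0.20
    binder_threshold_nM: float = 25.0
    censor_limit_nM: float = 1000.0
    alt_fraction: float = 0.0  # extra "alternative" stream for libraries
    analog_fraction: float = 0.20  # share of each class drawn near the parent
    latent: LatentAffinityModel = field(default_factory=LatentAffinityModel)
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not (0 < self.target_binder_fraction < 1):
            raise ValueError("target_binder_fraction must be in (0, 1)")
        if not (0 <= self.alt_fraction < 1):
            raise ValueError("alt_fraction must be in [0, 1)")


def _class_counts(cfg: SyntheticConfig) -> dict[str, int]:
    n_alt = int(round(cfg.n_compounds * cfg.alt_fraction))
    n_classes = cfg.n_compounds - n_alt
    quotas = [p * n_classes for p in cfg.class_proportions]
    counts = _largest_remainder(quotas, n_classes)
    out = dict(zip(STUDY_CLASSES, counts))
    if n_alt:
        out["A"] = n_alt
    return out


def _decorate(
    chemotype: str,
    count: int,
    rng: np.random.Generator,
    analog_fraction: float = 0.0,
) -> list[Molecule]:
    """Sample ``count`` unique decorated molecules for one chemotype.

    An ``analog_fraction`` share carries the pharmacophore decoration
    (R0 = dimethylamino) on any template; the rest is drawn from the
    remaining template×substituent space. No combination is used twice.
    """
    templates = SCAFFOLD_TEMPLATES[chemotype]
    n_subs = len(SUBSTITUENTS)
    total = len(templates) * n_subs * n_subs
    if count > total:
        raise ValueError(
            f"chemotype {chemotype}: requested {count} compounds but only "
            f"{total} template×substituent combinations exist"
        )
    analog_flat = np.array([], dtype=int)
    if chemotype in PARENT_DECORATIONS and analog_fraction > 0:
        i0 = SUBSTITUENTS.index(PHARMACOPHORE_R0)
        analog_space = np.array(
            [
                (t * n_subs + i0) * n_subs + j
                for t in range(len(templates))
                for j in range(n_subs)
            ]
        )
        n_analog = min(int(round(count * analog_fraction)), analog_space.size)
        analog_flat = rng.choice(analog_space, size=n_analog, replace=False)
        excluded = analog_space  # diverse stream never carries the pharmacophore
    else:
        excluded = analog_flat
    rest_space = np.setdiff1d(np.arange(total), excluded)
    n_rest = count - analog_flat.size
    rest_flat = rng.choice(rest_space, size=n_rest, replace=False)
    picks = np.concatenate([analog_flat, rest_flat])
    mols = []
    for rank, flat in enumerate(sorted(int(p) for p in picks)):
        t, rem = divmod(flat, n_subs * n_subs)
        i, j = divmod(rem, n_subs)
        smi = templates[t].format(R0=SUBSTITUENTS[i], R1=SUBSTITUENTS[j])
        mol = canonicalize(smi, id=f"{chemotype}{rank:05d}")
        if not mol.parse_ok:  # templates are pre-validated; guard anyway
            raise RuntimeError(f"generated invalid SMILES: {smi}")
        mols.append(mol)
    return mols


def generate_library(cfg: SyntheticConfig) -> list[tuple[Molecule, str]]:
    """Generate a scaffold-structured library of ``(molecule, chemotype)``.

    V/M/Z streams decorate the chemotype cores; the A stream (size set by
    ``alt_fraction``) uses unrelated templates. Deterministic given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[Molecule, str]] = []
    for chemotype, count in _class_counts(cfg).items():
        frac = cfg.analog_fraction if chemotype in PARENT_DECORATIONS else 0.0
        for mol in _decorate(chemotype, count, rng, frac):
            out.append((mol, chemotype))
    return out


def pharmacophores(cfg: SyntheticConfig) -> dict[str, FingerprintBits]:
    """Hidden per-chemotype pharmacophore fingerprints.

    Defaults to the shared fragment pattern; a configured fingerprint
    overrides it for all chemotypes.
    """
    if cfg.latent.pharmacophore_fp is not None:
        return {c: cfg.latent.pharmacophore_fp for c in STUDY_CLASSES}
    frag = morgan_fingerprint(
        canonicalize(PHARMACOPHORE_FRAGMENT_SMILES), cfg.fingerprint
    )
    return {c: frag for c in STUDY_CLASSES}


def assign_ground_truth_ki(
    mol: Molecule,
    model: LatentAffinityModel,
    seed: int,
    censor_limit_nM: float = 1000.0,
) -> BindingMeasurement:
    """Closed-form latent affinity for one molecule.

    ``log10(Ki) = intercept − slope·similarity + Normal(0, noise_sd)``;
    Ki above the censor limit becomes a censored "no binding" record.
    """
    if model.pharmacophore_fp is None:
        raise ValueError("latent model needs a pharmacophore fingerprint")
    fp = morgan_fingerprint(mol)
    sim = tanimoto(fp, model.pharmacophore_fp)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, model.noise_sd_log10) if model.noise_sd_log10 > 0 else 0.0
    log10ki = (
        model.intercept_log10Ki - model.slope_per_similarity * sim + noise
    )
    ki = 10.0 ** log10ki
    if ki > censor_limit_nM:
        return BindingMeasurement(ki_nM=None, censored_no_binding=True)
    return BindingMeasurement(ki_nM=ki)


def make_study_dataset(
    cfg: SyntheticConfig = SyntheticConfig(),
    labeling: Optional[LabelingConfig] = None,
    return_shifts: bool = False,
):
    """A labeled study-shaped dataset: chemotype counts in the configured
    proportions (largest-remainder rounding), latent Ki, binder labels.

    Raw log-affinities within each chemotype are shifted by a deterministic
    quantile offset so the fraction below the binder threshold matches
    ``target_binder_fraction``; with slope 0 this reduces labels to seeded
    noise at the target rate, destroying any structure→label association.
    """
    labeling = labeling or LabelingConfig(
        binder_threshold_nM=cfg.binder_threshold_nM,
        censor_limit_nM=cfg.censor_limit_nM,
    )
    rng = np.random.default_rng(cfg.seed)
    study_cfg = replace(cfg, alt_fraction=0.0)
    library = generate_library(study_cfg)
    parents = pharmacophores(cfg)

    records: list[CompoundRecord] = []
    shifts: dict[str, float] = {}
    log_thr = math.log10(cfg.binder_threshold_nM)
    for chemotype in STUDY_CLASSES:
        members = [m for m, c in library if c == chemotype]
        if not members:
            continue
        sims = np.array(
            [
                tanimoto(morgan_fingerprint(m, cfg.fingerprint), parents[chemotype])
                for m in members
            ]
        )
        noise = rng.normal(0.0, cfg.latent.noise_sd_log10, size=len(members))
        raw = (
            cfg.latent.intercept_log10Ki
            - cfg.latent.slope_per_similarity * sims
            + noise
        )
        # quantile calibration: realized binder fraction ≈ target
        shift = log_thr - np.quantile(raw, cfg.target_binder_fraction)
        shifts[chemotype] = float(shift)
        log10ki = raw + shift
        for mol, lk in zip(members, log10ki):
            ki = 10.0 ** lk
            if ki > cfg.censor_limit_nM:
                meas = BindingMeasurement(ki_nM=None, censored_no_binding=True)
            else:
                meas = BindingMeasurement(ki_nM=float(ki))
            records.append(
                CompoundRecord(
                    molecule=mol, measurement=meas, chemotype_tag=chemotype
                ).with_label(labeling)
            )
    if return_shifts:
        return records, shifts
    return records


def measure_library(
    molecules: Sequence[tuple[Molecule, str]],
    cfg: SyntheticConfig,
    shifts: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
) -> list[CompoundRecord]:
    """Latent-model 'wet lab': measure Ki for arbitrary library molecules.

    Alternative-stream compounds use their maximum similarity over the
    three pharmacophores. ``shifts`` (from :func:`make_study_dataset`)
    put the measurements on the same calibrated scale as the study data.
    """
    parents = pharmacophores(cfg)
    shifts = shifts or {}
    mean_shift = float(np.mean(list(shifts.values()))) if shifts else 0.0
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labeling = LabelingConfig(
        binder_threshold_nM=cfg.binder_threshold_nM,
        censor_limit_nM=cfg.censor_limit_nM,
    )
    records = []
    for mol, chemotype in molecules:
        fp = morgan_fingerprint(mol, cfg.fingerprint)
        if chemotype in parents:
            sim = tanimoto(fp, parents[chemotype])
            shift = shifts.get(chemotype, 0.0)
        else:
            sim = max(tanimoto(fp, p) for p in parents.values())
            shift = mean_shift
        noise = rng.normal(0.0, cfg.latent.noise_sd_log10)
        lk = (
            cfg.latent.intercept_log10Ki
            - cfg.latent.slope_per_similarity * sim
            + noise
            + shift
        )
        ki = 10.0 ** lk
        if ki > cfg.censor_limit_nM:
            meas = BindingMeasurement(ki_nM=None, censored_no_binding=True)
        else:
            meas = BindingMeasurement(ki_nM=float(ki))
        records.append(
            CompoundRecord(
                molecule=mol, measurement=meas, chemotype_tag=None
            ).with_label(labeling)
        )
    return records


def realized_binder_fraction(records: Sequence[CompoundRecord]) -> float:
    from fibrilscreen.labeling import BINDER

    return sum(1 for r in records if r.binder_label == BINDER) / len(records)
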