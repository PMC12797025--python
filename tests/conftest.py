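import numpy as np
import pytest

from fibrilscreen import simulate
from fibrilscreen.chem import Featurizer, FingerprintBits, Molecule, canonicalize
from fibrilscreen.labeling import (
    BINDER,
    NON_BINDER,
    BindingMeasurement,
    CompoundRecord,
    stratified_split,
)


def bits(*on, n=16) -> FingerprintBits:
    v = np.zeros(n, dtype=np.uint8)
    v[list(on)] = 1
    return FingerprintBits(bits=v)


@pytest.fixture(scope="session")
def study_records():
    """Default synthetic study dataset (n=315, seed 0)."""
    return simulate.make_study_dataset(simulate.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_split(study_records):
    split = stratified_split(study_records, 44 / 315, seed=0)
    by_id = {r.id: r for r in study_records}
    train = [by_id[i] for i in split.train_ids]
    test = [by_id[i] for i in split.test_ids]
    return train, test


@pytest.fixture(scope="session")
def small_matrices(small_split):
    train, test = small_split
    featurizer = Featurizer()
    featurizer.fit([r.molecule for r in train])
    return (
        featurizer.transform([r.molecule for r in train]),
        featurizer.transform([r.molecule for r in test]),
        train,
        test,
    )


def dummy_record(rid: str, ki=None, censored=False, label=None) -> CompoundRecord:
    """A record with a placeholder molecule, for label/split logic tests."""
    mol = Molecule(id=rid, smiles_input="C", smiles_canonical="C", parse_ok=True)
    rec = CompoundRecord(
        molecule=mol,
        measurement=BindingMeasurement(ki_nM=ki, censored_no_binding=censored),
    )
    if label is None:
        return rec.with_label()
    return CompoundRecord(
        molecule=mol, measurement=rec.measurement, binder_label=label
    )


@pytest.fixture()
def ethanol():
    return canonicalize("CCO", id="ethanol")
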