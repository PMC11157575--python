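import pytest

from cypsom import fixtures as fx
from cypsom.chem import record_from_smiles


@pytest.fixture(scope="session")
def planted_dataset():
    """80 synthetic molecules with the planted 'every sulfur atom is a SOM'
    rule on 3A4, noise-free."""
    mols = fx.make_molecules(80, seed=101)
    return fx.plant_soms(mols, fx.builtin_rule("sulfur_atoms"), "3A4", seed=102)


@pytest.fixture()
def ethanol():
    # atoms: C0, C1, O2
    return record_from_smiles("CCO", "ethanol")


@pytest.fixture()
def toluene():
    # atoms: C0 (methyl), ring C1..C6
    return record_from_smiles("Cc1ccccc1", "toluene")


@pytest.fixture()
def benzene():
    return record_from_smiles("c1ccccc1", "benzene")
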