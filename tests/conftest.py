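import pytest

from qsarscreen.molecules import mol_from_smiles

# Small fixture set spanning chains, rings, fused rings and heteroatoms;
# all have <= 12 heavy atoms so brute-force graph oracles stay cheap.
FIXTURE_SMILES = {
    "ethane": "CC",
    "propane": "CCC",
    "isobutane": "CC(C)C",
    "cyclohexane": "C1CCCCC1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "ethanol": "CCO",
    "acetic_acid": "CC(=O)O",
    "acetamide": "CC(=O)N",
    "aniline": "Nc1ccccc1",
    "pyridine": "c1ccncc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "benzenesulfonamide": "NS(=O)(=O)c1ccccc1",
    "acetohydroxamic_acid": "CC(=O)NO",
}


@pytest.fixture(scope="session")
def fixture_molecules():
    return {name: mol_from_smiles(smi, mol_id=name) for name, smi in FIXTURE_SMILES.items()}
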