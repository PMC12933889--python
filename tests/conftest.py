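"""Shared fixtures: reference molecules, toy crystals, and the hand-counted
descriptor oracle table."""

import warnings

import numpy as np
import pytest
from rdkit import RDLogger

import npfrag as nf

RDLogger.DisableLog("rdApp.*")
warnings.filterwarnings("ignore", category=UserWarning)

# ---------------------------------------------------------------------------
# Hand-counted descriptor oracle: 50 small molecules (<= 12 heavy atoms),
# columns (fsp3, fc_stereo, nar, hbd, hba, nrb).  Counts derived by hand from
# the definitions: fsp3 = sp3 carbons / all carbons; fc_stereo = stereogenic
# carbons (assigned or potential) / all carbons; nar = aromatic rings in the
# smallest ring basis; hbd = N/O atoms bearing >= 1 H; hba = N/O acceptor
# atoms with a lone pair (pyrrole-type N excluded); nrb = non-ring single
# bonds between two non-terminal heavy atoms, bonds to triple-bond carbons
# excluded.  Molecules whose acceptor counts depend on contested definitional
# edge cases (carboxyl-group collapsing, thioether acceptors) are deliberately
# not part of this exact-count suite.
DESCRIPTOR_ORACLE = {
    "C": (1, 0, 0, 0, 0, 0),
    "CC": (1, 0, 0, 0, 0, 0),
    "CCC": (1, 0, 0, 0, 0, 0),
    "CCCC": (1, 0, 0, 0, 0, 1),
    "CCCCC": (1, 0, 0, 0, 0, 2),
    "CCCCCC": (1, 0, 0, 0, 0, 3),
    "C=C": (0, 0, 0, 0, 0, 0),
    "C#C": (0, 0, 0, 0, 0, 0),
    "CC=C": (1 / 3, 0, 0, 0, 0, 0),
    "C/C=C/C": (1 / 2, 0, 0, 0, 0, 0),
    "CC(C)C": (1, 0, 0, 0, 0, 0),
    "CC(C)(C)C": (1, 0, 0, 0, 0, 0),
    "c1ccccc1": (0, 0, 1, 0, 0, 0),
    "Cc1ccccc1": (1 / 7, 0, 1, 0, 0, 0),
    "CCc1ccccc1": (1 / 4, 0, 1, 0, 0, 1),
    "c1ccncc1": (0, 0, 1, 0, 1, 0),
    "c1ccc2ccccc2c1": (0, 0, 2, 0, 0, 0),
    "c1ccc(-c2ccccc2)cc1": (0, 0, 2, 0, 0, 1),
    "C1CCCCC1": (1, 0, 0, 0, 0, 0),
    "C1CCCC1": (1, 0, 0, 0, 0, 0),
    "C1CC1": (1, 0, 0, 0, 0, 0),
    "C1=CCC=C1": (1 / 5, 0, 0, 0, 0, 0),
    "CO": (1, 0, 0, 1, 1, 0),
    "CCO": (1, 0, 0, 1, 1, 0),
    "CCCO": (1, 0, 0, 1, 1, 1),
    "COC": (1, 0, 0, 0, 1, 0),
    "CCOC": (1, 0, 0, 0, 1, 1),
    "OCC(O)CO": (1, 0, 0, 3, 3, 2),
    "CC(=O)C": (2 / 3, 0, 0, 0, 1, 0),
    "C=O": (0, 0, 0, 0, 1, 0),
    "CN": (1, 0, 0, 1, 1, 0),
    "CCN": (1, 0, 0, 1, 1, 0),
    "CNC": (1, 0, 0, 1, 1, 0),
    "CN(C)C": (1, 0, 0, 0, 1, 0),
    "CC#N": (1 / 2, 0, 0, 0, 1, 0),
    "CCCC#N": (3 / 4, 0, 0, 0, 1, 1),
    "N#Cc1ccccc1": (0, 0, 1, 0, 1, 0),
    "CCl": (1, 0, 0, 0, 0, 0),
    "CC(F)(F)F": (1, 0, 0, 0, 0, 0),
    "C1CCOC1": (1, 0, 0, 0, 1, 0),
    "C1CCNCC1": (1, 0, 0, 1, 1, 0),
    "C1COCCO1": (1, 0, 0, 0, 2, 0),
    "c1ccoc1": (0, 0, 1, 0, 1, 0),
    "c1cc[nH]c1": (0, 0, 1, 1, 0, 0),
    "Oc1ccccc1": (0, 0, 1, 1, 1, 0),
    "Nc1ccccc1": (0, 0, 1, 1, 1, 0),
    "Fc1ccccc1": (0, 0, 1, 0, 0, 0),
    "C[C@@H](O)CC": (1, 1 / 4, 0, 1, 1, 1),
    "C[C@H](Cl)Br": (1, 1 / 2, 0, 0, 0, 0),
    "C[C@H]1CCCC[C@@H]1C": (1, 1 / 4, 0, 0, 0, 0),
}


@pytest.fixture(scope="session")
def descriptor_oracle():
    return DESCRIPTOR_ORACLE


@pytest.fixture(scope="session")
def references():
    return nf.reference_fixtures()


@pytest.fixture(scope="session")
def toy_crystal(tmp_path_factory):
    """Default toy crystal, written to PDB and re-read through the parser."""
    crystal = nf.generate_toy_crystal()
    path = tmp_path_factory.mktemp("crystal") / "toy.pdb"
    crystal.write_pdb(path)
    model = nf.load_structure(path)
    return crystal, model


@pytest.fixture(scope="session")
def mirror_crystal(tmp_path_factory):
    crystal = nf.generate_toy_crystal(nf.mirror_interface_layout())
    path = tmp_path_factory.mktemp("crystal") / "mirror.pdb"
    crystal.write_pdb(path)
    model = nf.load_structure(path)
    return crystal, model


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
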