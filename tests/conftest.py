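import numpy as np
import pytest

from lidtraj import generate_toy_complex


THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  O   HOH A   2       9.125  -4.250   0.375  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def toy_complex():
    """Default two-domain pseudo-atom complex (30 core / 10 lid / 7 peptide)."""
    return generate_toy_complex()


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three_atoms.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
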