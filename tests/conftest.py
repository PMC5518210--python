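import numpy as np
import pytest

from serpinmap import synthetic_data as sd


@pytest.fixture(scope="session")
def helix():
    return sd.make_helix(20)


@pytest.fixture(scope="session")
def bundle():
    return sd.make_two_helix_bundle()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.300   1.500   0.200  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.950   2.800   0.300  1.00  0.00           C
ATOM      8  C   GLY A   2       5.400   2.700   0.700  1.00  0.00           C
ATOM      9  O   GLY A   2       5.900   1.600   0.900  1.00  0.00           O
END
"""

DUPLICATE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   1       3.300   1.500   0.200  1.00  0.00           N
ATOM      4  CA  GLY A   1       3.950   2.800   0.300  1.00  0.00           C
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture()
def duplicate_residue_pdb(tmp_path):
    path = tmp_path / "duplicate.pdb"
    path.write_text(DUPLICATE_RESIDUE_PDB)
    return path
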