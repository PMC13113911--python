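import numpy as np
import pytest

import chirobiophore as cb
from chirobiophore.synthetic import HelixSpec, make_bundle, make_helix

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  H   ALA A   1       1.800  -0.800   0.500  1.00  0.00           H
ATOM      5  N   ALA A   2       3.300   1.500   0.200  1.00  0.00           N
ATOM      6  CA AALA A   2       4.200   2.600   0.300  0.40  0.00           C
ATOM      7  CA BALA A   2       4.250   2.650   0.350  0.60  0.00           C
ATOM      8  C   ALA A   2       5.600   2.200   0.700  1.00  0.00           C
ATOM      9  N   ALA A   3       6.500   3.200   0.800  1.00  0.00           N
ATOM     10  CA  ALA A   3       7.900   2.900   1.100  1.00  0.00           C
ATOM     11  C   ALA A   3       8.700   4.200   1.300  1.00  0.00           C
HETATM   12  O   HOH A   4       9.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture(scope="session")
def decorated_bundle():
    """Four-helix splayed bundle with chiral side-chain decorations; all
    six descriptors are computable on it."""
    s = make_bundle(4, 30.0, [1, 1, -1, 1], seed=11, decorations=True,
                    noise_sd=0.04)
    return cb.infer_bonds(s)


@pytest.fixture(scope="session")
def ideal_right_helix():
    return make_helix(HelixSpec(30))


@pytest.fixture(scope="session")
def reference_matrix():
    return cb.load_reference_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
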