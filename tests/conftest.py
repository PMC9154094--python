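"""Shared fixtures: tiny hand-written PDB snippets and cached synthetic pockets."""

import numpy as np
import pytest

from bridgewater import FixtureSpec, PlacementParams
from bridgewater.synthetic import generate_calibration_complex, generate_complex

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  C1  LIG A   2       4.000   0.000   0.000  1.00  0.00           C
HETATM    3  O   HOH A   3       2.000   2.000   0.000  1.00  0.00           O
END
"""

# one GLY residue: backbone N, CA, C, O
BACKBONE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
HETATM    5  C1  LIG B   1       5.000   5.000   0.000  1.00  0.00           C
HETATM    6  O1  LIG B   1       6.200   5.500   0.000  1.00  0.00           O
HETATM    7  O2  LIG B   1       4.100   6.000   1.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def pocket_fixture():
    """One planted bridging site, one decoy; validated at default params."""
    return generate_complex(FixtureSpec(seed=11, n_planted_sites=1, n_decoy_waters=1))


@pytest.fixture(scope="session")
def two_site_fixture():
    return generate_complex(FixtureSpec(seed=5, n_planted_sites=2, n_decoy_waters=3))


@pytest.fixture(scope="session")
def calibration_fixture():
    return generate_calibration_complex(seed=0)


@pytest.fixture(scope="session")
def default_params():
    return PlacementParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
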