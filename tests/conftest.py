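import numpy as np
import pytest

from knotfold.synthetic import CurveSpec, make_curve


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.936  1.00  0.00           C
ATOM      4  CA  ALA A   2      14.000   7.500  -2.500  1.00  0.00           C
ATOM      5  CA  ALA A   3      16.500   8.000   0.200  1.00  0.00           C
END
"""

# chain with an altloc pair (B has higher occupancy) and a numbering gap
ALTLOC_GAP_PDB = """\
ATOM      1  CA AALA A   5       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   5       9.000   9.000   9.000  0.60  0.00           C
ATOM      3  CA  ALA A   6       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   9       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  CA  GLY B  -3       0.000   5.000   0.000  1.00  0.00           C
ATOM      6  CA  GLY B  -2       3.800   5.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def trefoil_curve():
    return make_curve(CurveSpec(kind="trefoil", n_vertices=200, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
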