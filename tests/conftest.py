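import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from foldcritic.structure_io import ProteinStructure
from foldcritic.synthetic import make_toy_native


THREE_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.750  -1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.970   2.840   0.100  1.00  0.00           C
ATOM      8  C   GLY A   2       5.480   2.700   0.200  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.600   0.250  1.00  0.00           O
ATOM     10  N   SER A   3       6.170   3.840   0.230  1.00  0.00           N
ATOM     11  CA  SER A   3       7.620   3.880   0.330  1.00  0.00           C
ATOM     12  C   SER A   3       8.200   5.290   0.380  1.00  0.00           C
ATOM     13  O   SER A   3       7.470   6.280   0.360  1.00  0.00           O
ATOM     14  CB  SER A   3       8.220   3.120   1.520  1.00  0.00           C
TER      15      SER A   3
END
"""


@pytest.fixture
def three_res_pdb() -> str:
    return THREE_RES_PDB


@pytest.fixture(scope="session")
def helix20() -> ProteinStructure:
    return make_toy_native(20, "helix", seed=0)


@pytest.fixture(scope="session")
def hairpin40() -> ProteinStructure:
    return make_toy_native(40, "helix_hairpin", seed=1)


def ca_only_structure(ca: np.ndarray, sequence: str | None = None) -> ProteinStructure:
    """Build a CA-trace ProteinStructure from an (L, 3) array."""
    L = len(ca)
    coords = np.full((L, 5, 3), np.nan)
    coords[:, 1, :] = ca
    mask = np.zeros((L, 5), dtype=bool)
    mask[:, 1] = True
    return ProteinStructure(np.arange(L), sequence or "A" * L, coords, mask)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans


def apply_rigid(structure: ProteinStructure, rot: np.ndarray,
                trans: np.ndarray) -> ProteinStructure:
    out = structure.copy()
    moved = out.coords @ rot.T + trans
    out.coords = np.where(out.atom_mask[:, :, None], moved, out.coords)
    return out
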