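import numpy as np
import pytest

from pkfunnel.fixtures import FixtureSpec, make_toy_complex
from pkfunnel.graphs import EmbeddingProvider, build_pocket_graph, extract_pocket, ligand_graph_from_smiles


@pytest.fixture
def provider():
    return EmbeddingProvider(seed=0)


@pytest.fixture
def toy_complex():
    return make_toy_complex(FixtureSpec(seed=7, n_residues=20))


@pytest.fixture
def small_pair(toy_complex, provider):
    """A (pocket graph, ligand graph) pair at toy scale for scoring tests."""
    sel = extract_pocket(toy_complex.structure, 0.8)
    pocket = build_pocket_graph(sel, provider)
    ligand = ligand_graph_from_smiles("CC(=O)Nc1ccccc1")
    return pocket, ligand


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.989   2.839   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.500   2.700   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.200   3.830   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.650   3.870   0.000  1.00  0.00           C
ATOM      9  OG  SER A   3       8.200   5.180   0.000  1.00  0.00           O
HETATM   10  C1  LIG A 101       2.000   0.500   3.000  1.00  0.00           C
HETATM   11  O1  LIG A 101       2.500   1.200   3.800  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb_text():
    return TOY_PDB


def rigid_transform(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Random proper rotation + translation, for invariance tests."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-20, 20, size=3)
    return rot.apply(coords) + shift
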