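"""Graph representations consumed by the scoring models.

Two graphs per protein-ligand pair:

* a **pocket graph** whose nodes are the protein residues within a stated
  distance of the reference ligand's heavy atoms, with an edge between two
  residues whenever their minimum heavy-atom distance is below a contact
  cutoff (default 0.5 nm), and a 30-dimensional embedding per residue built
  by summing chemical-group vectors;
* a **ligand graph** whose nodes are the molecule's heavy atoms with
  one-hot-like features (element class, degree, attached hydrogens, formal
  charge, aromaticity) and whose edges are covalent bonds.

Distance conventions: residue-ligand and residue-residue distances are
minimum heavy-atom to heavy-atom distances (not C-alpha, not centroid).
Cutoffs are given in nm at the API and converted once (see structio).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .structio import Structure, nm_to_angstrom

__all__ = [
    "EMBEDDING_DIM",
    "AMINO_ACID_GROUPS",
    "LIGAND_FEATURE_NAMES",
    "EmbeddingProvider",
    "PocketSelection",
    "PocketGraph",
    "LigandGraph",
    "SmilesParseError",
    "extract_pocket",
    "build_pocket_graph",
    "residue_embedding",
    "ligand_graph_from_smiles",
]

EMBEDDING_DIM = 30

# Chemical-group decomposition of the 20 standard amino acids: a shared
# backbone unit plus side-chain fragments.  Residue vectors are the sums of
# their group vectors, so chemically related residues land near each other
# even under the deterministic fallback table.
AMINO_ACID_GROUPS: dict[str, tuple[str, ...]] = {
    "GLY": ("backbone",),
    "ALA": ("backbone", "methyl"),
    "VAL": ("backbone", "methine", "methyl", "methyl"),
    "LEU": ("backbone", "methylene", "methine", "methyl", "methyl"),
    "ILE": ("backbone", "methine", "methylene", "methyl", "methyl"),
    "PRO": ("backbone", "methylene", "methylene", "methylene"),
    "PHE": ("backbone", "methylene", "phenyl"),
    "TYR": ("backbone", "methylene", "phenol"),
    "TRP": ("backbone", "methylene", "indole"),
    "SER": ("backbone", "methylene", "hydroxyl"),
    "THR": ("backbone", "methine", "methyl", "hydroxyl"),
    "CYS": ("backbone", "methylene", "thiol"),
    "MET": ("backbone", "methylene", "methylene", "thioether", "methyl"),
    "ASN": ("backbone", "methylene", "amide"),
    "GLN": ("backbone", "methylene", "methylene", "amide"),
    "ASP": ("backbone", "methylene", "carboxylate"),
    "GLU": ("backbone", "methylene", "methylene", "carboxylate"),
    "LYS": ("backbone", "methylene", "methylene", "methylene", "methylene", "amine"),
    "ARG": ("backbone", "methylene", "methylene", "methylene", "guanidinium"),
    "HIS": ("backbone", "methylene", "imidazole"),
}


class SmilesParseError(ValueError):
    """Raised when RDKit cannot parse a SMILES string."""


@dataclass
class EmbeddingProvider:
    """Supplies 30-dim chemical-group vectors for residue embeddings.

    ``mode="pretrained-table"`` reads vectors from an explicit mapping (e.g.
    exported from an external fragment-embedding model).  The default
    ``mode="deterministic-fallback"`` derives each group vector from a
    cryptographic hash of ``(seed, group name)``, which is reproducible
    across runs and machines and keeps the whole test suite self-contained.
    """

    mode: str = "deterministic-fallback"
    seed: int = 0
    group_vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("pretrained-table", "deterministic-fallback"):
            raise ValueError(f"unknown embedding mode {self.mode!r}")
        for key, vec in list(self.group_vectors.items()):
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (EMBEDDING_DIM,):
                raise ValueError(
                    f"group vector {key!r} has dimension {vec.shape}, "
                    f"expected ({EMBEDDING_DIM},)"
                )
            self.group_vectors[key] = vec

    def vector(self, group: str) -> np.ndarray:
        if group in self.group_vectors:
            return self.group_vectors[group]
        if self.mode == "pretrained-table":
            raise KeyError(f"group {group!r} missing from pretrained table")
        digest = hashlib.sha256(f"{self.seed}:{group}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        vec = rng.standard_normal(EMBEDDING_DIM)
        self.group_vectors[group] = vec
        return vec

    @classmethod
    def from_json(cls, text: str) -> "EmbeddingProvider":
        payload = json.loads(text)
        return cls(
            mode="pretrained-table",
            group_vectors={k: np.asarray(v, dtype=float) for k, v in payload.items()},
        )


def residue_embedding(
    residue_name: str, provider: EmbeddingProvider, strict: bool = True
) -> np.ndarray:
    """30-dim embedding of a residue = sum of its chemical-group vectors.

    Unknown residue names raise in strict mode and map to the zero vector
    otherwise (useful for modified residues in real structures).
    """
    name = residue_name.upper().strip()
    groups = AMINO_ACID_GROUPS.get(name)
    if groups is None:
        if strict:
            raise KeyError(f"unknown residue name {residue_name!r}")
        return np.zeros(EMBEDDING_DIM)
    out = np.zeros(EMBEDDING_DIM)
    for g in groups:
        out = out + provider.vector(g)
    return out


@dataclass
class PocketSelection:
    residue_indices: list[int]
    cutoff_nm: float
    source: Structure

    @property
    def residue_names(self) -> list[str]:
        return [self.source.residues[i].name for i in self.residue_indices]

    def id_map(self) -> dict[int, tuple[str, int]]:
        full = self.source.residue_id_map()
        return {i: full[i] for i in self.residue_indices}


@dataclass
class PocketGraph:
    nodes: list[int]                  # residue indices into the source structure
    node_features: np.ndarray         # (n_nodes, 30)
    edges: list[tuple[int, int]]      # position pairs (i, j), i < j, into nodes
    contact_cutoff_nm: float
    residue_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        n = len(self.nodes)
        if self.node_features.shape != (n, EMBEDDING_DIM):
            raise ValueError(
                f"node features must be ({n}, {EMBEDDING_DIM}), "
                f"got {self.node_features.shape}"
            )
        for i, j in self.edges:
            if i == j:
                raise ValueError("pocket graph must not contain self-edges")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for {n} nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


@dataclass
class LigandGraph:
    node_features: np.ndarray         # (n_heavy_atoms, n_features)
    edges: list[tuple[int, int]]      # bonds, i < j
    smiles: str
    atom_symbols: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a


def _min_heavy_distance_matrix(structure: Structure) -> list[np.ndarray]:
    return [r.heavy_coords() for r in structure.residues]


def extract_pocket(structure: Structure, cutoff_nm: float) -> PocketSelection:
    """Residues with any heavy atom within ``cutoff_nm`` of a ligand heavy atom.

    Selection order follows the structure's residue order.  The ligand's own
    atoms never become nodes.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    lig = structure.ligand_heavy_coords()
    if lig.size == 0:
        raise ValueError("structure has no ligand heavy atoms; cannot define pocket")
    cutoff_a = nm_to_angstrom(cutoff_nm)
    selected: list[int] = []
    for res in structure.residues:
        coords = res.heavy_coords()
        if coords.size == 0:
            continue
        if cdist(coords, lig).min() <= cutoff_a:
            selected.append(res.index)
    return PocketSelection(residue_indices=selected, cutoff_nm=cutoff_nm, source=structure)


def build_pocket_graph(
    selection: PocketSelection,
    provider: EmbeddingProvider,
    contact_cutoff_nm: float = 0.5,
    strict_residues: bool = True,
) -> PocketGraph:
    """Residue contact graph over a pocket selection.

    Edge (i, j) present iff the minimum heavy-atom distance between the two
    residues is <= ``contact_cutoff_nm`` (default 0.5 nm).
    """
    if not selection.residue_indices:
        raise ValueError("empty pocket selection")
    if contact_cutoff_nm <= 0:
        raise ValueError("contact cutoff must be positive")
    structure = selection.source
    cutoff_a = nm_to_angstrom(contact_cutoff_nm)

    coords = [structure.residues[i].heavy_coords() for i in selection.residue_indices]
    names = [structure.residues[i].name for i in selection.residue_indices]
    features = np.stack(
        [residue_embedding(n, provider, strict=strict_residues) for n in names]
    )

    edges: list[tuple[int, int]] = []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if coords[i].size and coords[j].size:
                if cdist(coords[i], coords[j]).min() <= cutoff_a:
                    edges.append((i, j))

    return PocketGraph(
        nodes=list(selection.residue_indices),
        node_features=features,
        edges=edges,
        contact_cutoff_nm=contact_cutoff_nm,
        residue_names=names,
    )


# Ligand atom feature schema ("GraphDTA-like" one-hot blocks).  The exact bin
# layout is part of a trained model's schema fingerprint.
_ELEMENT_CLASSES = ["C", "N", "O", "S", "F", "P", "Cl", "Br", "I", "other"]
_DEGREES = [0, 1, 2, 3, 4, 5]
_NUM_HS = [0, 1, 2, 3, 4]
_FORMAL_CHARGES = [-1, 0, 1]  # clipped to this range

LIGAND_FEATURE_NAMES: list[str] = (
    [f"element={e}" for e in _ELEMENT_CLASSES]
    + [f"degree={d}" for d in _DEGREES]
    + [f"num_h={h}" for h in _NUM_HS]
    + [f"charge={c}" for c in _FORMAL_CHARGES]
    + ["aromatic"]
)

LIGAND_FEATURE_DIM = len(LIGAND_FEATURE_NAMES)


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def _atom_features(atom: Chem.Atom) -> list[float]:
    symbol = atom.GetSymbol()
    if symbol not in _ELEMENT_CLASSES:
        symbol = "other"
    degree = min(atom.GetDegree(), _DEGREES[-1])
    num_h = min(atom.GetTotalNumHs(), _NUM_HS[-1])
    charge = int(np.clip(atom.GetFormalCharge(), _FORMAL_CHARGES[0], _FORMAL_CHARGES[-1]))
    return (
        _one_hot(symbol, _ELEMENT_CLASSES)
        + _one_hot(degree, _DEGREES)
        + _one_hot(num_h, _NUM_HS)
        + _one_hot(charge, _FORMAL_CHARGES)
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )


def ligand_graph_from_smiles(smiles: str) -> LigandGraph:
    """Heavy-atom molecular graph with one-hot-like atom features.

    Nodes follow RDKit's canonical atom ordering for the parsed molecule;
    edges are covalent bonds (undirected, stored once with i < j).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    features = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=float)
    if features.size == 0:
        raise SmilesParseError(f"SMILES {smiles!r} has no heavy atoms")
    edges = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
    return LigandGraph(
        node_features=features,
        edges=sorted(edges),
        smiles=smiles,
        atom_symbols=[a.GetSymbol() for a in mol.GetAtoms()],
    )
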