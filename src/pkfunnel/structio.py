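"""Structure and trajectory I/O with fixed unit conventions.

All coordinates are stored internally in Angstrom (the native PDB unit).
Every distance *cutoff* in the toolkit's public API is accepted in
nanometres and converted exactly once, at the API boundary, via
:func:`nm_to_angstrom`.  Mixing the two conventions silently is the classic
factor-of-ten bug in pocket definitions, so the conversion point is unique.

Protein structures come from PDB text (parsed with gemmi); trajectories
come from multi-model PDB or XYZ text.  Hydrogens are retained on parsing
but excluded from all heavy-atom distance operations downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "LigandNotFoundError",
    "StructureParseError",
    "TrajectoryFormatError",
    "nm_to_angstrom",
    "angstrom_to_nm",
    "parse_structure",
    "write_structure",
    "parse_trajectory",
    "write_trajectory_xyz",
]

_HYDROGEN_ELEMENTS = frozenset({"H", "D", "T"})
_WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})


class StructureParseError(ValueError):
    """Raised when PDB text contains no usable coordinate records."""


class LigandNotFoundError(ValueError):
    """Raised when a requested ligand residue code is absent from the file."""


class TrajectoryFormatError(ValueError):
    """Raised on malformed or internally inconsistent trajectory text."""


def nm_to_angstrom(value_nm: float) -> float:
    """Convert a distance from nanometres to Angstrom (the single unit boundary)."""
    return float(value_nm) * 10.0


def angstrom_to_nm(value_a: float) -> float:
    return float(value_a) / 10.0


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    coords: np.ndarray  # shape (3,), Angstrom
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.element:
            raise ValueError("atom element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    index: int          # 0-based internal index
    pdb_resid: int      # residue id as printed in the source file
    chain: str
    name: str           # 3-letter code
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name} {self.pdb_resid} has no atoms")
        for a in self.atoms:
            if a.residue_index != self.index:
                raise ValueError("all atoms of a residue must share its index")

    def heavy_coords(self) -> np.ndarray:
        """(n, 3) array of heavy-atom coordinates, Angstrom."""
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)


@dataclass
class Structure:
    residues: list[Residue]
    ligand_atoms: list[Atom] = field(default_factory=list)
    source_id: str = ""
    ligand_name: str = ""

    def __post_init__(self) -> None:
        for i, r in enumerate(self.residues):
            if r.index != i:
                raise ValueError("residue indices must be contiguous from 0")
        for a in self.ligand_atoms:
            if not a.is_hetero:
                raise ValueError("ligand atoms must be hetero atoms")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_id_map(self) -> dict[int, tuple[str, int]]:
        """Internal index -> (chain, original PDB residue id)."""
        return {r.index: (r.chain, r.pdb_resid) for r in self.residues}

    def ligand_heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms if a.is_heavy], dtype=float)


@dataclass
class Trajectory:
    frames: list[np.ndarray]          # each (n_atoms, 3), Angstrom
    atom_labels: list[str]
    timestep: float = 1.0             # ps between consecutive frames

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        n = self.frames[0].shape[0]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise TrajectoryFormatError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )
        if len(self.atom_labels) != n:
            raise ValueError("atom_labels length must equal atom count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.timestep

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinate array."""
        return np.stack(self.frames)


def _select_highest_occupancy(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Collapse altlocs: keep the highest-occupancy conformer per atom name."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        key = atom.name
        if key not in best:
            best[key] = atom
            order.append(key)
        elif atom.occ > best[key].occ:
            best[key] = atom
    return [best[k] for k in order]


def parse_structure(pdb_text: str, ligand_code: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Protein (ATOM) residues are reindexed 0..n-1 in file order; the original
    (chain, resid) labels stay available through ``residue_id_map``.  HETATM
    residues whose name equals ``ligand_code`` become ``ligand_atoms``;
    waters and other het groups are ignored.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureParseError("no coordinate records found")
    model = st[0]

    residues: list[Residue] = []
    ligand_atoms: list[Atom] = []
    ligand_code = ligand_code.strip()

    for chain in model:
        for res in chain:
            atoms = _select_highest_occupancy(res)
            if not atoms:
                continue
            is_het = res.het_flag == "H"
            if not is_het:
                idx = len(residues)
                converted = [
                    Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name or "X",
                        residue_index=idx,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        is_hetero=False,
                    )
                    for a in atoms
                ]
                residues.append(
                    Residue(
                        index=idx,
                        pdb_resid=res.seqid.num,
                        chain=chain.name,
                        name=res.name,
                        atoms=converted,
                        insertion_code=(res.seqid.icode or "").strip(),
                    )
                )
            elif ligand_code and res.name.strip() == ligand_code:
                for a in atoms:
                    ligand_atoms.append(
                        Atom(
                            serial=a.serial,
                            name=a.name,
                            element=a.element.name or "X",
                            residue_index=-1,
                            coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                            is_hetero=True,
                        )
                    )

    if not residues and not ligand_atoms:
        raise StructureParseError("no ATOM records found in PDB text")
    if ligand_code and not ligand_atoms:
        raise LigandNotFoundError(
            f"ligand {ligand_code!r} not found among HETATM records"
        )
    return Structure(
        residues=residues,
        ligand_atoms=ligand_atoms,
        source_id=st.name or "",
        ligand_name=ligand_code,
    )


def write_structure(structure: Structure) -> str:
    """Serialize a :class:`Structure` back to PDB text (3-decimal precision)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "pkfunnel"
    model = gemmi.Model("1")

    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.pdb_resid, res.insertion_code or " ")
        gres.het_flag = "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.serial = a.serial
            ga.pos = gemmi.Position(*a.coords)
            gres.add_atom(ga)
        chains[res.chain].add_residue(gres)

    if structure.ligand_atoms:
        lig_chain_name = "Z"
        if lig_chain_name not in chains:
            chains[lig_chain_name] = gemmi.Chain(lig_chain_name)
        gres = gemmi.Residue()
        gres.name = structure.ligand_name or "LIG"
        gres.seqid = gemmi.SeqId(1, " ")
        gres.het_flag = "H"
        for a in structure.ligand_atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.serial = a.serial
            ga.pos = gemmi.Position(*a.coords)
            gres.add_atom(ga)
        chains[lig_chain_name].add_residue(gres)

    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def _parse_xyz(text: str) -> tuple[list[np.ndarray], list[str]]:
    lines = text.splitlines()
    frames: list[np.ndarray] = []
    labels: list[str] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"line {pos + 1}: expected atom count, got {lines[pos]!r}"
            ) from exc
        if pos + 2 + n > len(lines):
            raise TrajectoryFormatError(
                f"frame starting at line {pos + 1} truncated: needs {n} atoms"
            )
        frame = np.empty((n, 3), dtype=float)
        frame_labels: list[str] = []
        for i in range(n):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"line {pos + 3 + i}: expected 'element x y z'"
                )
            frame_labels.append(parts[0])
            frame[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not labels:
            labels = frame_labels
        elif frame_labels != labels:
            raise TrajectoryFormatError(
                f"frame {len(frames)} atom labels differ from frame 0"
            )
        frames.append(frame)
        pos += 2 + n
    if not frames:
        raise TrajectoryFormatError("no frames found in XYZ text")
    return frames, labels


def _parse_multimodel_pdb(text: str) -> tuple[list[np.ndarray], list[str]]:
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise TrajectoryFormatError("no models found in PDB text")
    frames: list[np.ndarray] = []
    labels: list[str] = []
    for k, model in enumerate(st):
        coords = []
        model_labels = []
        for chain in model:
            for res in chain:
                for atom in res:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    model_labels.append(f"{res.name}:{atom.name}")
        if not labels:
            labels = model_labels
        elif len(model_labels) != len(labels):
            raise TrajectoryFormatError(
                f"model {k + 1} has {len(model_labels)} atoms, expected {len(labels)}"
            )
        frames.append(np.asarray(coords, dtype=float))
    return frames, labels


def parse_trajectory(text: str, format: str = "pdb", timestep: float = 1.0) -> Trajectory:
    """Parse trajectory text (multi-model PDB or XYZ) into a :class:`Trajectory`.

    Parameters
    ----------
    format:
        ``"pdb"`` for multi-model PDB (MODEL/ENDMDL blocks) or ``"xyz"``.
    timestep:
        Time between consecutive frames, ps.
    """
    fmt = format.lower()
    if fmt == "pdb":
        frames, labels = _parse_multimodel_pdb(text)
    elif fmt == "xyz":
        frames, labels = _parse_xyz(text)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(frames=frames, atom_labels=labels, timestep=timestep)


def write_trajectory_xyz(traj: Trajectory, comment: str = "") -> str:
    """Serialize a trajectory to XYZ text (element taken from atom labels)."""
    out = io.StringIO()
    for k, frame in enumerate(traj.frames):
        out.write(f"{traj.n_atoms}\n")
        out.write(f"{comment} frame {k}\n".strip() + "\n" if comment else f"frame {k}\n")
        for label, xyz in zip(traj.atom_labels, frame):
            element = label.split(":")[-1][:1] or "X"
            out.write(f"{element} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    return out.getvalue()
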