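"""Deterministic synthetic data for every stage of the funnel.

Each generator is a pure function of a :class:`FixtureSpec` (seed
included): the same spec produces byte-identical output, and every fixture
ships its own ground truth (pocket membership, expected survivors, analytic
RMSF, requested basin layout) so downstream tests are self-describing.

These are geometric/statistical toys, not physical molecules: residues are
small atom clusters placed at controlled distances from a central ligand,
trajectories oscillate atoms with prescribed amplitudes, and hills files
are synthesized to carve requested free-energy basins.  They exercise the
toolkit's contracts, not force-field realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .funnel import FunnelConfig, ScoreRecord, apply_funnel, read_score_table
from .metad_fes import HillsRecord, write_hills
from .structio import Atom, Residue, Structure, Trajectory

__all__ = [
    "FixtureSpec",
    "ToyComplex",
    "ScoreTableFixture",
    "BreathingTrajectory",
    "HillsFixture",
    "make_toy_complex",
    "make_score_table",
    "make_breathing_trajectory",
    "make_hills",
    "make_toy_smiles",
]

_RESIDUE_NAMES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Small drug-like SMILES pool for toy ligand sets.
_TOY_SMILES = (
    "c1ccccc1", "c1ccncc1", "CCO", "CC(=O)O", "CC(=O)Nc1ccccc1",
    "c1ccc2[nH]ccc2c1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Oc1ccccc1",
    "CCN(CC)CC", "C1CCOC1", "CC(=O)Oc1ccccc1C(=O)O", "c1ccc(cc1)S(=O)(=O)N",
)


@dataclass
class FixtureSpec:
    seed: int = 0
    n_residues: int = 20
    n_ligand_atoms: int = 8
    n_frames: int = 10
    noise_scale: float = 0.3       # Angstrom jitter within residue clusters
    table_size: int = 50

    def __post_init__(self) -> None:
        for name in ("n_residues", "n_ligand_atoms", "n_frames", "table_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed * 1_000_003 + salt) % 2**63)


@dataclass
class ToyComplex:
    structure: Structure
    residue_radii: np.ndarray          # designed min residue-ligand distance, A
    pocket_truth: dict[float, list[int]]  # cutoff_nm -> residue indices (brute force)


def _brute_force_pocket(structure: Structure, cutoff_nm: float) -> list[int]:
    """Exhaustive all-pairs heavy-atom scan; the oracle the fast path must match."""
    lig = structure.ligand_heavy_coords()
    out = []
    for res in structure.residues:
        coords = res.heavy_coords()
        best = min(
            float(np.linalg.norm(a - b)) for a in coords for b in lig
        )
        if best <= cutoff_nm * 10.0:
            out.append(res.index)
    return out


def make_toy_complex(
    spec: FixtureSpec,
    radii: list[float] | None = None,
    truth_cutoffs_nm: tuple[float, ...] = (0.5, 0.6, 0.8, 1.0),
) -> ToyComplex:
    """Protein shell of residue clusters around a central ligand blob.

    ``radii`` (Angstrom) are the designed closest-approach distances of
    each residue to the ligand surface region; when omitted they are drawn
    uniformly from 3-14 A.  Ground-truth pocket membership at the standard
    cutoffs is recomputed by brute force on the emitted coordinates, so it
    stays exact even with jitter.
    """
    rng = spec.rng(1)
    n = spec.n_residues
    if radii is None:
        radii = list(rng.uniform(3.0, 14.0, size=n))
    if len(radii) != n:
        raise ValueError("radii length must equal n_residues")

    # ligand: compact blob of heavy atoms within ~1.2 A of the origin
    lig_coords = rng.normal(scale=0.7, size=(spec.n_ligand_atoms, 3))
    lig_coords[0] = 0.0   # guarantee an atom exactly at the origin
    ligand_atoms = [
        Atom(
            serial=9000 + i,
            name=f"L{i}",
            element="C",
            residue_index=-1,
            coords=c,
            is_hetero=True,
        )
        for i, c in enumerate(lig_coords)
    ]

    residues: list[Residue] = []
    serial = 1
    for i, r in enumerate(radii):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # place the residue's nearest atom at distance ~r from the nearest
        # ligand atom along this direction; cluster others slightly behind
        anchor = direction * r
        name = _RESIDUE_NAMES[int(rng.integers(len(_RESIDUE_NAMES)))]
        atoms = []
        n_atoms = 4
        for k in range(n_atoms):
            offset = direction * (0.6 * k) + rng.normal(scale=spec.noise_scale, size=3)
            if k == 0:
                offset = np.zeros(3)  # anchor atom exactly at the design radius
            atoms.append(
                Atom(
                    serial=serial,
                    name=["N", "CA", "C", "O"][k],
                    element=["N", "C", "C", "O"][k],
                    residue_index=i,
                    coords=anchor + offset,
                )
            )
            serial += 1
        residues.append(
            Residue(index=i, pdb_resid=100 + i, chain="A", name=name, atoms=atoms)
        )

    structure = Structure(
        residues=residues,
        ligand_atoms=ligand_atoms,
        source_id=f"toy-{spec.seed}",
        ligand_name="LIG",
    )
    truth = {c: _brute_force_pocket(structure, c) for c in truth_cutoffs_nm}
    return ToyComplex(
        structure=structure,
        residue_radii=np.asarray(radii, dtype=float),
        pocket_truth=truth,
    )


@dataclass
class ScoreTableFixture:
    csv_text: str
    records: list[ScoreRecord]
    expected_survivors: list[str]     # ground truth under the config used
    config: FunnelConfig


def make_score_table(
    spec: FixtureSpec,
    fraction_passing: float = 0.3,
    config: FunnelConfig | None = None,
) -> ScoreTableFixture:
    """Synthetic score table shaped like a deep-learning + docking stage.

    Roughly ``fraction_passing`` of rows are constructed to satisfy every
    cutoff of ``config`` (default funnel config); the rest are constructed
    to fail at least one, chosen at random.  The exact expected survivor
    id list is emitted as ground truth.
    """
    if not 0.0 <= fraction_passing <= 1.0:
        raise ValueError("fraction_passing must lie in [0, 1]")
    if config is None:
        config = FunnelConfig()
    rng = spec.rng(2)
    rows = ["compound_id,bc,rg,docking"]
    expected: list[str] = []
    for i in range(spec.table_size):
        cid = f"T{spec.seed:03d}-{i:04d}"
        passing = rng.random() < fraction_passing
        if passing:
            bc = rng.uniform(config.bc_min, 1.0)
            rg = rng.uniform(config.rg_min, config.rg_min + 0.6)
            dock = rng.uniform(config.docking_max - 2.0, config.docking_max)
        else:
            bc = rng.uniform(max(config.bc_min - 0.2, 0.0), 1.0)
            rg = rng.uniform(config.rg_min - 1.0, config.rg_min + 0.6)
            dock = rng.uniform(config.docking_max - 2.0, config.docking_max + 2.0)
            # force at least one criterion to fail
            which = rng.integers(3)
            if which == 0:
                bc = rng.uniform(max(config.bc_min - 0.3, 0.0), config.bc_min * 0.999)
            elif which == 1:
                rg = rng.uniform(config.rg_min - 1.0, config.rg_min - 1e-6)
            else:
                dock = rng.uniform(config.docking_max + 1e-6, config.docking_max + 2.0)
        rows.append(f"{cid},{bc:.4f},{rg:.4f},{dock:.4f}")
    csv_text = "\n".join(rows) + "\n"
    records = read_score_table(csv_text)
    expected = [r.compound_id for r in apply_funnel(records, config)]
    return ScoreTableFixture(
        csv_text=csv_text, records=records, expected_survivors=expected, config=config
    )


@dataclass
class BreathingTrajectory:
    trajectory: Trajectory
    amplitudes: np.ndarray            # per-atom oscillation amplitude, A
    expected_rmsf: np.ndarray         # analytic per-atom RMSF (== amplitudes)


def make_breathing_trajectory(
    spec: FixtureSpec,
    amplitudes: np.ndarray | None = None,
) -> BreathingTrajectory:
    """Atoms oscillating along x with prescribed amplitudes.

    Atom i moves as base_i + a_i * s_t * x_hat with s_t alternating +1/-1
    over an even number of frames, so its time-mean position is its base
    and its RMSF is exactly a_i.  No rotation is involved, so the analytic
    value holds with superposition disabled.
    """
    rng = spec.rng(3)
    n_frames = spec.n_frames if spec.n_frames % 2 == 0 else spec.n_frames + 1
    n_atoms = max(spec.n_ligand_atoms, 2)
    if amplitudes is None:
        amplitudes = rng.uniform(0.0, 2.0, size=n_atoms)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (n_atoms,):
        raise ValueError(f"amplitudes must have shape ({n_atoms},)")
    base = rng.uniform(-5, 5, size=(n_atoms, 3))
    frames = []
    for t in range(n_frames):
        sign = 1.0 if t % 2 == 0 else -1.0
        frame = base.copy()
        frame[:, 0] += sign * amplitudes
        frames.append(frame)
    traj = Trajectory(
        frames=frames,
        atom_labels=[f"A{i}" for i in range(n_atoms)],
        timestep=1.0,
    )
    return BreathingTrajectory(
        trajectory=traj, amplitudes=amplitudes, expected_rmsf=amplitudes.copy()
    )


@dataclass
class HillsFixture:
    text: str
    records: list[HillsRecord]
    basins: list[tuple[float, float]]     # requested (center, depth kJ/mol)
    deepest_center: float


def make_hills(
    spec: FixtureSpec,
    basins: list[tuple[float, float]],
    sigma: float = 0.25,
    hills_per_basin: int = 20,
) -> HillsFixture:
    """Hills text whose reconstructed FES has minima at the requested centers.

    Each requested (center, depth) contributes ``hills_per_basin`` Gaussian
    hills of total height ``depth`` with small jitter around the center, so
    the negated bias has a basin of approximately that depth there; the
    deepest requested basin becomes the global minimum.
    """
    if not basins:
        raise ValueError("at least one basin is required")
    rng = spec.rng(4)
    records: list[HillsRecord] = []
    t = 0.0
    for center, depth in basins:
        if depth <= 0:
            raise ValueError("basin depth must be positive")
        for _ in range(hills_per_basin):
            records.append(
                HillsRecord(
                    time=t,
                    center=center + rng.normal(scale=sigma * 0.05),
                    width=sigma,
                    height=depth / hills_per_basin,
                )
            )
            t += 1.0
    records.sort(key=lambda r: r.time)
    deepest_center = max(basins, key=lambda b: b[1])[0]
    return HillsFixture(
        text=write_hills(records),
        records=records,
        basins=list(basins),
        deepest_center=deepest_center,
    )


def make_toy_smiles(spec: FixtureSpec, n: int | None = None) -> list[tuple[str, str]]:
    """Deterministic (id, SMILES) toy ligand library drawn from a small pool."""
    rng = spec.rng(5)
    if n is None:
        n = min(spec.table_size, len(_TOY_SMILES))
    picks = rng.choice(len(_TOY_SMILES), size=n, replace=n > len(_TOY_SMILES))
    return [
        (f"L{spec.seed:03d}-{i:03d}", _TOY_SMILES[int(p)])
        for i, p in enumerate(picks)
    ]
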