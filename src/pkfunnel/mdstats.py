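"""Post-MD triage statistics: RMSD, RMSF, hydrogen bonds, coordination number.

These are the quantities used to decide which docked candidates survive the
physics stage: a ligand whose RMSD stays low and stable kept its docked
binding mode; pocket residues and ligands with small RMSF indicate stable
binding; persistent hydrogen bonds support specific interactions; and the
coordination number between ligand and pocket heavy atoms is the collective
variable over which metadynamics free-energy profiles are computed.

Superposition uses the Kabsch least-squares fit (via scipy's rotation
alignment).  All distances are Angstrom internally; hydrogen-bond distance
criteria are accepted in nm at the API boundary, like every other cutoff in
the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structio import Trajectory, nm_to_angstrom

__all__ = [
    "RmsdSeries",
    "RmsfTable",
    "HBondCriteria",
    "superpose",
    "rmsd_series",
    "rmsf_per_entity",
    "count_hbonds",
    "hbond_series",
    "coordination_number",
]


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) fit of ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile``; both inputs are (n, 3).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class RmsdSeries:
    times: np.ndarray       # ps
    values: np.ndarray      # Angstrom
    selection: list[int]
    reference: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def to_csv(self) -> str:
        lines = ["time_ps,rmsd_A"]
        lines += [f"{t:.6g},{v:.6g}" for t, v in zip(self.times, self.values)]
        return "\n".join(lines) + "\n"


def rmsd_series(
    traj: Trajectory,
    selection: list[int] | None = None,
    reference: int | np.ndarray = 0,
    superpose_frames: bool = True,
    fit_selection: list[int] | None = None,
) -> RmsdSeries:
    """Per-frame RMSD of ``selection`` atoms against a reference.

    ``reference`` is a frame index or an explicit (n_atoms, 3) array.  When
    ``superpose_frames`` each frame is first least-squares fitted to the
    reference on ``fit_selection`` (default: the same atoms as
    ``selection``).  Fitting on pocket atoms while measuring the ligand
    gives binding-mode stability rather than global drift.
    """
    n_atoms = traj.n_atoms
    if selection is None:
        selection = list(range(n_atoms))
    if not selection:
        raise ValueError("selection is empty")
    sel = np.asarray(selection, dtype=int)
    if sel.min() < 0 or sel.max() >= n_atoms:
        raise ValueError("selection index out of range for trajectory atoms")
    fit = np.asarray(fit_selection, dtype=int) if fit_selection is not None else sel

    if isinstance(reference, (int, np.integer)):
        ref_frame = traj.frames[int(reference)]
        ref_label = f"frame {int(reference)}"
    else:
        ref_frame = np.asarray(reference, dtype=float)
        if ref_frame.shape != (n_atoms, 3):
            raise ValueError("external reference must match trajectory atom count")
        ref_label = "external"

    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        if superpose_frames:
            mc = frame[fit].mean(axis=0)
            rc = ref_frame[fit].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_frame[fit] - rc, frame[fit] - mc)
            moved = rot.apply(frame - mc) + rc
        else:
            moved = frame
        values[k] = _rmsd(moved[sel], ref_frame[sel])
    return RmsdSeries(times=traj.times, values=values, selection=list(sel), reference=ref_label)


@dataclass
class RmsfTable:
    entity_labels: list[str]
    values: np.ndarray            # Angstrom, per entity
    atom_values: np.ndarray = field(default=None)  # per-atom RMSF

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_csv(self) -> str:
        lines = ["entity,rmsf_A"]
        lines += [f"{e},{v:.6g}" for e, v in zip(self.entity_labels, self.values)]
        return "\n".join(lines) + "\n"


def rmsf_per_entity(
    traj: Trajectory,
    grouping: dict[str, list[int]] | None = None,
    superpose_frames: bool = True,
    fit_to: str = "average",
) -> RmsfTable:
    """Root-mean-square fluctuation per atom, averaged over entity groups.

    Per atom: RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>) over frames, after
    optional superposition of every frame onto either the time-average
    structure (``fit_to="average"``, iterated once from a first-frame fit)
    or the first frame (``fit_to="first"``).  Entity values (e.g. per
    residue, or the whole ligand) are means over member atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if fit_to not in ("average", "first"):
        raise ValueError("fit_to must be 'average' or 'first'")
    coords = traj.coords()

    if superpose_frames:
        ref = coords[0]
        aligned = np.stack([superpose(f, ref) for f in coords])
        if fit_to == "average":
            ref = aligned.mean(axis=0)
            aligned = np.stack([superpose(f, ref) for f in coords])
        coords = aligned

    mean_pos = coords.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))

    if grouping is None:
        grouping = {label: [i] for i, label in enumerate(traj.atom_labels)}
    labels = list(grouping)
    values = np.array([atom_rmsf[np.asarray(grouping[k], dtype=int)].mean() for k in labels])
    return RmsfTable(entity_labels=labels, values=values, atom_values=atom_rmsf)


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond definition (field-standard defaults)."""

    max_donor_acceptor_distance_nm: float = 0.35
    min_dha_angle_deg: float = 150.0

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance_nm <= 0:
            raise ValueError("distance criterion must be positive")
        if not 0 < self.min_dha_angle_deg <= 180:
            raise ValueError("angle criterion must lie in (0, 180]")


def _dha_angle_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def count_hbonds(
    frame: np.ndarray,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criteria: HBondCriteria | None = None,
) -> int:
    """Count hydrogen bonds in one frame by the geometric criterion.

    ``donors`` are (donor_heavy_index, hydrogen_index) pairs; ``acceptors``
    are heavy-atom indices.  A (D, H, A) triple is a hydrogen bond when the
    D-A distance is at most the distance criterion and the D-H-A angle is
    at least the angle criterion.  A donor heavy atom is never counted as
    its own acceptor.
    """
    if criteria is None:
        criteria = HBondCriteria()
    frame = np.asarray(frame, dtype=float)
    for d_idx, h_idx in donors:
        if h_idx is None:
            raise ValueError(f"donor atom {d_idx} has no attached hydrogen")
    max_da = nm_to_angstrom(criteria.max_donor_acceptor_distance_nm)
    count = 0
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            if np.linalg.norm(frame[d_idx] - frame[a_idx]) > max_da:
                continue
            if _dha_angle_deg(frame[d_idx], frame[h_idx], frame[a_idx]) >= criteria.min_dha_angle_deg:
                count += 1
    return count


def hbond_series(
    traj: Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criteria: HBondCriteria | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(times, per-frame hydrogen-bond counts) over a trajectory."""
    counts = np.array(
        [count_hbonds(f, donors, acceptors, criteria) for f in traj.frames]
    )
    return traj.times, counts


def coordination_number(
    frame: np.ndarray,
    group_a: list[int],
    group_b: list[int],
    r0_nm: float,
    n: int = 6,
    m: int = 12,
) -> float:
    """Smooth contact count between two atom groups.

    CN = sum over pairs (i in A, j in B) of the rational switching function

        s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m)

    which is ~1 for r << r0, ~0 for r >> r0, and has a removable
    singularity at r = r0 where s = n/m.  For the default m = 2n the
    function reduces exactly to 1 / (1 + (r/r0)^n), which is what we
    evaluate (numerically smooth through r = r0); the general case guards
    the singularity explicitly.  This is the collective variable over
    which binding/unbinding free-energy profiles are reconstructed.
    """
    if r0_nm <= 0:
        raise ValueError("r0 must be positive")
    if m <= n:
        raise ValueError("switching exponents require m > n")
    if not group_a or not group_b:
        raise ValueError("both atom groups must be non-empty")
    frame = np.asarray(frame, dtype=float)
    r0 = nm_to_angstrom(r0_nm)
    r = cdist(frame[np.asarray(group_a, dtype=int)], frame[np.asarray(group_b, dtype=int)])
    x = r / r0
    if m == 2 * n:
        s = 1.0 / (1.0 + x**n)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (1.0 - x**n) / (1.0 - x**m)
        s = np.where(np.abs(x - 1.0) < 1e-10, n / m, s)
    return float(s.sum())
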