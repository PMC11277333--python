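"""Free-energy profile reconstruction from metadynamics hill depositions.

Metadynamics deposits repulsive Gaussian "hills" along a collective
variable (CV); the negated accumulated bias approximates the free-energy
surface (FES).  For a 1-D CV with hills (height h_k, center c_k, width
sigma_k):

    F(s) = - sum_k  h_k * exp( -(s - c_k)^2 / (2 sigma_k^2) )

For well-tempered runs with bias factor gamma the deposited heights decay,
and the accumulated bias relates to the FES by the factor gamma/(gamma-1),
applied per hill when a bias factor column is present.  Profiles are
shifted so their minimum is zero.

The candidate-acceptance rule operates on profiles over a protein-ligand
coordination-number CV: a compound is accepted when its global free-energy
minimum sits at a coordination number above a threshold, i.e. the most
stable state keeps protein-ligand contacts (bound) rather than sitting at
zero contacts (unbound).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HillsRecord",
    "FESProfile",
    "Basin",
    "AcceptanceDecision",
    "HillsFormatError",
    "KJ_PER_KCAL",
    "read_hills",
    "write_hills",
    "fes_from_hills",
    "find_basins",
    "accept_candidate",
]

KJ_PER_KCAL = 4.184


class HillsFormatError(ValueError):
    """Malformed hills text."""


@dataclass
class HillsRecord:
    time: float                    # ps
    center: float                  # CV units
    width: float                   # Gaussian sigma, CV units
    height: float                  # kJ/mol
    bias_factor: float | None = None   # well-tempered gamma, if any

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("hill width must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")
        if self.bias_factor is not None and self.bias_factor <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")


def read_hills(text: str) -> list[HillsRecord]:
    """Parse whitespace-delimited hills text (time, center, sigma, height[, biasf]).

    Comment lines starting with ``#`` are ignored.  Non-monotone times emit
    a warning (restarted runs produce them); malformed lines raise with
    their line number.
    """
    records: list[HillsRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 4:
            raise HillsFormatError(
                f"line {lineno}: expected >= 4 columns (time cv sigma height), "
                f"got {len(parts)}"
            )
        try:
            values = [float(p) for p in parts[:5]]
        except ValueError as exc:
            raise HillsFormatError(f"line {lineno}: non-numeric field in {line!r}") from exc
        records.append(
            HillsRecord(
                time=values[0],
                center=values[1],
                width=values[2],
                height=values[3],
                bias_factor=values[4] if len(parts) >= 5 else None,
            )
        )
    if not records:
        raise HillsFormatError("no hill records found")
    times = [r.time for r in records]
    if any(b < a for a, b in zip(times, times[1:])):
        warnings.warn("hill times are not monotonically non-decreasing", stacklevel=2)
    return records


def write_hills(records: list[HillsRecord]) -> str:
    lines = ["# time cv sigma height biasf"]
    for r in records:
        cols = f"{r.time:.6g} {r.center:.10g} {r.width:.10g} {r.height:.10g}"
        if r.bias_factor is not None:
            cols += f" {r.bias_factor:.6g}"
        lines.append(cols)
    return "\n".join(lines) + "\n"


@dataclass
class FESProfile:
    grid: np.ndarray               # CV values, strictly increasing
    free_energy: np.ndarray        # kJ/mol, min shifted to 0
    cv_name: str = "coordination_number"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.free_energy.shape:
            raise ValueError("grid and free_energy must be matching 1-D arrays")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def in_kcal(self) -> np.ndarray:
        return self.free_energy / KJ_PER_KCAL

    def to_csv(self) -> str:
        lines = ["cv,free_energy_kj_mol"]
        lines += [f"{s:.10g},{f:.10g}" for s, f in zip(self.grid, self.free_energy)]
        return "\n".join(lines) + "\n"


def fes_from_hills(
    hills: list[HillsRecord],
    grid_min: float,
    grid_max: float,
    n_points: int = 500,
    shift_to_zero: bool = True,
    cv_name: str = "coordination_number",
) -> FESProfile:
    """Reconstruct F(s) by negated Gaussian-hill summation on a uniform grid.

    Well-tempered rescaling ``h * gamma/(gamma-1)`` is applied per hill
    when that hill carries a bias factor.  An empty hill list yields a flat
    zero profile (a run that deposited nothing has a flat estimate).
    """
    if n_points < 2:
        raise ValueError("grid must have at least 2 points")
    if grid_max <= grid_min:
        raise ValueError("grid_max must exceed grid_min")
    grid = np.linspace(grid_min, grid_max, n_points)
    if not hills:
        return FESProfile(grid=grid, free_energy=np.zeros_like(grid), cv_name=cv_name)

    centers = np.array([h.center for h in hills])
    widths = np.array([h.width for h in hills])
    heights = np.array(
        [
            h.height * (h.bias_factor / (h.bias_factor - 1.0))
            if h.bias_factor is not None
            else h.height
            for h in hills
        ]
    )
    # (n_points, n_hills) Gaussian matrix; fine at the scales a 1-D CV needs
    diff = grid[:, None] - centers[None, :]
    bias = np.exp(-(diff**2) / (2.0 * widths[None, :] ** 2)) @ heights
    fes = -bias
    if shift_to_zero:
        fes = fes - fes.min()
    return FESProfile(grid=grid, free_energy=fes, cv_name=cv_name)


@dataclass
class Basin:
    cv_location: float
    free_energy: float             # kJ/mol at the basin minimum
    depth: float                   # barrier-limited depth, kJ/mol
    grid_index: int
    is_global_minimum: bool = False
    is_boundary: bool = False


def _local_minima_indices(f: np.ndarray) -> tuple[list[int], list[int]]:
    """(interior minima, boundary minima); plateaus resolve to their leftmost point."""
    n = len(f)
    interior: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and f[j + 1] == f[j]:
            j += 1
        # plateau [i, j]; minimum iff strictly below both flanking values
        if f[i - 1] > f[i] and j + 1 < n and f[j + 1] > f[j]:
            interior.append(i)
        i = j + 1
    boundary: list[int] = []
    if n >= 2:
        if f[0] < f[1]:
            boundary.append(0)
        if f[-1] < f[-2]:
            boundary.append(n - 1)
    return interior, boundary


def find_basins(
    profile: FESProfile, min_depth: float = 0.0, include_boundary: bool = True
) -> list[Basin]:
    """Local minima of the profile with a barrier-limited depth filter.

    Depth of a basin is the smaller of the two barriers separating it from
    its neighbouring basins (profile ends count as infinite barriers are
    *not* assumed: the boundary value itself limits).  Interior basins need
    depth >= ``min_depth``; boundary minima are reported flagged so a
    monotone profile still exposes its end-point minimum.
    """
    f = profile.free_energy
    if len(f) < 3:
        raise ValueError("profile needs at least 3 grid points")
    interior, boundary = _local_minima_indices(f)

    basins: list[Basin] = []
    candidates = interior + (boundary if include_boundary else [])
    for idx in sorted(candidates):
        left_barrier = f[:idx].max() - f[idx] if idx > 0 else np.inf
        right_barrier = f[idx + 1:].max() - f[idx] if idx < len(f) - 1 else np.inf
        depth = float(min(left_barrier, right_barrier))
        is_bnd = idx in boundary
        if not is_bnd and depth < min_depth:
            continue
        basins.append(
            Basin(
                cv_location=float(profile.grid[idx]),
                free_energy=float(f[idx]),
                depth=depth,
                grid_index=idx,
                is_boundary=is_bnd,
            )
        )
    if basins:
        lowest = min(basins, key=lambda b: (b.free_energy, b.grid_index))
        lowest.is_global_minimum = True
    return basins


@dataclass
class AcceptanceDecision:
    accepted: bool
    basin_cv: float
    threshold: float
    margin: float
    rationale: str


def accept_candidate(profile: FESProfile, cv_threshold: float = 0.5) -> AcceptanceDecision:
    """Bound-state acceptance rule on a coordination-number FES.

    Accept iff the global free-energy minimum sits at CV above
    ``cv_threshold``: the most stable state retains protein-ligand
    contacts.  A global minimum at (or near) zero contacts means the
    unbound state is most favourable and the candidate is rejected.
    """
    basins = find_basins(profile, min_depth=0.0, include_boundary=True)
    if not basins:
        # profile without any minimum (e.g. strictly flat): fall back to argmin
        idx = int(np.argmin(profile.free_energy))
        basin_cv = float(profile.grid[idx])
    else:
        basin_cv = next(b for b in basins if b.is_global_minimum).cv_location
    accepted = basin_cv > cv_threshold
    margin = basin_cv - cv_threshold
    word = "exceeds" if accepted else "does not exceed"
    return AcceptanceDecision(
        accepted=accepted,
        basin_cv=basin_cv,
        threshold=cv_threshold,
        margin=margin,
        rationale=(
            f"global free-energy minimum at {profile.cv_name}={basin_cv:.4g} "
            f"{word} threshold {cv_threshold:.4g} (margin {margin:+.4g})"
        ),
    )
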