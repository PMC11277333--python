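"""Staged threshold funnel over candidate score tables.

A screening campaign reduces a compound library through successive stages:
a fast binary-classifier (BC) cut, an affinity-regressor (RG) cut on the
pKa scale, a docking-energy cut, and finally physics-based acceptance.
This module owns the score-table contract and the conjunction-of-cutoffs
selection rule:

    survivor  iff  BC >= bc_min  and  RG >= rg_min  and  docking <= docking_max

All comparisons are inclusive, exactly as the thresholds are stated
(tables contain boundary-adjacent values such as RG 9.0076, so strictness
matters).  A record missing a required score never survives: conservative
funnel semantics.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "ScoreRecord",
    "FunnelConfig",
    "ScoreTableError",
    "read_score_table",
    "load_reference_table",
    "apply_funnel",
    "rank_candidates",
    "funnel_report",
    "records_to_csv",
]

_MISSING_TOKENS = {"", "na", "nan", "none", "null", "-"}


class ScoreTableError(ValueError):
    """Malformed score table (duplicate ids, non-numeric cells, ...)."""


@dataclass
class ScoreRecord:
    compound_id: str
    bc: float | None = None          # binder probability in [0, 1]
    rg: float | None = None          # pKa-scale affinity prediction
    docking: float | None = None     # docking energy, kcal/mol
    fes_accept: bool | None = None   # metadynamics basin acceptance

    def __post_init__(self) -> None:
        if self.bc is not None and not (0.0 <= self.bc <= 1.0):
            raise ValueError(
                f"{self.compound_id}: BC score {self.bc} outside [0, 1]"
            )


@dataclass
class FunnelConfig:
    """Default cutoffs of the deep-learning + docking selection stage."""

    bc_min: float = 0.99
    rg_min: float = 9.0
    docking_max: float = -7.0        # kcal/mol, more negative = better
    require_fes: bool = False

    def __post_init__(self) -> None:
        # bc_min above 1 is permitted deliberately: an impossible threshold
        # is a legitimate way to express "nothing passes this stage".
        if not math.isfinite(self.bc_min):
            raise ValueError("bc_min must be finite")

    def passes(self, rec: ScoreRecord) -> bool:
        if rec.bc is None or rec.bc < self.bc_min:
            return False
        if rec.rg is None or rec.rg < self.rg_min:
            return False
        if rec.docking is None or rec.docking > self.docking_max:
            return False
        if self.require_fes and rec.fes_accept is not True:
            return False
        return True


_COLUMN_ALIASES = {
    "id": ("compound_id", "id", "chemdiv id", "chemdiv_id", "compound", "name"),
    "bc": ("bc", "deepbindgcn_bc", "bc_score"),
    "rg": ("rg", "deepbindgcn_rg", "rg_score", "pka"),
    "docking": ("docking", "docking_energy", "schrodinger docking (kcal/mol)",
                "schrodinger", "dock", "glide"),
    "fes": ("fes_accept", "fes", "metad_accept"),
}


def _resolve_columns(columns) -> dict[str, str]:
    lowered = {str(c).strip().lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for key, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[key] = lowered[alias]
                break
    if "id" not in resolved:
        raise ScoreTableError(
            f"no compound-id column found among {list(columns)}"
        )
    return resolved


def _parse_cell(value, column: str, row: int) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    text = str(value).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    # Unicode minus from typeset tables
    text = text.replace("−", "-")
    try:
        return float(text)
    except ValueError:
        raise ScoreTableError(
            f"row {row}: non-numeric {column} value {value!r}"
        ) from None


def read_score_table(csv_text: str) -> list[ScoreRecord]:
    """Parse CSV/TSV score-table text into records, in file order.

    The header is matched case-insensitively against common column names
    (id / BC / RG / docking).  Missing cells become missing fields, never
    zeros.  Duplicate compound ids and non-numeric score cells raise.
    """
    sep = "\t" if "\t" in csv_text.splitlines()[0] else ","
    df = pd.read_csv(
        io.StringIO(csv_text), sep=sep, comment="#", dtype=str,
        skip_blank_lines=True,
    )
    cols = _resolve_columns(df.columns)
    records: list[ScoreRecord] = []
    seen: set[str] = set()
    for row_number, (_, row) in enumerate(df.iterrows(), start=2):
        cid = str(row[cols["id"]]).strip()
        if cid in seen:
            raise ScoreTableError(f"duplicate compound id {cid!r}")
        seen.add(cid)
        fes_raw = row[cols["fes"]] if "fes" in cols else None
        fes: bool | None = None
        if fes_raw is not None and str(fes_raw).strip().lower() not in _MISSING_TOKENS:
            fes = str(fes_raw).strip().lower() in ("true", "1", "yes", "accept")
        records.append(
            ScoreRecord(
                compound_id=cid,
                bc=_parse_cell(row.get(cols.get("bc")), "BC", row_number),
                rg=_parse_cell(row.get(cols.get("rg")), "RG", row_number),
                docking=_parse_cell(row.get(cols.get("docking")), "docking", row_number),
                fes_accept=fes,
            )
        )
    return records


def load_reference_table() -> list[ScoreRecord]:
    """The packaged 19-candidate deep-learning + docking stage table."""
    text = resources.files("pkfunnel.data").joinpath("table1.csv").read_text()
    return read_score_table(text)


def apply_funnel(
    records: list[ScoreRecord], config: FunnelConfig | None = None
) -> list[ScoreRecord]:
    """Survivors of the conjunction of cutoffs, input order preserved."""
    if config is None:
        config = FunnelConfig()
    return [rec for rec in records if config.passes(rec)]


_RANK_KEYS = {"docking", "rg", "bc"}


def rank_candidates(
    records: list[ScoreRecord], key: str = "docking", ascending: bool | None = None
) -> list[ScoreRecord]:
    """Stable sort by one score; ties broken lexicographically by id.

    Default direction is "best first": ascending for docking energy (more
    negative = better), descending for BC and RG.  Records missing the key
    sort last.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"rank key must be one of {sorted(_RANK_KEYS)}")
    if ascending is None:
        ascending = key == "docking"
    sign = 1.0 if ascending else -1.0

    def sort_key(rec: ScoreRecord):
        value = getattr(rec, key)
        missing = value is None
        return (missing, sign * value if not missing else 0.0, rec.compound_id)

    return sorted(records, key=sort_key)


@dataclass
class FunnelReport:
    stages: list[tuple[str, int]]
    monotonic: bool = field(init=False)
    violations: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.violations = []
        for (name_a, n_a), (name_b, n_b) in zip(self.stages, self.stages[1:]):
            if n_b > n_a:
                self.violations.append(
                    f"stage {name_b!r} ({n_b}) exceeds preceding {name_a!r} ({n_a})"
                )
        self.monotonic = not self.violations

    def to_text(self) -> str:
        lines = ["stage,survivors"]
        lines += [f"{name},{count}" for name, count in self.stages]
        for v in self.violations:
            lines.append(f"# WARNING: {v}")
        return "\n".join(lines) + "\n"


def funnel_report(stages: list[tuple[str, int]]) -> FunnelReport:
    """Per-stage survivor counts; non-increasing counts asserted and flagged."""
    return FunnelReport(stages=list(stages))


def records_to_csv(records: list[ScoreRecord]) -> str:
    """Serialize records back to CSV (missing fields as empty cells)."""
    def cell(v):
        return "" if v is None else v

    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "bc": [cell(r.bc) for r in records],
            "rg": [cell(r.rg) for r in records],
            "docking": [cell(r.docking) for r in records],
        }
    )
    return df.to_csv(index=False)
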