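"""End-to-end funnel runs: resolved config, staged filtering, run reports.

A run takes a candidate score table (and optionally per-candidate
metadynamics hills files), applies the deep-learning/docking cutoffs and
the free-energy basin acceptance rule, and writes per-stage survivor
tables plus a machine-readable summary.  Identical config + inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .funnel import (
    FunnelConfig,
    ScoreRecord,
    apply_funnel,
    funnel_report,
    read_score_table,
    records_to_csv,
)
from .metad_fes import accept_candidate, fes_from_hills, read_hills

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

logger = logging.getLogger("pkfunnel")


@dataclass
class RunConfig:
    """Fully resolved run configuration; serializes through YAML losslessly."""

    bc_min: float = 0.99
    rg_min: float = 9.0
    docking_max: float = -7.0          # kcal/mol
    pocket_cutoff_bc_nm: float = 0.6
    pocket_cutoff_rg_nm: float = 0.8
    pocket_cutoff_report_nm: float = 1.0
    fes_cv_threshold: float = 0.5       # coordination-number units
    fes_grid_min: float = 0.0
    fes_grid_max: float = 10.0
    fes_grid_points: int = 500
    require_fes: bool = False
    seed: int = 0
    output_dir: str = "pkfunnel_run"
    energy_unit: str = "kJ/mol"

    def funnel_config(self) -> FunnelConfig:
        return FunnelConfig(
            bc_min=self.bc_min,
            rg_min=self.rg_min,
            docking_max=self.docking_max,
            require_fes=False,   # FES handled as its own stage
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class RunResult:
    stages: list[tuple[str, int]]
    survivors: list[ScoreRecord]
    fes_decisions: dict[str, bool] = field(default_factory=dict)
    output_dir: Path | None = None
    monotonic: bool = True


def run_pipeline(
    config: RunConfig,
    score_table_text: str,
    hills_by_candidate: dict[str, str] | None = None,
    write_outputs: bool = True,
) -> RunResult:
    """Run the staged funnel over a score table.

    ``hills_by_candidate`` maps compound id -> hills file text; when
    present (or when ``config.require_fes``), survivors of the score
    funnel additionally pass the free-energy basin acceptance rule.
    Missing hills for a candidate under ``require_fes`` is a named error
    raised before any output is written.
    """
    records = read_score_table(score_table_text)
    logger.info("loaded %d candidate records", len(records))
    logger.info("resolved config:\n%s", config.to_yaml())

    stages: list[tuple[str, int]] = [("input", len(records))]
    survivors = apply_funnel(records, config.funnel_config())
    stages.append(("score_funnel", len(survivors)))
    logger.info("score funnel: %d -> %d", len(records), len(survivors))

    fes_decisions: dict[str, bool] = {}
    if config.require_fes or hills_by_candidate:
        hills_by_candidate = hills_by_candidate or {}
        if config.require_fes:
            missing = [r.compound_id for r in survivors if r.compound_id not in hills_by_candidate]
            if missing:
                raise ValueError(
                    f"FES stage requested but hills are missing for: {missing}"
                )
        kept: list[ScoreRecord] = []
        for rec in survivors:
            text = hills_by_candidate.get(rec.compound_id)
            if text is None:
                continue
            hills = read_hills(text)
            profile = fes_from_hills(
                hills, config.fes_grid_min, config.fes_grid_max, config.fes_grid_points
            )
            decision = accept_candidate(profile, config.fes_cv_threshold)
            fes_decisions[rec.compound_id] = decision.accepted
            rec.fes_accept = decision.accepted
            logger.info("FES %s: %s", rec.compound_id, decision.rationale)
            if decision.accepted:
                kept.append(rec)
        survivors = kept
        stages.append(("fes_acceptance", len(survivors)))

    report = funnel_report(stages)
    result = RunResult(
        stages=stages,
        survivors=survivors,
        fes_decisions=fes_decisions,
        monotonic=report.monotonic,
    )

    if write_outputs:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config.to_yaml())
        (out / "survivors.csv").write_text(records_to_csv(survivors))
        (out / "stages.csv").write_text(report.to_text())
        summary = {
            "stages": [{"name": n, "survivors": c} for n, c in stages],
            "survivor_ids": [r.compound_id for r in survivors],
            "fes_decisions": fes_decisions,
            "monotonic": report.monotonic,
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        result.output_dir = out
    return result
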