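"""End-to-end model runs and report tables.

:func:`run_scenario` wires the whole chain for one scenario × uptake:
population projection → eligibility (stock and flow) → demand schedule →
sector split → capacity gap → revision streams → cost schedule.
:func:`run` sweeps selections of scenarios and uptakes, writes tidy CSVs plus
a JSON manifest, and :func:`demand_table` / :func:`cost_table` render the
uptake-by-year report layouts (person counts as integers, costs at 0.1 AUD
million — rounding happens only here, at the reporting boundary).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import ModelConfig, load_config
from .costs import baseline_cost_row, cost_schedule, round_millions, round_persons
from .demand_supply import (
    SCENARIO_NUMBERS,
    DemandSchedule,
    ScenarioKind,
    ScenarioSpec,
    capacity_gap,
    schedule_demand,
    split_by_sector,
)
from .demography import incident_flow, project_population
from .eligibility import eligible_total, incident_eligible, stock_at_year
from .fiscal import FiscalYear
from .revisions import RevisionSchedule, revision_schedule


@dataclass
class ScenarioResult:
    """Everything one scenario × uptake run produces."""

    spec: ScenarioSpec
    demand: DemandSchedule          # sectored
    gap: pd.DataFrame
    revisions: RevisionSchedule
    costs: pd.DataFrame

    @property
    def label(self) -> str:
        return f"scenario {self.spec.number} @ {self.spec.uptake:.0%}"


@dataclass
class ModelRun:
    """A full sweep over scenarios and uptake levels for one config."""

    config: ModelConfig
    eligible_stock_reference: float
    flow_total: pd.Series
    results: list[ScenarioResult] = field(default_factory=list)

    def get(self, scenario: int, uptake: float) -> ScenarioResult:
        for res in self.results:
            if res.spec.number == scenario and abs(res.spec.uptake - uptake) < 1e-9:
                return res
        raise KeyError(f"no result for scenario {scenario} at uptake {uptake}")


def run_scenario(cfg: ModelConfig, spec: ScenarioSpec,
                 stock: float | None = None,
                 flow_total: pd.Series | None = None) -> ScenarioResult:
    """Run the full chain for one scenario spec (inputs recomputed if absent)."""
    if stock is None or flow_total is None:
        projection = project_population(cfg.base_population, cfg.growth, cfg.horizon)
        if stock is None:
            counts = stock_at_year(cfg, projection, cfg.program.stock_reference_year)
            stock = eligible_total(cfg, counts)
        if flow_total is None:
            flow = incident_flow(projection)
            flow_total = incident_eligible(
                flow, cfg.eoss_distribution, cfg.comorbidity_fractions, cfg.rules,
                include_conditional=cfg.include_conditional_in_demand,
            )["total"]
    demand = schedule_demand(spec, stock, flow_total, cfg.horizon)
    demand = split_by_sector(demand, cfg.phi_share, cfg.oop_private_fraction)
    gap = capacity_gap(demand, cfg.supply)
    revisions = revision_schedule(demand, cfg.mix, cfg.revision_matrix)
    costs = cost_schedule(demand, revisions, cfg.unit_costs,
                          phi_share=cfg.phi_share,
                          oop_private_fraction=cfg.oop_private_fraction)
    return ScenarioResult(spec=spec, demand=demand, gap=gap, revisions=revisions, costs=costs)


def run_model(cfg: ModelConfig, scenarios: list[int] | None = None,
              uptakes: list[float] | None = None) -> ModelRun:
    """Sweep scenarios × uptake levels; shared upstream stages computed once."""
    scenarios = scenarios or [1, 2, 3]
    uptakes = uptakes or list(cfg.uptake_levels)

    projection = project_population(cfg.base_population, cfg.growth, cfg.horizon)
    stock_counts = stock_at_year(cfg, projection, cfg.program.stock_reference_year)
    stock = eligible_total(cfg, stock_counts)
    flow = incident_flow(projection)
    flow_total = incident_eligible(
        flow, cfg.eoss_distribution, cfg.comorbidity_fractions, cfg.rules,
        include_conditional=cfg.include_conditional_in_demand,
    )["total"]

    run = ModelRun(config=cfg, eligible_stock_reference=stock, flow_total=flow_total)
    for number in scenarios:
        kind = SCENARIO_NUMBERS[number]
        for uptake in uptakes:
            spec = ScenarioSpec(kind=kind, uptake=uptake, program=cfg.program)
            run.results.append(run_scenario(cfg, spec, stock=stock, flow_total=flow_total))
    return run


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def _year_labels(years) -> list[str]:
    return [FiscalYear(int(y)).label for y in years]


def revision_table(run: ModelRun, years: list[int] | None = None) -> pd.DataFrame:
    """Attributed 10-year revision streams, scenario × uptake rows by year.

    Cells under a year are the revisions the primaries of that year will
    generate over the following decade; program-silent years of the
    backlog-only scenario are blank.
    """
    years = years or [y for y in run.config.horizon.years
                      if y >= run.config.program.start_year.start]
    rows = {}
    for res in run.results:
        attributed = res.revisions.attributed
        row = {}
        for y in years:
            value = float(attributed.get(y, 0.0))
            primaries = res.demand.at(y)
            if res.spec.kind is ScenarioKind.BACKLOG_ONLY and primaries == 0.0:
                row[FiscalYear(y).label] = "-"
            else:
                row[FiscalYear(y).label] = round_persons(value)
        rows[(f"Scenario {res.spec.number}", f"{res.spec.uptake:.0%}")] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.names = ["scenario", "uptake"]
    return table


def cost_table(run: ModelRun, years: list[int] | None = None,
               include_baseline: bool = True) -> pd.DataFrame:
    """Total costs in AUD millions, (scenario, uptake, sector) rows by year."""
    years = years or [y for y in run.config.horizon.years
                      if y >= run.config.program.start_year.start]
    cfg = run.config
    rows: dict[tuple, dict] = {}
    if include_baseline:
        base = baseline_cost_row(cfg.supply, cfg.unit_costs)
        base_label = cfg.horizon.start.label
        for sector in ("public", "private", "total"):
            rows[("Baseline", "-", sector.capitalize())] = {
                base_label: round_millions(base[sector])
            }
    for res in run.results:
        for sector in ("public", "private", "total"):
            row = {}
            for y in years:
                value = float(res.costs.loc[y, ("total", sector)])
                primaries = res.demand.at(y)
                if res.spec.kind is ScenarioKind.BACKLOG_ONLY and primaries == 0.0 \
                        and value == 0.0:
                    row[FiscalYear(y).label] = "-"
                else:
                    row[FiscalYear(y).label] = round_millions(value)
            rows[(f"Scenario {res.spec.number}", f"{res.spec.uptake:.0%}",
                  sector.capitalize())] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.names = ["scenario", "uptake", "sector"]
    return table


# ---------------------------------------------------------------------------
# File-emitting runner + manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_path: str
    config_sha256: str
    scenarios: list[int]
    uptakes: list[float]
    seed: int | None
    outputs: list[str]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _demand_long(run: ModelRun) -> pd.DataFrame:
    records = []
    supply = {"public": run.config.supply.public, "private": run.config.supply.private,
              "total": run.config.supply.total}
    for res in run.results:
        for y in res.demand.years:
            for sector in ("public", "private", "total"):
                demand_v = res.demand.at(y, sector)
                records.append({
                    "year": FiscalYear(y).label,
                    "scenario": res.spec.number,
                    "uptake": res.spec.uptake,
                    "sector": sector,
                    "primaries": round_persons(demand_v),
                    "supply": round_persons(supply[sector]),
                    "gap": round_persons(max(0.0, demand_v - supply[sector])),
                    "fold": round(demand_v / supply["total"], 3) if sector == "total" else "",
                })
    return pd.DataFrame.from_records(records)


def _revisions_long(run: ModelRun) -> tuple[pd.DataFrame, pd.DataFrame]:
    attributed, occurrence = [], []
    for res in run.results:
        for y, v in res.revisions.attributed.items():
            attributed.append({
                "origin_year": FiscalYear(int(y)).label,
                "scenario": res.spec.number,
                "uptake": res.spec.uptake,
                "revisions_attributed": round_persons(v),
            })
        for y, v in res.revisions.occurrence.items():
            occurrence.append({
                "year": FiscalYear(int(y)).label,
                "scenario": res.spec.number,
                "uptake": res.spec.uptake,
                "revisions_occurring": round(float(v), 2),
            })
    return pd.DataFrame.from_records(attributed), pd.DataFrame.from_records(occurrence)


def _costs_long(run: ModelRun) -> pd.DataFrame:
    records = []
    for res in run.results:
        for y in res.costs.index:
            for component in ("primary", "revision", "total"):
                for sector in ("public", "private", "total"):
                    records.append({
                        "year": FiscalYear(int(y)).label,
                        "scenario": res.spec.number,
                        "uptake": res.spec.uptake,
                        "sector": sector,
                        "component": component,
                        "cost_aud_millions": round_millions(
                            res.costs.loc[y, (component, sector)]),
                    })
    return pd.DataFrame.from_records(records)


def run(config: str | Path | ModelConfig, scenarios: list[int] | None = None,
        uptakes: list[float] | None = None, outdir: str | Path = "out",
        seed: int | None = None) -> RunManifest:
    """Run the model and write demand/revision/cost CSVs plus a manifest.

    Deterministic: identical inputs produce identical files (the manifest's
    timestamp aside).
    """
    if isinstance(config, ModelConfig):
        cfg = config
        cfg_path, digest = "<in-memory>", _sha256_text(json.dumps(
            sorted_config_repr(cfg)))
    else:
        cfg_path = str(config)
        cfg = load_config(config)
        digest = _sha256_file(config)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model_run = run_model(cfg, scenarios=scenarios, uptakes=uptakes)

    outputs = []
    demand = _demand_long(model_run)
    attributed, occurrence = _revisions_long(model_run)
    costs = _costs_long(model_run)
    tables = {
        "demand.csv": demand,
        "revisions_attributed.csv": attributed,
        "revisions_occurring.csv": occurrence,
        "costs.csv": costs,
        "table_revisions.csv": revision_table(model_run).reset_index(),
        "table_costs.csv": cost_table(model_run).reset_index(),
    }
    for name, frame in tables.items():
        path = out / name
        frame.to_csv(path, index=False)
        outputs.append(str(path))

    manifest = RunManifest(
        config_path=cfg_path,
        config_sha256=digest,
        scenarios=scenarios or [1, 2, 3],
        uptakes=uptakes or list(cfg.uptake_levels),
        seed=seed,
        outputs=outputs,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def sorted_config_repr(cfg: ModelConfig) -> str:
    from .config import config_to_dict

    return json.dumps(config_to_dict(cfg), sort_keys=True)


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()
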