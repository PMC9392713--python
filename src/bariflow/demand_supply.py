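"""Scenario demand schedules, sector allocation, and the gap against supply.

Three provision scenarios are modelled:

1. ``newly_eligible_only`` — operate on the uptake-scaled incident flow of
   newly eligible people each year;
2. ``backlog_only`` — a fixed-duration program clearing the eligible stock of
   a reference year in equal annual tranches, uptake-scaled;
3. ``combined`` — the elementwise sum of both.

Demand is linear in uptake and additive across scenarios by construction.
Sector allocation is proportional to private-health-insurance coverage;
supply is held static at its baseline level throughout the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .config import BacklogProgram, Horizon, SupplyCapacity


class ScenarioKind(str, Enum):
    NEWLY_ELIGIBLE_ONLY = "newly_eligible_only"
    BACKLOG_ONLY = "backlog_only"
    COMBINED = "combined"


#: Conventional scenario numbering used by the CLI and reports.
SCENARIO_NUMBERS = {
    1: ScenarioKind.NEWLY_ELIGIBLE_ONLY,
    2: ScenarioKind.BACKLOG_ONLY,
    3: ScenarioKind.COMBINED,
}


@dataclass(frozen=True)
class ScenarioSpec:
    kind: ScenarioKind
    uptake: float
    program: BacklogProgram | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.uptake <= 1.0):
            raise ValueError(f"uptake must lie in (0, 1], got {self.uptake}")
        if self.kind is not ScenarioKind.NEWLY_ELIGIBLE_ONLY and self.program is None:
            raise ValueError(f"scenario kind {self.kind.value} requires a backlog program")

    @property
    def number(self) -> int:
        return {v: k for k, v in SCENARIO_NUMBERS.items()}[self.kind]


@dataclass
class DemandSchedule:
    """Primary procedures per fiscal year, with provenance and sector columns.

    ``frame`` is indexed by fiscal start year. It always carries ``incident``,
    ``backlog`` and ``total`` columns; :func:`split_by_sector` adds ``public``
    and ``private``.
    """

    frame: pd.DataFrame
    scenario: ScenarioSpec | None = None

    @property
    def total(self) -> pd.Series:
        return self.frame["total"]

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.frame.index]

    @property
    def is_sectored(self) -> bool:
        return "public" in self.frame.columns

    def at(self, year: int, column: str = "total") -> float:
        return float(self.frame.loc[int(year), column])


def schedule_demand(
    scenario: ScenarioSpec,
    stock: float | None,
    flow: pd.Series,
    horizon: Horizon,
) -> DemandSchedule:
    """Total primary-surgery demand per year under one scenario and uptake.

    ``stock`` is the eligible stock at the program's reference year (required
    for backlog scenarios); ``flow`` is the newly-eligible total per year.
    Backlog demand is uptake × stock/duration in each program year; incident
    demand is uptake × flow(y); the combined scenario sums both.
    """
    years = horizon.years
    incident = pd.Series(0.0, index=pd.Index(years, name="year"))
    backlog = incident.copy()

    if scenario.kind in (ScenarioKind.NEWLY_ELIGIBLE_ONLY, ScenarioKind.COMBINED):
        aligned = flow.reindex(years).fillna(0.0)
        incident = scenario.uptake * aligned

    if scenario.kind in (ScenarioKind.BACKLOG_ONLY, ScenarioKind.COMBINED):
        if stock is None:
            raise ValueError("backlog scenario requires the eligible stock at the "
                             "program reference year")
        program = scenario.program
        assert program is not None
        tranche = scenario.uptake * stock / program.duration
        for fy in program.years:
            if fy.start in backlog.index:
                backlog.loc[fy.start] = tranche

    frame = pd.DataFrame({"incident": incident, "backlog": backlog})
    frame["total"] = frame["incident"] + frame["backlog"]
    return DemandSchedule(frame=frame, scenario=scenario)


def split_by_sector(
    demand: DemandSchedule, phi_share: float, oop_private_fraction: float = 0.0
) -> DemandSchedule:
    """Allocate yearly demand to sectors in proportion to insurance coverage.

    The privately insured (``phi_share``) seek private care; of the uninsured,
    an optional ``oop_private_fraction`` pay out of pocket in the private
    sector; everyone else relies on public hospitals.
    """
    if not (0.0 <= phi_share <= 1.0):
        raise ValueError(f"phi_share must lie in [0, 1], got {phi_share}")
    if not (0.0 <= oop_private_fraction <= 1.0):
        raise ValueError("oop_private_fraction must lie in [0, 1]")
    private_share = phi_share + oop_private_fraction * (1.0 - phi_share)
    frame = demand.frame.copy()
    frame["private"] = private_share * frame["total"]
    frame["public"] = (1.0 - private_share) * frame["total"]
    return DemandSchedule(frame=frame, scenario=demand.scenario)


def split_series_by_sector(
    series: pd.Series, phi_share: float, oop_private_fraction: float = 0.0
) -> pd.DataFrame:
    """Insurance-proportional public/private split of any yearly series."""
    private_share = phi_share + oop_private_fraction * (1.0 - phi_share)
    return pd.DataFrame({
        "public": (1.0 - private_share) * series,
        "private": private_share * series,
        "total": series,
    })


def capacity_gap(demand: DemandSchedule, supply: SupplyCapacity) -> pd.DataFrame:
    """Per-year absolute gap by sector and demand as a fold of total capacity.

    gap(y, s) = max(0, demand(y, s) − supply(s)); fold(y) = demand(y) /
    (public + private supply), NaN when total supply is zero.
    """
    frame = demand.frame
    out = pd.DataFrame(index=frame.index)
    out["demand_total"] = frame["total"]
    if demand.is_sectored:
        out["gap_public"] = (frame["public"] - supply.public).clip(lower=0.0)
        out["gap_private"] = (frame["private"] - supply.private).clip(lower=0.0)
    out["gap_total"] = (frame["total"] - supply.total).clip(lower=0.0)
    if supply.total > 0:
        out["fold"] = frame["total"] / supply.total
    else:
        out["fold"] = np.nan
    return out


def peak_fold(demand: DemandSchedule, supply: SupplyCapacity) -> float:
    """Largest demand-to-total-capacity ratio over the horizon."""
    if supply.total <= 0:
        return math.nan
    return float((demand.total / supply.total).max())
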