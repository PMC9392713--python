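"""Project the adult population with obesity and derive the annual incident flow.

The growth model is constant per-class geometric growth: each BMI class
compounds at its own annual rate from the base-year count. The incident flow
is the year-on-year difference of the projection, floored at zero — a
shrinking class produces no newly eligible people.
"""

from __future__ import annotations

import pandas as pd

from .config import GrowthModel, Horizon, ObesityClass, PopulationTable
from .fiscal import FiscalYear


class PopulationProjection:
    """Persons by fiscal year × obesity class.

    Thin wrapper over a DataFrame indexed by fiscal start year with one
    column per class; ``.totals`` gives the per-year sum over classes.
    """

    def __init__(self, counts: pd.DataFrame, base_year: FiscalYear):
        self.counts = counts
        self.base_year = base_year

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.counts.index]

    def at(self, year: FiscalYear | int) -> pd.Series:
        y = year.start if isinstance(year, FiscalYear) else int(year)
        return self.counts.loc[y]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PopulationProjection({self.counts.index[0]}..{self.counts.index[-1]})"


def project_population(
    base: PopulationTable, growth: GrowthModel, horizon: Horizon
) -> PopulationProjection:
    """Compound each class geometrically from the base year over the horizon.

    count(y, c) = count(base, c) × (1 + rate_c)^(y − base); the projection
    always starts at the base year (≤ horizon start) so the incident flow is
    defined from the first horizon year onward.
    """
    if horizon.start.start < base.year.start:
        raise ValueError(
            f"horizon starts {horizon.start} before the base population year {base.year}"
        )
    years = list(range(base.year.start, horizon.end.start + 1))
    data = {}
    for cls in ObesityClass:
        rate = growth.rates[cls]
        base_count = base.counts[cls]
        data[cls.value] = [base_count * (1.0 + rate) ** (y - base.year.start) for y in years]
    df = pd.DataFrame(data, index=pd.Index(years, name="year"))
    return PopulationProjection(df, base.year)


def incident_flow(projection: PopulationProjection) -> pd.DataFrame:
    """Year-on-year increase per class, floored at zero.

    flow(y, c) = max(0, count(y, c) − count(y−1, c)), defined from the second
    projected year onward.
    """
    if len(projection.counts) < 2:
        raise ValueError("incident flow requires a projection spanning at least 2 years")
    flow = projection.counts.diff().iloc[1:].clip(lower=0.0)
    flow.index.name = "year"
    return flow


def calibrate_growth(
    anchor_a: tuple[FiscalYear | int, float], anchor_b: tuple[FiscalYear | int, float]
) -> float:
    """Solve the constant geometric rate connecting two (year, count) anchors.

    Returns r with count_b = count_a × (1+r)^(year_b − year_a); projecting with
    r reproduces both anchors exactly in closed form.
    """
    (ya, ca), (yb, cb) = anchor_a, anchor_b
    ya = ya.start if isinstance(ya, FiscalYear) else int(ya)
    yb = yb.start if isinstance(yb, FiscalYear) else int(yb)
    if ya == yb:
        raise ValueError("growth calibration needs two distinct years")
    if ca <= 0 or cb <= 0:
        raise ValueError("growth calibration needs positive counts at both anchors")
    span = yb - ya
    return (cb / ca) ** (1.0 / span) - 1.0
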