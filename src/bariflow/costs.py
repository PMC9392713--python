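"""Convert procedure schedules into direct medical costs by year and sector.

Costs are sector-level unit costs (AUD per procedure) applied to primary and
revision volumes; revisions are charged in the year they occur by default
(``mode="occurrence"``), or in their primary's year (``mode="attributed"``).
Only direct medical costs are modelled; prices are constant and undiscounted.
Reported figures are AUD millions at 0.1M precision, rounded only at the
reporting boundary.
"""

from __future__ import annotations

import pandas as pd

from .config import SupplyCapacity, UnitCosts
from .demand_supply import DemandSchedule, split_series_by_sector
from .revisions import RevisionSchedule

SECTORS = ("public", "private")
MILLION = 1e6


def cost_schedule(
    primaries: DemandSchedule,
    revisions: RevisionSchedule | None,
    costs: UnitCosts,
    phi_share: float | None = None,
    oop_private_fraction: float = 0.0,
    mode: str = "occurrence",
) -> pd.DataFrame:
    """AUD millions per fiscal year × sector × component (full precision).

    ``primaries`` must be sectored, or ``phi_share`` must be given so it can
    be split here; the revision stream is split with the same insurance
    proportions. Returns a frame indexed by year with MultiIndex columns
    (component ∈ {primary, revision, total}) × (sector ∈ {public, private,
    total}).
    """
    if mode not in ("occurrence", "attributed"):
        raise ValueError(f"unknown revision charging mode {mode!r}")
    frame = primaries.frame
    if not primaries.is_sectored:
        if phi_share is None:
            raise ValueError("primaries are not sectored and no phi_share was given")
        frame = frame.copy()
        sectored = split_series_by_sector(frame["total"], phi_share, oop_private_fraction)
        frame[["public", "private"]] = sectored[["public", "private"]]

    years = frame.index
    out = pd.DataFrame(index=years)
    for sector in SECTORS:
        out[("primary", sector)] = frame[sector] * costs.primary[sector] / MILLION

    if revisions is not None:
        stream = revisions.occurrence if mode == "occurrence" else revisions.attributed
        stream = stream.reindex(years).fillna(0.0)
        if phi_share is None:
            # recover the split proportions from the sectored primaries
            totals = frame["total"].replace(0.0, pd.NA)
            private_share = float((frame["private"] / totals).dropna().iloc[0]) \
                if totals.notna().any() else 0.0
        else:
            private_share = phi_share + oop_private_fraction * (1.0 - phi_share)
        rev_sector = {
            "private": stream * private_share,
            "public": stream * (1.0 - private_share),
        }
        for sector in SECTORS:
            out[("revision", sector)] = rev_sector[sector] * costs.revision[sector] / MILLION
    else:
        for sector in SECTORS:
            out[("revision", sector)] = 0.0

    for component in ("primary", "revision"):
        out[(component, "total")] = out[(component, "public")] + out[(component, "private")]
    for sector in (*SECTORS, "total"):
        out[("total", sector)] = out[("primary", sector)] + out[("revision", sector)]
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["component", "sector"])
    out.index.name = "year"
    return out


def baseline_cost_row(supply: SupplyCapacity, costs: UnitCosts) -> dict[str, float]:
    """Cost of baseline surgical activity (supply volumes at unit costs), AUD millions."""
    public = supply.public * costs.primary["public"] / MILLION
    private = supply.private * costs.primary["private"] / MILLION
    return {"public": public, "private": private, "total": public + private}


def calibrate_unit_costs(
    volumes: dict[str, float], totals_millions: dict[str, float]
) -> UnitCosts:
    """Recover per-procedure sector costs from known volumes and sector totals.

    unit(s) = total(s) × 10⁶ / volume(s); running :func:`cost_schedule` on the
    same volumes with the result reproduces the totals exactly. Revisions get
    the same sector unit cost as primaries (refine via config if per-type
    costs are available).
    """
    units: dict[str, float] = {}
    for sector in SECTORS:
        volume = volumes[sector]
        total = totals_millions[sector]
        if volume == 0:
            if total != 0:
                raise ValueError(f"{sector}: zero volume with nonzero total cost")
            units[sector] = 0.0
        else:
            units[sector] = total * MILLION / volume
    return UnitCosts(primary=dict(units), revision=dict(units))


def round_millions(value: float) -> float:
    """Reporting-boundary rounding for costs: 0.1 AUD million."""
    return round(float(value), 1)


def round_persons(value: float) -> int:
    """Reporting-boundary rounding for person counts: nearest integer."""
    return int(round(float(value)))
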