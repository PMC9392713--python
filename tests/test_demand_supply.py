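"""Scenario demand schedules, sector split, and the gap against supply."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bariflow.config import BacklogProgram, Horizon, SupplyCapacity
from bariflow.costs import round_persons
from bariflow.demand_supply import (
    ScenarioKind,
    ScenarioSpec,
    capacity_gap,
    peak_fold,
    schedule_demand,
    split_by_sector,
)
from bariflow.fiscal import FiscalYear

HORIZON = Horizon(FiscalYear(2018), FiscalYear(2029))
PROGRAM = BacklogProgram(FiscalYear(2019), FiscalYear(2022), 5)


def _flow(value=1000.0):
    return pd.Series(value, index=pd.Index(range(2018, 2030), name="year"))


def _spec(kind, uptake=1.0):
    return ScenarioSpec(kind=kind, uptake=uptake, program=PROGRAM)


class TestScheduleDemand:
    def test_backlog_full_uptake_reproduces_published_tranche(self):
        """Stock of 1,706,715 over five years → 341,343 primaries/year."""
        ds = schedule_demand(_spec(ScenarioKind.BACKLOG_ONLY), 1_706_715.0,
                             _flow(0.0), HORIZON)
        for year in range(2022, 2027):
            assert ds.at(year) == pytest.approx(341_343.0)
        assert ds.at(2021) == 0.0 and ds.at(2027) == 0.0

    def test_backlog_20_percent_uptake(self):
        ds = schedule_demand(_spec(ScenarioKind.BACKLOG_ONLY, 0.2), 1_706_715.0,
                             _flow(0.0), HORIZON)
        assert round_persons(ds.at(2022)) == 68_269

    def test_newly_eligible_only_scales_the_flow(self):
        ds = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 0.2), None,
                             _flow(44_921.0), HORIZON)
        assert ds.at(2023) == pytest.approx(0.2 * 44_921.0)
        assert (ds.frame["backlog"] == 0.0).all()

    def test_zero_inputs_give_all_zero_schedule(self):
        ds = schedule_demand(_spec(ScenarioKind.COMBINED), 0.0, _flow(0.0), HORIZON)
        assert (ds.frame == 0.0).all().all()

    def test_backlog_without_stock_is_an_error(self):
        with pytest.raises(ValueError, match="stock"):
            schedule_demand(_spec(ScenarioKind.BACKLOG_ONLY), None, _flow(), HORIZON)

    def test_program_must_be_supplied_for_backlog_kinds(self):
        with pytest.raises(ValueError, match="program"):
            ScenarioSpec(kind=ScenarioKind.BACKLOG_ONLY, uptake=0.5, program=None)

    @settings(derandomize=True, max_examples=40)
    @given(
        stock=st.floats(min_value=0.0, max_value=5e6),
        flow=st.floats(min_value=0.0, max_value=1e5),
        uptake=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_combined_is_the_sum_of_its_parts(self, stock, flow, uptake):
        parts = {
            kind: schedule_demand(_spec(kind, uptake), stock, _flow(flow), HORIZON)
            for kind in ScenarioKind
        }
        expected = (parts[ScenarioKind.NEWLY_ELIGIBLE_ONLY].total
                    + parts[ScenarioKind.BACKLOG_ONLY].total)
        pd.testing.assert_series_equal(parts[ScenarioKind.COMBINED].total, expected,
                                       check_names=False)

    @settings(derandomize=True, max_examples=40)
    @given(
        stock=st.floats(min_value=0.0, max_value=5e6),
        flow=st.floats(min_value=0.0, max_value=1e5),
        u=st.floats(min_value=0.01, max_value=0.5),
        scale=st.floats(min_value=1.0, max_value=2.0),
    )
    def test_demand_is_linear_in_uptake(self, stock, flow, u, scale):
        base = schedule_demand(_spec(ScenarioKind.COMBINED, u), stock,
                               _flow(flow), HORIZON)
        scaled = schedule_demand(_spec(ScenarioKind.COMBINED, min(1.0, u * scale)),
                                 stock, _flow(flow), HORIZON)
        factor = min(1.0, u * scale) / u
        pd.testing.assert_series_equal(scaled.total, base.total * factor,
                                       check_names=False, rtol=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        stock=st.floats(min_value=0.0, max_value=5e6),
        uptake=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_backlog_primaries_conserve_the_uptaken_stock(self, stock, uptake):
        ds = schedule_demand(_spec(ScenarioKind.BACKLOG_ONLY, uptake), stock,
                             _flow(0.0), HORIZON)
        assert ds.total.sum() == pytest.approx(uptake * stock, rel=1e-12, abs=1e-9)

    def test_combined_equals_incident_after_the_program_window(self):
        flow = _flow(50_000.0)
        combined = schedule_demand(_spec(ScenarioKind.COMBINED, 0.2), 1e6, flow, HORIZON)
        incident = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 0.2),
                                   None, flow, HORIZON)
        for year in range(2027, 2030):
            assert combined.at(year) == incident.at(year)


class TestSectorSplit:
    def test_insurance_share_split_of_the_published_flow(self):
        ds = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 1.0), None,
                             _flow(44_921.0), HORIZON)
        sectored = split_by_sector(ds, 0.46)
        assert round_persons(sectored.at(2023, "private")) == 20_664
        assert round_persons(sectored.at(2023, "public")) == 24_257

    def test_full_insurance_empties_the_public_sector(self):
        ds = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 1.0), None,
                             _flow(), HORIZON)
        assert (split_by_sector(ds, 1.0).frame["public"] == 0.0).all()

    def test_sectors_sum_to_total(self):
        ds = split_by_sector(
            schedule_demand(_spec(ScenarioKind.COMBINED, 0.35), 2e6, _flow(3e4), HORIZON),
            0.46,
        )
        pd.testing.assert_series_equal(
            ds.frame["public"] + ds.frame["private"], ds.frame["total"],
            check_names=False)

    def test_out_of_pocket_fraction_moves_uninsured_private(self):
        ds = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 1.0), None,
                             _flow(1000.0), HORIZON)
        sectored = split_by_sector(ds, 0.46, oop_private_fraction=0.5)
        assert sectored.at(2023, "private") == pytest.approx(1000.0 * (0.46 + 0.5 * 0.54))

    def test_invalid_share_rejected(self):
        ds = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 1.0), None,
                             _flow(), HORIZON)
        with pytest.raises(ValueError):
            split_by_sector(ds, 1.2)


class TestCapacityGap:
    SUPPLY = SupplyCapacity(public=3_022.0, private=38_512.0)

    def test_published_backlog_demand_is_an_eightfold_excess(self):
        ds = schedule_demand(_spec(ScenarioKind.BACKLOG_ONLY), 1_706_715.0,
                             _flow(0.0), HORIZON)
        assert peak_fold(ds, self.SUPPLY) == pytest.approx(341_343 / 41_534, rel=1e-9)
        assert peak_fold(ds, self.SUPPLY) > 8.0

    def test_demand_equal_to_supply_gives_fold_one_and_zero_gap(self):
        ds = split_by_sector(
            schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 1.0), None,
                            _flow(41_534.0), HORIZON),
            self.SUPPLY.private / self.SUPPLY.total,
        )
        gap = capacity_gap(ds, self.SUPPLY)
        assert gap["fold"].iloc[0] == pytest.approx(1.0)
        assert gap[["gap_public", "gap_private", "gap_total"]].abs().max().max() < 1e-6

    def test_public_demand_under_20pct_uptake_exceeds_public_supply(self, model_run):
        """Even 20% of newly eligible uninsured patients outstrip the public sector."""
        res = model_run.get(1, 0.2)
        assert (res.demand.frame["public"].loc[2019:] > self.SUPPLY.public).all()

    def test_zero_supply_reports_undefined_fold(self):
        ds = schedule_demand(_spec(ScenarioKind.NEWLY_ELIGIBLE_ONLY, 1.0), None,
                             _flow(), HORIZON)
        gap = capacity_gap(ds, SupplyCapacity(public=0.0, private=0.0))
        assert gap["fold"].isna().all()
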