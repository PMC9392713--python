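"""Eligibility rule evaluation and its expansion over population marginals."""

import pytest
from hypothesis import given, settings, strategies as st

from bariflow.config import (
    ComorbidityFractions,
    EossDistribution,
    ObesityClass,
    Verdict,
)
from bariflow.eligibility import (
    PersonProfile,
    classify,
    eligible_stock,
    incident_eligible,
)
from bariflow.synthetic import anzmoss_rules


RULES = anzmoss_rules()
NO_COMORBIDITY = ComorbidityFractions(class1_t2dm_poorly_controlled=0.0,
                                      class3_age_65_70_share=0.0)


class TestClassify:
    """The criteria table, row by row."""

    @pytest.mark.parametrize(
        "profile, verdict",
        [
            # class II, working age, EOSS 2 → eligible
            (PersonProfile(bmi=37, age=50, eoss=2), Verdict.ELIGIBLE),
            # class II excludes EOSS 1
            (PersonProfile(bmi=37, age=50, eoss=1), Verdict.INELIGIBLE),
            # class III seniors need EOSS 2–3; EOSS 1 not enough
            (PersonProfile(bmi=42, age=68, eoss=1), Verdict.INELIGIBLE),
            # class III 18–65 admits EOSS 1
            (PersonProfile(bmi=42, age=50, eoss=1), Verdict.ELIGIBLE),
            # class I with poorly controlled T2DM
            (PersonProfile(bmi=32, age=45, eoss=0, t2dm_poorly_controlled=True),
             Verdict.ELIGIBLE),
            # class I without it
            (PersonProfile(bmi=32, age=45, eoss=2), Verdict.INELIGIBLE),
            # class III, EOSS 4, working age → skilled-team assessment
            (PersonProfile(bmi=42, age=50, eoss=4), Verdict.CONDITIONAL_SKILLED_TEAM),
            # over the age ceiling
            (PersonProfile(bmi=37, age=72, eoss=2), Verdict.INELIGIBLE),
        ],
    )
    def test_table_rows(self, profile, verdict):
        assert classify(profile, RULES) is verdict

    def test_empty_rule_list_is_an_error(self):
        with pytest.raises(ValueError):
            classify(PersonProfile(bmi=37, age=50, eoss=2), [])

    def test_deterministic(self):
        p = PersonProfile(bmi=42, age=50, eoss=3)
        assert classify(p, RULES) is classify(p, RULES)


def _dist(class_ii_shares):
    shares = {
        ObesityClass.I: {0: 1.0},
        ObesityClass.II: class_ii_shares,
        ObesityClass.III: {0: 1.0},
    }
    return EossDistribution(shares)


def test_stock_is_population_times_allowed_stage_share():
    """1,000,000 class II with 30% EOSS 2 and 10% EOSS 3 → 400,000 eligible."""
    counts = eligible_stock(
        {ObesityClass.II: 1_000_000.0},
        _dist({0: 0.6, 2: 0.3, 3: 0.1}),
        NO_COMORBIDITY,
        RULES,
    )
    assert counts.eligible[ObesityClass.II] == pytest.approx(400_000.0)


def test_stock_zero_when_all_mass_on_disallowed_stages():
    counts = eligible_stock(
        {ObesityClass.II: 1_000_000.0},
        _dist({0: 0.5, 1: 0.3, 4: 0.2}),
        NO_COMORBIDITY,
        RULES,
    )
    assert counts.eligible[ObesityClass.II] == 0.0


def test_class_missing_from_distribution_is_an_error():
    dist = EossDistribution({ObesityClass.I: {0: 1.0}})
    with pytest.raises(KeyError, match="II"):
        eligible_stock({ObesityClass.II: 10.0}, dist, NO_COMORBIDITY, RULES)


@settings(derandomize=True, max_examples=40)
@given(
    raw=st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=5, max_size=5),
    pop=st.floats(min_value=1.0, max_value=1e7),
)
def test_enlarging_the_allowed_stage_set_never_decreases_stock(raw, pop):
    total = sum(raw)
    shares = {s: v / total for s, v in enumerate(raw)}
    from bariflow.config import EligibilityRule

    narrow = [EligibilityRule(ObesityClass.II, 18, 65, frozenset({2, 3}))]
    wide = [EligibilityRule(ObesityClass.II, 18, 65, frozenset({1, 2, 3}))]
    args = (_dist(shares), NO_COMORBIDITY)
    stock_narrow = eligible_stock({ObesityClass.II: pop}, *args, narrow)
    stock_wide = eligible_stock({ObesityClass.II: pop}, *args, wide)
    assert stock_wide.total >= stock_narrow.total - 1e-9


@settings(derandomize=True, max_examples=40)
@given(
    raw=st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=5, max_size=5),
    pop=st.floats(min_value=0.0, max_value=1e7),
    senior=st.floats(min_value=0.0, max_value=1.0),
)
def test_eligible_never_exceeds_class_population(raw, pop, senior):
    total = sum(raw)
    shares = {s: v / total for s, v in enumerate(raw)}
    dist = EossDistribution({c: shares for c in ObesityClass})
    frac = ComorbidityFractions(class1_t2dm_poorly_controlled=0.5,
                                class3_age_65_70_share=senior)
    counts = eligible_stock({c: pop for c in ObesityClass}, dist, frac, RULES)
    for cls in ObesityClass:
        assert counts.eligible[cls] <= pop + 1e-6


def test_incident_eligible_of_zero_flow_is_zero(ref_cfg):
    import pandas as pd

    flow = pd.DataFrame(0.0, index=range(2019, 2025),
                        columns=[c.value for c in ObesityClass])
    out = incident_eligible(flow, ref_cfg.eoss_distribution,
                            ref_cfg.comorbidity_fractions, ref_cfg.rules)
    assert (out == 0.0).all().all()


class TestReferenceCalibration:
    """The shipped calibration reproduces the published eligibility anchors."""

    def test_stock_near_1_8_million_by_2021(self, model_run, ref_cfg):
        from bariflow.demography import project_population
        from bariflow.eligibility import stock_at_year

        proj = project_population(ref_cfg.base_population, ref_cfg.growth,
                                  ref_cfg.horizon)
        stock = stock_at_year(ref_cfg, proj, 2021)
        assert stock.total == pytest.approx(1_800_425, rel=2e-4)

    def test_class_ii_exceeds_class_iii(self, ref_cfg):
        from bariflow.demography import project_population
        from bariflow.eligibility import stock_at_year

        proj = project_population(ref_cfg.base_population, ref_cfg.growth,
                                  ref_cfg.horizon)
        stock = stock_at_year(ref_cfg, proj, 2021)
        assert stock.eligible[ObesityClass.II] > stock.eligible[ObesityClass.III]

    def test_newly_eligible_endpoints(self, model_run):
        assert model_run.flow_total.loc[2019] == pytest.approx(44_921, rel=1e-6)
        assert model_run.flow_total.loc[2029] == pytest.approx(59_551, rel=1e-6)

    def test_flow_grows_monotonically_between_endpoints(self, model_run):
        flow = model_run.flow_total.loc[2019:2029]
        assert flow.is_monotonic_increasing


def test_microsim_agrees_with_aggregate_fractions(ref_cfg):
    """Person-by-person classification of a simulated cohort reproduces the
    aggregate eligible fraction within binomial sampling error."""
    import numpy as np

    from bariflow.synthetic import microsim_cohort

    n = 60_000
    cohort = microsim_cohort(n, ref_cfg, seed=7)
    p_hat = (cohort["verdict"] == "eligible").mean()

    total_pop = ref_cfg.base_population.total
    counts = eligible_stock(ref_cfg.base_population.counts,
                            ref_cfg.eoss_distribution,
                            ref_cfg.comorbidity_fractions, ref_cfg.rules)
    p = counts.total / total_pop
    se = np.sqrt(p * (1 - p) / n)
    assert abs(p_hat - p) < 3 * se
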