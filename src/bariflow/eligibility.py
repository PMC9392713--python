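"""ANZMOSS/EOSS eligibility: rule evaluation and population expansion.

Two surfaces, guaranteed to agree:

* :func:`classify` evaluates one person against the rule table
  (first-matching-rule semantics, mirroring the criteria table row order).
* :func:`eligible_stock` / :func:`incident_eligible` expand the same rules
  over a population by taking the exact expectation of ``classify`` over the
  discrete profile distribution implied by the config's marginals (EOSS stage
  × age band × T2DM status, independent within a BMI class).

Because the aggregate path is literally the expectation of the per-person
path, a microsimulated cohort drawn from the same marginals converges to the
aggregate counts at the binomial rate — the package's main internal oracle.

People matching a ``conditional_skilled_team`` rule (class III, EOSS 4,
18–65) are tracked separately and excluded from eligible totals unless the
config opts them in.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import (
    ComorbidityFractions,
    EligibilityRule,
    EossDistribution,
    ExtraCondition,
    ModelConfig,
    ObesityClass,
    Verdict,
)
from .demography import PopulationProjection
from .fiscal import FiscalYear

# Representative BMI per class for rule evaluation (any value inside the
# class bounds gives identical verdicts; rules key on class, not raw BMI).
REPRESENTATIVE_BMI = {ObesityClass.I: 32.0, ObesityClass.II: 37.0, ObesityClass.III: 42.0}
# Representative ages inside the two bands the rules distinguish.
AGE_BAND_MAIN = (18.0, 65.0, 40.0)  # (min, max, representative)
AGE_BAND_SENIOR = (65.0, 70.0, 67.0)


@dataclass(frozen=True)
class PersonProfile:
    """The clinical facts the eligibility rules can see."""

    bmi: float
    age: float
    eoss: int
    t2dm_poorly_controlled: bool = False
    has_established_diabetes: bool = False

    def __post_init__(self) -> None:
        if self.bmi <= 0:
            raise ValueError("BMI must be positive")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.eoss not in (0, 1, 2, 3, 4):
            raise ValueError(f"EOSS stage must be an integer in 0..4, got {self.eoss}")

    @property
    def obesity_class(self) -> ObesityClass:
        return ObesityClass.from_bmi(self.bmi)


def _rule_matches(rule: EligibilityRule, profile: PersonProfile) -> bool:
    if profile.obesity_class is not rule.obesity_class:
        return False
    if not (rule.age_min <= profile.age <= rule.age_max):
        return False
    if rule.eoss_allowed and profile.eoss not in rule.eoss_allowed:
        return False
    if rule.extra_condition is ExtraCondition.POORLY_CONTROLLED_T2DM:
        return profile.t2dm_poorly_controlled
    if rule.extra_condition is ExtraCondition.ESTABLISHED_DIABETES:
        return profile.has_established_diabetes
    return True


def classify(profile: PersonProfile, rules: list[EligibilityRule]) -> Verdict:
    """Verdict of the first matching rule; no match → ineligible."""
    if not rules:
        raise ValueError("empty rule list")
    for rule in rules:
        if _rule_matches(rule, profile):
            return rule.verdict
    return Verdict.INELIGIBLE


@dataclass
class EligibleCounts:
    """Eligible persons per class, with conditional (skilled-team) cases apart."""

    eligible: dict[ObesityClass, float]
    conditional: dict[ObesityClass, float]

    @property
    def total(self) -> float:
        return float(sum(self.eligible.values()))

    @property
    def total_conditional(self) -> float:
        return float(sum(self.conditional.values()))

    def as_series(self) -> pd.Series:
        return pd.Series({c.value: v for c, v in self.eligible.items()})


def class_verdict_fractions(
    cls: ObesityClass,
    dist: EossDistribution,
    frac: ComorbidityFractions,
    rules: list[EligibilityRule],
) -> tuple[float, float]:
    """Exact (eligible, conditional) fractions of one BMI class.

    Enumerates the discrete profile cells — EOSS stage × age band × T2DM
    status, independent marginals — and sums each cell's probability into the
    verdict bucket ``classify`` assigns it. Established diabetes is derived
    deterministically as (BMI > 35 and EOSS ∈ {2, 3}): stage 2 is where
    established obesity-related chronic disease (incl. T2DM) enters the
    staging, while stage 4 is end-stage disease with its own handling.
    """
    if cls not in dist.shares:
        raise KeyError(f"obesity class {cls.value} present in population but absent "
                       f"from the EOSS distribution")
    bmi = REPRESENTATIVE_BMI[cls]
    if cls is ObesityClass.III:
        senior = frac.class3_age_65_70_share
        age_bands = [(AGE_BAND_MAIN[2], 1.0 - senior), (AGE_BAND_SENIOR[2], senior)]
    else:
        age_bands = [(AGE_BAND_MAIN[2], 1.0)]
    if cls is ObesityClass.I:
        t2dm_branches = [(True, frac.class1_t2dm_poorly_controlled),
                         (False, 1.0 - frac.class1_t2dm_poorly_controlled)]
    else:
        t2dm_branches = [(False, 1.0)]

    eligible = 0.0
    conditional = 0.0
    for stage, stage_share in dist.shares[cls].items():
        if stage_share == 0.0:
            continue
        for age, age_share in age_bands:
            for t2dm, t2dm_share in t2dm_branches:
                weight = stage_share * age_share * t2dm_share
                if weight == 0.0:
                    continue
                profile = PersonProfile(
                    bmi=bmi,
                    age=age,
                    eoss=stage,
                    t2dm_poorly_controlled=t2dm,
                    has_established_diabetes=(bmi > 35.0 and stage in (2, 3)),
                )
                verdict = classify(profile, rules)
                if verdict is Verdict.ELIGIBLE:
                    eligible += weight
                elif verdict is Verdict.CONDITIONAL_SKILLED_TEAM:
                    conditional += weight
    return eligible, conditional


def eligible_stock(
    population: pd.Series | dict[ObesityClass, float],
    dist: EossDistribution,
    frac: ComorbidityFractions,
    rules: list[EligibilityRule],
) -> EligibleCounts:
    """Eligible stock from per-class population counts at one point in time."""
    if isinstance(population, pd.Series):
        population = {ObesityClass(str(k)): float(v) for k, v in population.items()}
    eligible: dict[ObesityClass, float] = {}
    conditional: dict[ObesityClass, float] = {}
    for cls, count in population.items():
        fe, fc = class_verdict_fractions(cls, dist, frac, rules)
        eligible[cls] = count * fe
        conditional[cls] = count * fc
    return EligibleCounts(eligible=eligible, conditional=conditional)


def incident_eligible(
    flow: pd.DataFrame,
    dist: EossDistribution,
    frac: ComorbidityFractions,
    rules: list[EligibilityRule],
    include_conditional: bool = False,
) -> pd.DataFrame:
    """Apply the per-class eligibility filter to each year's incident flow.

    Returns a DataFrame year × class of newly eligible persons, with a
    ``total`` column; conditional (skilled-team) cases are excluded unless
    ``include_conditional`` is set.
    """
    fractions = {}
    for cls in flow.columns:
        fe, fc = class_verdict_fractions(ObesityClass(cls), dist, frac, rules)
        fractions[cls] = fe + (fc if include_conditional else 0.0)
    out = flow.mul(pd.Series(fractions))
    out["total"] = out.sum(axis=1)
    return out


def stock_at_year(
    cfg: ModelConfig, projection: PopulationProjection, year: FiscalYear | int
) -> EligibleCounts:
    """Eligible stock at one fiscal year of a projection, under a config's
    distributions and rules (conditional cases folded in only if the config
    says so — see :meth:`eligible_total`)."""
    return eligible_stock(
        projection.at(year), cfg.eoss_distribution, cfg.comorbidity_fractions, cfg.rules
    )


def eligible_total(cfg: ModelConfig, counts: EligibleCounts) -> float:
    """Demand-relevant eligible total, honouring the skilled-team switch."""
    total = counts.total
    if cfg.include_conditional_in_demand:
        total += counts.total_conditional
    return total
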