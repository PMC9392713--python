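"""Model configuration: domain types, validation, and YAML I/O.

Every model input is a parameter carried by :class:`ModelConfig` — the baseline
obesity population and its growth, the EOSS stage distribution within BMI
classes, the ANZMOSS eligibility rules (data, not code), surgical supply by
sector, the private-health-insurance share, the procedure mix, per-procedure
10-year revision probabilities, and sector unit costs.

The YAML schema is strict: unknown keys are an error, and a loaded config is
validated against every structural invariant before it is returned.
Validation itself never raises; :func:`validate_config` returns a report
listing each failed invariant with its location, so a config can be inspected
wholesale rather than failing at the first defect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .fiscal import FiscalYear

__all__ = [
    "ObesityClass",
    "EossStage",
    "Verdict",
    "ExtraCondition",
    "PopulationTable",
    "GrowthModel",
    "EossDistribution",
    "ComorbidityFractions",
    "EligibilityRule",
    "SupplyCapacity",
    "ProcedureMix",
    "RevisionMatrix",
    "UnitCosts",
    "BacklogProgram",
    "Horizon",
    "ModelConfig",
    "ValidationIssue",
    "ValidationReport",
    "ConfigError",
    "load_config",
    "write_config",
    "validate_config",
    "config_to_dict",
    "config_from_dict",
]

EOSS_STAGES = (0, 1, 2, 3, 4)
REVISION_WINDOW = 10  # years over which a primary can generate its revision

_FLOAT_TOL = 1e-6


class ObesityClass(str, Enum):
    """WHO obesity classes by BMI: I = 30–35, II = 35–40, III = >40 kg/m²."""

    I = "I"
    II = "II"
    III = "III"

    @property
    def bmi_bounds(self) -> tuple[float, float]:
        return {"I": (30.0, 35.0), "II": (35.0, 40.0), "III": (40.0, math.inf)}[self.value]

    @classmethod
    def from_bmi(cls, bmi: float) -> "ObesityClass":
        if bmi < 30.0:
            raise ValueError(f"BMI {bmi} is below the obesity threshold of 30 kg/m²")
        for c in cls:
            lo, hi = c.bmi_bounds
            if lo <= bmi < hi:
                return c
        raise AssertionError("unreachable: classes cover BMI >= 30")


EossStage = int  # integer stage in 0..4 (Edmonton Obesity Staging System)


class Verdict(str, Enum):
    ELIGIBLE = "eligible"
    CONDITIONAL_SKILLED_TEAM = "conditional_skilled_team"
    INELIGIBLE = "ineligible"


class ExtraCondition(str, Enum):
    """Non-EOSS clinical condition a rule may additionally require."""

    NONE = "none"
    POORLY_CONTROLLED_T2DM = "poorly_controlled_t2dm"
    ESTABLISHED_DIABETES = "established_diabetes"


class ConfigError(ValueError):
    """Raised by :func:`load_config` for missing files, schema or invariant violations."""


@dataclass(frozen=True)
class ValidationIssue:
    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.location}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, location: str, message: str) -> None:
        self.issues.append(ValidationIssue(location, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __bool__(self) -> bool:
        return self.ok

    def __iter__(self):
        return iter(self.issues)

    def __str__(self) -> str:
        if self.ok:
            return "configuration valid"
        return "\n".join(str(i) for i in self.issues)


# ---------------------------------------------------------------------------
# Config blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationTable:
    """Adults with obesity by class, anchored to a base fiscal year."""

    year: FiscalYear
    counts: dict[ObesityClass, float]

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class GrowthModel:
    """Constant per-class geometric growth rates (fraction/year)."""

    rates: dict[ObesityClass, float]


@dataclass(frozen=True)
class EossDistribution:
    """Share of each EOSS stage within each obesity class."""

    shares: dict[ObesityClass, dict[int, float]]

    def stage_share(self, cls: ObesityClass, stages: Sequence[int]) -> float:
        return float(sum(self.shares[cls].get(s, 0.0) for s in stages))


@dataclass(frozen=True)
class ComorbidityFractions:
    """Marginal clinical fractions the eligibility rules key on.

    ``class1_t2dm_poorly_controlled`` — fraction of class I with T2DM (<10 y or
    favourable C-peptide) poorly controlled on medication.
    ``class3_age_65_70_share`` — fraction of class III aged 65–70 (the only
    class whose rules differ by age band).
    """

    class1_t2dm_poorly_controlled: float
    class3_age_65_70_share: float


@dataclass(frozen=True)
class EligibilityRule:
    """One row of the eligibility criteria table; rules are data, not code."""

    obesity_class: ObesityClass
    age_min: float
    age_max: float
    eoss_allowed: frozenset[int]
    extra_condition: ExtraCondition = ExtraCondition.NONE
    verdict: Verdict = Verdict.ELIGIBLE
    note: str = ""


@dataclass(frozen=True)
class SupplyCapacity:
    """Baseline surgical throughput (procedures/year) by sector, held static."""

    public: float
    private: float

    @property
    def total(self) -> float:
        return self.public + self.private


@dataclass(frozen=True)
class ProcedureMix:
    """Share of primary procedures by type (LAGB, RYGB, SG, ...)."""

    shares: dict[str, float]


@dataclass(frozen=True)
class RevisionMatrix:
    """Per-procedure 10-year revision probability, with an optional
    distribution of the revision over year-offsets 1..10 (default uniform)."""

    prob_10yr: dict[str, float]
    offsets: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def offset_distribution(self, procedure: str) -> tuple[float, ...]:
        if procedure in self.offsets:
            return self.offsets[procedure]
        return tuple([1.0 / REVISION_WINDOW] * REVISION_WINDOW)


@dataclass(frozen=True)
class UnitCosts:
    """Direct medical cost per procedure (AUD), by sector and component."""

    primary: dict[str, float]  # keys: public, private
    revision: dict[str, float]


@dataclass(frozen=True)
class BacklogProgram:
    """Fixed-duration program clearing the eligible stock in equal tranches."""

    stock_reference_year: FiscalYear
    start_year: FiscalYear
    duration: int

    @property
    def years(self) -> list[FiscalYear]:
        return [self.start_year + k for k in range(self.duration)]


@dataclass(frozen=True)
class Horizon:
    start: FiscalYear
    end: FiscalYear

    @property
    def years(self) -> list[int]:
        return list(range(self.start.start, self.end.start + 1))

    def __contains__(self, year) -> bool:
        y = year.start if isinstance(year, FiscalYear) else int(year)
        return self.start.start <= y <= self.end.start


@dataclass
class ModelConfig:
    """The complete, self-contained set of model inputs."""

    name: str
    currency_label: str
    horizon: Horizon
    base_population: PopulationTable
    growth: GrowthModel
    eoss_distribution: EossDistribution
    comorbidity_fractions: ComorbidityFractions
    rules: list[EligibilityRule]
    supply: SupplyCapacity
    phi_share: float
    mix: ProcedureMix
    revision_matrix: RevisionMatrix
    unit_costs: UnitCosts
    program: BacklogProgram
    uptake_levels: list[float] = field(default_factory=lambda: [0.2, 0.35, 0.75])
    oop_private_fraction: float = 0.0
    include_conditional_in_demand: bool = False

    def copy(self, **changes: Any) -> "ModelConfig":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_fraction(report: ValidationReport, loc: str, value: float, *, closed_low=True) -> None:
    if not math.isfinite(value):
        report.add(loc, f"must be finite, got {value}")
    elif not (0.0 <= value <= 1.0) or (not closed_low and value == 0.0):
        lo = "0" if closed_low else "(0"
        report.add(loc, f"probability-bound invariant: must lie in {lo}, 1], got {value}")


def validate_config(cfg: ModelConfig) -> ValidationReport:
    """Check every structural invariant; failures are report entries, not exceptions."""
    report = ValidationReport()

    # population
    for cls in ObesityClass:
        if cls not in cfg.base_population.counts:
            report.add(f"base_population.counts[{cls.value}]", "missing obesity class")
        elif cfg.base_population.counts[cls] < 0:
            report.add(f"base_population.counts[{cls.value}]", "counts must be non-negative")
    if cfg.base_population.total <= 0:
        report.add("base_population", "total population must be positive")

    # growth
    for cls in ObesityClass:
        rate = cfg.growth.rates.get(cls)
        if rate is None:
            report.add(f"growth.rates[{cls.value}]", "missing obesity class")
        elif not math.isfinite(rate) or rate <= -1.0:
            report.add(f"growth.rates[{cls.value}]", f"rate must be finite and > -1, got {rate}")

    # EOSS distribution
    for cls in ObesityClass:
        shares = cfg.eoss_distribution.shares.get(cls)
        if shares is None:
            report.add(f"eoss_distribution[{cls.value}]", "missing obesity class")
            continue
        if any(s not in EOSS_STAGES for s in shares):
            report.add(f"eoss_distribution[{cls.value}]", "stages must be integers 0..4")
        if any(v < -_FLOAT_TOL for v in shares.values()):
            report.add(f"eoss_distribution[{cls.value}]", "shares must be non-negative")
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-6:
            report.add(
                f"eoss_distribution[{cls.value}]",
                f"stage-share-sum invariant: shares must sum to 1, got {total:.6f}",
            )

    _check_fraction(report, "comorbidity_fractions.class1_t2dm_poorly_controlled",
                    cfg.comorbidity_fractions.class1_t2dm_poorly_controlled)
    _check_fraction(report, "comorbidity_fractions.class3_age_65_70_share",
                    cfg.comorbidity_fractions.class3_age_65_70_share)

    # rules
    if not cfg.rules:
        report.add("rules", "at least one eligibility rule is required")
    for i, rule in enumerate(cfg.rules):
        loc = f"rules[{i}]"
        if rule.age_min >= rule.age_max:
            report.add(loc, f"age band [{rule.age_min}, {rule.age_max}] is empty")
        if not rule.eoss_allowed and rule.extra_condition is ExtraCondition.NONE:
            report.add(loc, "rule matches no EOSS stage and requires no extra condition")
        if any(s not in EOSS_STAGES for s in rule.eoss_allowed):
            report.add(loc, "eoss_allowed must be a subset of {0..4}")

    # supply / insurance
    if cfg.supply.public < 0 or cfg.supply.private < 0:
        report.add("supply", "sector capacities must be non-negative")
    _check_fraction(report, "phi_share", cfg.phi_share)
    _check_fraction(report, "oop_private_fraction", cfg.oop_private_fraction)

    # uptake
    for i, u in enumerate(cfg.uptake_levels):
        _check_fraction(report, f"uptake_levels[{i}]", u, closed_low=False)

    # procedure mix
    if any(v < -_FLOAT_TOL for v in cfg.mix.shares.values()):
        report.add("mix", "procedure shares must be non-negative")
    mix_sum = sum(cfg.mix.shares.values())
    if abs(mix_sum - 1.0) > 1e-6:
        report.add("mix", f"mix-sum invariant: shares must sum to 1, got {mix_sum:.6f}")

    # revision matrix
    for proc, p in cfg.revision_matrix.prob_10yr.items():
        if not (0.0 <= p <= 1.0):
            report.add(f"revision_matrix.prob_10yr[{proc}]",
                       f"probability-bound invariant: must lie in [0, 1], got {p}")
    for proc, offs in cfg.revision_matrix.offsets.items():
        loc = f"revision_matrix.offsets[{proc}]"
        if len(offs) != REVISION_WINDOW:
            report.add(loc, f"offset distribution must have {REVISION_WINDOW} entries")
        elif any(o < -_FLOAT_TOL for o in offs):
            report.add(loc, "offset weights must be non-negative")
        elif abs(sum(offs) - 1.0) > 1e-6:
            report.add(loc, f"offset distribution must sum to 1, got {sum(offs):.6f}")
    for proc in cfg.mix.shares:
        if proc not in cfg.revision_matrix.prob_10yr:
            report.add(f"revision_matrix.prob_10yr[{proc}]",
                       "procedure present in mix but absent from revision matrix")

    # unit costs
    for component, table in (("primary", cfg.unit_costs.primary),
                             ("revision", cfg.unit_costs.revision)):
        for sector in ("public", "private"):
            v = table.get(sector)
            if v is None:
                report.add(f"unit_costs.{component}[{sector}]", "missing sector")
            elif v < 0:
                report.add(f"unit_costs.{component}[{sector}]", "unit costs must be non-negative")

    # horizon / program
    if cfg.horizon.end < cfg.horizon.start:
        report.add("horizon", "end precedes start")
    if cfg.base_population.year.start > cfg.horizon.start.start:
        report.add("horizon", "base population year must not be after the horizon start")
    prog = cfg.program
    if prog.duration < 1:
        report.add("program.duration", "duration must be at least 1 year")
    if prog.start_year < prog.stock_reference_year:
        report.add("program.start_year", "program cannot start before its stock reference year")
    if prog.duration >= 1 and not (prog.start_year in cfg.horizon
                                   and (prog.start_year + (prog.duration - 1)) in cfg.horizon):
        report.add("program", "horizon does not cover the program window")
    if prog.stock_reference_year.start < cfg.base_population.year.start:
        report.add("program.stock_reference_year", "precedes the base population year")

    return report


# ---------------------------------------------------------------------------
# Dict / YAML round trip
# ---------------------------------------------------------------------------


def _require_keys(mapping: Mapping[str, Any], allowed: set[str], required: set[str], loc: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{loc}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{loc}: missing required key(s) {sorted(missing)}")


def _class_dict(mapping: Mapping[str, Any], loc: str) -> dict[ObesityClass, Any]:
    out = {}
    for key, value in mapping.items():
        try:
            out[ObesityClass(str(key))] = value
        except ValueError:
            raise ConfigError(f"{loc}: unknown obesity class {key!r}") from None
    return out


def config_to_dict(cfg: ModelConfig) -> dict[str, Any]:
    """Plain-dict form of a config, suitable for YAML serialisation."""
    d: dict[str, Any] = {
        "name": cfg.name,
        "currency_label": cfg.currency_label,
        "horizon": {"start": cfg.horizon.start.start, "end": cfg.horizon.end.start},
        "base_population": {
            "year": cfg.base_population.year.start,
            "counts": {c.value: float(v) for c, v in cfg.base_population.counts.items()},
        },
        "growth": {"rates": {c.value: float(v) for c, v in cfg.growth.rates.items()}},
        "eoss_distribution": {
            c.value: {int(s): float(v) for s, v in shares.items()}
            for c, shares in cfg.eoss_distribution.shares.items()
        },
        "comorbidity_fractions": {
            "class1_t2dm_poorly_controlled": cfg.comorbidity_fractions.class1_t2dm_poorly_controlled,
            "class3_age_65_70_share": cfg.comorbidity_fractions.class3_age_65_70_share,
        },
        "rules": [
            {
                "class": r.obesity_class.value,
                "age_min": float(r.age_min),
                "age_max": float(r.age_max),
                "eoss_allowed": sorted(r.eoss_allowed),
                "extra_condition": r.extra_condition.value,
                "verdict": r.verdict.value,
                "note": r.note,
            }
            for r in cfg.rules
        ],
        "supply": {"public": cfg.supply.public, "private": cfg.supply.private},
        "phi_share": cfg.phi_share,
        "oop_private_fraction": cfg.oop_private_fraction,
        "uptake_levels": list(cfg.uptake_levels),
        "mix": {k: float(v) for k, v in cfg.mix.shares.items()},
        "revision_matrix": {
            "prob_10yr": {k: float(v) for k, v in cfg.revision_matrix.prob_10yr.items()},
            "offsets": {k: list(v) for k, v in cfg.revision_matrix.offsets.items()},
        },
        "unit_costs": {
            "primary": dict(cfg.unit_costs.primary),
            "revision": dict(cfg.unit_costs.revision),
        },
        "program": {
            "stock_reference_year": cfg.program.stock_reference_year.start,
            "start_year": cfg.program.start_year.start,
            "duration": cfg.program.duration,
        },
        "include_conditional_in_demand": cfg.include_conditional_in_demand,
    }
    return d


_TOP_KEYS = {
    "name", "currency_label", "horizon", "base_population", "growth",
    "eoss_distribution", "comorbidity_fractions", "rules", "supply", "phi_share",
    "oop_private_fraction", "uptake_levels", "mix", "revision_matrix",
    "unit_costs", "program", "include_conditional_in_demand",
}
_TOP_REQUIRED = _TOP_KEYS - {"oop_private_fraction", "include_conditional_in_demand", "name",
                             "currency_label"}


def config_from_dict(data: Mapping[str, Any]) -> ModelConfig:
    """Build a ModelConfig from its dict form; unknown keys are an error."""
    if not isinstance(data, Mapping):
        raise ConfigError("configuration root must be a mapping")
    _require_keys(data, _TOP_KEYS, _TOP_REQUIRED, "config")

    hz = data["horizon"]
    _require_keys(hz, {"start", "end"}, {"start", "end"}, "horizon")
    horizon = Horizon(FiscalYear.parse(hz["start"]), FiscalYear.parse(hz["end"]))

    bp = data["base_population"]
    _require_keys(bp, {"year", "counts"}, {"year", "counts"}, "base_population")
    base_population = PopulationTable(
        year=FiscalYear.parse(bp["year"]),
        counts={c: float(v) for c, v in _class_dict(bp["counts"], "base_population.counts").items()},
    )

    gr = data["growth"]
    _require_keys(gr, {"rates"}, {"rates"}, "growth")
    growth = GrowthModel({c: float(v) for c, v in _class_dict(gr["rates"], "growth.rates").items()})

    eoss = EossDistribution({
        c: {int(s): float(v) for s, v in shares.items()}
        for c, shares in _class_dict(data["eoss_distribution"], "eoss_distribution").items()
    })

    cf = data["comorbidity_fractions"]
    _require_keys(cf, {"class1_t2dm_poorly_controlled", "class3_age_65_70_share"},
                  {"class1_t2dm_poorly_controlled", "class3_age_65_70_share"},
                  "comorbidity_fractions")
    comorbidity = ComorbidityFractions(
        class1_t2dm_poorly_controlled=float(cf["class1_t2dm_poorly_controlled"]),
        class3_age_65_70_share=float(cf["class3_age_65_70_share"]),
    )

    rules = []
    for i, rd in enumerate(data["rules"]):
        loc = f"rules[{i}]"
        _require_keys(rd, {"class", "age_min", "age_max", "eoss_allowed",
                           "extra_condition", "verdict", "note"},
                      {"class", "age_min", "age_max", "eoss_allowed"}, loc)
        try:
            cls = ObesityClass(str(rd["class"]))
        except ValueError:
            raise ConfigError(f"{loc}: unknown obesity class {rd['class']!r}") from None
        rules.append(EligibilityRule(
            obesity_class=cls,
            age_min=float(rd["age_min"]),
            age_max=float(rd["age_max"]),
            eoss_allowed=frozenset(int(s) for s in rd["eoss_allowed"]),
            extra_condition=ExtraCondition(rd.get("extra_condition", "none")),
            verdict=Verdict(rd.get("verdict", "eligible")),
            note=str(rd.get("note", "")),
        ))

    sp = data["supply"]
    _require_keys(sp, {"public", "private"}, {"public", "private"}, "supply")
    supply = SupplyCapacity(public=float(sp["public"]), private=float(sp["private"]))

    mix = ProcedureMix({str(k): float(v) for k, v in data["mix"].items()})

    rm = data["revision_matrix"]
    _require_keys(rm, {"prob_10yr", "offsets"}, {"prob_10yr"}, "revision_matrix")
    revision_matrix = RevisionMatrix(
        prob_10yr={str(k): float(v) for k, v in rm["prob_10yr"].items()},
        offsets={str(k): tuple(float(x) for x in v) for k, v in rm.get("offsets", {}).items()},
    )

    uc = data["unit_costs"]
    _require_keys(uc, {"primary", "revision"}, {"primary", "revision"}, "unit_costs")
    unit_costs = UnitCosts(
        primary={str(k): float(v) for k, v in uc["primary"].items()},
        revision={str(k): float(v) for k, v in uc["revision"].items()},
    )

    pg = data["program"]
    _require_keys(pg, {"stock_reference_year", "start_year", "duration"},
                  {"stock_reference_year", "start_year", "duration"}, "program")
    program = BacklogProgram(
        stock_reference_year=FiscalYear.parse(pg["stock_reference_year"]),
        start_year=FiscalYear.parse(pg["start_year"]),
        duration=int(pg["duration"]),
    )

    return ModelConfig(
        name=str(data.get("name", "unnamed")),
        currency_label=str(data.get("currency_label", "AUD")),
        horizon=horizon,
        base_population=base_population,
        growth=growth,
        eoss_distribution=eoss,
        comorbidity_fractions=comorbidity,
        rules=rules,
        supply=supply,
        phi_share=float(data["phi_share"]),
        oop_private_fraction=float(data.get("oop_private_fraction", 0.0)),
        uptake_levels=[float(u) for u in data["uptake_levels"]],
        mix=mix,
        revision_matrix=revision_matrix,
        unit_costs=unit_costs,
        program=program,
        include_conditional_in_demand=bool(data.get("include_conditional_in_demand", False)),
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load, parse and fully validate a YAML model configuration.

    Raises :class:`ConfigError` naming the offending key or failed invariant;
    never returns a partially valid config.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"configuration file not found: {p}")
    with open(p, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML in {p}: {exc}") from exc
    cfg = config_from_dict(data)
    report = validate_config(cfg)
    if not report.ok:
        raise ConfigError(f"invalid configuration {p}:\n{report}")
    return cfg


def write_config(cfg: ModelConfig, path: str | Path) -> Path:
    """Serialise a config to YAML such that load_config round-trips it."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False, allow_unicode=True)
    return p
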