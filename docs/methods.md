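# Methods

## Model structure and assumptions

`bariflow` is a deterministic cohort-projection model. No individual-level
state is tracked in the main pipeline; every quantity is arithmetic over
aggregate counts and fractions. The chain is:

population projection → eligibility expansion → scenario demand →
sector split → capacity gap → revision streams → cost aggregation.

Its load-bearing assumptions:

* **Geometric growth, closed classes.** Each BMI class compounds at a
  constant annual rate. There are no births/deaths, no ageing across the
  18–70 window, and no transitions between BMI classes or EOSS stages over
  time — people do not become sicker or heavier within the horizon. A
  shrinking class contributes zero incident flow (floored difference).
* **Independence within class.** EOSS stage, age band and comorbidity status
  are independent marginals within a BMI class. No joint distribution is
  modelled; the expansion multiplies marginal fractions. The aggregate
  eligibility computation is implemented as the exact expectation of the
  per-person rule classifier over the cell distribution (stage × age band ×
  T2DM status), which is what makes the microsimulation a true oracle for it.
* **First-match rule semantics.** A person is counted once, under the first
  matching row of the criteria table. The trailing "BMI > 35 with established
  diabetes" row is retained as data, but the established-diabetes flag is
  derived as (BMI > 35 and EOSS ∈ {2, 3}) — stage 2 is where established
  obesity-related chronic disease, including T2DM, enters the staging, and
  stage 4 has its own end-stage handling — so the row never re-admits anyone
  the EOSS rows rejected and cohort and aggregate paths agree exactly.
* **Class III, EOSS 4, 18–65** is tracked separately as
  `conditional_skilled_team` and excluded from demand totals unless
  `include_conditional_in_demand` is set.
* **Static supply, proportional sectors.** Baseline sector throughput is held
  constant across the horizon. Demand splits private/public by the insurance
  share `phi_share`; `oop_private_fraction` (default 0) routes a fraction of
  the uninsured to out-of-pocket private care. Uptake is uniform across
  sectors and classes.
* **Two-state revision tree.** Each primary generates at most one revision
  within 10 years, with probability given by its procedure type; no
  re-revisions, no mortality or attrition between primary and revision. The
  revision's timing follows a per-procedure offset distribution over years
  1–10 after surgery, uniform by default (only 10-year totals were available
  to calibrate against). The attributed view (10-year total credited to the
  origin year) is the demand-reporting surface; the occurrence view is the
  costing surface.
* **Costing.** Sector-scalar unit costs, direct medical costs only, constant
  prices, no discounting. Revisions are charged in their occurrence year by
  default (`mode="attributed"` charges them with the primary instead). Person
  counts are rounded to integers and costs to 0.1 AUD million only at the
  reporting boundary; all internal arithmetic is full precision, which is why
  scenario additivity and uptake linearity hold exactly.

## Key parameters (shipped calibration)

| Parameter | Value | Units | Origin |
|---|---|---|---|
| Base population 18–70 with obesity (2017–18) | 4,919,600 | persons | published input |
| Class split I/II/III | 60 / 24 / 16 | % of base | chosen (see below) |
| Growth rate, classes II & III | 2.8594 | %/year | solved from flow anchors |
| Growth rate, class I eligible pool | 0 | %/year | solved (see below) |
| Class I poorly-controlled-T2DM fraction | 3.076 | % | solved |
| Class III share aged 65–70 | 10 | % | chosen |
| Supply public / private | 3,022 / 38,512 | procedures/yr | published input |
| Private health insurance share | 46 | % | published input |
| 10-y revision probability LAGB / RYGB / SG | 32.35 / 2.4 / 0.87 | % | published input |
| Procedure mix LAGB / RYGB / SG | 17.07 / 18 / 64.93 | % | solved (RYGB fixed) |
| Unit cost public / private | 11,714 / 11,698 | AUD/procedure | solved from baseline costs |
| Backlog program | 2022–23 start, 5 years, 2019–20 stock | — | published input |
| Uptake levels | 20 / 35 / 75 | % | published input |

## Calibration of the shipped configuration

Published values are carried verbatim; parameters only available in the
source study's supplementary material are solved in closed form from the
published outputs, in this order (each solved value is a documented stand-in,
not an estimate of the unpublished input):

1. **Growth rate.** r = (59,551 / 44,921)^(1/10) − 1 ≈ 0.028594, the rate
   connecting the newly-eligible flow endpoints of 2019–20 and 2029–30.
2. **Stock decomposition.** The 2019–20 eligible stock is 5 × 341,343 =
   1,706,715. A single shared growth rate cannot reconcile that stock with
   both flow endpoints (the implied rates differ, 2.70% vs 2.86%). Splitting
   the stock into a growing class II+III part S = flow₂₀₁₉(1+r)/r ≈ 1,615,918
   and a static class I part (≈ 90,797; growth 0) satisfies all three anchors
   exactly — and lands on a 2021–22 stock of 1,800,447 versus the published
   1,800,425, a 0.0012% residual, which is strong evidence this is the
   structure of the original calculation. (The study's own "34.6%" share for
   that stock is inconsistent with its printed numerator and denominator;
   this package reproduces counts, not that percentage.)
3. **Class allocation.** Base-year class shares 60/24/16% (a plausible
   National-Health-Survey-like split of the obese population) and a 59% class
   II share of the growing eligible stock (so class II eligible > class III,
   as reported). From these, per-class eligible fractions follow by division,
   and EOSS share vectors are backed out to realise them under the rule table
   (class II: s₂+s₃ equals the class II fraction; class III:
   (1−a)s₁ + (s₂+s₃) equals the class III fraction, with the 65–70 share a,
   s₁ = 0.12, and fixed shapes for the remainder). Several share vectors
   reproduce the same stock; the shipped one is one documented solution.
4. **Procedure mix.** With RYGB fixed at 18%, the LAGB share is solved so the
   blended 10-year revision rate equals the published primaries→revisions
   pair 637 / 9,773 ≈ 6.518%; SG takes the remainder.
5. **Unit costs.** Sector totals over sector volumes: 35.4M / 3,022 and
   450.5M / 38,512.

`reference_config()` performs this calibration at run time in float64; the
shipped YAML is its serialisation and round-trips bit-equal.

Cost-table note: absolute published cost cells beyond the baseline row depend
on per-procedure unit costs not available to this package; with
baseline-calibrated sector scalars the engine reproduces the baseline row
exactly and the published tables' additive structure (combined = sum of pure
scenarios, sectors sum to totals, exact uptake linearity), which is what the
tests assert.

## What the synthetic data does and does not emulate

`random_config` samples valid configurations (Dirichlet shares, bounded
rates and probabilities) for property tests: additivity, linearity,
conservation must hold for *any* valid configuration, not just the shipped
one. `microsim_cohort` draws individuals from the configured marginals under
the same independence assumption and simulates procedure assignment and
Bernoulli revision events; it validates the aggregate arithmetic at the
binomial-error scale (tests use n = 50,000–100,000 and 3-standard-error
bands, a few seconds on one core).

None of this makes the synthetic data more realistic than the model: real
EOSS distributions are correlated with age and comorbidity, real uptake
differs by sector and severity, and real revision hazards are not uniform in
time. Passing tests show the pipeline computes its stated model exactly —
not that the model captures joint clinical structure it deliberately omits.

## Numerical choices

* Internal arithmetic in float64 throughout; rounding only at the reporting
  boundary (persons → nearest integer, costs → 0.1M).
* The occurrence stream is an exact discrete convolution of the primary
  series with the offset kernel; conservation against the attributed view is
  exact up to float error (asserted at 1e-9).
* Degenerate inputs: zero total supply reports an undefined (NaN) fold rather
  than raising; zero-count populations propagate to all-zero schedules;
  empty rule lists, single-year projections and zero-volume/nonzero-cost
  calibrations raise with named errors.
* Validation collects all invariant violations into a report instead of
  failing at the first, so a config can be fixed wholesale; `load_config`
  refuses any config whose report is non-empty, and unknown YAML keys are
  errors rather than silently ignored.

## Known limitations

* EOSS-stage and BMI-class progression over time are not modelled, so
  eligible stocks are understated to the extent people become eligible by
  deterioration rather than by population growth.
* Clinical-assessment criteria (contraindications, documented prior
  weight-loss attempts, smoking cessation) are carried as rule labels only.
* The 65–70 age band applies within class III only; classes I and II are
  treated as entirely within the 18–65 eligibility window.
* Waiting-list dynamics, workforce constraints and differential uptake are
  out of scope; supply is a static comparator, not a queue.
* The alternative BMI-led (earlier-guideline) rule set is provided for the
  side-by-side eligibility comparison, but its relative size against the
  EOSS-staged criteria depends on the EOSS marginals supplied; the shipped
  calibration was solved against the EOSS-staged outputs only.
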