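# bariflow

A supply–demand–cost projection model for bariatric (weight-loss) surgery in
Australia, for health-economic and health-services analysts.

Access to publicly funded bariatric surgery in Australia is limited, while the
adult population with obesity keeps growing. `bariflow` quantifies that gap:
it estimates how many adults are eligible for primary bariatric surgery under
the ANZMOSS eligibility framework (which stages clinical severity with the
Edmonton Obesity Staging System, EOSS, alongside BMI class), schedules the
demand those people would generate under different provision scenarios and
uptake assumptions, splits it between the public and private hospital sectors,
propagates each year's primaries into a stream of revisional surgeries, and
aggregates the direct medical costs.

## The model

Everything is deterministic arithmetic over an explicit configuration
(`ModelConfig`, one YAML file):

1. **Demography.** Adults with obesity by BMI class (I: 30–35, II: 35–40,
   III: >40 kg/m²) compound geometrically from a base-year count
   *N<sub>c</sub>(y) = N<sub>c</sub>(y₀)(1+r<sub>c</sub>)<sup>y−y₀</sup>*;
   the incident flow is the year-on-year difference, floored at zero.
2. **Eligibility.** The ANZMOSS criteria are shipped as data (one rule per
   table row, first-match semantics): class II 18–65 at EOSS 2–3; class III
   18–65 at EOSS 1–3 (EOSS 4 flagged for skilled-team assessment); class III
   65–70 at EOSS 2–3; class I with poorly controlled T2DM. Rules are expanded
   over the config's EOSS/age/comorbidity marginals (independent within a
   class) to give an eligible stock and an annual newly-eligible flow — and
   the expansion is the exact expectation of the per-person classifier, so an
   individual-level microsimulated cohort converges to the same counts.
3. **Demand scenarios.** (1) newly eligible only: *uptake × flow(y)*;
   (2) backlog only: a fixed-duration program clearing the reference-year
   eligible stock in equal tranches, *uptake × stock/duration*;
   (3) combined: their sum. Demand is split private/public by the
   private-health-insurance share and compared against static baseline supply.
4. **Revisions.** A two-state decision tree: each primary either generates one
   revision within 10 years or none, with per-procedure probabilities blended
   through the procedure mix, Σ<sub>p</sub> mix<sub>p</sub>·prob<sub>p</sub>.
   Streams are reported both attributed to the origin year (10-year totals)
   and by occurrence year (uniform over offsets 1–10 by default).
5. **Costs.** Sector unit costs × volumes, AUD millions, revisions charged in
   their occurrence year by default; direct medical costs only, undiscounted.

The shipped `australia_2022.yaml` calibration reproduces the published
Australian figures: a 2019–20 eligible stock of 1,706,715 (341,343
primaries/year under a full-uptake 5-year program — more than eight times the
41,534 procedures/year of current capacity), newly eligible flow growing
44,921 → 59,551 over 2019–20 to 2029–30, and a baseline cost of
AUD 485.9M (35.4M public / 450.5M private).

## Worked example

```python
import bariflow as bf

cfg = bf.reference_config()                # the calibrated Australian inputs
run = bf.run_model(cfg, uptakes=[0.2])     # scenarios 1-3 at 20% uptake
res = run.get(3, 0.2)                      # combined scenario

print(f"{run.eligible_stock_reference:,.0f}")        # 1,706,715
print(f"{run.flow_total.loc[2019]:,.0f}")            # 44,921
print(f"{res.demand.at(2022):,.0f}")                 # 78,046
print(f"{res.demand.at(2022, 'public'):,.0f}")       # 42,145
print(f"{res.revisions.attributed.loc[2022]:,.0f}")  # 5,087
```

Reading: at 20% uptake the combined scenario calls for 78,046 primary
surgeries in 2022–23 (68,269 from the backlog program plus 9,777 newly
eligible), of which 42,145 fall on a public sector currently performing 3,022
procedures a year; that cohort of primaries will generate 5,087 revisional
surgeries over the following decade.

The same run from a shell:

```sh
bariflow run --config src/bariflow/data/australia_2022.yaml \
             --scenario 3 --uptake 0.2 --outdir out/
bariflow tables --config src/bariflow/data/australia_2022.yaml
```

`run` writes tidy CSVs (`demand.csv`, `revisions_attributed.csv`,
`revisions_occurring.csv`, `costs.csv`), the rendered report tables, and a
`manifest.json` with the config hash so every number is recomputable.
`bariflow simulate` draws an individual-level cohort from the same marginals
for cross-checking, and `bariflow calibrate` exposes the closed-form growth
and unit-cost solvers.

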