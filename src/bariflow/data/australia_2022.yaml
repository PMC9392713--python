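name: australia-2022
currency_label: AUD (undated)
horizon:
  start: 2018
  end: 2029
base_population:
  year: 2017
  counts:
    I: 2951760.0
    II: 1180704.0
    III: 787136.0
growth:
  rates:
    I: 0.0
    II: 0.028593947042500956
    III: 0.028593947042500956
eoss_distribution:
  I:
    0: 0.35
    1: 0.35
    2: 0.2
    3: 0.08
    4: 0.02
  II:
    0: 0.11839652200543982
    1: 0.09471721760435187
    2: 0.5495090083121666
    3: 0.21369794767695371
    4: 0.023679304401087967
  III:
    0: 0.16358570128252095
    1: 0.12
    2: 0.48128236364968857
    3: 0.20626387013558084
    4: 0.02886806493220958
comorbidity_fractions:
  class1_t2dm_poorly_controlled: 0.030760351664449074
  class3_age_65_70_share: 0.1
rules:
- class: II
  age_min: 18.0
  age_max: 65.0
  eoss_allowed:
  - 2
  - 3
  extra_condition: none
  verdict: eligible
  note: class II, 18–65, EOSS 2–3
- class: III
  age_min: 18.0
  age_max: 65.0
  eoss_allowed:
  - 1
  - 2
  - 3
  extra_condition: none
  verdict: eligible
  note: class III, 18–65, EOSS 1–3
- class: III
  age_min: 18.0
  age_max: 65.0
  eoss_allowed:
  - 4
  extra_condition: none
  verdict: conditional_skilled_team
  note: 'class III, 18–65, EOSS 4: requires a skilled bariatric team'
- class: III
  age_min: 65.0
  age_max: 70.0
  eoss_allowed:
  - 2
  - 3
  extra_condition: none
  verdict: eligible
  note: class III, 65–70, EOSS 2–3
- class: I
  age_min: 18.0
  age_max: 70.0
  eoss_allowed: []
  extra_condition: poorly_controlled_t2dm
  verdict: eligible
  note: class I, T2DM <10y or favourable C-peptide, poorly controlled with medication
- class: II
  age_min: 18.0
  age_max: 70.0
  eoss_allowed: []
  extra_condition: established_diabetes
  verdict: eligible
  note: BMI > 35 with established diabetes
- class: III
  age_min: 18.0
  age_max: 70.0
  eoss_allowed: []
  extra_condition: established_diabetes
  verdict: eligible
  note: BMI > 35 with established diabetes
supply:
  public: 3022.0
  private: 38512.0
phi_share: 0.46
oop_private_fraction: 0.0
uptake_levels:
- 0.2
- 0.35
- 0.75
mix:
  LAGB: 0.1706657445486495
  RYGB: 0.18
  SG: 0.6493342554513506
revision_matrix:
  prob_10yr:
    LAGB: 0.3235
    RYGB: 0.024
    SG: 0.0087
  offsets: {}
unit_costs:
  primary:
    public: 11714.09662475182
    private: 11697.652679684254
  revision:
    public: 11714.09662475182
    private: 11697.652679684254
program:
  stock_reference_year: 2019
  start_year: 2022
  duration: 5
include_conditional_in_demand: false
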