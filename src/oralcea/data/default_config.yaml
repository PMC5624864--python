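# Default analysis configuration: the published model inputs.
#
# Probability parameters are derived from the cohort counts below; costs and
# resources carry their base value, deterministic low/high range, and PSA
# distribution (kind followed by its shape parameters).  All costs are 2014
# CAD from the combined private-payer and patient perspective.

counts:
  per_grade: {Severe: 29, Moderate: 38, Mild: 40}
  per_grade_risk:
    Severe:   {High: 27, Medium: 2,  Low: 0}
    Moderate: {High: 6,  Medium: 32, Low: 0}
    Mild:     {High: 0,  Medium: 20, Low: 20}
  cancers_per_grade: {Severe: 22, Moderate: 24, Mild: 15}
  cancers_per_grade_risk:
    Severe:   {High: 22, Medium: 0,  Low: 0}
    Moderate: {High: 5,  Medium: 19, Low: 0}
    Mild:     {High: 0,  Medium: 11, Low: 4}

costs:
  cHistopathology:
    {base: 88, low: 70.4, high: 105.6, dist: [gamma, 100, 0.88],
     units: 2014 CAD, source: provincial fee schedule}
  cBiomarker:
    {base: 250, low: 200, high: 300, dist: [gamma, 100, 2.5],
     units: 2014 CAD, source: manufacturer}
  cExcision:
    {base: 384, low: 307.2, high: 460.8, dist: [gamma, 100, 3.84],
     units: 2014 CAD, source: provincial fee schedule}
  cFollow-up:
    {base: 129, low: 103.2, high: 154.8, dist: [gamma, 100, 1.29],
     units: 2014 CAD, source: provincial fee schedule}
  cPathology:
    {base: 95, low: 76, high: 114, dist: [gamma, 100, 0.95],
     units: 2014 CAD, source: expert opinion}
  cPainMed_T2:
    {base: 12.65, low: 10.15, high: 15.15, dist: [gamma, 100, 0.127],
     units: 2014 CAD, source: expert opinion}
  cPainMed_P:
    {base: 25.17, low: 22.67, high: 27.67, dist: [gamma, 100, 0.252],
     units: 2014 CAD, source: expert opinion}
  cWork_Loss:
    {base: 25.42, low: 20.336, high: 30.504, dist: [gamma, 100, 0.254],
     units: 2014 CAD per hour, source: national wage statistics}
  cTransportation:
    {base: 0.575, low: 0.46, high: 0.69, dist: [gamma, 100, 0.00575],
     units: 2014 CAD per km, source: national travel statistics}
  cParking:
    {base: 20, low: 16, high: 24, dist: [gamma, 100, 0.2],
     units: 2014 CAD per visit, source: assumption}

resources:
  HRSofWORK:
    {base: 24, low: 0, high: 40, dist: [gamma, 100, 0.24],
     units: hours per excision episode, source: expert opinion}
  avgDISTANCE:
    {base: 60, low: 48, high: 72, dist: [gamma, 100, 0.6],
     units: km per round trip, source: assumption}
  employed:
    {base: 0.927, dist: [fixed],
     units: proportion, source: national employment statistics}
  V_E6M_year:
    {base: 2, low: 1, high: 3, dist: [fixed],
     units: visits per year, source: expert opinion}
  V_E3M_year:
    {base: 4, low: 3, high: 5, dist: [fixed],
     units: visits per year, source: expert opinion}

effects:
  rrMT:
    {base: 0.51, low: 0.230, high: 1.140, dist: [lognormal, -0.673, 0.408],
     units: relative risk, source: systematic review and meta-analysis}

# Management actions per classification label.  Histology-managed excised
# lesions are followed 3-monthly after surgery and surveilled mild lesions
# reviewed 6-monthly; under biomarker stratification the follow-up
# intensity scales with the risk call (High 3-monthly, Medium and Low
# 6-monthly) — the de-escalation of confidently lower-risk patients is the
# test's resource-saving mechanism.  Visit symbols resolve against the
# registry so one-way sensitivity analysis on visit frequency flows
# through.
policy:
  histopathology:
    actions: {Severe: excision, Moderate: excision, Mild: surveillance}
    post_excision_visits: {Severe: V_E3M_year, Moderate: V_E3M_year}
    surveillance_visits: {Mild: V_E6M_year}
  straticyte:
    actions: {High: excision, Medium: excision, Low: surveillance}
    post_excision_visits: {High: V_E3M_year, Medium: V_E6M_year}
    surveillance_visits: {Low: V_E6M_year}

ledger:
  per_visit_work_loss_hours: 0
  parking_mode: per_visit

discount:
  annual_rate: 0.05
  first_discounted_year: 2

horizon_years: 5

scenarios:
  base_case:  {straticyte_applied_to: [Severe, Moderate, Mild]}
  scenario_1: {straticyte_applied_to: [Moderate, Mild]}
  scenario_2: {straticyte_applied_to: [Mild]}

psa:
  n_draws: 5000
  seed: 0
  wtp_min: 0
  wtp_max: 100000
  wtp_step: 1000
  truncate_probabilities: true
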