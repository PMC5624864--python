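# Methods

## Model structure and assumptions

The model is a two-arm decision tree evaluated on a cohort of adults with
biopsy-confirmed oral epithelial dysplasia, over a fixed 5-year horizon.
Terminal events are 5-year cumulative malignant transformations; there is
no annual cycling, no state transition after the classification step, and
no modelling of time-to-progression. The key behavioural assumption is
that classification determines management deterministically (a treatment
policy maps each grade or risk class to excision or surveillance, plus a
follow-up visit schedule), and that excision acts multiplicatively on the
5-year cancer probability through a single relative risk `rrMT`.

Probabilities come from a 107-patient retrospective cohort observed
without excision: grade shares (29/38/40), risk-class splits within grade,
and malignant transformations per (grade, risk) cell. The registry stores
them as conjugate-count distributions (Dirichlet for simplex splits, Beta
for conditional event probabilities), so the base-case values are exact
count ratios and every probabilistic draw lies on the simplex by
construction. Cells with zero observed patients or zero observed cancers
carry no information about the event probability; they are represented
explicitly as *unavailable* and held at constant zero everywhere — base
case, one-way analysis, and all Monte-Carlo draws.

### Policy reconciliation

The elicited excision policy is not part of the shipped inputs; it is
recovered by evaluating all 2³ × 2³ = 64 excision assignments (per grade in
the comparator arm, per risk class in the biomarker arm) and keeping those
whose per-arm expected cancer cases, rounded half-up to two decimals, match
the published totals (0.36 and 0.31). On the shipped registry exactly one
assignment matches — excise Severe and Moderate grades, excise High and
Medium risk — and a regression test pins this uniqueness. If the registry
is perturbed so that no assignment matches, the reconciliation reports the
nearest candidates instead of guessing.

## Key parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `rrMT` | relative risk of 5-year malignant transformation with excision | 0.51 (LogNormal ln-mean −0.673, ln-SE 0.408) | ratio |
| `cBiomarker` | biomarker test fee, once per stratified patient | 250 | 2014 CAD |
| `cExcision` + pain meds | excision episode (one-time) | 384 + 12.65 + 25.17 | 2014 CAD |
| `cFollow-up` | fee per follow-up visit | 129 | 2014 CAD |
| `cTransportation`·`avgDISTANCE` | travel per clinic trip (printed distance treated as the full round trip, no doubling) | 0.575 × 60 | 2014 CAD |
| `cParking` | parking charge per visit | 20 | 2014 CAD |
| `cWork_Loss`·`HRSofWORK`·`employed` | absenteeism per excision episode | 25.42 × 24 × 0.927 | 2014 CAD |
| `V_E3M_year`, `V_E6M_year` | 3-monthly / 6-monthly schedules | 4, 2 | visits/year |
| discount rate | applied to costs beyond year 1 | 5% | per year |

The relative-risk point estimate is the back-transformed log estimate
`exp(ln-mean) = 0.51` (the log-normal median), not the arithmetic mean
`exp(μ + σ²/2)`; that is the value the rest of the model consumes, and the
registry validator enforces base-vs-distribution consistency on that
convention (within 0.001 for probabilities, 0.5% for costs).

Deterministic ranges for count-derived probabilities are normal-approximation
95% bounds `p ± 1.96·√(p(1−p)/n)` with the lower bound floored at zero and
the upper bound left uncapped (a near-boundary cell can print a bound above
1); truncation to [0, 1] happens only at use time in the one-way analysis.
Parameters without a stored range fall back to mean ± 20%.

## Cost composition (a documented calibration)

The per-path cost composition is configuration, not data. The default
ledger attaches: histopathology reading + pathology report to every
patient; the biomarker fee once per stratified patient; the excision
bundle, one absenteeism episode and one travel round trip to excised
paths; and a discounted per-visit stream (follow-up fee + travel +
parking) at the path's schedule. Default schedules: histology-managed
patients get 3-monthly follow-up after excision and 6-monthly surveillance
for unexcised mild lesions; under biomarker stratification the schedule
scales with the risk call (High 3-monthly, Medium and Low 6-monthly).
The risk-informed de-escalation of follow-up is the mechanism by which the
test can pay for its own fee, and with it the default configuration
reproduces the qualitative published pattern: dominance in the base case
and the moderate+mild scenario, and a positive ICER in the mild-only
scenario. Dollar totals are sensitive to this composition and are
deliberately not treated as fixed outputs of the package; every attachment
can be overridden in the `ledger`/`policy` config sections. Two readings of
the parking row are supported (`per_visit` charge, the default, or a
`total_events` count with an explicit per-event price).

Discounting follows the convention that only costs beyond the first year
are discounted: year *t* carries factor `(1+r)^−(t−1)` for `t ≥ 2`. Health
effects are not discounted by default: the 5-year cancer probabilities are
single terminal quantities with no event-timing information, and the
published per-arm totals are reproduced exactly by undiscounted
expectations. (`DiscountSpec` can be pointed at effects by the caller, but
nothing in the shipped pipeline does so.)

## Sensitivity analysis

**One-way:** each parameter is set to its low and high value with all
others at base. Moving one component of a probability simplex renormalizes
its siblings proportionally, so the tree's path probabilities always sum
to one. The discount rate is exposed as a pseudo-parameter varied over
0–10%. Entries are ranked by the swing of the incremental net monetary
benefit at a reference willingness-to-pay (default $10,000/case avoided),
which captures both cost-side and effect-side leverage in one ordering.

**Probabilistic:** 5,000 Monte-Carlo draws by default. Grade mixes and
risk splits are drawn jointly per simplex (Dirichlet over the observed
counts, zero-count components pinned at zero), cancer probabilities from
conjugate Betas, costs from Gammas, `rrMT` from its log-normal; `employed`
and the visit-frequency parameters are fixed. The ledger is rebuilt from
the sampled values in every draw. Ties in NMB are split equally between
the strategies so CEAC fractions always partition the draws. The default
willingness-to-pay grid is $0–100,000 per case avoided in $1,000 steps.

## Meta-analysis

`rrMT` is produced by fixed-effect pooling of per-study 2×2 tables
(events/total, excision vs. none). Mantel–Haenszel weighting with the
Greenland–Robins variance is the default; inverse-variance pooling on the
log scale is available. Studies with a single zero cell are continuity-
corrected by adding 0.5 to all four cells; double-zero studies are excluded
with a warning. The pooled `(ln RR, SE)` exports directly as the registry's
log-normal parameterization.

## Synthetic data and what passing tests show

The cohort generator draws grade ~ multinomial, risk|grade ~ multinomial,
cancer|(grade, risk) ~ Bernoulli, with defaults equal to the observed
cohort's count ratios (n = 107); grade-level cancer counts are aggregated
from the cell level, so the two-partition conservation invariant holds by
construction. The study-set generator draws binomial arms at a known
control rate and true RR. These generators reproduce the *sampling
structure* the estimators assume — they do not emulate grading
misclassification, correlated costs, loss to follow-up, or secular changes
in practice, so passing recovery tests demonstrates internal consistency
of the estimators, not robustness to real-world violations.

Recovery experiments use cohort sizes {10³, 10⁴, 10⁵} with 8 replications
each (the acceptance-scale run) — large enough that the monotone-RMSE and
±0.01 recovery checks are far from their noise floor while the whole suite
stays interactive.

## Numerical conventions

- Reported per-arm totals are rounded **half-up** to two decimals
  (`0.375 → 0.38`), and "cases avoided" is the difference of the two
  rounded totals (the raw difference is also carried for NMB/PSA use).
- Dominance requires strictly lower cost and strictly positive cases
  avoided; a zero effect difference yields a verdict, never a division.
- All randomness flows through explicitly seeded `numpy` generators;
  replicate seeds in the recovery experiment are spawned from a
  `SeedSequence` and kept below 2³¹.
- Cost itemizations must reconcile with path totals to $0.01; the
  registry validator, the tree's path-sum check (1 ± 10⁻⁹), and the count
  validators all raise rather than renormalize silently.

## Known limitations

- No QALY outcomes, no cancer-treatment costs (consistent with the
  private-payer/patient perspective), no Markov extension, no
  time-to-event modelling.
- The dollar outputs depend on the calibrated default ledger composition;
  they should be read as a configurable scaffold, not as authoritative
  costing of any particular jurisdiction.
- Fixed-effect pooling only; no heterogeneity statistics or
  random-effects models.
- The deterministic bounds convention (uncapped upper bounds) mirrors the
  source parameter table rather than enforcing probabilistic coherence;
  downstream consumers must truncate, as the one-way analysis does.
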