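# oralcea

Early (pre-market) cost-effectiveness analysis of adding a biomarker
risk-stratification test to histopathology for **oral epithelial
dysplasia**.

Oral dysplasia is graded Mild / Moderate / Severe from a biopsy; grading is
subjective, and a substantial fraction of lesions progress to oral cancer
within five years. A prognostic biomarker test re-stratifies lesions into
High / Medium / Low 5-year cancer risk. `oralcea` implements the
decision-analytic machinery to ask: *is it worth adding the test?* It is
aimed at health-economics and HTA analysts who want a scriptable,
reproducible version of this class of early decision model.

## The model

A two-arm decision tree over a 5-year horizon:

- **Comparator** — histopathology alone: each patient lands on one of three
  terminal paths (the grades) with probability `p_g`; managed by excision
  or surveillance per grade.
- **Intervention** — histopathology + biomarker: grades under test
  stratification fan out over risk classes with probability
  `p_g × p_{r|g}`; managed per risk class.

Each path carries a 5-year malignant-transformation probability `p_C`
(observed in a 107-patient retrospective cohort with no excision).
Excision multiplies it by the relative risk `rrMT`, pooled from the
literature by fixed-effect (Mantel–Haenszel) meta-analysis:

```
E[cases per patient] = Σ_paths  p_path · p_C · rrMT^{1[excised]}
```

Costs (2014 CAD, private-payer + patient perspective) attach to paths via a
configurable ledger — test fees, excision bundle, follow-up visit streams,
travel, parking, and absenteeism — with costs beyond year one discounted at
5% per year. Strategies are compared by incremental cost, cancer cases
avoided, and the ICER (CAD per cancer case avoided) or a dominance verdict;
decision uncertainty is summarized by net monetary benefit
`NMB = −C − λ·E` and cost-effectiveness acceptability curves over a
willingness-to-pay grid.

All probability parameters are derived from the cohort's conjugate counts
(Dirichlet/Beta), so the simplex constraints hold exactly, in the base case
and in every Monte-Carlo draw. Cells the cohort never observed are held at
a constant zero everywhere. A distinctive feature: the excision policy
(which branches are excised) is **recovered computationally** by exhaustive
search over all 64 assignments against the published per-arm totals, rather
than configured by hand — on the shipped inputs the solution is unique.

## Worked example

```
$ oralcea --out-dir out scenario
```

prints (abridged):

```
  scenario                       strategy   total_cost total_cases_rounded cases_avoided       icer_or_verdict
 base_case histopathology_plus_straticyte  3463.03                 0.31
 base_case                 histopathology  3548.42                 0.36
 base_case                    incremental                                           0.05              dominant
scenario_1                    incremental                                           0.07              dominant
scenario_2                    incremental                                           0.14 5507 CAD/case avoided
```

Reading: in the base case the biomarker arm expects 0.31 cancer cases per
patient over five years versus 0.36 without it (0.05 avoided per patient,
i.e. 5 per 100), at a lower expected cost — it *dominates*. Restricting the
test to moderate+mild lesions (scenario 1) preserves dominance; applying it
only to mild lesions (scenario 2) avoids the most cases (0.14) but at a
price of about $5.5k per cancer case avoided. Under the default ledger a
5000-draw probabilistic sensitivity analysis prefers the biomarker arm in
~79% of draws at a willingness-to-pay of zero, rising to ~83% at
$100,000/case avoided.

Other subcommands: `validate`, `basecase`, `owsa` (tornado table), `psa`
(draws + CEAC), `pool` (meta-analysis from a study CSV), `simulate`
(synthetic cohort + study set). Everything is driven by one YAML
configuration (`src/oralcea/data/default_config.yaml` is the shipped
default) and is reproducible from a seed.

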