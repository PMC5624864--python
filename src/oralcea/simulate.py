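"""Synthetic data generation and parameter-recovery experiments.

Two generators mirror the statistical structure the analysis assumes:

- :func:`simulate_cohort` draws a retrospective dysplasia cohort: histology
  grade ~ multinomial over the grade mix, biomarker risk class ~ multinomial
  within grade, and 5-year malignant transformation ~ Bernoulli per
  (grade, risk) cell, with no excision.  Cancer is simulated on the finest
  partition and grade-level counts are aggregated from it, so the
  two-partition count-conservation invariant holds by construction.
- :func:`simulate_meta_studies` draws a set of transformation-rate studies
  with a known true control-arm rate and true relative risk, for exercising
  the pooling machinery.

Defaults reproduce the observed cohort's structure (n = 107, count-ratio
probabilities), so simulated datasets have zero counts exactly where the
source cohort does.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta import StudyCounts
from .parameters import (
    GRADES,
    RISKS,
    CohortCounts,
    counts_to_probabilities,
    table_counts,
)
from .tree import Strategy, TreatmentPolicy, enumerate_paths, expected_cancer_cases


def _default_truth() -> tuple[dict, dict, dict]:
    counts = table_counts()
    n = counts.n_total
    grade_mix = {g: counts.per_grade[g] / n for g in GRADES}
    risk_split = {
        g: {r: counts.per_grade_risk[(g, r)] / counts.per_grade[g] for r in RISKS}
        for g in GRADES
    }
    p_cancer = {
        (g, r): (
            counts.cancers_per_grade_risk[(g, r)] / counts.per_grade_risk[(g, r)]
            if counts.per_grade_risk[(g, r)] > 0
            else 0.0
        )
        for g in GRADES
        for r in RISKS
    }
    return grade_mix, risk_split, p_cancer


@dataclass(frozen=True)
class CohortSimSpec:
    """True generating parameters of a synthetic cohort."""

    n_patients: int = 107
    grade_mix: Mapping[str, float] = field(default_factory=lambda: _default_truth()[0])
    risk_split: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _default_truth()[1]
    )
    p_cancer: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: _default_truth()[2]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.grade_mix[g] for g in GRADES) - 1.0) > 1e-9:
            raise ValueError("grade mix must sum to 1")
        for g in GRADES:
            if abs(sum(self.risk_split[g][r] for r in RISKS) - 1.0) > 1e-9:
                raise ValueError(f"risk split for {g} must sum to 1")
        for cell, p in self.p_cancer.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"cancer probability for {cell} outside [0, 1]")


def simulate_cohort(spec: CohortSimSpec) -> CohortCounts:
    """Draw one synthetic cohort; the result always validates."""
    rng = np.random.default_rng(spec.seed)
    grade_counts = rng.multinomial(
        spec.n_patients, [spec.grade_mix[g] for g in GRADES]
    )
    per_grade = dict(zip(GRADES, (int(c) for c in grade_counts)))
    per_grade_risk: dict[tuple[str, str], int] = {}
    cancers_cell: dict[tuple[str, str], int] = {}
    for g in GRADES:
        risk_counts = rng.multinomial(
            per_grade[g], [spec.risk_split[g][r] for r in RISKS]
        )
        for r, n_gr in zip(RISKS, risk_counts):
            n_gr = int(n_gr)
            per_grade_risk[(g, r)] = n_gr
            p = spec.p_cancer.get((g, r), 0.0)
            cancers_cell[(g, r)] = int(rng.binomial(n_gr, p)) if n_gr else 0
    cancers_grade = {
        g: sum(cancers_cell[(g, r)] for r in RISKS) for g in GRADES
    }
    cohort = CohortCounts(
        per_grade=per_grade,
        per_grade_risk=per_grade_risk,
        cancers_per_grade=cancers_grade,
        cancers_per_grade_risk=cancers_cell,
    )
    cohort.validate()
    return cohort


@dataclass(frozen=True)
class MetaSimSpec:
    """True generating parameters of a synthetic study set."""

    k_studies: int = 10
    n_excision: int = 500
    n_no_excision: int = 500
    control_mtr: float = 0.3
    true_rr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not (0.0 <= self.control_mtr <= 1.0):
            raise ValueError("control MTR must be a probability")
        if self.true_rr <= 0:
            raise ValueError("true RR must be positive")
        if self.true_rr * self.control_mtr > 1.0:
            raise ValueError(
                "true RR x control MTR exceeds 1; excision-arm rate is not a "
                "probability"
            )


def simulate_meta_studies(spec: MetaSimSpec) -> list[StudyCounts]:
    rng = np.random.default_rng(spec.seed)
    p_exc = spec.true_rr * spec.control_mtr
    studies = []
    for k in range(spec.k_studies):
        studies.append(
            StudyCounts(
                study=f"synthetic_{k + 1:02d}",
                events_excision=int(rng.binomial(spec.n_excision, p_exc)),
                n_excision=spec.n_excision,
                events_no_excision=int(rng.binomial(spec.n_no_excision, spec.control_mtr)),
                n_no_excision=spec.n_no_excision,
            )
        )
    return studies


# --- parameter recovery --------------------------------------------------


def _true_arm_expectation(
    spec: CohortSimSpec,
    histology_policy: TreatmentPolicy,
    risk_policy: TreatmentPolicy | None,
    rr_mt: float,
) -> float:
    """Arm expectation computed exactly from the generating parameters."""
    from .tree import EXCISION

    total = 0.0
    for g in GRADES:
        w = spec.grade_mix[g]
        if risk_policy is None:
            # histopathology arm: grade-level cancer probability is the
            # risk-split-weighted cell probability.
            p_c = sum(
                spec.risk_split[g][r] * spec.p_cancer.get((g, r), 0.0) for r in RISKS
            )
            rr = rr_mt if histology_policy.action(g) == EXCISION else 1.0
            total += w * p_c * rr
        else:
            for r in RISKS:
                p_r = spec.risk_split[g][r]
                if p_r <= 0:
                    continue
                p_c = spec.p_cancer.get((g, r), 0.0)
                rr = rr_mt if risk_policy.action(r) == EXCISION else 1.0
                total += w * p_r * p_c * rr
    return total


def recovery_experiment(
    n_grid: Sequence[int],
    replications: int,
    seed: int,
    spec: CohortSimSpec | None = None,
    histology_policy: TreatmentPolicy | None = None,
    risk_policy: TreatmentPolicy | None = None,
    rr_mt: float = 0.51,
) -> pd.DataFrame:
    """Bias/RMSE of the recovered arm-level cancer expectation vs. the truth.

    For each cohort size in ``n_grid``, repeatedly simulates a cohort,
    derives probabilities from its counts, evaluates both arms' expected
    cancer cases, and compares them to the expectations computed exactly
    from the generating parameters.
    """
    from .tree import EXCISION, SURVEILLANCE

    base = spec or CohortSimSpec()
    histology_policy = histology_policy or TreatmentPolicy(
        actions={"Severe": EXCISION, "Moderate": EXCISION, "Mild": SURVEILLANCE}
    )
    risk_policy = risk_policy or TreatmentPolicy(
        actions={"High": EXCISION, "Medium": EXCISION, "Low": SURVEILLANCE}
    )
    truth_h = _true_arm_expectation(base, histology_policy, None, rr_mt)
    truth_c = _true_arm_expectation(base, histology_policy, risk_policy, rr_mt)

    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        errs_h, errs_c = [], []
        for child in seed_seq.spawn(replications):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            sim_spec = CohortSimSpec(
                n_patients=int(n),
                grade_mix=base.grade_mix,
                risk_split=base.risk_split,
                p_cancer=base.p_cancer,
                seed=rep_seed,
            )
            counts = simulate_cohort(sim_spec)
            reg = counts_to_probabilities(counts)
            values = reg.values_dict()
            values["rrMT"] = rr_mt
            from .tree import mix_from_values

            mix = mix_from_values(values)
            e_h = expected_cancer_cases(
                enumerate_paths(Strategy.histopathology(histology_policy), values, mix)
            )
            e_c = expected_cancer_cases(
                enumerate_paths(
                    Strategy.combined(risk_policy, histology_policy), values, mix
                )
            )
            errs_h.append(e_h - truth_h)
            errs_c.append(e_c - truth_c)
        errs_h_a = np.asarray(errs_h)
        errs_c_a = np.asarray(errs_c)
        rows.append(
            {
                "n": int(n),
                "replications": replications,
                "truth_histopathology": truth_h,
                "truth_combined": truth_c,
                "bias_histopathology": float(errs_h_a.mean()),
                "bias_combined": float(errs_c_a.mean()),
                "mae_histopathology": float(np.abs(errs_h_a).mean()),
                "mae_combined": float(np.abs(errs_c_a).mean()),
                "rmse_histopathology": float(np.sqrt((errs_h_a**2).mean())),
                "rmse_combined": float(np.sqrt((errs_c_a**2).mean())),
            }
        )
    return pd.DataFrame(rows)
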