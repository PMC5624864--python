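"""Base-case and scenario cost-effectiveness comparisons.

A comparison evaluates both arms on the same population, reports expected
5-year cost and cancer cases per arm, and classifies the result: the
combined strategy *dominates* when it is cheaper and more effective, is
*dominated* when dearer and less effective, and otherwise the incremental
cost-effectiveness ratio (ICER, CAD per cancer case avoided) is reported.

Cancer cases avoided are reported as the difference of the two per-arm
totals each rounded half-up to two decimals, matching the convention of the
published tables; the raw (unrounded) difference is carried alongside for
downstream use (NMB, PSA).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

from .costs import CostLedger, DiscountSpec, arm_expected_cost
from .parameters import GRADES, ParameterRegistry
from .tree import (
    Strategy,
    TreatmentPolicy,
    enumerate_paths,
    expected_cancer_cases,
    mix_from_values,
    restrict_mix,
    round_half_up,
)

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADEOFF = "tradeoff"
NO_EFFECT_DIFFERENCE = "no effect difference"
NO_DIFFERENCE = "no difference"


@dataclass(frozen=True)
class ScenarioSpec:
    """Which grades the biomarker is applied to, and on what population.

    The comparator arm is always evaluated on the same (restricted,
    renormalized) population as the combined arm.
    """

    name: str
    straticyte_applied_to: tuple[str, ...]
    population_grades: tuple[str, ...]

    @staticmethod
    def base_case() -> "ScenarioSpec":
        return ScenarioSpec("base_case", GRADES, GRADES)

    @staticmethod
    def moderate_and_mild() -> "ScenarioSpec":
        return ScenarioSpec("scenario_1", ("Moderate", "Mild"), ("Moderate", "Mild"))

    @staticmethod
    def mild_only() -> "ScenarioSpec":
        return ScenarioSpec("scenario_2", ("Mild",), ("Mild",))


STANDARD_SCENARIOS = {
    "base_case": ScenarioSpec.base_case(),
    "scenario_1": ScenarioSpec.moderate_and_mild(),
    "scenario_2": ScenarioSpec.mild_only(),
}


@dataclass(frozen=True)
class CEAResult:
    scenario: str
    cost_combined: float
    cost_comparator: float
    cases_combined: float            # raw expectation
    cases_comparator: float
    incremental_cost: float          # combined - comparator
    cases_avoided: float             # difference of rounded per-arm totals
    cases_avoided_raw: float
    icer: float | None
    verdict: str

    @property
    def cases_combined_rounded(self) -> float:
        return round_half_up(self.cases_combined)

    @property
    def cases_comparator_rounded(self) -> float:
        return round_half_up(self.cases_comparator)

    @property
    def icer_or_verdict(self) -> str:
        if self.verdict == TRADEOFF and self.icer is not None:
            return f"{self.icer:.0f} CAD/case avoided"
        return self.verdict


def icer_and_verdict(
    incremental_cost: float, cases_avoided: float
) -> tuple[float | None, str]:
    """Classify an incremental (cost, effect) pair.

    ``cases_avoided`` is on the "more is better" scale (comparator cases
    minus combined cases).
    """
    if incremental_cost < 0 and cases_avoided > 0:
        return None, DOMINANT
    if incremental_cost > 0 and cases_avoided < 0:
        return None, DOMINATED
    if cases_avoided == 0:
        return None, NO_DIFFERENCE if incremental_cost == 0 else NO_EFFECT_DIFFERENCE
    return incremental_cost / cases_avoided, TRADEOFF


def run_comparison(
    scenario: ScenarioSpec,
    reg: ParameterRegistry | Mapping[str, float],
    histology_policy: TreatmentPolicy,
    risk_policy: TreatmentPolicy,
    ledger: CostLedger,
    discount: DiscountSpec = DiscountSpec(),
    horizon_years: int = 5,
) -> CEAResult:
    """Evaluate both arms under one scenario and classify the result."""
    values = reg.values_dict() if isinstance(reg, ParameterRegistry) else reg
    mix = restrict_mix(mix_from_values(values), scenario.population_grades)

    comparator = Strategy.histopathology(histology_policy)
    combined = Strategy.combined(
        risk_policy, histology_policy, scenario.straticyte_applied_to
    )

    paths_comp = enumerate_paths(comparator, values, mix)
    paths_comb = enumerate_paths(combined, values, mix)

    cases_comp = expected_cancer_cases(paths_comp)
    cases_comb = expected_cancer_cases(paths_comb)
    cost_comp = arm_expected_cost(paths_comp, ledger, discount, horizon_years)
    cost_comb = arm_expected_cost(paths_comb, ledger, discount, horizon_years)

    inc_cost = cost_comb.expected_cost - cost_comp.expected_cost
    avoided_rounded = round_half_up(cases_comp) - round_half_up(cases_comb)
    avoided_raw = cases_comp - cases_comb
    icer, verdict = icer_and_verdict(inc_cost, avoided_rounded)
    return CEAResult(
        scenario=scenario.name,
        cost_combined=cost_comb.expected_cost,
        cost_comparator=cost_comp.expected_cost,
        cases_combined=cases_comb,
        cases_comparator=cases_comp,
        incremental_cost=inc_cost,
        cases_avoided=round_half_up(avoided_rounded),
        cases_avoided_raw=avoided_raw,
        icer=icer,
        verdict=verdict,
    )
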