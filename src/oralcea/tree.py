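"""Two-arm prognostic decision tree.

The model compares two strategies for managing biopsied oral epithelial
dysplasia over a 5-year horizon:

- **histopathology**: patients are classified by histology grade
  (Severe / Moderate / Mild) and managed per grade;
- **histopathology_plus_straticyte**: grades in the biomarker's application
  set are further stratified into High / Medium / Low 5-year cancer risk and
  managed per risk class.

Each terminal path carries a classification probability, the 5-year cancer
probability in the absence of excision, and the effective cancer probability
after treatment: excision multiplies the no-excision probability by the
pooled relative risk ``rrMT``.  Cancer is a single terminal event on the
5-year horizon; there is no annual cycling.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product

from .parameters import GRADES, RISKS, ParameterRegistry

EXCISION = "excision"
SURVEILLANCE = "surveillance"

HISTOPATHOLOGY = "histopathology"
COMBINED = "histopathology_plus_straticyte"


class ConfigurationError(ValueError):
    """A policy or strategy does not cover a reachable label."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.375 -> 0.38), as used for reported totals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TreatmentPolicy:
    """Management action and visit schedule per classification label.

    ``actions`` maps a label (a grade or a risk class) to ``excision`` or
    ``surveillance``.  Visit schedules are given either as a plain number of
    visits per year or as the name of a registry symbol (``V_E6M_year`` /
    ``V_E3M_year``) resolved at evaluation time, so sensitivity analysis on
    the visit-frequency parameters flows through automatically.
    """

    actions: Mapping[str, str]
    surveillance_visits: Mapping[str, float | str] = field(default_factory=dict)
    post_excision_visits: Mapping[str, float | str] = field(default_factory=dict)

    def action(self, label: str) -> str:
        try:
            return self.actions[label]
        except KeyError:
            raise ConfigurationError(f"no management action configured for {label!r}")

    def visits_per_year(self, label: str, values: Mapping[str, float]) -> float:
        table = (
            self.post_excision_visits
            if self.action(label) == EXCISION
            else self.surveillance_visits
        )
        v = table.get(label, 0)
        if isinstance(v, str):
            return float(values[v])
        return float(v)


@dataclass(frozen=True)
class Strategy:
    name: str
    policy: TreatmentPolicy
    straticyte_applied_to: tuple[str, ...] = ()
    histology_policy: TreatmentPolicy | None = None

    @staticmethod
    def histopathology(policy: TreatmentPolicy) -> "Strategy":
        return Strategy(name=HISTOPATHOLOGY, policy=policy)

    @staticmethod
    def combined(
        risk_policy: TreatmentPolicy,
        histology_policy: TreatmentPolicy,
        applied_to: tuple[str, ...] = GRADES,
    ) -> "Strategy":
        return Strategy(
            name=COMBINED,
            policy=risk_policy,
            straticyte_applied_to=tuple(applied_to),
            histology_policy=histology_policy,
        )


@dataclass(frozen=True)
class PopulationMix:
    """Probability weights over histology grades."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"population weights sum to {total}, not 1")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigurationError("negative population weight")

    def weight(self, grade: str) -> float:
        return self.weights.get(grade, 0.0)

    @property
    def grades(self) -> tuple[str, ...]:
        return tuple(g for g in GRADES if self.weight(g) > 0)


def mix_from_values(values: Mapping[str, float]) -> PopulationMix:
    """Full-cohort grade mix taken from the registry's grade-share parameters."""
    return PopulationMix({g: values[f"p{g}"] for g in GRADES})


def restrict_mix(full: PopulationMix, grades: tuple[str, ...]) -> PopulationMix:
    """Restrict to a grade subset and renormalize the retained weights."""
    grades = tuple(grades)
    if not grades:
        raise ConfigurationError("cannot restrict to an empty grade subset")
    total = sum(full.weight(g) for g in grades)
    if total <= 0:
        raise ConfigurationError("restricted population has zero mass")
    return PopulationMix({g: full.weight(g) / total for g in grades})


@dataclass(frozen=True)
class TerminalPath:
    grade: str
    risk: str | None
    managed_by: str
    visits_per_year: float
    p_path: float
    p_cancer_no_excision: float
    p_cancer_effective: float
    straticyte: bool  # biomarker test performed on this path

    @property
    def label(self) -> str:
        return self.grade if self.risk is None else f"{self.grade}/{self.risk}"


def _values(reg: ParameterRegistry | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(reg, ParameterRegistry):
        return reg.values_dict()
    return reg


def enumerate_paths(
    strategy: Strategy,
    reg: ParameterRegistry | Mapping[str, float],
    mix: PopulationMix,
) -> list[TerminalPath]:
    """Enumerate the terminal paths of one arm under a population mix.

    In the histopathology arm each grade in the mix yields one path.  In the
    combined arm, grades under biomarker stratification fan out over their
    risk classes; never-observed (zero-probability) cells contribute no path.
    Grades outside the biomarker's application set fall back to the
    histology policy and incur no biomarker test.
    """
    values = _values(reg)
    rr = values["rrMT"]
    paths: list[TerminalPath] = []
    for grade in mix.grades:
        w = mix.weight(grade)
        stratified = (
            strategy.name == COMBINED and grade in strategy.straticyte_applied_to
        )
        if stratified:
            for risk in RISKS:
                p_risk = values.get(f"p{grade}_{risk}R", 0.0)
                if p_risk <= 0.0:
                    continue
                p_c = values.get(f"p{grade}_{risk}R_C", 0.0)
                action = strategy.policy.action(risk)
                paths.append(
                    TerminalPath(
                        grade=grade,
                        risk=risk,
                        managed_by=action,
                        visits_per_year=strategy.policy.visits_per_year(risk, values),
                        p_path=w * p_risk,
                        p_cancer_no_excision=p_c,
                        p_cancer_effective=p_c * rr if action == EXCISION else p_c,
                        straticyte=True,
                    )
                )
        else:
            policy = (
                strategy.histology_policy
                if strategy.name == COMBINED
                else strategy.policy
            )
            assert policy is not None
            p_c = values[f"p{grade}_C"]
            action = policy.action(grade)
            paths.append(
                TerminalPath(
                    grade=grade,
                    risk=None,
                    managed_by=action,
                    visits_per_year=policy.visits_per_year(grade, values),
                    p_path=w,
                    p_cancer_no_excision=p_c,
                    p_cancer_effective=p_c * rr if action == EXCISION else p_c,
                    straticyte=False,
                )
            )
    total = sum(p.p_path for p in paths)
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            f"terminal path probabilities sum to {total}, not 1 "
            f"(arm {strategy.name})"
        )
    return paths


def expected_cancer_cases(paths: list[TerminalPath]) -> float:
    """Expected 5-year cancer cases per patient (raw, undiscounted)."""
    return sum(p.p_path * p.p_cancer_effective for p in paths)


def derive_policy_by_reconciliation(
    reg: ParameterRegistry | Mapping[str, float],
    printed_histopathology: float = 0.36,
    printed_combined: float = 0.31,
) -> tuple[TreatmentPolicy, TreatmentPolicy]:
    """Recover the excision policy from the published per-arm cancer totals.

    The elicited treatment policy (which branches receive excision) is not
    printed; it is recovered by exhaustively evaluating all 2^3 x 2^3 = 64
    excision assignments — per grade in the histopathology arm, per risk
    class in the combined arm — and keeping those whose rounded expected
    cancer cases match the published totals.  On the shipped registry the
    solution is unique: excise Severe and Moderate (histopathology arm) and
    High and Medium risk (combined arm).

    Returns the (histology policy, risk-class policy) pair; raises
    :class:`ConfigurationError` listing the nearest candidates if no
    assignment matches.
    """
    values = _values(reg)
    mix = mix_from_values(values)
    matches: list[tuple[TreatmentPolicy, TreatmentPolicy]] = []
    candidates: list[tuple[float, str]] = []
    for histo_exc in product((EXCISION, SURVEILLANCE), repeat=3):
        histo = TreatmentPolicy(actions=dict(zip(GRADES, histo_exc)))
        e_h = expected_cancer_cases(
            enumerate_paths(Strategy.histopathology(histo), values, mix)
        )
        for risk_exc in product((EXCISION, SURVEILLANCE), repeat=3):
            risk = TreatmentPolicy(actions=dict(zip(RISKS, risk_exc)))
            e_c = expected_cancer_cases(
                enumerate_paths(Strategy.combined(risk, histo), values, mix)
            )
            err = abs(round_half_up(e_h) - printed_histopathology) + abs(
                round_half_up(e_c) - printed_combined
            )
            desc = (
                f"excise {[g for g, a in zip(GRADES, histo_exc) if a == EXCISION]} / "
                f"{[r for r, a in zip(RISKS, risk_exc) if a == EXCISION]}"
                f" -> ({round_half_up(e_h):.2f}, {round_half_up(e_c):.2f})"
            )
            candidates.append((err, desc))
            if err == 0.0:
                matches.append((histo, risk))
    if not matches:
        nearest = sorted(candidates)[:5]
        raise ConfigurationError(
            "no excision assignment reproduces the printed totals "
            f"({printed_histopathology}, {printed_combined}); nearest: "
            + "; ".join(d for _, d in nearest)
        )
    if len(matches) > 1:
        raise ConfigurationError(
            f"{len(matches)} excision assignments match the printed totals; "
            "reconciliation is ambiguous"
        )
    return matches[0]
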