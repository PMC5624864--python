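"""Full analysis configuration: one YAML file drives the whole pipeline.

Sections: ``counts``, ``costs``, ``resources``, ``effects`` (the parameter
registry, see :mod:`oralcea.parameters`), ``policy`` (treatment actions and
visit schedules per arm), ``ledger`` (cost-composition options),
``discount``, ``horizon_years``, ``scenarios`` and ``psa``.
"""

from __future__ import annotations

import hashlib
from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .cea import STANDARD_SCENARIOS, ScenarioSpec
from .costs import DiscountSpec
from .parameters import (
    GRADES,
    ParameterRegistry,
    ValidationError,
    registry_from_sections,
)
from .tree import EXCISION, SURVEILLANCE, TreatmentPolicy
from .uncertainty import PSAConfig

_TOP_KEYS = {
    "counts", "costs", "resources", "effects",
    "policy", "ledger", "discount", "horizon_years", "scenarios", "psa",
}


@dataclass
class AnalysisConfig:
    registry: ParameterRegistry
    histology_policy: TreatmentPolicy
    risk_policy: TreatmentPolicy
    ledger_options: dict = field(default_factory=dict)
    discount: DiscountSpec = DiscountSpec()
    horizon_years: int = 5
    scenarios: dict[str, ScenarioSpec] = field(
        default_factory=lambda: dict(STANDARD_SCENARIOS)
    )
    psa: PSAConfig = PSAConfig()
    digest: str = ""


def _policy_from_mapping(raw: Mapping) -> TreatmentPolicy:
    unknown = set(raw) - {"actions", "surveillance_visits", "post_excision_visits"}
    if unknown:
        raise ValidationError(f"policy: unknown keys {sorted(unknown)}")
    actions = dict(raw["actions"])
    for label, action in actions.items():
        if action not in (EXCISION, SURVEILLANCE):
            raise ValidationError(f"policy: unknown action {action!r} for {label!r}")
    return TreatmentPolicy(
        actions=actions,
        surveillance_visits=dict(raw.get("surveillance_visits", {})),
        post_excision_visits=dict(raw.get("post_excision_visits", {})),
    )


def _scenario_from_mapping(name: str, raw: Mapping) -> ScenarioSpec:
    applied = tuple(raw["straticyte_applied_to"])
    population = tuple(raw.get("population", applied))
    for g in (*applied, *population):
        if g not in GRADES:
            raise ValidationError(f"scenario {name}: unknown grade {g!r}")
    return ScenarioSpec(name, applied, population)


def load_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{path}: not a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown top-level keys {sorted(unknown)}")
    registry = registry_from_sections(doc)

    policy_raw = doc.get("policy", {})
    histology = _policy_from_mapping(policy_raw["histopathology"])
    risk = _policy_from_mapping(policy_raw["straticyte"])

    discount_raw = doc.get("discount", {})
    discount = DiscountSpec(
        annual_rate=float(discount_raw.get("annual_rate", 0.05)),
        first_discounted_year=int(discount_raw.get("first_discounted_year", 2)),
    )

    scenarios = dict(STANDARD_SCENARIOS)
    for name, raw in (doc.get("scenarios") or {}).items():
        scenarios[name] = _scenario_from_mapping(name, raw)

    psa_raw = doc.get("psa", {})
    wtp = psa_raw.get("wtp_grid")
    if wtp is None:
        lo = float(psa_raw.get("wtp_min", 0))
        hi = float(psa_raw.get("wtp_max", 100_000))
        step = float(psa_raw.get("wtp_step", 1000))
        wtp = []
        w = lo
        while w <= hi + 1e-9:
            wtp.append(w)
            w += step
    psa = PSAConfig(
        n_draws=int(psa_raw.get("n_draws", 5000)),
        seed=int(psa_raw.get("seed", 0)),
        wtp_grid=tuple(float(w) for w in wtp),
        truncate_probabilities=bool(psa_raw.get("truncate_probabilities", True)),
    )

    return AnalysisConfig(
        registry=registry,
        histology_policy=histology,
        risk_policy=risk,
        ledger_options=dict(doc.get("ledger", {})),
        discount=discount,
        horizon_years=int(doc.get("horizon_years", 5)),
        scenarios=scenarios,
        psa=psa,
        digest=hashlib.sha256(text.encode()).hexdigest(),
    )


def default_config_path() -> Path:
    """Path of the packaged default configuration."""
    return Path(resources.files("oralcea") / "data" / "default_config.yaml")


def load_default_config() -> AnalysisConfig:
    return load_config(default_config_path())
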