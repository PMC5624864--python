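"""Sensitivity analyses: one-way (tornado) and probabilistic (Monte Carlo).

Probabilistic sensitivity analysis samples every non-fixed parameter from
its assigned distribution: the grade mix and the per-grade risk splits from
joint Dirichlet distributions over the observed counts (so each sampled
vector lies exactly on the simplex), conditional cancer probabilities from
conjugate Beta distributions, costs from Gamma, and the excision relative
risk from its log-normal.  Cells the source cohort never observed are held
at a constant zero in every draw rather than sampled.

Decision uncertainty is summarized by the net monetary benefit (NMB): at a
willingness-to-pay of ``wtp`` CAD per cancer case avoided, a strategy with
expected cost ``C`` and expected cancer cases ``E`` has
``NMB = -C - wtp * E``.  The cost-effectiveness acceptability curve (CEAC)
reports, per willingness-to-pay value, the fraction of draws in which each
strategy attains the highest NMB (exact ties split equally).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEAResult, ScenarioSpec, run_comparison
from .costs import CostLedger, DiscountSpec
from .parameters import GRADES, RISKS, ParameterRegistry
from .tree import COMBINED, HISTOPATHOLOGY, TreatmentPolicy


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 5000
    seed: int = 0
    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 100_001, 1000))
    truncate_probabilities: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not self.wtp_grid or any(w < 0 for w in self.wtp_grid):
            raise ValueError("wtp_grid must be non-empty and non-negative")


def nmb(cost: float, cases: float, wtp: float) -> float:
    """Net monetary benefit of one strategy; cases are harms."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return -cost - wtp * cases


def sample_draw(
    reg: ParameterRegistry, rng: np.random.Generator
) -> dict[str, float]:
    """One joint sample of all uncertain parameters.

    Requires the registry to carry its cohort-count provenance, from which
    the Dirichlet simplexes are sampled jointly.  Returns a complete value
    map (fixed parameters at their base values).
    """
    counts = reg.provenance
    if counts is None:
        raise ValueError("registry lacks cohort-count provenance for joint sampling")
    values = reg.values_dict()

    # Grade mix: joint Dirichlet over the three observed grade counts.
    grade_alpha = np.array([counts.per_grade[g] for g in GRADES], dtype=float)
    grade_mix = rng.dirichlet(grade_alpha)
    for g, v in zip(GRADES, grade_mix):
        values[f"p{g}"] = float(v)

    # Risk split within each grade: Dirichlet over the non-zero counts,
    # zero-count components held at exactly 0.
    for g in GRADES:
        alpha = np.array([counts.per_grade_risk[(g, r)] for r in RISKS], dtype=float)
        nz = alpha > 0
        draw = np.zeros(len(RISKS))
        if nz.sum() == 1:
            draw[nz] = 1.0
        else:
            draw[nz] = rng.dirichlet(alpha[nz])
        for r, v in zip(RISKS, draw):
            values[f"p{g}_{r}R"] = float(v)

    # Conditional cancer probabilities: conjugate Beta; never-observed
    # (zero-count) cells stay at constant 0.
    def beta_or_zero(events: int, total: int) -> float:
        if events == 0 or total == 0:
            return 0.0
        non_events = total - events
        if non_events == 0:
            return 1.0 if events == total else 0.0
        return float(rng.beta(events, non_events))

    for g in GRADES:
        values[f"p{g}_C"] = beta_or_zero(
            counts.cancers_per_grade[g], counts.per_grade[g]
        )
        for r in RISKS:
            values[f"p{g}_{r}R_C"] = beta_or_zero(
                counts.cancers_per_grade_risk[(g, r)], counts.per_grade_risk[(g, r)]
            )

    # Costs, resources and the excision relative risk.
    for name, q in reg.items():
        if name.startswith("p") or not q.available:
            continue
        kind = q.dist.kind
        if kind == "gamma":
            shape, scale = q.dist.shape
            values[name] = float(rng.gamma(shape, scale))
        elif kind == "lognormal":
            ln_mean, ln_se = q.dist.shape
            values[name] = float(rng.lognormal(ln_mean, ln_se))
        elif kind == "beta":
            a, b = q.dist.shape
            values[name] = float(rng.beta(a, b))
        # fixed parameters keep their base value
    return values


@dataclass
class PSAResult:
    config: PSAConfig
    draws: pd.DataFrame      # one row per draw: per-arm cost/cases, increments
    ceac: pd.DataFrame       # wtp, p_best per strategy
    sampled: pd.DataFrame    # one row per draw: sampled parameter values


def _ceac_from_draws(
    inc_cost: np.ndarray, avoided: np.ndarray, wtp_grid: Sequence[float]
) -> pd.DataFrame:
    rows = []
    n = len(inc_cost)
    for wtp in wtp_grid:
        # incremental NMB of the combined arm over the comparator
        inc_nmb = -inc_cost + wtp * avoided
        wins = float(np.sum(inc_nmb > 0))
        ties = float(np.sum(inc_nmb == 0))
        p_comb = (wins + 0.5 * ties) / n
        rows.append(
            {"wtp": float(wtp), COMBINED: p_comb, HISTOPATHOLOGY: 1.0 - p_comb}
        )
    return pd.DataFrame(rows)


def run_psa(
    config: PSAConfig,
    reg: ParameterRegistry,
    histology_policy: TreatmentPolicy,
    risk_policy: TreatmentPolicy,
    ledger_options: Mapping | None = None,
    discount: DiscountSpec = DiscountSpec(),
    horizon_years: int = 5,
    scenario: ScenarioSpec | None = None,
) -> PSAResult:
    """Monte-Carlo evaluation of both arms under joint parameter uncertainty.

    The cost ledger is rebuilt from the sampled values in every draw, so
    cost uncertainty propagates through the same composition as the base
    case.  Reproducible: the same seed and configuration give identical
    draws and an identical CEAC table.
    """
    scenario = scenario or ScenarioSpec.base_case()
    ledger_options = dict(ledger_options or {})
    rng = np.random.default_rng(config.seed)
    rows = []
    sampled_rows = []
    for i in range(config.n_draws):
        values = sample_draw(reg, rng)
        ledger = CostLedger.from_values(values, **ledger_options)
        res = run_comparison(
            scenario, values, histology_policy, risk_policy, ledger,
            discount, horizon_years,
        )
        rows.append(
            {
                "draw": i,
                "cost_combined": res.cost_combined,
                "cost_comparator": res.cost_comparator,
                "cases_combined": res.cases_combined,
                "cases_comparator": res.cases_comparator,
                "incremental_cost": res.incremental_cost,
                "cases_avoided_raw": res.cases_avoided_raw,
            }
        )
        sampled_rows.append(values)
    draws = pd.DataFrame(rows)
    ceac = _ceac_from_draws(
        draws["incremental_cost"].to_numpy(),
        draws["cases_avoided_raw"].to_numpy(),
        config.wtp_grid,
    )
    return PSAResult(
        config=config, draws=draws, ceac=ceac, sampled=pd.DataFrame(sampled_rows)
    )


# --- one-way sensitivity analysis ---------------------------------------

#: pseudo-parameter handled specially: the annual discount rate, varied
#: over 0%..10% (the model names it as an OWSA input but prints no range).
DISCOUNT_RATE = "discount_rate"
DISCOUNT_RATE_RANGE = (0.0, 0.10)

#: reference willingness-to-pay used to collapse (cost, effect) swings into
#: a single tornado ordering.
DEFAULT_WTP_REFERENCE = 10_000.0


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    at_low: CEAResult
    at_high: CEAResult
    swing: float  # |incremental NMB(high) - incremental NMB(low)| at reference WTP


def _simplex_override(
    values: Mapping[str, float], name: str, x: float
) -> dict[str, float]:
    """Set one parameter, renormalizing simplex siblings where needed.

    Grade shares (``pSevere``/``pModerate``/``pMild``) and within-grade risk
    shares (``p<G>_<R>R``) live on probability simplexes: when one component
    is moved in a one-way analysis, its siblings are rescaled to absorb the
    complement so the tree's path probabilities still sum to one.  All other
    parameters are free and overridden directly.
    """
    out = {**values, name: x}
    siblings: list[str] = []
    if name in {f"p{g}" for g in GRADES}:
        siblings = [f"p{g}" for g in GRADES if f"p{g}" != name]
    else:
        for g in GRADES:
            group = [f"p{g}_{r}R" for r in RISKS]
            if name in group:
                siblings = [s for s in group if s != name]
                break
    if siblings:
        rest = sum(values[s] for s in siblings)
        if rest > 0:
            scale = (1.0 - x) / rest
            for s in siblings:
                out[s] = values[s] * scale
        else:
            share = (1.0 - x) / len(siblings)
            for s in siblings:
                out[s] = share
    return out


def one_way_analysis(
    reg: ParameterRegistry,
    targets: Sequence[str],
    histology_policy: TreatmentPolicy,
    risk_policy: TreatmentPolicy,
    ledger_options: Mapping | None = None,
    discount: DiscountSpec = DiscountSpec(),
    horizon_years: int = 5,
    scenario: ScenarioSpec | None = None,
    truncate_probabilities: bool = True,
    wtp_reference: float = DEFAULT_WTP_REFERENCE,
) -> list[TornadoEntry]:
    """Re-run the comparison at each parameter's low and high value.

    Ranges come from the registry's deterministic low/high columns; missing
    ranges fall back to mean +/- 20%.  Probability inputs can exceed [0, 1]
    in the stored ranges (they are kept verbatim from the source table) and
    are truncated here at use time when ``truncate_probabilities`` is set.
    Entries are sorted by decreasing swing of the incremental NMB at the
    reference willingness-to-pay.
    """
    scenario = scenario or ScenarioSpec.base_case()
    ledger_options = dict(ledger_options or {})
    base_values = reg.values_dict()

    def evaluate(values: Mapping[str, float], dspec: DiscountSpec) -> CEAResult:
        ledger = CostLedger.from_values(values, **ledger_options)
        return run_comparison(
            scenario, values, histology_policy, risk_policy, ledger,
            dspec, horizon_years,
        )

    def inc_nmb(res: CEAResult) -> float:
        return -res.incremental_cost + wtp_reference * res.cases_avoided_raw

    entries: list[TornadoEntry] = []
    for name in targets:
        if name == DISCOUNT_RATE:
            lo_in, hi_in = DISCOUNT_RATE_RANGE
            at_low = evaluate(base_values, DiscountSpec(annual_rate=lo_in))
            at_high = evaluate(base_values, DiscountSpec(annual_rate=hi_in))
        else:
            if name not in reg:
                raise KeyError(f"unknown parameter {name!r}")
            q = reg[name]
            lo_in, hi_in = q.owsa_range()
            if truncate_probabilities and q.is_probability:
                lo_in = min(max(lo_in, 0.0), 1.0)
                hi_in = min(max(hi_in, 0.0), 1.0)
            at_low = evaluate(_simplex_override(base_values, name, lo_in), discount)
            at_high = evaluate(_simplex_override(base_values, name, hi_in), discount)
        entries.append(
            TornadoEntry(
                parameter=name,
                low_input=lo_in,
                high_input=hi_in,
                at_low=at_low,
                at_high=at_high,
                swing=abs(inc_nmb(at_high) - inc_nmb(at_low)),
            )
        )
    entries.sort(key=lambda e: -e.swing)
    return entries


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "parameter": e.parameter,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "incremental_cost_low": e.at_low.incremental_cost,
                "incremental_cost_high": e.at_high.incremental_cost,
                "cases_avoided_low": e.at_low.cases_avoided_raw,
                "cases_avoided_high": e.at_high.cases_avoided_raw,
                "icer_or_verdict_low": e.at_low.icer_or_verdict,
                "icer_or_verdict_high": e.at_high.icer_or_verdict,
                "swing": e.swing,
            }
        )
    return pd.DataFrame(rows)
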