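"""Model parameter registry.

Every input of the decision model lives here as a named
:class:`UncertainQuantity`: a base-case value, a deterministic low/high range
for one-way sensitivity analysis, and a probability distribution for
probabilistic sensitivity analysis.  Probability parameters are never entered
by hand — they are derived from the retrospective cohort counts
(:class:`CohortCounts`) so that the conjugate Dirichlet/Beta shapes, the
base-case point estimates, and the simplex constraints are consistent by
construction.

Naming convention (shared with the rest of the package):

``pSevere``             probability a dysplasia case is graded Severe
``pSevere_C``           5-year cancer probability given Severe, no excision
``pSevere_HighR``       probability of a High biomarker risk call given Severe
``pSevere_HighR_C``     5-year cancer probability given Severe & High risk
``rrMT``                relative risk of malignant transformation with excision
``c<Name>``             cost component, 2014 CAD
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import yaml

GRADES = ("Severe", "Moderate", "Mild")
RISKS = ("High", "Medium", "Low")

#: z-quantile used throughout for 95% intervals.
Z95 = 1.96

DIST_KINDS = ("dirichlet_component", "beta", "gamma", "lognormal", "fixed")


class ValidationError(ValueError):
    """Raised when counts or a registry violate a structural invariant."""


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution assigned to a parameter for probabilistic sampling.

    ``shape`` meaning by kind:

    - ``dirichlet_component`` / ``beta``: the two conjugate counts
      (events, non-events); the mean is ``a / (a + b)``.
    - ``gamma``: shape ``alpha`` and scale ``beta``; mean ``alpha * beta``.
    - ``lognormal``: mean and SE on the natural-log scale; the point
      estimate is ``exp(ln_mean)`` (the median), which is what the model's
      base-case values reproduce.
    - ``fixed``: empty; the parameter never varies in PSA.
    """

    kind: str
    shape: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in DIST_KINDS:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "shape", tuple(float(s) for s in self.shape))
        if self.kind in ("beta", "dirichlet_component"):
            if len(self.shape) != 2 or any(s < 0 for s in self.shape):
                raise ValidationError(
                    f"{self.kind} needs two non-negative counts, got {self.shape}"
                )
        elif self.kind == "gamma":
            if len(self.shape) != 2 or any(s <= 0 for s in self.shape):
                raise ValidationError(
                    f"gamma needs two strictly positive parameters, got {self.shape}"
                )
        elif self.kind == "lognormal":
            if len(self.shape) != 2 or self.shape[1] <= 0:
                raise ValidationError(
                    f"lognormal needs (ln-mean, ln-SE>0), got {self.shape}"
                )
        elif self.kind == "fixed" and self.shape:
            raise ValidationError("fixed distribution takes no shape parameters")


def distribution_mean(dist: DistributionSpec, base: float | None = None) -> float:
    """Point estimate implied by a distribution's shape parameters.

    For ``fixed`` parameters the base value is returned unchanged (it must be
    supplied).  For ``lognormal`` the median ``exp(ln_mean)`` is returned
    rather than the arithmetic mean ``exp(mu + sigma^2/2)``: the model's
    relative-risk point estimate is the back-transformed log estimate.
    """
    if dist.kind in ("beta", "dirichlet_component"):
        a, b = dist.shape
        if a + b == 0:
            raise ValidationError("beta/dirichlet with zero total count has no mean")
        return a / (a + b)
    if dist.kind == "gamma":
        alpha, scale = dist.shape
        return alpha * scale
    if dist.kind == "lognormal":
        return math.exp(dist.shape[0])
    if dist.kind == "fixed":
        if base is None:
            raise ValidationError("fixed distribution needs the base value")
        return base
    raise ValidationError(f"unknown distribution kind {dist.kind!r}")


@dataclass(frozen=True)
class UncertainQuantity:
    """A named model parameter with its deterministic range and distribution.

    ``available`` is False for cells the source cohort never observed
    (zero numerator or zero denominator); such parameters are held at a
    constant 0 everywhere downstream, including in every PSA draw.
    """

    name: str
    base: float
    dist: DistributionSpec
    low: float | None = None
    high: float | None = None
    units: str = ""
    source: str = ""
    available: bool = True

    def __post_init__(self) -> None:
        if self.available and self.low is not None and self.high is not None:
            if not (self.low <= self.base <= self.high):
                raise ValidationError(
                    f"{self.name}: low <= base <= high violated "
                    f"({self.low}, {self.base}, {self.high})"
                )

    @property
    def is_probability(self) -> bool:
        return self.units == "probability"

    def value(self) -> float:
        return self.base if self.available else 0.0

    def owsa_range(self, pm_fraction: float = 0.20) -> tuple[float, float]:
        """Deterministic (low, high), falling back to mean +/- 20%."""
        if self.low is not None and self.high is not None:
            return (self.low, self.high)
        return (self.base * (1 - pm_fraction), self.base * (1 + pm_fraction))


@dataclass(frozen=True)
class CohortCounts:
    """Integer counts from the retrospective dysplasia cohort.

    Two partitions of the same patients are carried: by histology grade, and
    by (grade, biomarker risk class).  Cancer counts are 5-year malignant
    transformations in the absence of excision.
    """

    per_grade: Mapping[str, int]
    per_grade_risk: Mapping[tuple[str, str], int]
    cancers_per_grade: Mapping[str, int]
    cancers_per_grade_risk: Mapping[tuple[str, str], int]

    @property
    def n_total(self) -> int:
        return sum(self.per_grade.values())

    def validate(self) -> None:
        for g in GRADES:
            if g not in self.per_grade:
                raise ValidationError(f"missing grade count for {g}")
        for g in GRADES:
            n_g = self.per_grade[g]
            split = sum(self.per_grade_risk.get((g, r), 0) for r in RISKS)
            if split != n_g:
                raise ValidationError(
                    f"risk-class counts for {g} sum to {split}, expected {n_g}"
                )
            if self.cancers_per_grade.get(g, 0) > n_g:
                raise ValidationError(f"more cancers than patients in grade {g}")
            for r in RISKS:
                n_gr = self.per_grade_risk.get((g, r), 0)
                c_gr = self.cancers_per_grade_risk.get((g, r), 0)
                if n_gr < 0 or c_gr < 0:
                    raise ValidationError(f"negative count in cell ({g}, {r})")
                if c_gr > n_gr:
                    raise ValidationError(
                        f"more cancers than patients in cell ({g}, {r})"
                    )
        by_grade = sum(self.cancers_per_grade.get(g, 0) for g in GRADES)
        by_cell = sum(
            self.cancers_per_grade_risk.get((g, r), 0) for g in GRADES for r in RISKS
        )
        if by_grade != by_cell:
            raise ValidationError(
                "cancer counts disagree between the grade partition "
                f"({by_grade}) and the (grade, risk) partition ({by_cell})"
            )


def table_counts() -> CohortCounts:
    """The shipped 107-patient cohort counts."""
    counts = CohortCounts(
        per_grade={"Severe": 29, "Moderate": 38, "Mild": 40},
        per_grade_risk={
            ("Severe", "High"): 27, ("Severe", "Medium"): 2, ("Severe", "Low"): 0,
            ("Moderate", "High"): 6, ("Moderate", "Medium"): 32, ("Moderate", "Low"): 0,
            ("Mild", "High"): 0, ("Mild", "Medium"): 20, ("Mild", "Low"): 20,
        },
        cancers_per_grade={"Severe": 22, "Moderate": 24, "Mild": 15},
        cancers_per_grade_risk={
            ("Severe", "High"): 22, ("Severe", "Medium"): 0, ("Severe", "Low"): 0,
            ("Moderate", "High"): 5, ("Moderate", "Medium"): 19, ("Moderate", "Low"): 0,
            ("Mild", "High"): 0, ("Mild", "Medium"): 11, ("Mild", "Low"): 4,
        },
    )
    counts.validate()
    return counts


class ParameterRegistry(Mapping):
    """Collection of :class:`UncertainQuantity` keyed by symbol name."""

    def __init__(
        self,
        entries: Mapping[str, UncertainQuantity] | None = None,
        provenance: CohortCounts | None = None,
    ) -> None:
        self._entries: dict[str, UncertainQuantity] = dict(entries or {})
        self.provenance = provenance

    def add(self, entry: UncertainQuantity) -> None:
        if entry.name in self._entries:
            raise ValidationError(f"duplicate parameter {entry.name}")
        self._entries[entry.name] = entry

    def __getitem__(self, name: str) -> UncertainQuantity:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def value(self, name: str) -> float:
        return self._entries[name].value()

    def values_dict(self) -> dict[str, float]:
        """Base-case value per symbol (unavailable cells as 0)."""
        return {name: q.value() for name, q in self._entries.items()}

    def merged(self, other: "ParameterRegistry") -> "ParameterRegistry":
        out = ParameterRegistry(self._entries, self.provenance)
        for q in other._entries.values():
            out.add(q)
        if out.provenance is None:
            out.provenance = other.provenance
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterRegistry) and self._entries == other._entries


def _binomial_bounds(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% bounds with the lower bound floored at 0.

    The upper bound is deliberately not capped at 1: the deterministic
    ranges mirror the source table, which reports upper bounds above 1 for
    near-boundary cells; truncation is applied at use time (OWSA) instead.
    """
    se = math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - Z95 * se), p + Z95 * se)


def _prob_entry(name: str, num: int, den: int, kind: str, source: str) -> UncertainQuantity:
    shape = (float(num), float(den - num))
    if den == 0 or num == 0:
        # Never-observed cell: held constant at zero, never sampled.
        return UncertainQuantity(
            name=name, base=0.0, dist=DistributionSpec("fixed"),
            units="probability", source=source, available=False,
        )
    p = num / den
    low, high = _binomial_bounds(p, den)
    return UncertainQuantity(
        name=name, base=p, dist=DistributionSpec(kind, shape),
        low=low, high=high, units="probability", source=source,
    )


def counts_to_probabilities(counts: CohortCounts) -> ParameterRegistry:
    """Derive every transition-probability parameter from cohort counts.

    Grade shares are Dirichlet components of the joint grade split; risk
    shares are Dirichlet components within each grade; cancer probabilities
    are Beta with conjugate (cancer, non-cancer) counts.  Cells with a zero
    numerator or denominator become unavailable (constant-zero) parameters
    rather than raising a division error.
    """
    counts.validate()
    reg = ParameterRegistry(provenance=counts)
    n = counts.n_total
    src = "retrospective cohort"
    for g in GRADES:
        n_g = counts.per_grade[g]
        reg.add(_prob_entry(f"p{g}", n_g, n, "dirichlet_component", src))
    for g in GRADES:
        n_g = counts.per_grade[g]
        c_g = counts.cancers_per_grade[g]
        reg.add(_prob_entry(f"p{g}_C", c_g, n_g, "beta", src))
    for g in GRADES:
        n_g = counts.per_grade[g]
        for r in RISKS:
            n_gr = counts.per_grade_risk[(g, r)]
            reg.add(_prob_entry(f"p{g}_{r}R", n_gr, n_g, "dirichlet_component", src))
    for g in GRADES:
        for r in RISKS:
            n_gr = counts.per_grade_risk[(g, r)]
            c_gr = counts.cancers_per_grade_risk[(g, r)]
            reg.add(_prob_entry(f"p{g}_{r}R_C", c_gr, n_gr, "beta", src))
    return reg


# --- validation ----------------------------------------------------------

PROB_TOL = 1e-3          # |base - distribution mean| for probabilities
COST_REL_TOL = 5e-3      # relative deviation for costs/resources


@dataclass
class ValidationReport:
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    def __str__(self) -> str:
        return "registry OK" if self.ok else "\n".join(self.flags)


def validate_registry(reg: ParameterRegistry) -> ValidationReport:
    """Check every entry's base value against its distribution mean.

    Probabilities must match the conjugate-count mean within 0.001 and lie
    in [0, 1]; other quantities must match their distribution mean within
    0.5% relative.  Unavailable (constant-zero) entries are skipped.
    """
    report = ValidationReport()
    for name, q in reg.items():
        if not q.available:
            continue
        if q.is_probability and not (0.0 <= q.base <= 1.0):
            report.flags.append(f"{name}: probability {q.base} outside [0, 1]")
        if q.dist.kind == "fixed":
            continue
        mean = distribution_mean(q.dist, q.base)
        if q.is_probability:
            if abs(q.base - mean) > PROB_TOL:
                report.flags.append(
                    f"{name}: base {q.base:.4f} deviates from "
                    f"distribution mean {mean:.4f} by more than {PROB_TOL}"
                )
        else:
            denom = abs(mean) if mean else 1.0
            if abs(q.base - mean) / denom > COST_REL_TOL:
                report.flags.append(
                    f"{name}: base {q.base} deviates from "
                    f"distribution mean {mean} by more than {COST_REL_TOL:.1%}"
                )
    return report


# --- config I/O ----------------------------------------------------------

COST_SYMBOLS = (
    "cHistopathology", "cBiomarker", "cExcision", "cFollow-up", "cPathology",
    "cPainMed_T2", "cPainMed_P", "cWork_Loss", "cTransportation", "cParking",
)
RESOURCE_SYMBOLS = ("HRSofWORK", "avgDISTANCE", "employed", "V_E6M_year", "V_E3M_year")
EFFECT_SYMBOLS = ("rrMT",)

#: every symbol a full registry must contain.
ALL_SYMBOLS = tuple(
    [f"p{g}" for g in GRADES]
    + [f"p{g}_C" for g in GRADES]
    + [f"p{g}_{r}R" for g in GRADES for r in RISKS]
    + [f"p{g}_{r}R_C" for g in GRADES for r in RISKS]
    + list(EFFECT_SYMBOLS) + list(COST_SYMBOLS) + list(RESOURCE_SYMBOLS)
)

_ENTRY_KEYS = {"base", "low", "high", "dist", "units", "source"}


def _entry_from_mapping(name: str, raw: Mapping) -> UncertainQuantity:
    unknown = set(raw) - _ENTRY_KEYS
    if unknown:
        raise ValidationError(f"{name}: unknown keys {sorted(unknown)}")
    dist_raw = raw.get("dist", ["fixed"])
    dist = DistributionSpec(dist_raw[0], tuple(dist_raw[1:]))
    return UncertainQuantity(
        name=name,
        base=float(raw["base"]),
        low=None if raw.get("low") is None else float(raw["low"]),
        high=None if raw.get("high") is None else float(raw["high"]),
        dist=dist,
        units=str(raw.get("units", "")),
        source=str(raw.get("source", "")),
    )


def _counts_from_mapping(raw: Mapping) -> CohortCounts:
    need = {"per_grade", "per_grade_risk", "cancers_per_grade", "cancers_per_grade_risk"}
    unknown = set(raw) - need
    if unknown:
        raise ValidationError(f"counts: unknown keys {sorted(unknown)}")
    missing = need - set(raw)
    if missing:
        raise ValidationError(f"counts: missing keys {sorted(missing)}")
    return CohortCounts(
        per_grade={g: int(v) for g, v in raw["per_grade"].items()},
        per_grade_risk={
            (g, r): int(v)
            for g, row in raw["per_grade_risk"].items()
            for r, v in row.items()
        },
        cancers_per_grade={g: int(v) for g, v in raw["cancers_per_grade"].items()},
        cancers_per_grade_risk={
            (g, r): int(v)
            for g, row in raw["cancers_per_grade_risk"].items()
            for r, v in row.items()
        },
    )


def registry_from_sections(sections: Mapping) -> ParameterRegistry:
    """Build the full registry from parsed counts/costs/resources/effects."""
    for key in ("counts", "costs", "resources", "effects"):
        if key not in sections:
            raise ValidationError(f"configuration missing section {key!r}")
    counts = _counts_from_mapping(sections["counts"])
    reg = counts_to_probabilities(counts)
    expected = {"costs": COST_SYMBOLS, "resources": RESOURCE_SYMBOLS,
                "effects": EFFECT_SYMBOLS}
    for section, symbols in expected.items():
        raw = sections[section]
        unknown = set(raw) - set(symbols)
        if unknown:
            raise ValidationError(f"{section}: unknown symbols {sorted(unknown)}")
        missing = set(symbols) - set(raw)
        if missing:
            raise ValidationError(f"{section}: missing symbols {sorted(missing)}")
        for name in symbols:
            reg.add(_entry_from_mapping(name, raw[name]))
    return reg


def load_registry(path: str | Path) -> ParameterRegistry:
    """Load the parameter registry from a YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"{path}: not a mapping")
    sections = {k: doc[k] for k in ("counts", "costs", "resources", "effects") if k in doc}
    return registry_from_sections(sections)


def registry_sections(reg: ParameterRegistry) -> dict:
    """Serialize a registry back to its config sections (inverse of load)."""
    counts = reg.provenance
    if counts is None:
        raise ValidationError("registry has no cohort-count provenance to serialize")

    def entry(q: UncertainQuantity) -> dict:
        d: dict = {"base": q.base}
        if q.low is not None:
            d["low"] = q.low
        if q.high is not None:
            d["high"] = q.high
        d["dist"] = [q.dist.kind, *q.dist.shape]
        if q.units:
            d["units"] = q.units
        if q.source:
            d["source"] = q.source
        return d

    return {
        "counts": {
            "per_grade": dict(counts.per_grade),
            "per_grade_risk": {
                g: {r: counts.per_grade_risk[(g, r)] for r in RISKS} for g in GRADES
            },
            "cancers_per_grade": dict(counts.cancers_per_grade),
            "cancers_per_grade_risk": {
                g: {r: counts.cancers_per_grade_risk[(g, r)] for r in RISKS}
                for g in GRADES
            },
        },
        "costs": {name: entry(reg[name]) for name in COST_SYMBOLS},
        "resources": {name: entry(reg[name]) for name in RESOURCE_SYMBOLS},
        "effects": {name: entry(reg[name]) for name in EFFECT_SYMBOLS},
    }


def save_registry(reg: ParameterRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(registry_sections(reg), fh, sort_keys=False)
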