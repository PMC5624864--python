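"""Fixed-effect relative-risk meta-analysis.

Pools per-study 2x2 counts (malignant transformations / lesions, excision
arm vs. no-excision arm) into a fixed-effect relative risk with 95% CI,
by Mantel-Haenszel weighting (default) or inverse-variance weighting on the
log scale.  The pooled estimate is exported as the log-normal
parameterization consumed by the decision model's ``rrMT`` parameter:
LogNormal(ln-mean = pooled ln RR, ln-SE = its standard error), whose point
estimate is ``exp(ln RR)``.

Zero-cell handling follows the common continuity-correction convention:
0.5 is added to all four cells of any study with a zero event cell in one
arm; studies with zero events in both arms carry no information about the
ratio and are excluded with a warning.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .parameters import Z95, DistributionSpec

MANTEL_HAENSZEL = "mantel_haenszel"
INVERSE_VARIANCE = "inverse_variance"


@dataclass(frozen=True)
class StudyCounts:
    study: str
    events_excision: int
    n_excision: int
    events_no_excision: int
    n_no_excision: int

    def __post_init__(self) -> None:
        for events, n, arm in (
            (self.events_excision, self.n_excision, "excision"),
            (self.events_no_excision, self.n_no_excision, "no-excision"),
        ):
            if n <= 0:
                raise ValueError(f"{self.study}: {arm} arm has no patients")
            if not (0 <= events <= n):
                raise ValueError(f"{self.study}: {arm} events outside [0, n]")

    @property
    def double_zero(self) -> bool:
        return self.events_excision == 0 and self.events_no_excision == 0

    def corrected(self) -> tuple[float, float, float, float]:
        """(a, n1, c, n2), continuity-corrected if either arm has zero events."""
        a, n1 = float(self.events_excision), float(self.n_excision)
        c, n2 = float(self.events_no_excision), float(self.n_no_excision)
        if a == 0 or c == 0:
            a, c = a + 0.5, c + 0.5
            n1, n2 = n1 + 1.0, n2 + 1.0
        return a, n1, c, n2


@dataclass(frozen=True)
class PooledEstimate:
    ln_rr: float
    se_ln_rr: float
    method: str
    k_studies: int

    @property
    def rr(self) -> float:
        return math.exp(self.ln_rr)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.ln_rr - Z95 * self.se_ln_rr),
            math.exp(self.ln_rr + Z95 * self.se_ln_rr),
        )


def study_log_rr(study: StudyCounts) -> tuple[float, float]:
    """Log relative risk and its SE for one study.

    SE uses the standard delta-method formula
    ``sqrt(1/a - 1/n1 + 1/c - 1/n2)`` on (continuity-corrected) counts.
    """
    if study.double_zero:
        raise ValueError(f"{study.study}: zero events in both arms, no RR defined")
    a, n1, c, n2 = study.corrected()
    ln_rr = math.log((a / n1) / (c / n2))
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    return ln_rr, se


def _include(studies: Sequence[StudyCounts]) -> list[StudyCounts]:
    kept = []
    for s in studies:
        if s.double_zero:
            warnings.warn(f"excluding study {s.study}: zero events in both arms")
            continue
        kept.append(s)
    if not kept:
        raise ValueError("no includable studies (all have zero events in both arms)")
    return kept


def pool_fixed_effect(
    studies: Sequence[StudyCounts], method: str = MANTEL_HAENSZEL
) -> PooledEstimate:
    """Fixed-effect pooled relative risk over the includable studies.

    Mantel-Haenszel pools on the risk-ratio scale with the Greenland-Robins
    variance; inverse-variance pools the per-study log RRs weighted by
    ``1/SE^2``.
    """
    kept = _include(studies)
    if method == MANTEL_HAENSZEL:
        r = s = p = 0.0
        for st in kept:
            a, n1, c, n2 = st.corrected()
            big_n = n1 + n2
            r += a * n2 / big_n
            s += c * n1 / big_n
            p += (n1 * n2 * (a + c) - a * c * big_n) / big_n**2
        if r == 0 or s == 0:
            raise ValueError("Mantel-Haenszel pooled RR undefined (zero margin)")
        ln_rr = math.log(r / s)
        se = math.sqrt(p / (r * s))
    elif method == INVERSE_VARIANCE:
        num = den = 0.0
        for st in kept:
            ln_i, se_i = study_log_rr(st)
            w = 1.0 / se_i**2
            num += w * ln_i
            den += w
        ln_rr = num / den
        se = math.sqrt(1.0 / den)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    return PooledEstimate(ln_rr=ln_rr, se_ln_rr=se, method=method, k_studies=len(kept))


def to_lognormal_param(est: PooledEstimate) -> DistributionSpec:
    """Export the pooled estimate as the decision model's rrMT distribution."""
    return DistributionSpec("lognormal", (est.ln_rr, est.se_ln_rr))


STUDY_COLUMNS = ("study", "events_excision", "n_excision", "events_control", "n_control")


def read_studies_csv(path: str | Path) -> list[StudyCounts]:
    """Read a study table (CSV with the columns of :data:`STUDY_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        StudyCounts(
            study=str(row["study"]),
            events_excision=int(row["events_excision"]),
            n_excision=int(row["n_excision"]),
            events_no_excision=int(row["events_control"]),
            n_no_excision=int(row["n_control"]),
        )
        for _, row in df.iterrows()
    ]


def write_studies_csv(studies: Sequence[StudyCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "study": s.study,
                "events_excision": s.events_excision,
                "n_excision": s.n_excision,
                "events_control": s.events_no_excision,
                "n_control": s.n_no_excision,
            }
            for s in studies
        ]
    ).to_csv(path, index=False)
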