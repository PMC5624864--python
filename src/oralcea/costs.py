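"""Cost ledger and discounting.

Costs are 2014 CAD from the combined private-payer and patient perspective:
direct components (histopathology reading, pathology report, biomarker test,
excision, pain medication, follow-up visits) plus indirect components
(absenteeism valued at the hourly wage times employment rate, travel at a
per-km rate over the clinic distance, and parking).

The per-path composition of the ledger is configuration, not data: which
paths carry surveillance schedules and which components attach to an
excision episode are documented defaults that can be overridden.  The
published per-arm dollar totals are calibration references for that
configuration, not quantities this module promises to reproduce.

Discounting follows the model's convention that only costs beyond the first
year are discounted: year 1 carries factor 1, year ``t`` carries
``(1 + rate)^-(t - 1)``.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

from .tree import EXCISION, TerminalPath


@dataclass(frozen=True)
class DiscountSpec:
    annual_rate: float = 0.05
    first_discounted_year: int = 2

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("discount rate must be non-negative")


def discount_factor(year: int, spec: DiscountSpec) -> float:
    """Discount factor for a cost occurring in calendar year ``year`` (1-based)."""
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    if year < spec.first_discounted_year:
        return 1.0
    return (1.0 + spec.annual_rate) ** (-(year - 1))


def annuity_factor(horizon_years: int, spec: DiscountSpec) -> float:
    """Sum of discount factors over years 1..horizon."""
    return sum(discount_factor(t, spec) for t in range(1, horizon_years + 1))


def recurring_stream_cost(
    per_visit_cost: float,
    visits_per_year: float,
    horizon_years: int,
    spec: DiscountSpec,
) -> float:
    """Discounted cost of a constant per-visit stream over the horizon."""
    if per_visit_cost < 0 or visits_per_year < 0 or horizon_years < 0:
        raise ValueError("recurring-stream inputs must be non-negative")
    return per_visit_cost * visits_per_year * annuity_factor(horizon_years, spec)


PARKING_MODES = ("per_visit", "total_events")


@dataclass(frozen=True)
class CostLedger:
    """Cost components resolved to CAD amounts, attached to path predicates.

    Built from registry values by :meth:`from_values`.  Default composition:

    - every patient: histopathology reading + pathology report (one-time);
    - biomarker-stratified paths: one biomarker test fee;
    - excision paths: excision bundle (procedure + pain medication), one
      work-loss episode (hours x hourly wage x employment rate) and one
      travel round trip with parking, all in year 1;
    - every path: a surveillance/follow-up visit stream at the path's
      visits-per-year, each visit costing the follow-up fee + travel +
      parking (+ optional per-visit work-loss hours), discounted.
    """

    baseline_one_time: float          # histopathology + pathology, all patients
    biomarker_fee: float              # stratified paths only
    excision_one_time: float          # excision + pain medication bundle
    excision_work_loss: float         # hours x wage x employment rate
    travel_per_trip: float            # per-km rate x distance
    parking_per_visit: float
    follow_up_fee: float
    per_visit_work_loss: float = 0.0
    parking_lump: float = 0.0         # one-time, under the event-count reading

    @staticmethod
    def from_values(
        values: Mapping[str, float],
        per_visit_work_loss_hours: float = 0.0,
        parking_mode: str = "per_visit",
        parking_event_cost: float | None = None,
    ) -> "CostLedger":
        if parking_mode not in PARKING_MODES:
            raise ValueError(f"parking_mode must be one of {PARKING_MODES}")
        wage = values["cWork_Loss"] * values["employed"]
        parking_per_visit = 0.0
        parking_lump = 0.0
        if parking_mode == "per_visit":
            parking_per_visit = values["cParking"]
        else:
            # cParking read as a count of paid-parking events over the
            # horizon; an explicit per-event charge is then required.
            if parking_event_cost is None:
                raise ValueError(
                    "parking_mode='total_events' needs parking_event_cost"
                )
            parking_lump = parking_event_cost * values["cParking"]
        return CostLedger(
            baseline_one_time=values["cHistopathology"] + values["cPathology"],
            biomarker_fee=values["cBiomarker"],
            excision_one_time=(
                values["cExcision"] + values["cPainMed_T2"] + values["cPainMed_P"]
            ),
            excision_work_loss=values["HRSofWORK"] * wage,
            travel_per_trip=values["cTransportation"] * values["avgDISTANCE"],
            parking_per_visit=parking_per_visit,
            follow_up_fee=values["cFollow-up"],
            per_visit_work_loss=per_visit_work_loss_hours * wage,
            parking_lump=parking_lump,
        )

    @staticmethod
    def zero() -> "CostLedger":
        return CostLedger(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class CostItem:
    component: str
    amount: float            # undiscounted
    discounted_amount: float


@dataclass(frozen=True)
class PathCost:
    path: TerminalPath
    items: tuple[CostItem, ...]

    @property
    def total(self) -> float:
        return sum(it.discounted_amount for it in self.items)

    @property
    def undiscounted_total(self) -> float:
        return sum(it.amount for it in self.items)


@dataclass(frozen=True)
class ArmCost:
    expected_cost: float
    per_path: tuple[PathCost, ...]


def path_cost(
    path: TerminalPath,
    ledger: CostLedger,
    spec: DiscountSpec,
    horizon_years: int = 5,
) -> PathCost:
    """Discounted 5-year cost of one terminal path, itemized by component."""
    items: list[CostItem] = [
        CostItem("histopathology+pathology", ledger.baseline_one_time,
                 ledger.baseline_one_time),
    ]
    if path.straticyte:
        items.append(CostItem("biomarker_test", ledger.biomarker_fee,
                              ledger.biomarker_fee))
    if path.managed_by == EXCISION:
        items.append(CostItem("excision_bundle", ledger.excision_one_time,
                              ledger.excision_one_time))
        items.append(CostItem("excision_work_loss", ledger.excision_work_loss,
                              ledger.excision_work_loss))
        trip = ledger.travel_per_trip + ledger.parking_per_visit
        items.append(CostItem("excision_travel", trip, trip))
    per_visit = (
        ledger.follow_up_fee
        + ledger.travel_per_trip
        + ledger.parking_per_visit
        + ledger.per_visit_work_loss
    )
    visits_total = path.visits_per_year * horizon_years
    undiscounted = per_visit * visits_total
    discounted = recurring_stream_cost(
        per_visit, path.visits_per_year, horizon_years, spec
    )
    if visits_total > 0:
        items.append(CostItem("follow_up_stream", undiscounted, discounted))
    if ledger.parking_lump > 0:
        items.append(CostItem("parking_total", ledger.parking_lump,
                              ledger.parking_lump))
    return PathCost(path=path, items=tuple(items))


def arm_expected_cost(
    paths: list[TerminalPath],
    ledger: CostLedger,
    spec: DiscountSpec,
    horizon_years: int = 5,
) -> ArmCost:
    """Probability-weighted expected discounted cost per patient for one arm."""
    per_path = tuple(path_cost(p, ledger, spec, horizon_years) for p in paths)
    expected = sum(pc.path.p_path * pc.total for pc in per_path)
    return ArmCost(expected_cost=expected, per_path=per_path)
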