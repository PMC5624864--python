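"""Cost ledger: discounting, streams, itemization, arm expectations."""

import dataclasses

import pytest

from oralcea import (
    CostLedger,
    DiscountSpec,
    Strategy,
    arm_expected_cost,
    discount_factor,
    enumerate_paths,
    path_cost,
    recurring_stream_cost,
)
from oralcea.costs import annuity_factor
from oralcea.tree import TerminalPath, mix_from_values


@pytest.fixture(scope="module")
def base_paths(values, histology_policy, risk_policy):
    mix = mix_from_values(values)
    return {
        "histopathology": enumerate_paths(
            Strategy.histopathology(histology_policy), values, mix
        ),
        "combined": enumerate_paths(
            Strategy.combined(risk_policy, histology_policy), values, mix
        ),
    }


class TestDiscounting:
    @pytest.mark.parametrize(
        "year, expected",
        [(1, 1.0), (2, 0.95238), (3, 0.90703), (5, 0.82270)],
    )
    def test_first_year_exempt_then_compound(self, year, expected):
        assert discount_factor(year, DiscountSpec()) == pytest.approx(
            expected, abs=1e-5
        )

    def test_year_before_one_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0, DiscountSpec())

    def test_zero_rate_gives_unit_factors(self):
        spec = DiscountSpec(annual_rate=0.0)
        assert all(discount_factor(t, spec) == 1.0 for t in range(1, 6))

    def test_five_year_annuity_factor(self):
        assert annuity_factor(5, DiscountSpec()) == pytest.approx(4.54595, abs=1e-5)


class TestRecurringStream:
    def test_six_monthly_follow_up_stream(self):
        assert recurring_stream_cost(129, 2, 5, DiscountSpec()) == pytest.approx(
            1172.85, abs=0.01
        )

    def test_zero_visits_cost_nothing(self):
        assert recurring_stream_cost(500.0, 0, 5, DiscountSpec()) == 0.0

    def test_linearity_in_visit_count(self):
        spec = DiscountSpec()
        four = recurring_stream_cost(129, 4, 5, spec)
        two = recurring_stream_cost(129, 2, 5, spec)
        assert four - two == pytest.approx(1172.85, abs=0.01)


class TestPathCost:
    def test_baseline_components_on_any_path(self, values):
        ledger = dataclasses.replace(
            CostLedger.zero(),
            baseline_one_time=values["cHistopathology"] + values["cPathology"],
        )
        path = TerminalPath("Mild", None, "surveillance", 0, 1.0, 0.375, 0.375, False)
        assert path_cost(path, ledger, DiscountSpec()).total == pytest.approx(183.0)

    def test_excision_one_time_bundle(self, ledger):
        # excision + pain medication on top of the baseline reading
        assert ledger.excision_one_time == pytest.approx(384 + 12.65 + 25.17)
        assert ledger.baseline_one_time + ledger.excision_one_time == pytest.approx(
            604.82
        )

    def test_excision_work_loss_component(self, ledger):
        assert ledger.excision_work_loss == pytest.approx(
            25.42 * 24 * 0.927, abs=0.01
        )
        assert ledger.excision_work_loss == pytest.approx(565.54, abs=0.01)

    def test_itemization_sums_to_total(self, base_paths, ledger):
        for paths in base_paths.values():
            for p in paths:
                pc = path_cost(p, ledger, DiscountSpec())
                assert sum(i.discounted_amount for i in pc.items) == pytest.approx(
                    pc.total, abs=0.01
                )


class TestArmExpectedCost:
    def test_zero_ledger_costs_nothing(self, base_paths):
        for paths in base_paths.values():
            arm = arm_expected_cost(paths, CostLedger.zero(), DiscountSpec())
            assert arm.expected_cost == 0.0

    def test_expectation_of_toy_two_path_arm(self):
        ledger = dataclasses.replace(CostLedger.zero(), baseline_one_time=100.0)
        cheap = TerminalPath("Mild", None, "surveillance", 0, 0.5, 0.1, 0.1, False)
        dear = TerminalPath("Mild", None, "surveillance", 4, 0.5, 0.1, 0.1, False)
        ledger2 = dataclasses.replace(ledger, follow_up_fee=0.0)
        arm = arm_expected_cost([cheap, dear], ledger2, DiscountSpec())
        assert arm.expected_cost == pytest.approx(100.0)

    def test_weighted_paths_sum_to_arm_total(self, base_paths, ledger):
        for paths in base_paths.values():
            arm = arm_expected_cost(paths, ledger, DiscountSpec())
            recomputed = sum(pc.path.p_path * pc.total for pc in arm.per_path)
            assert arm.expected_cost == pytest.approx(recomputed, abs=0.01)

    def test_biomarker_fee_differencing(self, values, base_paths):
        # ledgers identical except the biomarker fee: the combined arm with
        # full stratification costs exactly +250 more than the comparator
        ledger = dataclasses.replace(CostLedger.zero(), biomarker_fee=250.0)
        cost_h = arm_expected_cost(
            base_paths["histopathology"], ledger, DiscountSpec()
        ).expected_cost
        cost_c = arm_expected_cost(
            base_paths["combined"], ledger, DiscountSpec()
        ).expected_cost
        assert cost_c - cost_h == pytest.approx(250.0, abs=1e-9)

    def test_discounting_never_increases_cost(self, base_paths, ledger):
        for paths in base_paths.values():
            at_5 = arm_expected_cost(paths, ledger, DiscountSpec()).expected_cost
            at_0 = arm_expected_cost(
                paths, ledger, DiscountSpec(annual_rate=0.0)
            ).expected_cost
            assert at_5 <= at_0

    def test_discount_equality_without_recurring_costs(self, base_paths, ledger):
        one_time_only = dataclasses.replace(
            ledger, follow_up_fee=0.0, travel_per_trip=ledger.travel_per_trip,
            parking_per_visit=0.0, per_visit_work_loss=0.0,
        )
        # visit streams priced at zero: discounting cannot change the total
        paths = base_paths["histopathology"]
        ledger_no_stream = dataclasses.replace(
            one_time_only, travel_per_trip=0.0
        )
        at_5 = arm_expected_cost(paths, ledger_no_stream, DiscountSpec()).expected_cost
        at_0 = arm_expected_cost(
            paths, ledger_no_stream, DiscountSpec(annual_rate=0.0)
        ).expected_cost
        assert at_5 == pytest.approx(at_0)

    @pytest.mark.parametrize(
        "component",
        ["baseline_one_time", "biomarker_fee", "excision_one_time",
         "excision_work_loss", "follow_up_fee", "parking_per_visit"],
    )
    def test_arm_cost_linear_in_each_ledger_amount(
        self, base_paths, ledger, component
    ):
        # cost(2x) - cost(x) == cost(x) - cost(0) for every component
        paths = base_paths["combined"]

        def total(scale):
            led = dataclasses.replace(
                ledger, **{component: getattr(ledger, component) * scale}
            )
            return arm_expected_cost(paths, led, DiscountSpec()).expected_cost

        assert total(2.0) - total(1.0) == pytest.approx(
            total(1.0) - total(0.0), abs=1e-6
        )


class TestLedgerConfiguration:
    def test_travel_uses_printed_round_trip_distance(self, ledger):
        assert ledger.travel_per_trip == pytest.approx(0.575 * 60)

    def test_event_count_parking_mode_needs_a_charge(self, values):
        with pytest.raises(ValueError, match="parking_event_cost"):
            CostLedger.from_values(values, parking_mode="total_events")
        led = CostLedger.from_values(
            values, parking_mode="total_events", parking_event_cost=5.0
        )
        assert led.parking_per_visit == 0.0
        assert led.parking_lump == pytest.approx(100.0)

    def test_unknown_parking_mode_rejected(self, values):
        with pytest.raises(ValueError):
            CostLedger.from_values(values, parking_mode="hourly")
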