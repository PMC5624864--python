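"""Sensitivity machinery: PSA sampling, CEAC, one-way analysis."""

import numpy as np
import pandas as pd
import pytest

from oralcea import PSAConfig, one_way_analysis, run_psa, sample_draw
from oralcea.parameters import GRADES, RISKS
from oralcea.tree import COMBINED, HISTOPATHOLOGY
from oralcea.uncertainty import DISCOUNT_RATE, _simplex_override


class TestSampleDraw:
    def test_zero_count_cells_are_exactly_zero(self, registry):
        rng = np.random.default_rng(0)
        for _ in range(500):
            v = sample_draw(registry, rng)
            assert v["pMild_HighR"] == 0.0
            assert v["pSevere_LowR"] == 0.0
            assert v["pModerate_LowR"] == 0.0
            assert v["pSevere_MediumR_C"] == 0.0
            assert v["pMild_HighR_C"] == 0.0

    def test_sampled_simplexes_sum_to_one(self, registry):
        rng = np.random.default_rng(1)
        for _ in range(200):
            v = sample_draw(registry, rng)
            assert sum(v[f"p{g}"] for g in GRADES) == pytest.approx(1.0, abs=1e-12)
            for g in GRADES:
                assert sum(v[f"p{g}_{r}R"] for r in RISKS) == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_sampled_probabilities_in_unit_interval(self, registry):
        rng = np.random.default_rng(2)
        for _ in range(200):
            v = sample_draw(registry, rng)
            for name, x in v.items():
                if registry[name].is_probability:
                    assert 0.0 <= x <= 1.0, name

    def test_mild_risk_split_mean_matches_counts(self, registry):
        rng = np.random.default_rng(3)
        draws = [sample_draw(registry, rng)["pMild_MediumR"] for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.50, abs=0.02)

    def test_fixed_parameters_never_vary(self, registry, values):
        rng = np.random.default_rng(4)
        for _ in range(50):
            v = sample_draw(registry, rng)
            assert v["employed"] == values["employed"]
            assert v["V_E6M_year"] == values["V_E6M_year"]
            assert v["V_E3M_year"] == values["V_E3M_year"]

    def test_empirical_means_match_distribution_means(self, registry):
        # sampled parameter means within 3 standard errors
        n = 10_000
        rng = np.random.default_rng(5)
        checks = {
            "cHistopathology": (88.0, 8.8),       # gamma(100, 0.88): sd = 8.8
            "pSevere_C": (22 / 29, None),
            "pSevere": (29 / 107, None),
            "rrMT": (np.exp(-0.673 + 0.408**2 / 2), None),  # arithmetic mean
        }
        sums = {k: [] for k in checks}
        for _ in range(n):
            v = sample_draw(registry, rng)
            for k in checks:
                sums[k].append(v[k])
        for name, (mean, sd) in checks.items():
            xs = np.asarray(sums[name])
            se = (sd if sd is not None else xs.std()) / np.sqrt(n)
            assert abs(xs.mean() - mean) < 3 * se, name

    def test_same_seed_reproduces_the_draw_sequence(self, registry):
        a = [sample_draw(registry, np.random.default_rng(42)) for _ in range(3)]
        b = [sample_draw(registry, np.random.default_rng(42)) for _ in range(3)]
        assert a == b


@pytest.fixture(scope="module")
def psa_result(config):
    cfg = PSAConfig(n_draws=800, seed=11, wtp_grid=tuple(range(0, 100_001, 10_000)))
    return run_psa(
        cfg, config.registry, config.histology_policy, config.risk_policy,
        config.ledger_options, config.discount, config.horizon_years,
    )


class TestRunPsa:
    def test_ceac_fractions_partition_the_draws(self, psa_result):
        total = psa_result.ceac[COMBINED] + psa_result.ceac[HISTOPATHOLOGY]
        assert np.allclose(total, 1.0)
        assert ((psa_result.ceac[COMBINED] >= 0) & (psa_result.ceac[COMBINED] <= 1)).all()

    def test_per_draw_wtp_monotonicity_for_positive_effects(self, psa_result):
        # a draw in which the combined arm avoids cases can only become more
        # attractive as willingness-to-pay rises
        d = psa_result.draws
        pos = d[d["cases_avoided_raw"] > 0]
        low, high = 0.0, 100_000.0
        nmb_low = -pos["incremental_cost"] + low * pos["cases_avoided_raw"]
        nmb_high = -pos["incremental_cost"] + high * pos["cases_avoided_raw"]
        assert (nmb_high >= nmb_low).all()

    def test_same_seed_bit_identical_ceac(self, config, psa_result):
        cfg = psa_result.config
        again = run_psa(
            cfg, config.registry, config.histology_policy, config.risk_policy,
            config.ledger_options, config.discount, config.horizon_years,
        )
        pd.testing.assert_frame_equal(psa_result.ceac, again.ceac)
        pd.testing.assert_frame_equal(psa_result.draws, again.draws)

    def test_degenerate_distributions_give_step_function_ceac(self, config):
        # with no sampling variability every draw equals the base case, so
        # the CEAC is a 0/1 step determined by the base-case verdict
        cfg = PSAConfig(n_draws=20, seed=0, wtp_grid=(0.0, 50_000.0))
        values = config.registry.values_dict()

        from oralcea.cea import ScenarioSpec, run_comparison
        from oralcea.costs import CostLedger
        from oralcea.uncertainty import _ceac_from_draws

        ledger = CostLedger.from_values(values, **config.ledger_options)
        res = run_comparison(
            ScenarioSpec.base_case(), values, config.histology_policy,
            config.risk_policy, ledger, config.discount,
        )
        inc = np.full(cfg.n_draws, res.incremental_cost)
        avoided = np.full(cfg.n_draws, res.cases_avoided_raw)
        ceac = _ceac_from_draws(inc, avoided, cfg.wtp_grid)
        assert set(ceac[COMBINED]) <= {0.0, 1.0}
        expected = 1.0 if -res.incremental_cost > 0 else 0.0
        assert ceac[COMBINED].iloc[0] == expected


class TestOneWay:
    def test_table_ranges_are_used(self, config):
        entries = one_way_analysis(
            config.registry, ["cHistopathology", "V_E3M_year"],
            config.histology_policy, config.risk_policy, config.ledger_options,
        )
        by_name = {e.parameter: e for e in entries}
        assert by_name["cHistopathology"].low_input == pytest.approx(70.4)
        assert by_name["cHistopathology"].high_input == pytest.approx(105.6)
        assert by_name["V_E3M_year"].low_input == 3
        assert by_name["V_E3M_year"].high_input == 5

    def test_parameter_unused_by_any_path_has_zero_swing(self, config):
        # pSevere_MediumR_C is a never-observed (constant zero) cell held
        # at zero; the mean+/-20% fallback keeps it at zero at both ends
        entries = one_way_analysis(
            config.registry, ["pSevere_MediumR_C"],
            config.histology_policy, config.risk_policy, config.ledger_options,
        )
        assert entries[0].swing == pytest.approx(0.0, abs=1e-9)

    def test_discount_rate_pseudo_parameter(self, config):
        entries = one_way_analysis(
            config.registry, [DISCOUNT_RATE],
            config.histology_policy, config.risk_policy, config.ledger_options,
        )
        e = entries[0]
        assert (e.low_input, e.high_input) == (0.0, 0.10)
        # discounting shrinks both arms' follow-up streams; the incremental
        # cost must differ between the two rates
        assert e.at_low.incremental_cost != e.at_high.incremental_cost

    def test_probability_bounds_truncated_at_use_time(self, config):
        # pSevere_HighR's stored high bound exceeds 1; OWSA clips it
        entries = one_way_analysis(
            config.registry, ["pSevere_HighR"],
            config.histology_policy, config.risk_policy, config.ledger_options,
        )
        assert entries[0].high_input == 1.0

    def test_unknown_parameter_rejected(self, config):
        with pytest.raises(KeyError):
            one_way_analysis(
                config.registry, ["pNope"],
                config.histology_policy, config.risk_policy,
                config.ledger_options,
            )

    def test_entries_sorted_by_swing(self, config):
        entries = one_way_analysis(
            config.registry, ["rrMT", "cParking", "cBiomarker"],
            config.histology_policy, config.risk_policy, config.ledger_options,
        )
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)


class TestSimplexOverride:
    def test_grade_share_override_renormalizes_siblings(self, values):
        out = _simplex_override(values, "pSevere", 0.187)
        assert sum(out[f"p{g}"] for g in GRADES) == pytest.approx(1.0)
        # siblings keep their relative proportions
        assert out["pModerate"] / out["pMild"] == pytest.approx(
            values["pModerate"] / values["pMild"]
        )

    def test_risk_share_override_stays_within_grade(self, values):
        out = _simplex_override(values, "pMild_MediumR", 0.345)
        assert sum(out[f"pMild_{r}R"] for r in RISKS) == pytest.approx(1.0)
        assert out["pSevere_HighR"] == values["pSevere_HighR"]

    def test_free_parameters_override_directly(self, values):
        out = _simplex_override(values, "rrMT", 0.23)
        assert out["rrMT"] == 0.23
        assert out["pSevere"] == values["pSevere"]
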