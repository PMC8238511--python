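"""One-way sensitivity, distribution fitting, PSA and scenario runs."""

import math

import numpy as np
import pytest

from oafiscal import (
    ConfigurationError,
    RelativeEffect,
    RelativeEffectSet,
    fit_distribution,
    one_way,
    psa,
    run_comparison,
    run_scenario,
    standard_scenarios,
)
from oafiscal.sensitivity import ScenarioSpec, _FastComparison, uncertain_parameters


def employment_only_inputs(base_inputs, point=0.57, lo=0.21, hi=1.54):
    """Effect set where the employment odds ratio is the only live parameter."""
    es = RelativeEffectSet(
        "moderate",
        [RelativeEffect("employment", "odds_ratio", point, lo, hi)],
    )
    return base_inputs.with_effects("moderate", es)


class TestOneWay:
    def test_degenerate_ci_gives_equal_bounds(self, synthetic_inputs):
        inputs = employment_only_inputs(synthetic_inputs, 0.57, 0.57, 0.57)
        entries = one_way(inputs, "moderate", targets=["moderate:employment_odds_ratio"])
        (entry,) = entries
        assert entry.low_bound_int == entry.high_bound_int == entry.base_int

    def test_point_estimates_reproduce_base_int(self, synthetic_inputs):
        base = run_comparison(synthetic_inputs, "moderate").int_value
        entries = one_way(synthetic_inputs, "moderate")
        assert all(e.base_int == pytest.approx(base) for e in entries)

    def test_sorted_by_descending_swing(self, uk_inputs):
        entries = one_way(uk_inputs, "moderate")
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)
        # the employment odds ratio is the dominant parameter
        assert entries[0].parameter == "moderate:employment_odds_ratio"

    def test_employment_or_above_one_flips_the_int_sign(self, uk_inputs):
        inputs = employment_only_inputs(uk_inputs)
        (entry,) = one_way(inputs, "moderate", targets=["moderate:employment_odds_ratio"])
        assert entry.base_int > 0.0
        # at the upper bound the uncontrolled cohort is *more* likely to be
        # employed, so the government gains: negative INT
        assert entry.high_bound_int < 0.0
        assert entry.low_bound_int > entry.base_int

    def test_unknown_target_skipped_with_warning(self, synthetic_inputs, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="oafiscal"):
            entries = one_way(synthetic_inputs, "moderate", targets=["no_such_param"])
        assert entries == []
        assert any("skipped" in r.message for r in caplog.records)


class TestFitDistribution:
    def test_degenerate_ci_returns_point_mass(self):
        s = fit_distribution(1.0, 1.0, 1.0, value_type="ratio")
        rng = np.random.default_rng(0)
        assert (s.sample(rng, 5) == 1.0).all()

    def test_lognormal_log_sd_from_ci_width(self):
        s = fit_distribution(0.57, 0.21, 1.54, value_type="ratio")
        assert s.dist.kwds.get("s") or s.dist.args  # frozen scipy dist
        sigma = math.log(1.54 / 0.21) / (2 * 1.959964)
        assert sigma == pytest.approx(0.5082, abs=1e-4)
        assert s.dist.median() == pytest.approx(0.57, rel=1e-9)

    def test_beta_symmetric_ci_gives_equal_shapes(self):
        s = fit_distribution(0.5, 0.3, 0.7, value_type="probability")
        a, b = s.dist.args
        assert a == pytest.approx(b)
        assert s.mean == pytest.approx(0.5)

    def test_gamma_mean_matches_point(self):
        s = fit_distribution(1000.0, 600.0, 1400.0, value_type="cost")
        assert s.mean == pytest.approx(1000.0, rel=1e-9)

    def test_inconsistent_cis_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_distribution(1000.0, -50.0, 1400.0, value_type="cost")
        with pytest.raises(ConfigurationError):
            # bounds outside the unit interval are inconsistent with a beta
            fit_distribution(0.5, -0.2, 1.2, value_type="probability")
        with pytest.raises(ConfigurationError):
            fit_distribution(0.5, 0.6, 1.0)

    def test_sampler_reproducible_given_seed(self):
        s = fit_distribution(0.57, 0.21, 1.54, value_type="ratio")
        a = s.sample(np.random.default_rng(42), 10)
        b = s.sample(np.random.default_rng(42), 10)
        np.testing.assert_array_equal(a, b)


class TestPsa:
    def test_identical_seeds_identical_summaries(self, uk_inputs):
        r1 = psa(uk_inputs, "moderate", n=200, seed=9)
        r2 = psa(uk_inputs, "moderate", n=200, seed=9)
        assert (r1.mean_int, r1.ci_low, r1.ci_high) == (
            r2.mean_int,
            r2.ci_low,
            r2.ci_high,
        )

    def test_degenerate_distributions_recover_deterministic_int(self, uk_inputs):
        es = RelativeEffectSet(
            "moderate",
            [
                RelativeEffect(e.outcome, e.measure, e.point, e.point, e.point)
                for e in uk_inputs.effects["moderate"].effects
            ],
        )
        import dataclasses

        inputs = uk_inputs.with_effects("moderate", es)
        inputs = dataclasses.replace(
            inputs,
            mortality=dataclasses.replace(inputs.mortality, oa_excess_ci=(1.11, 1.11)),
        )
        det = run_comparison(inputs, "moderate").int_value
        res = psa(inputs, "moderate", n=50, seed=1)
        assert res.mean_int == pytest.approx(det, rel=1e-9)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-6)

    def test_mean_converges_to_deterministic_as_widths_shrink(self, uk_inputs):
        det = run_comparison(uk_inputs, "moderate").int_value
        gaps = []
        for shrink in (1.0, 0.1, 0.01):
            es = RelativeEffectSet(
                "moderate",
                [
                    RelativeEffect(
                        e.outcome,
                        e.measure,
                        e.point,
                        e.point * (e.ci_low / e.point) ** shrink,
                        e.point * (e.ci_high / e.point) ** shrink,
                    )
                    for e in uk_inputs.effects["moderate"].effects
                ],
            )
            res = psa(uk_inputs.with_effects("moderate", es), "moderate", n=400, seed=3)
            gaps.append(abs(res.mean_int - det))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 0.01 * abs(det)

    def test_fast_engine_matches_reference_pipeline(self, uk_inputs):
        for severity in ("moderate", "severe"):
            det = run_comparison(uk_inputs, severity).int_value
            fast = _FastComparison(uk_inputs, severity).int_value({})
            assert fast == pytest.approx(det, rel=1e-9)

    def test_rejection_rate_above_ten_percent_errors(self, synthetic_inputs):
        es = RelativeEffectSet(
            "moderate",
            [
                RelativeEffect("employment", "odds_ratio", 0.57, 0.57, 0.57),
                # every draw pushes lt sickness far above 1
                RelativeEffect("lt_sickness", "relative_risk", 300.0, 200.0, 400.0),
            ],
        )
        inputs = synthetic_inputs.with_effects("moderate", es)
        with pytest.raises(ConfigurationError, match="rejected"):
            psa(inputs, "moderate", n=50, seed=0)

    def test_minimum_sample_size(self, synthetic_inputs):
        with pytest.raises(ConfigurationError):
            psa(synthetic_inputs, "moderate", n=1, seed=0)

    def test_parameter_registry_covers_effects_and_mortality(self, uk_inputs):
        ids = {p.parameter_id for p in uncertain_parameters(uk_inputs, "moderate")}
        assert "moderate:employment_odds_ratio" in ids
        assert "oa_excess_hr" in ids


class TestScenarios:
    def test_empty_overrides_reproduce_base(self, uk_inputs):
        base = run_comparison(uk_inputs, "moderate").int_value
        res = run_scenario(ScenarioSpec("noop", {}), uk_inputs)
        assert res.int_values["moderate"] == pytest.approx(base)

    def test_unknown_override_key_rejected(self, uk_inputs):
        with pytest.raises(ConfigurationError, match="unknown"):
            run_scenario(ScenarioSpec("bad", {"retirement_age": 67}), uk_inputs)

    def test_lifetime_horizon_increases_int(self, uk_inputs):
        base = run_scenario(ScenarioSpec("base", {}), uk_inputs)
        life = run_scenario(ScenarioSpec("lifetime", {"lifetime": True}), uk_inputs)
        for severity in ("moderate", "severe"):
            assert abs(life.int_values[severity]) > abs(base.int_values[severity])

    def test_lower_uplift_reduces_healthcare_share_and_int(self, uk_inputs):
        base = run_scenario(ScenarioSpec("base", {}), uk_inputs)
        low = run_scenario(
            ScenarioSpec(
                "uplift_minus10",
                {"healthcare_uplift_moderate": 0.10, "healthcare_uplift_severe": 0.20},
            ),
            uk_inputs,
        )
        for severity in ("moderate", "severe"):
            assert (
                low.comparisons[severity].healthcare_share
                < base.comparisons[severity].healthcare_share
            )
            assert low.int_values[severity] < base.int_values[severity]

    def test_pct_change_zero_for_unchanged_scenario(self, uk_inputs):
        base = run_scenario(ScenarioSpec("base", {}), uk_inputs)
        again = run_scenario(ScenarioSpec("noop", {}), uk_inputs, reference=base)
        assert again.pct_change["moderate"] == pytest.approx(0.0, abs=1e-9)

    def test_standard_set_has_base_and_six_variants(self):
        names = [s.name for s in standard_scenarios()]
        assert names[0] == "base" and len(names) == 7
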