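"""Input types, probability derivations and effect application."""

import logging

import numpy as np
import pandas as pd
import pytest

from oafiscal import (
    AgeBand,
    BaselineParticipation,
    ConfigurationError,
    InactivityInputs,
    LifeTable,
    ModelConfig,
    MortalityAdjustment,
    RelativeEffect,
    RelativeEffectSet,
    adjust_mortality,
    apply_relative_effects,
    derive_inactivity_probabilities,
    null_effect_set,
)
from oafiscal.parameters import OUTCOMES, check_band_coverage, effect_multiplier


def participation_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["age_lower", "age_upper", *OUTCOMES],
    )


@pytest.fixture
def simple_base():
    return BaselineParticipation(
        participation_frame(
            [
                (50, 64, 0.718, 0.028, 0.031, 0.017, 0.039),
                (65, 100, 0.107, 0.0, 0.061, 0.0, 0.369),
            ]
        )
    )


class TestAgeBand:
    def test_label_round_trip(self):
        assert AgeBand.from_label("50 to 54") == AgeBand(50, 54)
        assert AgeBand.from_label("90 to 90+") == AgeBand(90, 90)
        assert AgeBand(70, 74).label == "70 to 74"

    def test_inverted_band_rejected(self):
        with pytest.raises(ConfigurationError):
            AgeBand(60, 55)

    def test_coverage_gap_detected(self):
        with pytest.raises(ConfigurationError, match="gap"):
            check_band_coverage([AgeBand(50, 54), AgeBand(56, 60)], 50, 60)


class TestBaselineParticipation:
    def test_probability_sum_above_one_rejected(self):
        with pytest.raises(ConfigurationError, match="sum"):
            BaselineParticipation(
                participation_frame([(50, 100, 0.7, 0.2, 0.2, 0.1, 0.1)])
            )

    def test_spa_zeroing_enforced_on_demand(self, simple_base):
        table = simple_base.table.copy()
        table.loc[1, "unemployment"] = 0.05
        bp = BaselineParticipation(table)
        with pytest.raises(ConfigurationError, match="pension"):
            bp.validate(spa=65)
        bp.zero_post_spa(65).validate(spa=65)

    def test_age_lookup_and_expansion(self, simple_base):
        assert simple_base.at_age(63)["employment"] == 0.718
        arr = simple_base.as_age_array(50, 66)
        assert arr.shape == (17, 5)
        assert arr[0, 0] == 0.718 and arr[-1, 0] == 0.107


class TestDeriveInactivity:
    def test_fully_employed_band_gets_zero_inactivity(self):
        base = BaselineParticipation(
            participation_frame([(50, 100, 1.0, 0.0, 0.0, 0.0, 0.0)])
        )
        inputs = InactivityInputs(0.5, 0.5, {AgeBand(50, 100): 0.0}, {AgeBand(50, 100): 0.0})
        out = derive_inactivity_probabilities(base, inputs)
        assert out.at_age(55)["lt_sickness"] == 0.0
        assert out.at_age(55)["early_retirement"] == 0.0

    def test_mean_times_inactive_share(self, simple_base):
        inputs = InactivityInputs(
            0.1, 0.0, {AgeBand(50, 100): 0.0}, {AgeBand(50, 100): 0.0}
        )
        out = derive_inactivity_probabilities(simple_base, inputs)
        # 0.1 * (1 - 0.718 - 0.028)
        assert out.at_age(52)["lt_sickness"] == pytest.approx(0.0254)

    def test_spa_band_zeroes_unemployment_and_early_retirement(self):
        base = BaselineParticipation(
            participation_frame([(65, 69, 0.107, 0.016, 0.0, 0.033, 0.0)])
        )
        inputs = InactivityInputs(
            0.0, 0.2, {AgeBand(65, 69): 0.2}, {AgeBand(65, 69): 0.5}
        )
        out = derive_inactivity_probabilities(base, inputs, ModelConfig())
        row = out.at_age(66)
        assert row["disability"] == pytest.approx(0.1)  # 0.2 * 0.5
        assert row["early_retirement"] == 0.0
        assert row["unemployment"] == 0.0

    def test_disability_zero_above_65(self):
        base = BaselineParticipation(
            participation_frame([(70, 74, 0.015, 0.0, 0.0, 0.0, 0.0)])
        )
        inputs = InactivityInputs(
            0.0, 0.0, {AgeBand(70, 74): 0.4}, {AgeBand(70, 74): 0.5}
        )
        out = derive_inactivity_probabilities(base, inputs)
        assert out.at_age(72)["disability"] == 0.0


class TestRelativeEffects:
    def test_ci_must_bracket_point(self):
        with pytest.raises(ConfigurationError):
            RelativeEffect("employment", "odds_ratio", 0.5, 0.6, 1.0)

    def test_set_requires_employment_effect(self):
        with pytest.raises(ConfigurationError, match="employment"):
            RelativeEffectSet(
                "moderate",
                [RelativeEffect("disability", "relative_risk", 2.0, 1.5, 2.5)],
            )

    def test_null_set_is_identity(self, simple_base):
        out = apply_relative_effects(simple_base, null_effect_set())
        pd.testing.assert_frame_equal(out.table, simple_base.table)

    def test_or_chain_on_employment(self, simple_base):
        effects = RelativeEffectSet(
            "moderate",
            [RelativeEffect("employment", "odds_ratio", 0.57, 0.57, 0.57)],
        )
        out = apply_relative_effects(simple_base, effects)
        # OR->RR at p0=0.718 gives 0.824581; times 0.718 -> 0.592049
        rr = 0.57 / (1.0 - 0.718 + 0.718 * 0.57)
        assert out.at_age(52)["employment"] == pytest.approx(0.718 * rr, abs=1e-9)

    def test_rr_scales_directly(self, simple_base):
        effects = RelativeEffectSet(
            "moderate",
            [
                RelativeEffect("employment", "relative_risk", 1.0, 1.0, 1.0),
                RelativeEffect("lt_sickness", "relative_risk", 2.0, 2.0, 2.0),
            ],
        )
        out = apply_relative_effects(simple_base, effects)
        assert out.at_age(52)["lt_sickness"] == pytest.approx(0.062)

    def test_or_used_directly_below_rare_threshold(self):
        effect = RelativeEffect("unemployment", "odds_ratio", 2.0, 2.0, 2.0)
        config = ModelConfig()
        assert effect_multiplier(effect, 0.05, config) == 2.0  # rare: no conversion
        assert effect_multiplier(effect, 0.5, config) == pytest.approx(
            2.0 / (1.0 - 0.5 + 0.5 * 2.0)
        )
        always = ModelConfig(or_conversion="always")
        assert effect_multiplier(effect, 0.05, always) < 2.0

    def test_clipping_logs_warning(self, simple_base, caplog):
        effects = RelativeEffectSet(
            "severe",
            [RelativeEffect("employment", "relative_risk", 3.0, 3.0, 3.0)],
        )
        with caplog.at_level(logging.WARNING, logger="oafiscal"):
            out = apply_relative_effects(simple_base, effects)
        assert out.at_age(52)["employment"] == 1.0
        assert any("CLIP" in r.message for r in caplog.records)

    def test_band_sum_renormalised_preserving_employment(self, simple_base, caplog):
        effects = RelativeEffectSet(
            "severe",
            [
                RelativeEffect("employment", "relative_risk", 1.0, 1.0, 1.0),
                RelativeEffect("disability", "relative_risk", 2.5, 2.5, 2.5),
            ],
        )
        with caplog.at_level(logging.WARNING, logger="oafiscal"):
            out = apply_relative_effects(simple_base, effects)
        row = out.at_age(66)  # 0.107 + 0.061 + 0.9225 > 1 before renorm
        total = sum(row[o] for o in OUTCOMES)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert row["employment"] == 0.107  # anchor untouched
        assert any("RENORM" in r.message for r in caplog.records)


class TestAdjustMortality:
    def lifetable(self, rate=0.01):
        rows = []
        for sex in ("female", "male"):
            for age in range(50, 101):
                rows.append({"age": age, "sex": sex, "rate": rate})
        return LifeTable(pd.DataFrame(rows))

    def test_identity_hazard_ratio(self):
        adj = MortalityAdjustment(oa_excess_hr=1.0)
        out = adjust_mortality(
            self.lifetable(0.01), adj, "controlled", ModelConfig(), sex="male"
        )
        assert out[0] == pytest.approx(0.01, abs=1e-12)

    def test_arms_identical_without_differential_mortality(self):
        adj = MortalityAdjustment(womac_delta=40.0)
        config = ModelConfig()  # differential off
        c = adjust_mortality(self.lifetable(), adj, "controlled", config)
        u = adjust_mortality(self.lifetable(), adj, "severe", config)
        np.testing.assert_array_equal(c, u)

    def test_womac_delta_scales_uncontrolled_rate(self):
        adj = MortalityAdjustment(
            oa_excess_hr=1.0, womac_hr_per_10=1.04, womac_delta=10.0
        )
        config = ModelConfig(differential_mortality=True)
        c = adjust_mortality(self.lifetable(0.01), adj, "controlled", config)
        u = adjust_mortality(self.lifetable(0.01), adj, "severe", config)
        assert u[0] == pytest.approx(1.04 * c[0], rel=1e-12)

    def test_probabilities_capped_at_one(self):
        adj = MortalityAdjustment(oa_excess_hr=3.0)
        out = adjust_mortality(
            self.lifetable(0.5), adj, "controlled", ModelConfig()
        )
        assert (out <= 1.0).all()

    def test_missing_age_raises(self):
        table = self.lifetable()
        with pytest.raises(ConfigurationError, match="age"):
            table.rate("male", 45)


class TestModelConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(discount_rate=1.5),
            dict(female_share=1.2),
            dict(start_age=66),  # >= default SPA
            dict(state_pension_age=72),  # > max working age
            dict(or_conversion="sometimes"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelConfig(**kwargs)

    def test_lifetime_horizon_runs_to_age_100(self):
        assert ModelConfig(lifetime=True).effective_horizon == 50
        assert ModelConfig(horizon=15).effective_horizon == 15
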