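"""Validated model inputs and the probability derivations built on them.

Houses the domain types of the fiscal cohort model — age bands, baseline
labour-market participation tables, relative-effect sets, lifetables,
mortality adjustments and the run configuration — together with the
operations that turn raw inputs into per-arm transition probabilities:

* deriving age-stratified long-term-sickness / early-retirement / disability
  probabilities from aggregate means and inactivity shares,
* applying odds-ratio or relative-risk effects to the baseline probabilities
  to construct the uncontrolled-pain arm, and
* adjusting lifetable mortality with hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conversions import odds_ratio_to_relative_risk, rate_to_probability

logger = logging.getLogger("oafiscal")

#: Labour-market outcomes tracked by the baseline participation table.
OUTCOMES = (
    "employment",
    "unemployment",
    "lt_sickness",
    "early_retirement",
    "disability",
)

SEXES = ("female", "male")

#: Oldest age covered by lifetables and lifetime runs.
MAX_AGE = 100


class ConfigurationError(ValueError):
    """Raised when model inputs are structurally invalid."""


# ---------------------------------------------------------------------------
# Age bands
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed integer age interval ``[lower, upper]``."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ConfigurationError(
                f"AgeBand lower {self.lower} exceeds upper {self.upper}"
            )

    def contains(self, age: int) -> bool:
        return self.lower <= age <= self.upper

    @property
    def label(self) -> str:
        return f"{self.lower} to {self.upper}"

    @classmethod
    def from_label(cls, label: str) -> "AgeBand":
        lo, _, hi = label.partition(" to ")
        hi = hi.replace("+", "").strip() or lo
        return cls(int(lo), int(hi))


def check_band_coverage(bands: Sequence[AgeBand], lo: int, hi: int) -> None:
    """Ensure bands are non-overlapping and tile ``[lo, hi]`` with no gaps."""
    ordered = sorted(bands)
    if not ordered:
        raise ConfigurationError("no age bands supplied")
    if ordered[0].lower > lo or ordered[-1].upper < hi:
        raise ConfigurationError(
            f"age bands cover [{ordered[0].lower}, {ordered[-1].upper}], "
            f"need [{lo}, {hi}]"
        )
    for a, b in zip(ordered, ordered[1:]):
        if b.lower != a.upper + 1:
            raise ConfigurationError(
                f"age bands {a.label!r} and {b.label!r} overlap or leave a gap"
            )


# ---------------------------------------------------------------------------
# Baseline participation
# ---------------------------------------------------------------------------


class BaselineParticipation:
    """Age-banded probabilities of the five labour-market outcomes.

    One table describes one cohort (one arm, one sex).  Per band the five
    probabilities must sum to at most 1; the residual is the tax-neutral
    "unknown fiscal consequences" mass.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age_lower", "age_upper", *OUTCOMES}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(
                f"participation table missing columns: {sorted(missing)}"
            )
        table = table.sort_values("age_lower").reset_index(drop=True)
        self.table = table
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(
        self,
        spa: int | None = None,
        max_working_age: int | None = None,
    ) -> None:
        t = self.table
        for col in OUTCOMES:
            bad = t[(t[col] < 0) | (t[col] > 1)]
            if not bad.empty:
                raise ConfigurationError(
                    f"{col} outside [0, 1] in band "
                    f"{int(bad.iloc[0].age_lower)}-{int(bad.iloc[0].age_upper)}"
                )
        sums = t[list(OUTCOMES)].sum(axis=1)
        over = sums > 1.0 + 1e-9
        if over.any():
            i = int(np.argmax(over.to_numpy()))
            raise ConfigurationError(
                f"outcome probabilities sum to {sums.iloc[i]:.6f} > 1 in band "
                f"{int(t.age_lower.iloc[i])}-{int(t.age_upper.iloc[i])}"
            )
        check_band_coverage(self.bands(), int(t.age_lower.min()), int(t.age_upper.max()))
        if spa is not None:
            post = t[t.age_lower >= spa]
            if (post["unemployment"] > 0).any() or (post["early_retirement"] > 0).any():
                raise ConfigurationError(
                    f"unemployment/early retirement must be 0 at or above "
                    f"state pension age {spa}"
                )
        if max_working_age is not None:
            post = t[t.age_lower > max_working_age]
            if (post["employment"] > 0).any():
                raise ConfigurationError(
                    f"employment must be 0 above maximum working age {max_working_age}"
                )

    # -- access -----------------------------------------------------------

    def bands(self) -> list[AgeBand]:
        return [
            AgeBand(int(r.age_lower), int(r.age_upper))
            for r in self.table.itertuples()
        ]

    def band_for(self, age: int) -> AgeBand:
        for b in self.bands():
            if b.contains(age):
                return b
        raise ConfigurationError(f"no age band covers age {age}")

    def at_age(self, age: int) -> dict[str, float]:
        t = self.table
        row = t[(t.age_lower <= age) & (t.age_upper >= age)]
        if row.empty:
            raise ConfigurationError(f"no age band covers age {age}")
        return {c: float(row.iloc[0][c]) for c in OUTCOMES}

    def as_age_array(self, start: int, stop: int) -> np.ndarray:
        """Outcome probabilities per single year of age, shape ``(stop-start+1, 5)``."""
        out = np.empty((stop - start + 1, len(OUTCOMES)))
        for i, age in enumerate(range(start, stop + 1)):
            row = self.at_age(age)
            out[i] = [row[c] for c in OUTCOMES]
        return out

    def copy(self) -> "BaselineParticipation":
        return BaselineParticipation(self.table.copy())

    def zero_post_spa(self, spa: int) -> "BaselineParticipation":
        """Return a copy with unemployment/early retirement zeroed at >= SPA."""
        t = self.table.copy()
        mask = t.age_lower >= spa
        t.loc[mask, ["unemployment", "early_retirement"]] = 0.0
        return BaselineParticipation(t)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BaselineParticipation) and self.table.equals(
            other.table
        )


@dataclass
class InactivityInputs:
    """Aggregate inputs from which inactivity probabilities are derived.

    Long-term sickness and early retirement are published as single mean
    proportions of the economically inactive population; disability combines
    an age-specific probability of being disabled with the age-specific
    prevalence of economic inactivity among disabled people (available up to
    age 65).
    """

    lt_sickness_mean: float
    early_retirement_mean: float
    disability_prob_by_age: Mapping[AgeBand, float]
    disabled_inactivity_prevalence_by_age: Mapping[AgeBand, float]

    def __post_init__(self) -> None:
        for name in ("lt_sickness_mean", "early_retirement_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("disability_prob_by_age", "disabled_inactivity_prevalence_by_age"):
            for band, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(
                        f"{name}[{band.label}] must be in [0, 1], got {v!r}"
                    )

    def _lookup(self, mapping: Mapping[AgeBand, float], band: AgeBand) -> float:
        if band in mapping:
            return mapping[band]
        for b, v in mapping.items():
            if b.contains(band.lower) and b.contains(band.upper):
                return v
        raise ConfigurationError(f"no inactivity input covers band {band.label!r}")


# ---------------------------------------------------------------------------
# Relative effects
# ---------------------------------------------------------------------------

MEASURES = ("odds_ratio", "relative_risk")


@dataclass(frozen=True)
class RelativeEffect:
    """Multiplicative effect of uncontrolled pain on one labour-market outcome."""

    outcome: str
    measure: str
    point: float
    ci_low: float
    ci_high: float
    age_band: AgeBand | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(
                f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}"
            )
        if self.measure not in MEASURES:
            raise ConfigurationError(
                f"unknown measure {self.measure!r}; expected one of {MEASURES}"
            )
        if not (0.0 < self.ci_low <= self.point <= self.ci_high):
            raise ConfigurationError(
                f"effect on {self.outcome}: need 0 < ci_low <= point <= ci_high, "
                f"got ({self.ci_low}, {self.point}, {self.ci_high})"
            )

    @property
    def parameter_id(self) -> str:
        tag = f"{self.outcome}_{self.measure}"
        if self.age_band is not None:
            tag += f"_{self.age_band.lower}_{self.age_band.upper}"
        return tag

    def with_point(self, value: float) -> "RelativeEffect":
        """Copy with the point estimate replaced (CIs widened to keep validity)."""
        return replace(
            self,
            point=value,
            ci_low=min(self.ci_low, value),
            ci_high=max(self.ci_high, value),
        )


@dataclass
class RelativeEffectSet:
    """All effects describing one uncontrolled-pain severity arm."""

    severity: str
    effects: tuple[RelativeEffect, ...]

    def __init__(self, severity: str, effects: Iterable[RelativeEffect]):
        if severity not in ("moderate", "severe"):
            raise ConfigurationError(
                f"severity must be 'moderate' or 'severe', got {severity!r}"
            )
        effects = tuple(effects)
        keys = [(e.outcome, e.age_band) for e in effects]
        if len(keys) != len(set(keys)):
            raise ConfigurationError(
                "at most one effect per (outcome, age band) is allowed"
            )
        if not any(e.outcome == "employment" for e in effects):
            raise ConfigurationError(
                "effect set must contain an employment effect (the model's "
                "most influential parameter)"
            )
        self.severity = severity
        self.effects = effects

    def effect_for(self, outcome: str, age: int) -> RelativeEffect | None:
        generic = None
        for e in self.effects:
            if e.outcome != outcome:
                continue
            if e.age_band is None:
                generic = e
            elif e.age_band.contains(age):
                return e
        return generic

    def replace_effect(self, parameter_id: str, value: float) -> "RelativeEffectSet":
        out = [
            e.with_point(value) if e.parameter_id == parameter_id else e
            for e in self.effects
        ]
        if all(e is o for e, o in zip(out, self.effects)):
            raise ConfigurationError(f"no effect with parameter id {parameter_id!r}")
        return RelativeEffectSet(self.severity, out)


def null_effect_set(severity: str = "moderate") -> RelativeEffectSet:
    """Effect set leaving the baseline unchanged (all multipliers 1)."""
    return RelativeEffectSet(
        severity,
        [
            RelativeEffect(o, "relative_risk", 1.0, 1.0, 1.0)
            for o in OUTCOMES
        ],
    )


# ---------------------------------------------------------------------------
# Mortality
# ---------------------------------------------------------------------------


class LifeTable:
    """Annual mortality rates per sex and single year of age."""

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "rate"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigurationError(f"lifetable missing columns: {sorted(missing)}")
        if (table["rate"] < 0).any():
            raise ConfigurationError("lifetable rates must be non-negative")
        self.table = table.sort_values(["sex", "age"]).reset_index(drop=True)
        self._by_sex = {
            sex: g.set_index("age")["rate"] for sex, g in self.table.groupby("sex")
        }

    def rate(self, sex: str, age: int) -> float:
        try:
            return float(self._by_sex[sex].loc[age])
        except KeyError:
            raise ConfigurationError(
                f"lifetable has no rate for sex={sex!r} age={age}"
            ) from None

    def rates(self, sex: str, start: int, stop: int) -> np.ndarray:
        return np.array([self.rate(sex, a) for a in range(start, stop + 1)])

    def validate_coverage(self, start: int, stop: int = MAX_AGE) -> None:
        for sex in self._by_sex:
            ages = set(self._by_sex[sex].index)
            missing = [a for a in range(start, stop + 1) if a not in ages]
            if missing:
                raise ConfigurationError(
                    f"lifetable for {sex} missing ages {missing[:5]}..."
                )


@dataclass
class MortalityAdjustment:
    """Hazard-ratio adjustments applied to lifetable mortality.

    ``oa_excess_hr`` applies to both arms (excess mortality of the condition
    itself).  ``womac_hr_per_10`` is the per-10-point pain-score hazard ratio
    used only in the differential-mortality scenario, where the uncontrolled
    arm is additionally multiplied by ``womac_hr_per_10 ** (womac_delta/10)``.
    """

    oa_excess_hr: float = 1.11
    oa_excess_ci: tuple[float, float] = (1.06, 1.17)
    womac_hr_per_10: float = 1.04
    womac_hr_ci: tuple[float, float] = (1.01, 1.07)
    womac_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.oa_excess_hr <= 0 or self.womac_hr_per_10 <= 0:
            raise ConfigurationError("hazard ratios must be strictly positive")

    def arm_hazard_ratio(self, arm: str, differential: bool) -> float:
        hr = self.oa_excess_hr
        if differential and arm != "controlled":
            hr *= self.womac_hr_per_10 ** (self.womac_delta / 10.0)
        return hr


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Structural and economic settings of a model run.

    Defaults describe the base case: cohort entry at 50 with 15 years of
    remaining work expectancy, state pension age 65, maximum working age 70,
    3.5 %/year discounting, 58.6 % female cohort, and +20 %/+30 % health-care
    uplifts for moderate/severe uncontrolled pain.
    """

    start_age: int = 50
    state_pension_age: int = 65
    max_working_age: int = 70
    horizon: int = 15
    lifetime: bool = False
    discount_rate: float = 0.035
    female_share: float = 0.586
    cycle_length: float = 1.0
    healthcare_uplift_moderate: float = 0.20
    healthcare_uplift_severe: float = 0.30
    differential_mortality: bool = False
    seed: int = 0
    # residual mass pre-SPA goes to the tax-neutral UNKNOWN state by default;
    # set True to route it straight to EMPLOYED (skipping the 1-cycle detour)
    residual_to_employment: bool = False
    # odds ratios are converted to relative risks only when the baseline
    # probability is at least this (the "not rare" rule); force with
    # or_conversion = "always" | "never" | "threshold"
    or_rare_threshold: float = 0.10
    or_conversion: str = "threshold"

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigurationError("discount_rate must be in [0, 1)")
        if not 0.0 <= self.female_share <= 1.0:
            raise ConfigurationError("female_share must be in [0, 1]")
        if not self.start_age < self.state_pension_age <= self.max_working_age:
            raise ConfigurationError(
                "need start_age < state_pension_age <= max_working_age, got "
                f"{self.start_age} / {self.state_pension_age} / {self.max_working_age}"
            )
        if self.cycle_length != 1.0:
            raise ConfigurationError("cycle_length is fixed at 1 year")
        for name in ("healthcare_uplift_moderate", "healthcare_uplift_severe"):
            if getattr(self, name) < -1.0:
                raise ConfigurationError(f"{name} must be above -1")
        if self.or_conversion not in ("threshold", "always", "never"):
            raise ConfigurationError(
                "or_conversion must be 'threshold', 'always' or 'never'"
            )
        if self.horizon < 1:
            raise ConfigurationError("horizon must be at least 1 cycle")

    @property
    def effective_horizon(self) -> int:
        """Number of annual cycles actually simulated."""
        if self.lifetime:
            return MAX_AGE - self.start_age
        return min(self.horizon, MAX_AGE - self.start_age)

    def healthcare_uplift(self, arm: str) -> float:
        if arm == "controlled":
            return 0.0
        if arm == "moderate":
            return self.healthcare_uplift_moderate
        if arm == "severe":
            return self.healthcare_uplift_severe
        raise ConfigurationError(f"unknown arm {arm!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def derive_inactivity_probabilities(
    base: BaselineParticipation,
    inputs: InactivityInputs,
    config: ModelConfig | None = None,
) -> BaselineParticipation:
    """Fill the inactivity columns from aggregate means and shares.

    Per band ``b``::

        lt_sickness(b)      = lt_sickness_mean      * (1 - employment - unemployment)
        early_retirement(b) = early_retirement_mean * (1 - employment - unemployment)
        disability(b)       = disability_prob(b) * disabled_inactivity_prevalence(b)

    Disability is zero for bands entirely above 65 (the inactivity prevalence
    source covers ages up to 65); unemployment and early retirement are
    zeroed at or above state pension age.
    """
    config = config or ModelConfig()
    t = base.table.copy()
    spa = config.state_pension_age
    for i, row in t.iterrows():
        band = AgeBand(int(row.age_lower), int(row.age_upper))
        inactive = 1.0 - row.employment - row.unemployment
        if inactive < -1e-9:
            raise ConfigurationError(
                f"employment + unemployment > 1 in band {band.label!r}"
            )
        inactive = max(inactive, 0.0)
        t.loc[i, "lt_sickness"] = inputs.lt_sickness_mean * inactive
        t.loc[i, "early_retirement"] = inputs.early_retirement_mean * inactive
        if band.lower > 65:
            t.loc[i, "disability"] = 0.0
        else:
            t.loc[i, "disability"] = inputs._lookup(
                inputs.disability_prob_by_age, band
            ) * inputs._lookup(inputs.disabled_inactivity_prevalence_by_age, band)
        if band.lower >= spa:
            t.loc[i, "unemployment"] = 0.0
            t.loc[i, "early_retirement"] = 0.0
    return BaselineParticipation(t)


def effect_multiplier(
    effect: RelativeEffect, p0: float, config: ModelConfig
) -> float:
    """Relative risk actually applied to a baseline probability.

    Odds ratios are converted via the OR->RR identity when the outcome is
    not rare (p0 >= ``or_rare_threshold``), or always/never when forced.
    """
    if effect.measure == "relative_risk":
        return effect.point
    convert = {
        "always": True,
        "never": False,
        "threshold": p0 >= config.or_rare_threshold,
    }[config.or_conversion]
    if convert:
        return odds_ratio_to_relative_risk(effect.point, p0)
    return effect.point


def apply_relative_effects(
    base: BaselineParticipation,
    effects: RelativeEffectSet,
    config: ModelConfig | None = None,
) -> BaselineParticipation:
    """Construct the uncontrolled-arm participation table.

    Each outcome with an effect has its baseline probability multiplied by
    the (possibly OR->RR converted) effect; results are clipped to [0, 1]
    with a warning.  If a band's five probabilities then exceed 1, the excess
    is first absorbed by shrinking the unknown residual to zero; any
    remaining excess is removed by proportionally scaling the four
    non-employment outcomes (employment is the model's anchor parameter).
    """
    config = config or ModelConfig()
    t = base.table.copy()
    for i, row in t.iterrows():
        band_mid = int(row.age_lower)
        for outcome in OUTCOMES:
            eff = effects.effect_for(outcome, band_mid)
            if eff is None:
                continue
            p0 = float(row[outcome])
            new = p0 * effect_multiplier(eff, p0, config)
            if new > 1.0:
                logger.warning(
                    "CLIP outcome=%s band=%s-%s value=%.6f clipped to 1",
                    outcome,
                    int(row.age_lower),
                    int(row.age_upper),
                    new,
                )
                new = 1.0
            t.loc[i, outcome] = new
        total = float(t.loc[i, list(OUTCOMES)].sum())
        if total > 1.0 + 1e-12:
            # residual (unknown) mass is already implicitly zero here; scale
            # the non-employment outcomes down so the band sums to exactly 1
            emp = float(t.loc[i, "employment"])
            others = total - emp
            if others <= 0.0 or emp > 1.0:
                raise ConfigurationError(
                    f"cannot renormalise band {int(row.age_lower)}-"
                    f"{int(row.age_upper)}: employment alone exceeds 1"
                )
            scale = (1.0 - emp) / others
            logger.warning(
                "RENORM band=%s-%s sum=%.6f non-employment outcomes scaled by %.6f",
                int(row.age_lower),
                int(row.age_upper),
                total,
                scale,
            )
            for outcome in OUTCOMES[1:]:
                t.loc[i, outcome] = float(t.loc[i, outcome]) * scale
    return BaselineParticipation(t)


def adjust_mortality(
    table: LifeTable,
    adj: MortalityAdjustment,
    arm: str,
    config: ModelConfig,
    sex: str = "female",
    start: int | None = None,
    stop: int | None = None,
) -> np.ndarray:
    """Annual death probabilities per single year of age for one arm.

    The lifetable rate at each age is multiplied by the excess-mortality
    hazard ratio (both arms) and, in the differential-mortality scenario, by
    the pain-score hazard ratio for the uncontrolled arm; adjusted rates are
    converted to annual probabilities and capped at 1.
    """
    start = config.start_age if start is None else start
    stop = (config.start_age + config.effective_horizon - 1) if stop is None else stop
    hr = adj.arm_hazard_ratio(arm, config.differential_mortality)
    rates = table.rates(sex, start, stop) * hr
    out = np.empty_like(rates)
    for i, r in enumerate(rates):
        if r >= 1.0:
            out[i] = 1.0
        else:
            out[i] = rate_to_probability(r, 1.0, config.cycle_length)
    return out
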