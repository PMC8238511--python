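"""End-to-end model runs: arms, sexes, weighting and the comparison report.

A run takes a :class:`ModelInputs` bundle, builds each arm's participation
probabilities (controlled = baseline; uncontrolled = baseline with relative
effects applied), adjusts mortality, simulates the cohort per sex, converts
occupancy into discounted cash flows and weights the sexes by the female
share.  The headline statistic is the incremental net tax (INT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fiscal import (
    FiscalResult,
    FiscalSchedule,
    HealthcareCostTable,
    annual_healthcare_cost,
    cash_flow_matrix,
    disaggregate,
    incremental,
    incremental_net_tax,
    npv,
)
from .markov import CohortTrace, build_transition_matrix, initial_occupancy, run_cohort
from .parameters import (
    BaselineParticipation,
    ConfigurationError,
    LifeTable,
    ModelConfig,
    MortalityAdjustment,
    RelativeEffectSet,
    SEXES,
    adjust_mortality,
    apply_relative_effects,
)

SEVERITIES = ("moderate", "severe")


@dataclass
class ModelInputs:
    """Complete input bundle for a comparison run.

    ``participation`` maps sex -> baseline table for the controlled-pain
    (general-population) cohort; ``effects`` maps severity -> the
    uncontrolled arm's relative-effect set.
    """

    participation: dict[str, BaselineParticipation]
    lifetable: LifeTable
    effects: dict[str, RelativeEffectSet]
    schedule: FiscalSchedule = field(default_factory=FiscalSchedule)
    healthcare: HealthcareCostTable = field(default_factory=HealthcareCostTable)
    mortality: MortalityAdjustment = field(default_factory=MortalityAdjustment)
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.participation:
                raise ConfigurationError(f"participation table missing for {sex!r}")
        end_age = self.config.start_age + self.config.effective_horizon - 1
        self.lifetable.validate_coverage(self.config.start_age, end_age)
        for sex in SEXES:
            self.participation[sex].validate(
                spa=self.config.state_pension_age,
            )

    def with_config(self, **overrides) -> "ModelInputs":
        """Copy with ModelConfig fields replaced (unknown keys rejected)."""
        cfg_fields = {f.name for f in ModelConfig.__dataclass_fields__.values()}
        bad = set(overrides) - cfg_fields
        if bad:
            raise ConfigurationError(f"unknown config overrides: {sorted(bad)}")
        return replace(self, config=replace(self.config, **overrides))

    def with_effects(self, severity: str, effects: RelativeEffectSet) -> "ModelInputs":
        new = dict(self.effects)
        new[severity] = effects
        return replace(self, effects=new)


@dataclass
class ArmRun:
    result: FiscalResult
    traces: dict[str, CohortTrace]


@dataclass
class ComparisonResult:
    """Both arms of one severity comparison plus the incremental column."""

    severity: str
    controlled: FiscalResult
    uncontrolled: FiscalResult
    traces: dict[str, dict[str, CohortTrace]]

    @property
    def incremental(self) -> FiscalResult:
        return incremental(self.controlled, self.uncontrolled)

    @property
    def int_value(self) -> float:
        return incremental_net_tax(self.controlled, self.uncontrolled)

    @property
    def healthcare_share(self) -> float:
        """Incremental health-care cost as a share of incremental government cost."""
        inc = self.incremental
        total = abs(inc.total_transfers)
        return abs(inc.healthcare) / total if total > 0 else float("nan")


def arm_participation(inputs: ModelInputs, arm: str, sex: str) -> BaselineParticipation:
    base = inputs.participation[sex]
    if arm == "controlled":
        return base
    if arm not in inputs.effects:
        raise ConfigurationError(f"no effect set for severity {arm!r}")
    return apply_relative_effects(base, inputs.effects[arm], inputs.config)


def run_arm_sex(inputs: ModelInputs, arm: str, sex: str) -> tuple[FiscalResult, CohortTrace]:
    """Simulate one arm for one sex and return discounted totals + trace."""
    config = inputs.config
    T = config.effective_horizon
    ages = np.arange(config.start_age, config.start_age + T)
    participation = arm_participation(inputs, arm, sex)
    death = adjust_mortality(
        inputs.lifetable, inputs.mortality, arm, config, sex=sex
    )
    matrices = np.stack(
        [
            build_transition_matrix(
                int(age), participation.at_age(int(age)), float(death[t]), config
            )
            for t, age in enumerate(ages)
        ]
    )
    init = initial_occupancy(participation.at_age(config.start_age))
    trace = run_cohort(init, matrices, config.start_age, arm=arm, sex=sex)
    hc = annual_healthcare_cost(arm, inputs.healthcare, config)
    flows = cash_flow_matrix(ages, inputs.schedule, config, hc)
    result = npv(trace, flows, config.discount_rate, arm=arm)
    return result, trace


def run_arm(inputs: ModelInputs, arm: str) -> ArmRun:
    """Run both sexes for one arm and weight by the female share."""
    f = inputs.config.female_share
    traces: dict[str, CohortTrace] = {}
    weighted: FiscalResult | None = None
    for sex, w in (("female", f), ("male", 1.0 - f)):
        res, trace = run_arm_sex(inputs, arm, sex)
        traces[sex] = trace
        part = res.scaled(w)
        weighted = part if weighted is None else weighted + part
    assert weighted is not None
    weighted.arm = arm
    return ArmRun(weighted, traces)


def run_comparison(inputs: ModelInputs, severity: str) -> ComparisonResult:
    """Controlled vs uncontrolled comparison for one pain severity."""
    if severity not in SEVERITIES:
        raise ConfigurationError(f"severity must be one of {SEVERITIES}")
    controlled = run_arm(inputs, "controlled")
    uncontrolled = run_arm(inputs, severity)
    return ComparisonResult(
        severity=severity,
        controlled=controlled.result,
        uncontrolled=uncontrolled.result,
        traces={"controlled": controlled.traces, severity: uncontrolled.traces},
    )


def run_base_case(inputs: ModelInputs):
    """Run both severity comparisons and return the disaggregated report.

    Returns ``(report, comparisons)`` where ``report`` is a DataFrame with
    one column per arm plus incremental columns, and ``comparisons`` maps
    severity -> :class:`ComparisonResult`.
    """
    comparisons = {s: run_comparison(inputs, s) for s in SEVERITIES if s in inputs.effects}
    if not comparisons:
        raise ConfigurationError("inputs carry no effect sets to compare")
    first = next(iter(comparisons.values()))
    report = disaggregate(
        first.controlled, {s: c.uncontrolled for s, c in comparisons.items()}
    )
    return report, comparisons
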