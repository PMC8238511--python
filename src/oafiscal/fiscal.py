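"""Fiscal accounting: cash flows per state, discounting and incremental net tax.

Each person-year in a fiscal state generates taxes (direct + national
insurance folded into the 30.9 % tax wedge, plus 13.7 % indirect tax on
disposable income — labour or benefit), transfer payments (jobseeker's
allowance, employment and support allowance, personal independence payment,
state pension, attendance allowance) and health-care costs.  Flows are
discounted to a net present value per arm and compared as an incremental
net tax (INT): controlled-arm net tax minus uncontrolled-arm net tax, so a
positive INT is a cost of uncontrolled pain to the government.

Earnings are back-computed from the age-band labour-tax amount and the tax
wedge (earnings = labour tax / wedge); tariffs print the tax, results report
the earnings.  Amounts are nominal GBP with no inflation indexing; rounding
to whole pounds happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import FiscalState, N_STATES, CohortTrace
from .parameters import AgeBand, ConfigurationError, ModelConfig

#: Monetary components tracked per cycle and arm.
COMPONENTS = (
    "earnings",
    "gross_tax",
    "jobseekers",
    "esa",
    "pip",
    "early_retirement_pension",
    "state_pension_plus_attendance",
    "healthcare",
)
TRANSFER_COMPONENTS = (
    "jobseekers",
    "esa",
    "pip",
    "early_retirement_pension",
    "state_pension_plus_attendance",
)


@dataclass
class FiscalSchedule:
    """Tax rates and annualised benefit amounts (GBP per capita per year)."""

    median_labour_tax_by_age: tuple[tuple[AgeBand, float], ...] = (
        (AgeBand(0, 59), 10886.0),
        (AgeBand(60, 64), 10015.0),
        (AgeBand(65, 200), 8825.0),
    )
    tax_wedge: float = 0.309
    indirect_tax_rate: float = 0.137
    jobseekers_allowance: float = 3866.0
    esa: float = 4885.0
    pip: float = 6102.0
    basic_state_pension: float = 9110.0
    attendance_allowance: float = 3258.0
    attendance_share_disabled: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "jobseekers_allowance",
            "esa",
            "pip",
            "basic_state_pension",
            "attendance_allowance",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("tax_wedge", "indirect_tax_rate", "attendance_share_disabled"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for band, amount in self.median_labour_tax_by_age:
            if amount < 0:
                raise ConfigurationError(
                    f"labour tax for band {band.label!r} must be non-negative"
                )

    def labour_tax(self, age: int) -> float:
        for band, amount in self.median_labour_tax_by_age:
            if band.contains(age):
                return amount
        raise ConfigurationError(f"no labour-tax band covers age {age}")


@dataclass
class HealthcareCostTable:
    """Annual health-care resource use and unit costs (GBP).

    Aggregate annual drug and appointment costs are taken as printed;
    referrals and surgical revisions enter as expected costs
    (probability x unit cost).  Primary surgery annual probabilities are not
    published and default to 0 (configurable).
    """

    annual_drug_cost: float = 203.0
    annual_appointment_cost: float = 713.0
    referral_share: float = 0.7082
    referral_cost: float = 82.0
    primary_hip: tuple[float, float] = (0.0, 6714.0)
    primary_knee: tuple[float, float] = (0.0, 6296.0)
    revision_hip_aseptic: tuple[float, float] = (0.0047, 12444.0)
    revision_hip_septic: tuple[float, float] = (0.0004, 22946.0)
    revision_knee_aseptic: tuple[float, float] = (0.0035, 10325.0)
    revision_knee_septic: tuple[float, float] = (0.0009, 32094.0)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                prob, cost = v
                if not 0.0 <= prob <= 1.0:
                    raise ConfigurationError(f"{f.name} probability outside [0, 1]")
                if cost < 0:
                    raise ConfigurationError(f"{f.name} cost must be non-negative")
            elif v < 0:
                raise ConfigurationError(f"{f.name} must be non-negative")

    def base_annual_cost(self) -> float:
        """Expected annual health-care cost per living person, controlled pain."""
        expected_surgery = sum(
            prob * cost
            for prob, cost in (
                self.primary_hip,
                self.primary_knee,
                self.revision_hip_aseptic,
                self.revision_hip_septic,
                self.revision_knee_aseptic,
                self.revision_knee_septic,
            )
        )
        return (
            self.annual_drug_cost
            + self.annual_appointment_cost
            + self.referral_share * self.referral_cost
            + expected_surgery
        )


def annual_healthcare_cost(
    arm: str, table: HealthcareCostTable, config: ModelConfig
) -> float:
    """Annual health-care cost per living person-year for one arm.

    The uncontrolled arms consume 20 % (moderate) or 30 % (severe) more
    resources than the controlled-pain base.
    """
    uplift = config.healthcare_uplift(arm)
    if uplift < -1.0:
        raise ConfigurationError(f"healthcare uplift {uplift} below -1")
    return table.base_annual_cost() * (1.0 + uplift)


@dataclass
class CashFlowBreakdown:
    """Per-person-year monetary flows of one state at one age (GBP)."""

    earnings: float = 0.0
    gross_tax: float = 0.0
    jobseekers: float = 0.0
    esa: float = 0.0
    pip: float = 0.0
    early_retirement_pension: float = 0.0
    state_pension_plus_attendance: float = 0.0
    healthcare: float = 0.0

    @property
    def total_transfers(self) -> float:
        return (
            self.jobseekers
            + self.esa
            + self.pip
            + self.early_retirement_pension
            + self.state_pension_plus_attendance
            + self.healthcare
        )

    @property
    def net_tax(self) -> float:
        return self.gross_tax - self.total_transfers

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENTS])


def state_cash_flows(
    state: FiscalState,
    age: int,
    schedule: FiscalSchedule,
    config: ModelConfig,
    healthcare_cost: float = 0.0,
) -> CashFlowBreakdown:
    """Cash flows generated by one person-year in ``state`` at ``age``.

    Employment pays the age-band labour tax plus indirect tax on disposable
    labour income; benefit recipients generate indirect tax on their gross
    benefit income; disabled people past state pension age receive the
    pension plus a 50 % share of attendance allowance.  UNKNOWN is
    tax-neutral and DEAD generates nothing; every living state incurs the
    arm's health-care cost.
    """
    if not isinstance(state, FiscalState):
        raise ConfigurationError(f"unknown state {state!r}")
    flow = CashFlowBreakdown()
    spa = config.state_pension_age
    ind = schedule.indirect_tax_rate

    if state == FiscalState.DEAD:
        return flow

    flow.healthcare = healthcare_cost

    if state == FiscalState.EMPLOYED:
        tax = schedule.labour_tax(age)
        earnings = tax / schedule.tax_wedge if schedule.tax_wedge > 0 else 0.0
        flow.earnings = earnings
        flow.gross_tax = tax + ind * (earnings - tax)
    elif state == FiscalState.UNEMPLOYED:
        if age < spa:
            flow.jobseekers = schedule.jobseekers_allowance
            flow.gross_tax = ind * flow.jobseekers
    elif state == FiscalState.LT_SICK:
        flow.esa = schedule.esa
        flow.gross_tax = ind * flow.esa
    elif state == FiscalState.DISABLED:
        if age < spa:
            flow.pip = schedule.pip
            flow.gross_tax = ind * flow.pip
        else:
            flow.state_pension_plus_attendance = (
                schedule.basic_state_pension
                + schedule.attendance_share_disabled * schedule.attendance_allowance
            )
            flow.gross_tax = ind * flow.state_pension_plus_attendance
    elif state == FiscalState.EARLY_RETIRED:
        flow.early_retirement_pension = schedule.basic_state_pension
        flow.gross_tax = ind * flow.early_retirement_pension
    elif state == FiscalState.RETIRED:
        flow.state_pension_plus_attendance = schedule.basic_state_pension
        flow.gross_tax = ind * flow.state_pension_plus_attendance
    # UNKNOWN: tax-neutral, only health care

    return flow


def cash_flow_matrix(
    ages: Sequence[int],
    schedule: FiscalSchedule,
    config: ModelConfig,
    healthcare_cost: float,
) -> np.ndarray:
    """Per-cycle, per-state component flows, shape ``(T, N_STATES, n_components)``."""
    out = np.zeros((len(ages), N_STATES, len(COMPONENTS)))
    for t, age in enumerate(ages):
        for s in FiscalState:
            out[t, s] = state_cash_flows(
                s, int(age), schedule, config, healthcare_cost
            ).as_vector()
    return out


@dataclass
class FiscalResult:
    """Discounted per-capita totals for one arm (GBP, except life-years)."""

    earnings: float = 0.0
    gross_tax: float = 0.0
    jobseekers: float = 0.0
    esa: float = 0.0
    pip: float = 0.0
    early_retirement_pension: float = 0.0
    state_pension_plus_attendance: float = 0.0
    healthcare: float = 0.0
    life_years: float = 0.0
    arm: str = ""

    @property
    def total_transfers(self) -> float:
        return (
            self.jobseekers
            + self.esa
            + self.pip
            + self.early_retirement_pension
            + self.state_pension_plus_attendance
            + self.healthcare
        )

    @property
    def net_tax(self) -> float:
        return self.gross_tax - self.total_transfers

    def scaled(self, w: float) -> "FiscalResult":
        kw = {c: getattr(self, c) * w for c in COMPONENTS}
        return FiscalResult(**kw, life_years=self.life_years * w, arm=self.arm)

    def __add__(self, other: "FiscalResult") -> "FiscalResult":
        kw = {c: getattr(self, c) + getattr(other, c) for c in COMPONENTS}
        return FiscalResult(
            **kw, life_years=self.life_years + other.life_years, arm=self.arm
        )


def npv(
    trace: CohortTrace,
    flows: np.ndarray,
    discount_rate: float,
    arm: str = "",
) -> FiscalResult:
    """Discount per-cycle flows weighted by occupancy into a FiscalResult.

    ``flows`` has shape ``(T, N_STATES, n_components)`` (from
    :func:`cash_flow_matrix`); cycle ``t`` (0-based, t = 0 undiscounted)
    is discounted by ``(1+r)^t`` and weighted by cycle-start occupancy.
    """
    if discount_rate <= -1.0:
        raise ConfigurationError("discount rate must exceed -1")
    T = trace.n_cycles
    if flows.shape[0] != T:
        raise ConfigurationError(
            f"flows cover {flows.shape[0]} cycles, trace has {T}"
        )
    occ = trace.occupancy[:T]  # cycle-start occupancy
    disc = (1.0 + discount_rate) ** -np.arange(T)
    totals = np.einsum("t,ts,tsc->c", disc, occ, flows)
    kw = dict(zip(COMPONENTS, totals.tolist()))
    living = trace.living()[:T]
    ly = float(np.sum(living * disc))
    return FiscalResult(**kw, life_years=ly, arm=arm)


def incremental(controlled: FiscalResult, uncontrolled: FiscalResult) -> FiscalResult:
    """Component-wise controlled - uncontrolled differences.

    Under this single convention tax and earnings increments come out
    positive and transfer increments negative when uncontrolled pain reduces
    work and raises benefit receipt, matching the published sign convention.
    """
    kw = {c: getattr(controlled, c) - getattr(uncontrolled, c) for c in COMPONENTS}
    return FiscalResult(
        **kw,
        life_years=controlled.life_years - uncontrolled.life_years,
        arm=f"{controlled.arm} - {uncontrolled.arm}",
    )


def incremental_net_tax(
    controlled: FiscalResult, uncontrolled: FiscalResult
) -> float:
    """INT: controlled-arm net tax minus uncontrolled-arm net tax (GBP)."""
    return controlled.net_tax - uncontrolled.net_tax


_REPORT_ROWS = (
    ("Earnings", "earnings"),
    ("Gross Tax Revenue", "gross_tax"),
    ("Job-Seeking Allowance", "jobseekers"),
    ("Employment and Support Allowance", "esa"),
    ("Personal Independence Payment", "pip"),
    ("Early Retirement Pension", "early_retirement_pension"),
    ("Basic State Pension + Attendance Allowance", "state_pension_plus_attendance"),
    ("Health-care costs", "healthcare"),
)


def disaggregate(
    controlled: FiscalResult,
    by_severity: dict[str, FiscalResult],
) -> pd.DataFrame:
    """Disaggregated results table: one column per arm plus incremental columns.

    Rows are earnings, gross tax, the five transfer components, health-care
    costs, total transfers, net tax and life-years; incremental columns are
    controlled minus uncontrolled throughout (transfers therefore show
    negative when the uncontrolled arm receives more).
    """
    cols: dict[str, dict[str, float]] = {}

    def column(res: FiscalResult) -> dict[str, float]:
        col = {label: getattr(res, attr) for label, attr in _REPORT_ROWS}
        col["Total Transfers"] = res.total_transfers
        col["Net Tax"] = res.net_tax
        col["Life-Years"] = res.life_years
        return col

    cols["controlled"] = column(controlled)
    for severity, res in by_severity.items():
        cols[severity] = column(res)
        cols[f"incremental_{severity}"] = column(incremental(controlled, res))
    return pd.DataFrame(cols)
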