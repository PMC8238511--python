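"""Packaged UK reference inputs built from published national figures.

The participation table, tax/benefit tariffs and health-care costs encode
the published UK per-capita values the model was designed around.  Two
classes of input are *not* published and are filled with documented
stand-ins, so this bundle is runnable but explicitly non-calibrated:

* the lifetable (national data we deliberately do not ship) — replaced by
  the package's synthetic Gompertz lifetable at UK-like magnitudes;
* the relative-effect confidence intervals beyond the moderate employment
  odds ratio (point 0.57, upper bound 1.54 published; lower bound set by
  log-symmetry) — replaced by the synthetic direction-realistic templates.

``published_base_case`` returns the published disaggregated base-case
results (GBP, 15-year horizon, 3.5 % discounting) for side-by-side
comparison and arithmetic-identity checking; the model does not read it.
"""

from __future__ import annotations

import logging

import pandas as pd

from .fiscal import FiscalSchedule, HealthcareCostTable
from .model import ModelInputs
from .parameters import (
    BaselineParticipation,
    ModelConfig,
    MortalityAdjustment,
)
from .synthetic import SyntheticSpec, make_effect_set, make_lifetable

logger = logging.getLogger("oafiscal")

#: Published age-banded probabilities for the controlled-pain cohort.
#: Blank (merged) cells carry the last stated value forward within a band
#: bracket; unemployment/early retirement are zeroed at and above state
#: pension age 65 (the structural rule); the 50-54 values are carried back
#: to 45-49 to support onset-at-45 scenarios (no band is published below 50).
_PARTICIPATION_ROWS = [
    # age_lower, age_upper, employment, unemployment, lt_sickness, early_ret, disability
    (45, 49, 0.718, 0.028, 0.031, 0.017, 0.039),
    (50, 54, 0.718, 0.028, 0.031, 0.017, 0.039),
    (55, 59, 0.718, 0.028, 0.043, 0.017, 0.039),
    (60, 64, 0.718, 0.028, 0.059, 0.017, 0.039),
    (65, 69, 0.107, 0.0, 0.061, 0.0, 0.369),
    (70, 74, 0.015, 0.0, 0.0, 0.0, 0.0),
    (75, 100, 0.0, 0.0, 0.0, 0.0, 0.0),
]

#: Published per-drug utilisation and annual costs (reference only; the
#: model uses the published aggregate annual drug cost).
DRUG_UTILISATION = pd.DataFrame(
    {
        "drug": ["non_opioid", "opioid", "adjuvant_analgesic"],
        "annual_share_patients": [0.8674, 0.9621, 0.5833],
        "annual_cost_gbp": [64.0, 125.0, 13.0],
    }
)


def uk_participation() -> BaselineParticipation:
    return BaselineParticipation(
        pd.DataFrame(
            _PARTICIPATION_ROWS,
            columns=[
                "age_lower",
                "age_upper",
                "employment",
                "unemployment",
                "lt_sickness",
                "early_retirement",
                "disability",
            ],
        )
    )


def uk_reference_inputs(
    seed: int = 0, config: ModelConfig | None = None
) -> ModelInputs:
    """Runnable UK input bundle (published tariffs, synthetic lifetable/CIs)."""
    logger.warning(
        "FIXTURE uk_reference_inputs is non-calibrated: lifetable and most "
        "effect CIs are synthetic stand-ins"
    )
    config = config or ModelConfig(seed=seed)
    spec = SyntheticSpec(seed=seed)
    table = uk_participation()
    effects = {}
    for strength in ("moderate-like", "severe-like"):
        eff = make_effect_set(
            SyntheticSpec(**{**spec.__dict__, "effect_strength": strength})
        )
        effects[eff.severity] = eff
    return ModelInputs(
        participation={"female": table, "male": table.copy()},
        lifetable=make_lifetable(spec),
        effects=effects,
        schedule=FiscalSchedule(),
        healthcare=HealthcareCostTable(),
        mortality=MortalityAdjustment(),
        config=config,
    )


def published_base_case() -> pd.DataFrame:
    """Published disaggregated base-case results (GBP; life-years unitless).

    Columns: controlled, moderate, incremental_moderate, severe,
    incremental_severe.  Incremental = controlled - uncontrolled throughout
    (transfer rows therefore print negative).
    """
    rows = {
        "Earnings": (208968, 139586, 69383, 82584, 126384),
        "Gross Tax Revenue": (82172, 57865, 24307, 37247, 44925),
        "Job-Seeking Allowance": (1002, 1592, -589, 1335, -332),
        "Employment and Support Allowance": (2001, 4280, -2279, 5476, -3475),
        "Personal Independence Payment": (6933, 14005, -7072, 18657, -11724),
        "Early Retirement Pension": (5727, 9786, -4059, 12973, -7246),
        "Basic State Pension + Attendance Allowance": (0, 0, 0, 0, 0),
        "Health-care costs": (10390, 12424, -2034, 13441, -3051),
        "Total Transfers": (26053, 42087, -16034, 51882, -25829),
        "Net Tax": (56119, 15778, 40341, -14634, 70754),
        "Life-Years": (11.101, 11.101, 0.0, 11.101, 0.0),
    }
    return pd.DataFrame(
        rows,
        index=[
            "controlled",
            "moderate",
            "incremental_moderate",
            "severe",
            "incremental_severe",
        ],
    ).T
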