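"""Cohort Markov engine over the fiscal state space.

Eight states: EMPLOYED, UNEMPLOYED, LT_SICK, DISABLED, EARLY_RETIRED,
RETIRED, UNKNOWN and DEAD, with annual cycles.  Structural rules:

* DEAD is absorbing; death is applied first, structural transitions are
  conditional on survival.
* UNEMPLOYED and LT_SICK are 1-cycle tunnel states: self-transitions are
  forbidden and exit mass competes over the remaining destinations using the
  age-specific baseline probabilities renormalised over what is permitted.
* DISABLED and EARLY_RETIRED permit no return to employment.
* UNKNOWN (tax-neutral residual) routes to EMPLOYED the following cycle.
* At or after state pension age no mass may enter UNEMPLOYED or
  EARLY_RETIRED; EARLY_RETIRED occupants and the residual convert to
  RETIRED.  Above the maximum working age no mass may enter EMPLOYED.
* DISABLED occupants stay DISABLED after state pension age (they keep the
  disabled flag for the attendance-allowance rule) and are paid
  pension-style benefits by the accounting layer.

No half-cycle correction is applied; occupancy is evaluated at cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .parameters import OUTCOMES, ModelConfig


class FiscalState(IntEnum):
    EMPLOYED = 0
    UNEMPLOYED = 1
    LT_SICK = 2
    DISABLED = 3
    EARLY_RETIRED = 4
    RETIRED = 5
    UNKNOWN = 6
    DEAD = 7


N_STATES = len(FiscalState)
TUNNEL_STATES = (FiscalState.UNEMPLOYED, FiscalState.LT_SICK)
LIVING_STATES = tuple(s for s in FiscalState if s != FiscalState.DEAD)

#: Column order of outcome probabilities as used throughout this module.
_OUTCOME_STATE = {
    "employment": FiscalState.EMPLOYED,
    "unemployment": FiscalState.UNEMPLOYED,
    "lt_sickness": FiscalState.LT_SICK,
    "early_retirement": FiscalState.EARLY_RETIRED,
    "disability": FiscalState.DISABLED,
}


class InvariantViolation(RuntimeError):
    """A transition matrix or trace failed a structural invariant."""


def _structural_pool(
    probs: dict[str, float], age: int, config: ModelConfig
) -> tuple[np.ndarray, float, FiscalState]:
    """Outcome destination probabilities after age rules, plus residual."""
    p = {k: float(probs[k]) for k in OUTCOMES}
    if age >= config.state_pension_age:
        p["unemployment"] = 0.0
        p["early_retirement"] = 0.0
    if age > config.max_working_age:
        p["employment"] = 0.0
    vec = np.zeros(N_STATES)
    for outcome, state in _OUTCOME_STATE.items():
        vec[state] = p[outcome]
    residual = 1.0 - vec.sum()
    if residual < -1e-9:
        raise InvariantViolation(
            f"outcome probabilities sum to {vec.sum():.6f} > 1 at age {age}"
        )
    residual = max(residual, 0.0)
    if age >= config.state_pension_age:
        residual_dest = FiscalState.RETIRED
    elif config.residual_to_employment:
        residual_dest = FiscalState.EMPLOYED
    else:
        residual_dest = FiscalState.UNKNOWN
    return vec, residual, residual_dest


def build_transition_matrix(
    age: int,
    probs: dict[str, float],
    death_prob: float,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """One-cycle transition matrix at attained age ``age``.

    ``probs`` maps the five outcome names to this age's probabilities for
    the arm being modelled; ``death_prob`` is the arm's annual death
    probability at this age.  Death applies from every living state first;
    conditional on survival, destinations follow the structural rules in the
    module docstring.
    """
    config = config or ModelConfig()
    if not 0.0 <= death_prob <= 1.0:
        raise InvariantViolation(f"death probability {death_prob!r} outside [0, 1]")
    vec, residual, residual_dest = _structural_pool(probs, age, config)
    survive = 1.0 - death_prob

    def active_row() -> np.ndarray:
        row = vec.copy()
        row[residual_dest] += residual
        return row

    rows = np.zeros((N_STATES, N_STATES))

    rows[FiscalState.EMPLOYED] = active_row()

    for tunnel in TUNNEL_STATES:
        pool = vec.copy()
        stay = pool[tunnel]
        pool[tunnel] = 0.0
        res = residual
        if stay < 1.0 - 1e-12:
            pool = pool / (1.0 - stay)
            res = residual / (1.0 - stay)
        else:
            pool[:] = 0.0
            res = 1.0
        row = pool
        row[residual_dest] += res
        rows[tunnel] = row

    rows[FiscalState.DISABLED, FiscalState.DISABLED] = 1.0

    if age >= config.state_pension_age:
        rows[FiscalState.EARLY_RETIRED, FiscalState.RETIRED] = 1.0
    else:
        rows[FiscalState.EARLY_RETIRED, FiscalState.EARLY_RETIRED] = 1.0

    rows[FiscalState.RETIRED, FiscalState.RETIRED] = 1.0

    if age > config.max_working_age:
        rows[FiscalState.UNKNOWN, FiscalState.RETIRED] = 1.0
    else:
        rows[FiscalState.UNKNOWN, FiscalState.EMPLOYED] = 1.0

    matrix = survive * rows
    matrix[:, FiscalState.DEAD] += death_prob
    matrix[FiscalState.DEAD] = 0.0
    matrix[FiscalState.DEAD, FiscalState.DEAD] = 1.0

    validate_transition_matrix(matrix, age, config)
    return matrix


def validate_transition_matrix(
    matrix: np.ndarray, age: int | None = None, config: ModelConfig | None = None
) -> None:
    if matrix.shape != (N_STATES, N_STATES):
        raise InvariantViolation(f"matrix shape {matrix.shape} != ({N_STATES}, {N_STATES})")
    if (matrix < -1e-12).any() or (matrix > 1.0 + 1e-12).any():
        raise InvariantViolation("matrix entries outside [0, 1]")
    sums = matrix.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-10):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise InvariantViolation(
            f"row {FiscalState(bad).name} sums to {sums[bad]!r}, expected 1"
        )
    dead = np.zeros(N_STATES)
    dead[FiscalState.DEAD] = 1.0
    if not np.allclose(matrix[FiscalState.DEAD], dead, atol=0):
        raise InvariantViolation("DEAD row must be the unit vector on DEAD")
    if config is not None and age is not None:
        if age >= config.state_pension_age:
            if matrix[:, FiscalState.UNEMPLOYED].any() or matrix[
                :, FiscalState.EARLY_RETIRED
            ].any():
                raise InvariantViolation(
                    f"transition into UNEMPLOYED/EARLY_RETIRED at age {age} >= SPA"
                )
        if age > config.max_working_age and matrix[:, FiscalState.EMPLOYED].any():
            raise InvariantViolation(
                f"transition into EMPLOYED at age {age} > maximum working age"
            )


def build_transition_matrices(
    ages: np.ndarray,
    probs: np.ndarray,
    death: np.ndarray,
    config: ModelConfig,
) -> np.ndarray:
    """Vectorised equivalent of :func:`build_transition_matrix` over cycles.

    ``probs`` has shape ``(T, 5)`` with columns in ``OUTCOMES`` order,
    ``ages`` and ``death`` shape ``(T,)``.  Produces bit-identical matrices
    to the scalar builder (property-tested) without per-cycle Python
    overhead; used by the probabilistic sensitivity analysis.
    """
    ages = np.asarray(ages)
    probs = np.asarray(probs, dtype=float)
    death = np.asarray(death, dtype=float)
    T = len(ages)
    E, U, L, D, ER, R, UNK, DEAD = (
        FiscalState.EMPLOYED,
        FiscalState.UNEMPLOYED,
        FiscalState.LT_SICK,
        FiscalState.DISABLED,
        FiscalState.EARLY_RETIRED,
        FiscalState.RETIRED,
        FiscalState.UNKNOWN,
        FiscalState.DEAD,
    )
    spa_mask = ages >= config.state_pension_age
    mwa_mask = ages > config.max_working_age
    pe = np.where(mwa_mask, 0.0, probs[:, 0])
    pu = np.where(spa_mask, 0.0, probs[:, 1])
    pl = probs[:, 2]
    per = np.where(spa_mask, 0.0, probs[:, 3])
    pd_ = probs[:, 4]
    total = pe + pu + pl + per + pd_
    if (total > 1.0 + 1e-9).any():
        t = int(np.argmax(total))
        raise InvariantViolation(
            f"outcome probabilities sum to {total[t]:.6f} > 1 at age {int(ages[t])}"
        )
    resid = np.clip(1.0 - total, 0.0, None)
    pre_dest = FiscalState.EMPLOYED if config.residual_to_employment else FiscalState.UNKNOWN
    resid_dest = np.where(spa_mask, int(R), int(pre_dest))

    dest = np.zeros((T, N_STATES))
    dest[:, E] = pe
    dest[:, U] = pu
    dest[:, L] = pl
    dest[:, D] = pd_
    dest[:, ER] = per

    idx = np.arange(T)
    rows = np.zeros((T, N_STATES, N_STATES))

    row_e = dest.copy()
    row_e[idx, resid_dest] += resid
    rows[:, E] = row_e

    for tunnel, stay in ((U, pu), (L, pl)):
        open_ = stay < 1.0 - 1e-12
        factor = np.where(open_, 1.0 / np.where(open_, 1.0 - stay, 1.0), 0.0)
        pool = dest.copy()
        pool[:, tunnel] = 0.0
        pool *= factor[:, None]
        res = np.where(open_, resid * factor, 1.0)
        pool[idx, resid_dest] += res
        rows[:, tunnel] = pool

    rows[:, D, D] = 1.0
    rows[:, ER, ER] = np.where(spa_mask, 0.0, 1.0)
    rows[:, ER, R] = np.where(spa_mask, 1.0, 0.0)
    rows[:, R, R] = 1.0
    rows[:, UNK, E] = np.where(mwa_mask, 0.0, 1.0)
    rows[:, UNK, R] = np.where(mwa_mask, 1.0, 0.0)

    matrices = rows * (1.0 - death)[:, None, None]
    matrices[:, :, DEAD] += death[:, None]
    matrices[:, DEAD, :] = 0.0
    matrices[:, DEAD, DEAD] = 1.0
    return matrices


@dataclass
class CohortTrace:
    """Per-cycle occupancy of the fiscal states for one arm and sex."""

    occupancy: np.ndarray  # (T+1, N_STATES)
    ages: np.ndarray  # (T+1,)
    arm: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise InvariantViolation(f"occupancy shape {occ.shape} invalid")
        if (occ < -1e-10).any():
            raise InvariantViolation("negative occupancy")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise InvariantViolation("occupancies must sum to 1 each cycle")
        dead = occ[:, FiscalState.DEAD]
        if (np.diff(dead) < -1e-12).any():
            raise InvariantViolation("DEAD occupancy must be non-decreasing")
        self.occupancy = occ
        self.ages = np.asarray(self.ages)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def living(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, FiscalState.DEAD]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format trace (cycle, age, state, occupancy, arm, sex)."""
        records = []
        for t in range(self.occupancy.shape[0]):
            for s in FiscalState:
                records.append(
                    {
                        "cycle": t,
                        "age": int(self.ages[t]),
                        "state": s.name,
                        "occupancy": self.occupancy[t, s],
                        "arm": self.arm,
                        "sex": self.sex,
                    }
                )
        return pd.DataFrame.from_records(records)


def initial_occupancy(probs: dict[str, float]) -> np.ndarray:
    """Cycle-0 occupancy vector echoing the participation probabilities."""
    vec = np.zeros(N_STATES)
    for outcome, state in _OUTCOME_STATE.items():
        vec[state] = float(probs[outcome])
    total = vec.sum()
    if total > 1.0 + 1e-9:
        raise InvariantViolation(f"initial probabilities sum to {total:.6f} > 1")
    vec[FiscalState.UNKNOWN] = max(1.0 - total, 0.0)
    return vec


def run_cohort(
    initial: np.ndarray,
    matrices: np.ndarray,
    start_age: int,
    arm: str = "",
    sex: str = "",
) -> CohortTrace:
    """Propagate an initial occupancy through per-cycle transition matrices."""
    initial = np.asarray(initial, dtype=float)
    matrices = np.asarray(matrices, dtype=float)
    if initial.shape != (N_STATES,):
        raise InvariantViolation(f"initial vector shape {initial.shape} invalid")
    if matrices.ndim != 3 or matrices.shape[1:] != (N_STATES, N_STATES):
        raise InvariantViolation(f"matrices shape {matrices.shape} invalid")
    if abs(initial.sum() - 1.0) > 1e-9:
        raise InvariantViolation("initial occupancy must sum to 1")
    T = matrices.shape[0]
    occ = np.empty((T + 1, N_STATES))
    occ[0] = initial
    for t in range(T):
        occ[t + 1] = occ[t] @ matrices[t]
    ages = start_age + np.arange(T + 1)
    return CohortTrace(occ, ages, arm=arm, sex=sex)


def life_years(trace: CohortTrace, discount_rate: float = 0.0) -> float:
    """Discounted life-years: living occupancy at cycle start, 1-year cycles.

    Cycle ``t`` (t = 0 undiscounted) contributes ``living(t) / (1+r)^t`` for
    t in 0..T-1.
    """
    if discount_rate <= -1.0:
        raise ValueError("discount rate must exceed -1")
    living = trace.living()[: trace.n_cycles]
    t = np.arange(trace.n_cycles)
    return float(np.sum(living / (1.0 + discount_rate) ** t))
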