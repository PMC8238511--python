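"""Elementary rate/probability and effect-measure conversions.

These are the two closed-form identities the rest of the model relies on:
converting a probability observed over one period to the probability over a
model cycle (constant-hazard assumption), and converting an odds ratio to a
relative risk at a given baseline risk so that it can be applied
multiplicatively to a transition probability.
"""

from __future__ import annotations

import math

__all__ = [
    "rate_to_probability",
    "probability_to_rate",
    "odds_ratio_to_relative_risk",
]


def rate_to_probability(p_i: float, t_i: float = 1.0, t: float = 1.0) -> float:
    """Convert a probability over period ``t_i`` to one over period ``t``.

    Assumes a constant hazard within the period: the survival fraction
    ``1 - p_i`` over ``t_i`` years is rescaled to ``t`` years, giving

        p = 1 - exp(ln(1 - p_i) / t_i * t)

    Parameters
    ----------
    p_i : probability of the event over the index period, in [0, 1).
    t_i : index period length in years, > 0.
    t : target cycle length in years, > 0.
    """
    if not 0.0 <= p_i < 1.0:
        raise ValueError(f"p_i must be in [0, 1), got p_i={p_i!r}")
    if t_i <= 0.0:
        raise ValueError(f"t_i must be positive, got t_i={t_i!r}")
    if t <= 0.0:
        raise ValueError(f"t must be positive, got t={t!r}")
    return 1.0 - math.exp(math.log(1.0 - p_i) / t_i * t)


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: instantaneous rate over ``t`` years."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got p={p!r}")
    if t <= 0.0:
        raise ValueError(f"t must be positive, got t={t!r}")
    return -math.log(1.0 - p) / t


def odds_ratio_to_relative_risk(odds_ratio: float, p0: float) -> float:
    """Convert an odds ratio to a relative risk at baseline risk ``p0``.

    Uses the standard identity

        RR = OR / (1 - p0 + p0 * OR)

    where ``p0`` is the outcome probability in the unexposed group.  The
    result equals OR when the outcome is rare (p0 -> 0) and shrinks toward 1
    as p0 grows, so the RR always lies between 1 and the OR.
    """
    if odds_ratio <= 0.0:
        raise ValueError(f"odds_ratio must be positive, got {odds_ratio!r}")
    if not 0.0 <= p0 < 1.0:
        raise ValueError(f"p0 must be in [0, 1), got p0={p0!r}")
    return odds_ratio / (1.0 - p0 + p0 * odds_ratio)
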