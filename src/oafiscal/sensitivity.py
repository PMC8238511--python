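"""Deterministic and probabilistic sensitivity analysis and scenario runs.

* One-way sensitivity analysis (OSA): re-run the full model at the lower and
  upper 95 % CI bound of each relative-effect / hazard-ratio parameter and
  report the resulting incremental net tax swing (tornado ordering).
* Probabilistic sensitivity analysis (PSA): fit standard distributions to
  the uncertain parameters (log-normal for ratio measures, beta for
  probabilities, gamma for costs), draw jointly-independent samples, re-run
  the model per draw and summarise the INT distribution with its mean and
  2.5/97.5 percentile credible interval.
* Scenario runner: declarative overrides of the run configuration
  (time horizon, pension age, onset age, health-care uplifts, differential
  mortality) with percent changes against a named reference run.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .fiscal import cash_flow_matrix, annual_healthcare_cost
from .markov import (
    N_STATES,
    build_transition_matrices,
    initial_occupancy,
)
from .model import ComparisonResult, ModelInputs, run_comparison
from .parameters import (
    ConfigurationError,
    ModelConfig,
    OUTCOMES,
    RelativeEffect,
)

logger = logging.getLogger("oafiscal")

Z95 = 1.959964  # two-sided 95 % normal quantile


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertainParameter:
    """One model input carrying a 95 % CI, addressable by id."""

    parameter_id: str
    point: float
    ci_low: float
    ci_high: float
    value_type: str  # "ratio" | "probability" | "cost"
    apply: Callable[[ModelInputs, float], ModelInputs]


def uncertain_parameters(
    inputs: ModelInputs, severity: str
) -> list[UncertainParameter]:
    """All CI-carrying parameters entering the OSA/PSA for one comparison."""
    params: list[UncertainParameter] = []
    for effect in inputs.effects[severity].effects:
        pid = f"{severity}:{effect.parameter_id}"

        def apply_effect(
            ins: ModelInputs, value: float, _pid=effect.parameter_id, _sev=severity
        ) -> ModelInputs:
            return ins.with_effects(
                _sev, ins.effects[_sev].replace_effect(_pid, value)
            )

        params.append(
            UncertainParameter(
                pid, effect.point, effect.ci_low, effect.ci_high, "ratio", apply_effect
            )
        )

    def apply_oa_hr(ins: ModelInputs, value: float) -> ModelInputs:
        return replace(ins, mortality=replace(ins.mortality, oa_excess_hr=value))

    m = inputs.mortality
    params.append(
        UncertainParameter(
            "oa_excess_hr", m.oa_excess_hr, *m.oa_excess_ci, "ratio", apply_oa_hr
        )
    )
    if inputs.config.differential_mortality:

        def apply_womac_hr(ins: ModelInputs, value: float) -> ModelInputs:
            return replace(
                ins, mortality=replace(ins.mortality, womac_hr_per_10=value)
            )

        params.append(
            UncertainParameter(
                "womac_hr_per_10",
                m.womac_hr_per_10,
                *m.womac_hr_ci,
                "ratio",
                apply_womac_hr,
            )
        )
    return params


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    low_bound_int: float
    high_bound_int: float
    base_int: float

    @property
    def swing(self) -> float:
        return abs(self.high_bound_int - self.low_bound_int)


def one_way(
    inputs: ModelInputs,
    severity: str,
    targets: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """Tornado table: INT at each parameter's CI bounds, widest swing first.

    Baseline participation probabilities and fiscal tariffs are not subject
    to this analysis (they are national statistics / statutory tariffs, not
    the model's sources of uncertainty).
    """
    params = {p.parameter_id: p for p in uncertain_parameters(inputs, severity)}
    if targets is None:
        selected = list(params.values())
    else:
        selected = []
        for t in targets:
            if t not in params:
                logger.warning("OSA target %r has no CI-carrying parameter; skipped", t)
                continue
            selected.append(params[t])
    base_int = run_comparison(inputs, severity).int_value
    entries = []
    for p in selected:
        low_int = run_comparison(p.apply(inputs, p.ci_low), severity).int_value
        high_int = run_comparison(p.apply(inputs, p.ci_high), severity).int_value
        entry = TornadoEntry(p.parameter_id, low_int, high_int, base_int)
        if not (
            min(low_int, high_int) - 1e-6 <= base_int <= max(low_int, high_int) + 1e-6
        ):
            logger.warning(
                "OSA parameter %s: base INT %.2f outside bound interval "
                "[%.2f, %.2f] (non-monotone response)",
                p.parameter_id,
                base_int,
                min(low_int, high_int),
                max(low_int, high_int),
            )
        entries.append(entry)
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------


class Sampler:
    """Reproducible sampler for one uncertain parameter."""

    def __init__(self, name: str, kind: str, point: float, dist=None):
        self.name = name
        self.kind = kind
        self.point = point
        self.dist = dist

    @property
    def mean(self) -> float:
        return self.point if self.dist is None else float(self.dist.mean())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist is None:
            return np.full(n, self.point)
        return self.dist.rvs(size=n, random_state=rng)


def fit_distribution(
    point: float,
    ci_low: float,
    ci_high: float,
    kind: str = "auto",
    value_type: str = "ratio",
    name: str = "",
) -> Sampler:
    """Fit a standard sampling distribution to a point estimate and 95 % CI.

    ``auto`` maps ratio measures (OR/RR/HR) to a log-normal with log-point
    as the log-scale location and ``ln(hi/lo)/3.92`` as the log-SD,
    probabilities to a beta matched to the point (mean) and the CI-implied
    SD ``(hi-lo)/3.92``, and costs to a gamma matched the same way.  A
    degenerate CI returns a point-mass sampler.  The fitted mean is checked
    against the point estimate; for log-normal fits (median = point) a
    deviation beyond 2 % is reported as a warning rather than an error.
    """
    if not ci_low <= point <= ci_high:
        raise ConfigurationError(
            f"{name or 'parameter'}: need ci_low <= point <= ci_high, "
            f"got ({ci_low}, {point}, {ci_high})"
        )
    if kind == "auto":
        kind = {"ratio": "lognormal", "probability": "beta", "cost": "gamma"}[
            value_type
        ]
    if ci_low == ci_high:
        return Sampler(name, "degenerate", point)

    sd = (ci_high - ci_low) / (2.0 * Z95)
    var = sd * sd

    if kind == "lognormal":
        if ci_low <= 0:
            raise ConfigurationError(
                f"{name or 'parameter'}: log-normal fit needs positive bounds"
            )
        sigma = float(np.log(ci_high / ci_low)) / (2.0 * Z95)
        dist = stats.lognorm(s=sigma, scale=point)
        sampler = Sampler(name, kind, point, dist)
        if abs(sampler.mean / point - 1.0) > 0.02:
            logger.warning(
                "FIT %s: log-normal mean %.4f deviates >2%% from point %.4f "
                "(median matches the point)",
                name or "parameter",
                sampler.mean,
                point,
            )
        return sampler
    if kind == "beta":
        if not (0.0 <= ci_low and ci_high <= 1.0 and 0.0 < point < 1.0):
            raise ConfigurationError(
                f"{name or 'parameter'}: beta fit needs point/CI within (0, 1)"
            )
        nu = point * (1.0 - point) / var - 1.0
        if nu <= 0:
            raise ConfigurationError(
                f"{name or 'parameter'}: CI too wide for a beta at mean {point}"
            )
        dist = stats.beta(point * nu, (1.0 - point) * nu)
        return Sampler(name, kind, point, dist)
    if kind == "gamma":
        if ci_low < 0 or point <= 0:
            raise ConfigurationError(
                f"{name or 'parameter'}: gamma fit needs non-negative bounds "
                "and a positive point"
            )
        shape = point * point / var
        dist = stats.gamma(shape, scale=var / point)
        return Sampler(name, kind, point, dist)
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaResult:
    n_samples: int
    mean_int: float
    ci_low: float
    ci_high: float
    seed: int
    rejections: int = 0
    draws: np.ndarray | None = None


def _parameter_rng(seed: int, parameter_id: str) -> np.random.Generator:
    # independent substream per parameter: adding a parameter never perturbs
    # the draws of the others
    salt = zlib.crc32(parameter_id.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


class _FastComparison:
    """Cached vectorised evaluator of one severity comparison.

    Pre-expands per-age baseline probabilities, lifetable rates and cash-flow
    matrices so that one PSA draw costs a handful of small numpy operations.
    Exact equality with the reference pipeline is covered by tests.
    """

    def __init__(self, inputs: ModelInputs, severity: str):
        self.inputs = inputs
        self.severity = severity
        cfg = inputs.config
        self.T = cfg.effective_horizon
        self.ages = np.arange(cfg.start_age, cfg.start_age + self.T)
        self.config = cfg
        self.base_probs = {
            sex: inputs.participation[sex].as_age_array(
                cfg.start_age, cfg.start_age + self.T - 1
            )
            for sex in ("female", "male")
        }
        self.rates = {
            sex: inputs.lifetable.rates(
                sex, cfg.start_age, cfg.start_age + self.T - 1
            )
            for sex in ("female", "male")
        }
        self.flows = {
            arm: cash_flow_matrix(
                self.ages,
                inputs.schedule,
                cfg,
                annual_healthcare_cost(arm, inputs.healthcare, cfg),
            )
            for arm in ("controlled", severity)
        }
        self.disc = (1.0 + cfg.discount_rate) ** -np.arange(self.T)
        self.weights = {"female": cfg.female_share, "male": 1.0 - cfg.female_share}
        # resolve which effect governs each (outcome, age), honouring
        # age-specific effects over generic ones
        effect_set = inputs.effects[severity]
        self.effect_spans: list[tuple[int, "RelativeEffect", str, np.ndarray]] = []
        for j, outcome in enumerate(OUTCOMES):
            resolved = [effect_set.effect_for(outcome, int(a)) for a in self.ages]
            for effect in {id(e): e for e in resolved if e is not None}.values():
                mask = np.array([r is effect for r in resolved])
                pid = f"{severity}:{effect.parameter_id}"
                self.effect_spans.append((j, effect, pid, mask))

    # -- pieces -----------------------------------------------------------

    def _death(self, sex: str, hr: float) -> np.ndarray:
        return np.clip(self.rates[sex] * hr, 0.0, 1.0)

    def _adjusted_probs(
        self, sex: str, values: dict[str, float]
    ) -> tuple[np.ndarray, bool]:
        """Apply (possibly sampled) effect values; returns (probs, was_invalid)."""
        probs = self.base_probs[sex].copy()
        invalid = False
        for j, effect, pid, mask in self.effect_spans:
            value = values.get(pid, effect.point)
            p0 = probs[mask, j]
            if effect.measure == "odds_ratio":
                conv = {
                    "always": np.ones_like(p0, dtype=bool),
                    "never": np.zeros_like(p0, dtype=bool),
                    "threshold": p0 >= self.config.or_rare_threshold,
                }[self.config.or_conversion]
                rr = np.where(conv, value / (1.0 - p0 + p0 * value), value)
            else:
                rr = value
            new = p0 * rr
            if (new > 1.0 + 1e-12).any():
                invalid = True
            probs[mask, j] = np.clip(new, 0.0, 1.0)
        # same band-sum rule as the deterministic pipeline: absorb into the
        # unknown residual, then scale the non-employment outcomes
        total = probs.sum(axis=1)
        over = total > 1.0 + 1e-12
        if over.any():
            emp = probs[:, 0]
            others = total - emp
            if (others[over] <= 0.0).any():
                invalid = True
            else:
                scale = np.where(over, (1.0 - emp) / np.where(over, others, 1.0), 1.0)
                probs[:, 1:] *= scale[:, None]
        return probs, invalid

    def _npv_net_tax(self, probs: np.ndarray, death: np.ndarray, arm: str) -> float:
        matrices = build_transition_matrices(self.ages, probs, death, self.config)
        occ = np.empty((self.T, N_STATES))
        occ[0] = initial_occupancy(dict(zip(OUTCOMES, probs[0])))
        for t in range(self.T - 1):
            occ[t + 1] = occ[t] @ matrices[t]
        flows = self.flows[arm]
        comp = np.einsum("t,ts,tsc->c", self.disc, occ, flows)
        gross_tax = comp[1]
        transfers = comp[2:8].sum()
        return float(gross_tax - transfers)

    # -- public -----------------------------------------------------------

    def int_value(self, values: dict[str, float] | None = None) -> float:
        """Evaluate INT for one joint parameter draw (id -> value).

        Raises :class:`_InvalidDraw` if the drawn effects push any
        probability outside [0, 1] or a band sum above 1.
        """
        values = values or {}
        hr = values.get("oa_excess_hr", self.inputs.mortality.oa_excess_hr)
        womac_factor = 1.0
        if self.config.differential_mortality:
            whr = values.get(
                "womac_hr_per_10", self.inputs.mortality.womac_hr_per_10
            )
            womac_factor = whr ** (self.inputs.mortality.womac_delta / 10.0)
        total = 0.0
        for sex, w in self.weights.items():
            probs_u, invalid = self._adjusted_probs(sex, values)
            if invalid:
                raise _InvalidDraw
            death_c = self._death(sex, hr)
            controlled = self._npv_net_tax(self.base_probs[sex], death_c, "controlled")
            death_u = self._death(sex, hr * womac_factor)
            uncontrolled = self._npv_net_tax(probs_u, death_u, self.severity)
            total += w * (controlled - uncontrolled)
        return total


class _InvalidDraw(Exception):
    pass


def psa(
    inputs: ModelInputs,
    severity: str,
    n: int = 10_000,
    seed: int = 0,
    retain_draws: bool = False,
    max_rejection_fraction: float = 0.10,
) -> PsaResult:
    """Probabilistic sensitivity analysis of the INT for one comparison.

    Fits distributions to every CI-carrying parameter, draws ``n`` joint
    samples (independently across parameters, each from its own seeded
    substream), evaluates the full model per draw and summarises the INT
    distribution.  Draws producing invalid probabilities are rejected and
    resampled; more than ``max_rejection_fraction`` rejections is an error.
    """
    if n < 2:
        raise ConfigurationError("PSA needs at least 2 samples")
    params = uncertain_parameters(inputs, severity)
    samplers = {
        p.parameter_id: fit_distribution(
            p.point, p.ci_low, p.ci_high, value_type=p.value_type, name=p.parameter_id
        )
        for p in params
    }
    rngs = {pid: _parameter_rng(seed, pid) for pid in samplers}
    engine = _FastComparison(inputs, severity)

    draws = {pid: s.sample(rngs[pid], n) for pid, s in samplers.items()}
    rejections = 0
    ints = np.empty(n)
    for i in range(n):
        values = {pid: float(draws[pid][i]) for pid in draws}
        while True:
            try:
                ints[i] = engine.int_value(values)
                break
            except _InvalidDraw:
                rejections += 1
                if rejections > max_rejection_fraction * (n + rejections):
                    raise ConfigurationError(
                        f"PSA rejected {rejections} draws (> "
                        f"{max_rejection_fraction:.0%} of total); distributions "
                        "are inconsistent with valid probabilities"
                    ) from None
                values = {
                    pid: float(samplers[pid].sample(rngs[pid], 1)[0])
                    for pid in draws
                }
    if rejections:
        logger.warning("PSA resampled %d invalid draws", rejections)
    lo, med, hi = np.percentile(ints, [2.5, 50.0, 97.5])
    if not lo <= med <= hi:
        raise RuntimeError("percentile ordering violated")
    return PsaResult(
        n_samples=n,
        mean_int=float(ints.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        rejections=rejections,
        draws=ints if retain_draws else None,
    )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Named set of configuration overrides.

    Override keys are ModelConfig field names, plus ``womac_delta`` which
    routes to the mortality adjustment (pain-score gap between arms, WOMAC
    points, used with ``differential_mortality``).
    """

    name: str
    overrides: dict


@dataclass
class ScenarioResult:
    name: str
    comparisons: dict[str, ComparisonResult]
    reference_int: dict[str, float] | None = None

    @property
    def int_values(self) -> dict[str, float]:
        return {s: c.int_value for s, c in self.comparisons.items()}

    @property
    def pct_change(self) -> dict[str, float] | None:
        if self.reference_int is None:
            return None
        out = {}
        for s, v in self.int_values.items():
            ref = self.reference_int.get(s)
            out[s] = (
                float("nan") if not ref else (v - ref) / abs(ref) * 100.0
            )
        return out


def apply_overrides(inputs: ModelInputs, overrides: dict) -> ModelInputs:
    overrides = dict(overrides)
    womac_delta = overrides.pop("womac_delta", None)
    out = inputs.with_config(**overrides) if overrides else inputs
    if womac_delta is not None:
        out = replace(out, mortality=replace(out.mortality, womac_delta=womac_delta))
    return out


def run_scenario(
    spec: ScenarioSpec,
    inputs: ModelInputs,
    reference: ScenarioResult | None = None,
    severities: Sequence[str] = ("moderate", "severe"),
) -> ScenarioResult:
    """Apply overrides, re-run both severity comparisons, report % change."""
    modified = apply_overrides(inputs, spec.overrides)
    comparisons = {s: run_comparison(modified, s) for s in severities}
    ref_int = reference.int_values if reference is not None else None
    return ScenarioResult(spec.name, comparisons, ref_int)


def standard_scenarios() -> list[ScenarioSpec]:
    """The scenario set explored alongside the base case.

    Lifetime horizon; state pension age 67 on a lifetime horizon; health-care
    uplifts shifted by +-10 percentage points; differential pain-related
    mortality (20 WOMAC points between arms); onset at 45 with 20 years of
    work expectancy.
    """
    return [
        ScenarioSpec("base", {}),
        ScenarioSpec("lifetime", {"lifetime": True}),
        ScenarioSpec("spa67_lifetime", {"lifetime": True, "state_pension_age": 67}),
        ScenarioSpec(
            "uplift_minus10",
            {"healthcare_uplift_moderate": 0.10, "healthcare_uplift_severe": 0.20},
        ),
        ScenarioSpec(
            "uplift_plus10",
            {"healthcare_uplift_moderate": 0.30, "healthcare_uplift_severe": 0.40},
        ),
        ScenarioSpec(
            "excess_pain_mortality",
            {"differential_mortality": True, "womac_delta": 20.0},
        ),
        ScenarioSpec("onset45", {"start_age": 45, "horizon": 20}),
    ]
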