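# Methods

## The model

`oafiscal` is a deterministic cohort (Markov-chain) model with annual cycles
over eight fiscal states: EMPLOYED, UNEMPLOYED, LT_SICK (long-term sick),
DISABLED, EARLY_RETIRED, RETIRED, UNKNOWN (tax-neutral residual) and DEAD.
Two cohorts of 50-year-olds are compared: a controlled-pain arm with
general-population labour-market behaviour and an uncontrolled-pain arm
(moderate or severe) whose participation probabilities are multiplied by
relative effects. The result is the incremental net tax (INT): the
difference in discounted net tax (taxes minus transfers and health-care
costs) between the arms, positive when uncontrolled pain costs the
government.

### Transition structure

Each cycle, death is applied first from every living state using the arm's
annual death probability; structural transitions are conditional on
survival. Conditional on survival, destinations are distributed according to
the age-banded participation probabilities of the arm, with these rules:

- **Tunnel states.** UNEMPLOYED and LT_SICK are 1-cycle tunnels: the
  self-transition is forbidden and exit mass competes over the remaining
  destinations using the age-specific probabilities renormalised over what
  is permitted (dividing by 1 − p_self). In a cohort matrix this is the
  exact equivalent of a one-cycle entry clock: a pulse entering the state is
  fully redistributed the following cycle.
- **Absorbing inactivity.** DISABLED and EARLY_RETIRED permit no return to
  employment. At state pension age (SPA) EARLY_RETIRED occupants convert to
  RETIRED; DISABLED occupants remain DISABLED so the accounting layer can
  apply the post-SPA attendance-allowance rule to them.
- **Age rules.** No transitions into UNEMPLOYED or EARLY_RETIRED at or above
  SPA (default 65); no transitions into EMPLOYED above the maximum working
  age (default 70).
- **Residual.** Probability mass not claimed by the five outcomes goes to
  UNKNOWN before SPA (tax-neutral for one cycle, routed to EMPLOYED the next
  cycle — a config flag `residual_to_employment` can skip the detour) and to
  RETIRED at/after SPA.

No half-cycle correction is applied; occupancy is valued at cycle start.
Cycle 0 is undiscounted. These are the standard conventions for annual-cycle
cohort models and the source material specifies none.

An important structural consequence: the participation table's disability
and early-retirement values act as *per-cycle entry probabilities into
absorbing states*, so their occupancy accumulates over the horizon rather
than tracking the cross-sectional stock. This is the faithful reading of the
state rules, but it means per-state cost totals are larger than a
stock-matching model would produce; comparisons between arms (the INT) are
the model's meaningful output, not per-state levels.

### Probability machinery

- Period-to-cycle conversion: p = 1 − exp(ln(1 − p_i)/t_i · t). The annual
  lifetable value is fed through this with t_i = t = 1 after multiplying by
  the hazard ratio, i.e. adjusted p = min(HR · q, 1).
- Odds ratios are converted to relative risks, RR = OR/(1 − p₀ + p₀·OR),
  when the baseline probability is ≥ 0.10 (the "not rare" rule); below the
  threshold the OR is used directly. `or_conversion = always|never|threshold`
  overrides this.
- After applying effects, any probability above 1 is clipped with a logged
  warning; a band whose five probabilities sum above 1 first absorbs the
  excess from the unknown residual and then scales the four non-employment
  outcomes proportionally (employment is the anchor parameter), again with a
  logged warning.
- Mortality: both arms carry the excess-mortality hazard ratio (default
  1.11, 95 % CI 1.06–1.17). The differential-mortality scenario additionally
  multiplies the uncontrolled arm's hazard by HR_per10^(Δ/10) with HR_per10 =
  1.04 (1.01–1.07) per 10 pain-score points and Δ the configured score gap.

### Fiscal accounting

Per person-year (all amounts nominal GBP/year, no indexation; rounding to
whole pounds only at report time):

| state | tax | transfer |
|---|---|---|
| EMPLOYED | age-band labour tax (10 886 / 10 015 / 8 825 for 50–59/60–64/65+) + 13.7 % of disposable labour income | — |
| UNEMPLOYED (<SPA) | 13.7 % of benefit | jobseeker's allowance 3 866 |
| LT_SICK | 13.7 % of benefit | employment and support allowance 4 885 |
| DISABLED <SPA / ≥SPA | 13.7 % of benefit | PIP 6 102 / pension 9 110 + 50 % × attendance 3 258 |
| EARLY_RETIRED | 13.7 % of benefit | basic state pension 9 110 |
| RETIRED | 13.7 % of benefit | basic state pension 9 110 |
| UNKNOWN, DEAD | — | — |

Earnings are back-computed from the labour-tax amount and the 30.9 % tax
wedge (earnings = tax/0.309): tariff tables print the tax, results report
the earnings, and this is the only consistent bridge between them. Indirect
tax on benefit income is booked as tax revenue, not netted from transfers.
The full annualised ESA amount is applied to every LT_SICK person-year
(employer-borne statutory sick pay is excluded); this is a documented
choice where the source description is self-contradictory.

Health care: every living person-year costs the controlled-pain base
(aggregate drug cost 203 + appointments 713 + 70.82 % × 82 referral +
expected surgical-revision costs, probability × unit cost; ≈ £1 107/year),
uplifted by +20 % (moderate) or +30 % (severe). Primary surgery annual
probabilities are not published and default to 0 (configurable).

NPV components are discounted by (1+r)^−t with r = 0.035 and summed per arm;
INT = net-tax NPV (controlled) − net-tax NPV (uncontrolled). Sexes are run
separately (per-sex lifetable, optionally per-sex participation) and
weighted by the female share (0.586); the model is linear in the cohort mix.

## Sensitivity analysis

**One-way (OSA).** For each parameter carrying a 95 % CI (the relative
effects and the hazard ratios — baseline participation and statutory tariffs
are national statistics and not varied), the full model is re-run at the
lower and upper bound; entries are sorted by |INT(hi) − INT(lo)| for tornado
plotting. A base INT outside the bound interval (non-monotone response) is
reported as a warning, not an error.

**Probabilistic (PSA).** Distributions are fitted per parameter: ratios →
log-normal with the log-point as location and ln(hi/lo)/3.92 as log-SD;
probabilities → beta moment-matched to the point and the CI-implied SD
(hi − lo)/3.92; costs → gamma matched the same way. The log-normal's
*median* equals the point estimate; its analytic mean therefore exceeds the
point for wide CIs, and a deviation beyond 2 % is reported as a warning at
fit time (beta/gamma means match exactly). Parameters are sampled
independently — each from its own substream spawned from the master seed and
a CRC of the parameter id, so adding a parameter never perturbs the others'
draws. Draws pushing any single probability above 1 are rejected and
resampled (band-sum overflows are renormalised exactly as in the
deterministic pipeline); more than 10 % rejections aborts the analysis. The
default 10 000 evaluations use a cached vectorised engine that is
regression-tested to agree with the reference pipeline to 1 part in 10⁹;
results report the empirical mean and 2.5/97.5 percentile credible interval.

**Scenarios.** Declarative config overrides: lifetime horizon (to age 100,
by which >99 % of the cohort is dead), SPA 67 on a lifetime horizon,
health-care uplifts shifted ±10 *percentage points* (the reading consistent
with the published scenario arithmetic), differential pain mortality (score
gap Δ = 20 by default; the INT is insensitive to it), and onset at 45 with a
20-year work expectancy. Percent changes are reported against a named
reference run.

## Synthetic inputs and the packaged reference bundle

National lifetables and labour-force statistics are external data the
package deliberately does not ship. The generator (`oafiscal.synthetic`)
produces:

- a **Gompertz lifetable**, rate(a) = A·e^{B·a}, defaults A = 3.5e−5,
  B = 0.092, female rates × 0.6 — UK-like magnitudes (male q₅₀ ≈ 0.0035,
  doubling every ≈ 8 years);
- a **banded participation table**: employment ≈ 0.72 at 50–54 declining
  0.07/decade, collapsing after SPA; LT sickness/early retirement derived by
  multiplying single means (0.122, 0.067 of the inactive share) by the
  band's inactive fraction; disability as age-rising probability × 0.5
  inactivity prevalence, zero above 65. Employment is capped per band so the
  derived outcome sum stays below 1 under multiplicative noise;
- **effect sets** with the field's direction pattern (employment OR < 1,
  everything else > 1) at "moderate-like" and "severe-like" strengths, or an
  all-ones null set.

The packaged UK reference bundle (`oafiscal.datasets.uk_reference_inputs`)
combines the published participation values (blank table cells carry the
last stated value forward; unemployment/early retirement zeroed at ≥ SPA;
the 50–54 row carried back to 45–49 for onset-at-45 runs), the published
tax/benefit tariffs and health-care costs, the synthetic lifetable, and
effect sets whose employment points (OR 0.57 moderate / 0.28 severe, the
published 43 %/72 % odds reductions) and moderate upper bound (1.54) are
published while the remaining points and CIs are documented synthetic
choices. Those invented CIs are kept narrow enough that the employment odds
ratio remains the dominant sensitivity parameter, matching the published
one-way-analysis finding that no other parameter moves the result by more
than ~20 %. The bundle logs a "non-calibrated" warning on construction.

**What passing tests show — and don't.** The synthetic data reproduce the
*structure* of the real inputs (banded age profiles, Gompertz mortality,
direction-consistent effects), not their joint statistics: no cohort trends,
no sex-specific participation differences, no correlation between effects.
Green tests demonstrate the machinery is correct (mass conservation, oracle
equality, accounting identities, seed determinism), not that the packaged
bundle reproduces any published total — headline published figures are
checked as arithmetic identities on the published components themselves.

## Numerical choices

- Row sums and occupancy checked to 1e−10; the path-enumeration oracle to
  1e−10; NPV linearity to 1e−9.
- Transition rows with a tunnel share ≥ 1 − 1e−12 route everything to the
  residual destination (degenerate but valid).
- Probability clipping, band renormalisation, PSA rejections and
  non-calibrated fixture use all emit machine-parsable log warnings
  (`CLIP …`, `RENORM …`, `PSA …`, `FIXTURE …`); the CLI collects them into
  the run manifest.
- Reports embed only the deterministic manifest keys (config hash, version,
  seed) so identical config + seed give byte-identical report files; the
  timestamped manifest is written separately.

## Problem sizes

Defaults throughout are the study conditions: 15 annual cycles (50 on
lifetime runs), both sexes, both severities, PSA n = 10 000. The acceptance
script runs the full grid — base case, six scenarios, OSA bounds and two
10 000-draw PSAs — in tens of seconds on one CPU thanks to the vectorised
PSA engine.

## Known limitations

- Per-state occupancy accumulates in absorbing states (see above); levels
  are not comparable to stock-based statistics.
- Housing benefit, employer sick-pay costs, short-term absence, informal
  care and joint-replacement effects on participation are out of scope.
- Effects are sampled independently in the PSA; a user-supplied joint
  sampler can be substituted by overriding the parameter registry.
- The packaged bundle's lifetable and most effect CIs are synthetic; users
  with access to national lifetables and the source publications should
  supply them via the YAML bundle for calibrated results.
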