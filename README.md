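# oafiscal

Fiscal (public-economic) Markov cohort model of **controlled vs uncontrolled
osteoarthritis (OA) hip/knee pain** from a UK government perspective.

Health-technology assessment usually stops at health-sector costs. From a
government's point of view, chronic pain in working-age people has a much
larger fiscal footprint: lost income-tax and national-insurance revenue when
people stop working, plus transfer payments (jobseeker's allowance,
employment and support allowance, personal independence payment, early
pensions). `oafiscal` implements a generational-accounting comparison of two
cohorts of 50-year-olds — one whose OA pain is controlled (general-population
labour-market behaviour) and one with uncontrolled moderate or severe pain —
and prices every person-year of each labour-market state.

It is intended for health economists and modellers who want a tested,
scriptable implementation of this class of fiscal model: every input is a
validated type, every published tariff is packaged, and a synthetic-data
generator stands in for the national datasets so the whole pipeline runs
offline.

## Model

- **States**: employed, unemployed, long-term (LT) sick, disabled, early
  retired, retired, a tax-neutral "unknown" residual, dead. Annual cycles,
  cohort entry at age 50, 58.6 % female, base-case horizon 15 years
  (remaining work expectancy), discounting at *r* = 3.5 %/year.
- **Structure**: death first (lifetable rates × excess-mortality HR 1.11,
  converted by *p* = 1 − exp(ln(1 − p_i)/t_i · t)); conditional on survival,
  destinations follow age-banded participation probabilities. Unemployment
  and LT sickness are 1-cycle tunnel states; disability and early retirement
  permit no return to work; after state pension age (SPA, 65) nobody enters
  unemployment or early retirement and non-workers convert to the pensioned
  retired state; 70 is the maximum working age.
- **Uncontrolled arm**: published odds/risk ratios multiply the baseline
  probabilities (odds ratios converted to relative risks via
  RR = OR / (1 − p₀ + p₀·OR) when the outcome is not rare, p₀ ≥ 0.10).
- **Cash flows**: employment pays the age-band labour tax (30.9 % tax wedge;
  earnings back-computed as tax/0.309) plus 13.7 % indirect tax on disposable
  income; benefits generate 13.7 % indirect tax on gross benefit income;
  post-SPA disabled receive the pension plus half the attendance allowance;
  every living person-year incurs health-care costs (+20 %/+30 % for
  moderate/severe uncontrolled pain).
- **Headline statistic**: incremental net tax,
  **INT = NPV(net tax | controlled) − NPV(net tax | uncontrolled)**, where
  net tax = Σ_t (Tax_t − Cost_t)/(1+r)^t. Positive INT = uncontrolled pain
  costs the government.
- **Uncertainty**: one-way sensitivity analysis over CI bounds (tornado),
  10 000-draw probabilistic sensitivity analysis (log-normal for ratios,
  beta for probabilities, gamma for costs) with percentile credible
  intervals, and a declarative scenario runner (lifetime horizon, SPA 67,
  ±10-point health-care uplifts, differential pain mortality, onset at 45).

## Worked example

```python
from oafiscal import uk_reference_inputs, run_base_case

inputs = uk_reference_inputs(seed=1)      # published tariffs, synthetic lifetable
report, comparisons = run_base_case(inputs)
for severity, comp in comparisons.items():
    print(severity, f"INT = GBP {comp.int_value:,.0f}")
```

prints

```
moderate INT = GBP 36,489
severe INT = GBP 57,375
```

i.e. with these inputs a 50-year-old with moderate uncontrolled OA pain
costs the public purse £36.5k more than an identical person with controlled
pain over 15 years (severe: £57.4k), the sum of forgone taxes and extra
benefit and health-care spending. `report` is the full disaggregated table
(earnings, gross tax, five transfer rows, health care, net tax, life-years;
one column per arm plus incremental columns). The packaged bundle is
explicitly **non-calibrated**: the lifetable and most effect CIs are
documented synthetic stand-ins, so these numbers illustrate the mechanics
rather than reproduce any published total. The `examples/` directory has one
narrative script per capability (base case, tornado, PSA, scenarios,
synthetic generation).

A thin CLI mirrors the library:

```bash
oafiscal run --out out/                      # report + traces + manifest
oafiscal sensitivity --mode psa --n 10000 --seed 1 --out out/
oafiscal scenarios --out out/
oafiscal make-synthetic --seed 2 --out syn/ && oafiscal validate --config syn/inputs.yaml
```

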