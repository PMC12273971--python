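# Methods

## Model

The package implements a deterministic comparative risk assessment (CRA)
linking counterfactual reductions in the prevalence of four NCD risk factors
(tobacco, alcohol, high systolic blood pressure, high blood glucose) to
savings in projected current health expenditure (CHE) and to DALY reductions
for five conditions (cancer, type-2 diabetes, CVD, COPD, CKD) across 24
Latin American and Caribbean countries, 2020–2050.

The annual impact per (country, age group, condition, risk factor, year) is

    impact = CHE(country, age, chapter(condition), year)
             × share_within_chapter(condition)
             × reduction(risk factor)
             × PAF(country, age, condition, risk factor, year)
             × ramp(year)

with impacts summed over age groups and reported undiscounted and discounted.
Assumptions baked into this form:

- **No interaction terms.** Joint scenarios are the cellwise *sum* of
  single-factor scenarios, never compounded multiplicatively. The published
  combined-savings column equals the row sum of the four single-factor
  columns exactly, which forces additivity.
- **Linearity in the reduction.** A 25% scenario is exactly five times a 5%
  scenario. Negative reductions (prevalence increases) are permitted and
  yield negative savings.
- **One lag structure for all conditions.** A risk-factor change translates
  into condition prevalence via a single linear ten-year ramp; no
  condition-specific latency.
- **Attributable fractions as DALY ratios.** The PAF enters as the ratio of
  attributable to total DALYs, taken as exogenous input per country, age,
  condition, risk factor and year. All factors in the product are evaluated
  at the impact year (the alternative — reading the PAF a decade earlier —
  is not implemented; with the default time-constant PAFs the two coincide).
- **Deterministic point estimates.** No uncertainty propagation anywhere.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| within-chapter cost shares | 1.0, 0.2485, 0.9191, 0.3689, 0.372 (cancer, diabetes, CVD, COPD, CKD) | fraction | 2015–2019 Colombian RIPS averages, assumed region-wide; stored as fractions to avoid double scaling |
| reduction levels | 0.05 / 0.10 / 0.25 | fraction of prevalence | the three standard scenarios |
| `ramp_years` | 10 | years | full policy effect a decade after adoption; ramp is 0 at `start_year`, 1 at `start_year + ramp_years` |
| `start_year` / `horizon_end` | 2020 / 2050 | year | the accounting window; effects persist at full strength after the ramp |
| `discount_rate` / `base_year` | 0.03 / 2020 | per annum / year | end-of-year convention, exponent = year − base_year |
| link matrix | 12 pairs | boolean | tobacco→{CVD, cancer, COPD, diabetes}; SBP→{CVD, CKD}; glucose→{CVD, cancer, diabetes, CKD}; alcohol→{CVD, cancer}; PAFs must be zero elsewhere |

Design choices where the source material was genuinely open:

- **Ramp anchor.** The exact calendar anchor of the ten-year interpolation is
  unstated; the default ramps 2020→2030 and is configurable.
- **Percent denominator.** Percent-of-cumulative-expenditure uses the
  *discounted* cumulative total CHE over all 22 chapters, keeping the
  statistic unit-free (a discounted/undiscounted mix would not be); a flag
  switches to the undiscounted denominator. The statistic is invariant to a
  common currency rescaling of CHE.
- **Cross-country averaging of DALY reductions.** Unweighted mean across
  countries, DALY-weighted within country across age bands, evaluated at the
  latest year common to the PAF and DALY tables (with time-constant PAFs any
  full-ramp year gives the same number). A `daly_weighted` across-country
  option exists.
- **Age-specific cost shares.** Only a single national value per condition is
  available; the engine accepts an optional (condition, age) share table but
  defaults to the scalar for all ages.
- **Baseline recurrence.** The counterfactual projection multiplies
  `(1+pop)(1+prev)(1+residual)` at annual boundaries (discrete compounding).
  Whether the original expenditure forecast compounds the three factors
  multiplicatively or additively is not documented; multiplicative is
  implemented and flagged here. Chapter XXI (contact with health services:
  screening, immunisation, certificates) gets a flat prevalence trend. The
  residual is exogenous input; no attempt is made to re-estimate it from
  GDP or technology data.

## Synthetic data: what it emulates, what it does not

`ncdcra.synthetic` fabricates the three undeposited inputs with the joint
structure the analysis assumes:

- 16 Latin American + 8 Caribbean countries in four expenditure groups, with
  2020 total-country CHE group means of 40,000 / 16,000 / 6,000 / 2,400
  million 2018 US$ (lognormal country jitter), split across 18 age bands
  (expenditure rising with age) and all 22 ICD-10 chapters (circulatory and
  neoplasm chapters weighted up), growing at ~4.5%/yr (sd 1%) — magnitudes
  chosen once as realistic for the region.
- PAFs drawn uniformly per (country, age) in bands centred on the values
  back-solved from the published average DALY-reduction table (e.g.
  tobacco→COPD 0.458, SBP→CVD 0.5232, glucose→diabetes 1.0), ±10% relative
  half-width (symmetric, clipped at 1), *time-constant* by default: the
  model gives no within-horizon PAF dynamics, so constancy is the
  least-assumption default. Optional knobs add a linear drift or a mild
  monotone age gradient (both off).
- DALY totals scaled by country size (proxied by expenditure group) with
  CVD > cancer > diabetes > COPD > CKD relative magnitudes and a slow
  secular increase.

Determinism: one named random stream per dataset per country, keyed
(seed, dataset code, country index) — adding a country never perturbs
earlier countries' draws, and a fixed seed reproduces byte-identical CSVs.

What a green test therefore establishes: the *arithmetic* of the model
(products, ramp, discounting, aggregation, additivity, linearity) on inputs
with realistic structure. What it does not: agreement with any real
country's burden or expenditure levels — the generator does not model
demography, epidemiological transitions, between-country PAF correlation, or
the econometrics behind real CHE projections. Published country-level
savings are reproduced only through `calibrate_to_totals`, which solves for
per-risk-factor CHE scale factors (savings are exactly linear in CHE) so the
four single-factor totals match their printed values; the combined total
then matches by additivity. That check validates the accounting identity,
not the input data.

## Numerical notes

- All internal arithmetic in float64; display rounding (savings to integer
  millions, percents to two decimals) happens only in `reporting`.
  Subtotals are computed before rounding, so a displayed subtotal can differ
  from the sum of displayed member rows by ≤ 1 unit in the last place per
  member.
- CSV round-trips are bit-exact: writers use shortest-repr floats and readers
  parse with `float_precision="round_trip"`.
- Ramp conservation: with the endpoint convention (0 at start, 1 at
  start + R), a horizon covering the full ramp forgoes exactly
  (R + 1)/2 annual full-effect amounts relative to an instant-effect run on
  constant inputs; the test suite pins this against a brute-force year loop.
- Countries with zero total DALYs for a condition are excluded from that
  condition's cross-country average with a logged warning rather than
  propagating NaN.
- Degenerate inputs rejected with keyed messages: negative expenditure,
  year gaps, PAFs outside [0, 1] or positive off the link matrix, growth
  factors ≤ −1, discounting before the base year.

## Known limitations

- Only the five named conditions and four risk factors; savings through other
  conditions linked to the same risk factors are not captured.
- The within-chapter cost shares come from one country's administrative data
  applied region-wide; where local epidemiology differs (e.g. Chagas disease
  inflating the circulatory chapter, indoor-cooking COPD), attributable
  costs will be over- or under-stated.
- No intervention costs, no monetisation of DALYs, no confidence intervals.
- The baseline projection module is a stand-in recurrence, not a
  re-implementation of any published expenditure forecast.
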