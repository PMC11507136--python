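# Methods

## Decision problem and model structure

The package evaluates two primary-care delivery strategies for
community-dwelling people living with ADRD — start with in-person visits
or start with telehealth visits — from a healthcare-system perspective.
The disease itself is not modelled (ADRD severity and progression are out
of scope); what is modelled is the *delivery process*: how people move
between delivery modes, how fast they die under each mode, what each mode
costs per year, and how much caregiver burden each mode is associated
with.

The core is a three-state Markov cohort model (in-person, telehealth,
dead) with a 1-year cycle, a 10-year horizon (reflecting the limited life
expectancy of the population) and 3% annual discounting of both costs and
effectiveness. Within a cycle death is applied first and switching only
among survivors, so the annual mortality input is the actual probability
of dying in the year and the switch input is the probability of switching
conditional on surviving. The dead state is absorbing and earns zero cost
and zero effectiveness; awarding the dead the burden scale's maximum
(100 = no burden) would reward mortality, so zero is used.

Rewards accrue at cycle start for the states occupied during the cycle
(cycle 0 undiscounted). A half-cycle-correction flag exists
(`half_cycle_correction`, default off) that instead applies rewards to the
average of adjacent occupancies at half-cycle discount times.

## Effectiveness: modified ZBI-12

Caregiver burden substitutes for quality-of-life weights because direct
QoL assessment is unreliable in moderate-to-severe dementia and caregivers
are the de-facto healthcare decision-makers. Raw ZBI-12 scores run 0
(minimum burden) to 48 (maximum burden); the model's effectiveness scale
inverts and stretches this to 0 (maximum burden) – 100 (minimum burden).
The map is taken to be linear, `modified = 100 * (1 - raw/48)`, the
simplest bijection consistent with the stated endpoints; linearity is an
assumption, not a published fact.

## The ICER and its sign convention

All differences are telehealth − in-person. Two ratios are emitted:
`icer_standard = ΔC/ΔE` (textbook) and `icer_reported = -ΔC/ΔE`, the
convention of the published scenario results, under which a negative
number reads "USD saved per burden point with telehealth".

**Why the headline comparison is per alive person-year.** The published
scenario ICERs (−9.44, +29.26, −320.93 USD/point) are numerically
consistent — sign exactly, magnitude within the rounding of 2-decimal
inputs — only with the per-cycle incremental ratio −Δc/Δe of the annual
delivery costs and burden means. They are *not* consistent with the ratio
of strategy-total discounted costs and effects from the cohort traces:
because telehealth carries lower mortality, the telehealth-start cohort
accumulates more discounted alive-time, and the trace-total ratio comes
out an order of magnitude smaller (and, for the urban-minority scenario,
with the opposite sign). The package therefore computes the headline
scenario ICER from outcomes normalized per discounted alive person-year,
with rewards attributed to the strategy's delivery mode; for constant
per-cycle rewards this is exactly −Δc/Δe, independent of horizon and
discount rate. The trace-total, state-attributed ICER is always computed
alongside it (`result_trace_totals`) and the deviation from the published
values is logged, never corrected.

The incremental-cost inputs (USD 202–503/year) are the delivery-mode
costs only — telehealth training labor, respectively travel plus caregiver
productivity loss — not ED/hospitalization spending, whose magnitudes
(thousands of USD per event) are incompatible with those printed totals.
An `include_utilization_costs` flag (default off) adds
`ed_rate × c_ed + hosp_rate × c_hosp` to each live state's per-cycle cost
for total-cost analyses.

## Parameters

Per scenario (Models A/B/C; urban non-Hispanic White, urban minority,
rural):

| parameter | units | A | B | C |
|---|---|---|---|---|
| switch in→tele / tele→in | prob/yr | .3137/.1829 | .2167/.2677 | .2667/.3000 |
| mortality in / tele | prob/yr | .1147/.0810 | .1690/.1125 | .1029/.0752 |
| ED, hosp rate (in) | events/yr | 2.24, 1.86 | 2.24, 2.71 | 1.20, 0.96 |
| ED, hosp rate (tele) | events/yr | 1.52, 0.74 | 1.52, 1.22 | 0.93, 0.61 |
| ED, hosp unit cost | USD/event | 6177, 34950 | 6459, 40635 | 5193, 30346 |
| delivery cost in / tele | USD/yr | 230/202 | 237/220 | 503/436 |
| effectiveness in / tele | 0–100 | 70.28/67.35 | 72.94/73.55 | 60.58/60.37 |

Discount rate 0.03/yr and horizon 10 cycles throughout. Fixture values are
stored exactly as published (percent → decimal).

## Synthetic data generator

The generator emulates the two unavailable sources: person-year delivery
records (payor administrative data) and ED/inpatient discharge abstracts
(statewide HCUP-style databases). Its defaults are the study conditions:

- **Ages**: truncated normal whose *truncated* mean/SD equal the profile's
  published values (urban 81.3 ± 9.7 on [61, 98]; rural 82.6 ± 6.5 on
  [63, 89]). The parent parameters are solved by least squares at run
  time. Naive truncation of N(mean, SD) would bias the urban mean ~0.5–3
  years low. The urban range uses the results-text bound 98: the
  tabulated bound 89 is infeasible for any truncated normal with the
  published moments. The rural target is itself infeasible on [63, 89];
  the closest attainable pair (≈82.2 ± 5.8) is used.
- **Gender/race**: categorical draws at the published shares (gender as
  exact count fractions, since the printed percentages sum to 100.3).
- **Events**: death then switch as Bernoulli draws per year with
  modality-specific probabilities; ED/hospitalization counts Poisson with
  modality-specific means; follow-up ends at death.
- **Burden**: integer ZBI-12 raw scores from a moment-matched truncated
  normal on [0, 48]; per-modality means are the inverse-rescaled published
  effectiveness values; the SD (8 points, not published) is typical of
  caregiver samples.
- **Discharges**: one record per counted event. ED stays are 1 day (priced
  per event); inpatient length of stay is 1 + Poisson(los_mean − 1). Daily
  charges are lognormal (hospital charges are right-skewed),
  parameterized by method of moments. Per scenario, the daily-charge mean
  is set to the published ED unit cost and `los_mean` to the
  hospitalization/ED cost ratio, so the implied mean per-event costs
  equal the published unit costs. A configurable fraction of records
  receives non-ADRD principal diagnoses to exercise the F01/F02/F03
  filter.

What the generator does **not** emulate: real claim layouts, within-person
correlation of utilization across years, seasonality, charge-to-cost
ratios, coding error beyond the contamination mechanism, and any
dependence of mortality or switching on age, gender or race. Passing
tests therefore demonstrate internal consistency of the pipeline under
the stated stochastic structure, not robustness to real administrative
data.

## Estimators

- Annual probabilities: events / person-years at risk, with the year
  attributed to the modality at its start; the switch denominator excludes
  decedents (the exact inverse of the death-first Markov decomposition).
  95% intervals are Wilson score intervals (well behaved at small n).
- Utilization rates: total events / person-years; Poisson SE.
- Per-event costs: each event priced as length-of-stay × mean daily charge
  of its (age band × gender × principal diagnosis) group; event costs
  averaged within (age band × gender) cells; cells combined by fixed
  population weights (direct standardization). Age bands are {≤79, 80+} —
  the only published split — crossed with binary gender; "other" gender is
  pooled with the majority gender for weighting only. Weight mass on cells
  absent from the data is renormalized away with a warning.
- Delivery costs: telehealth = trainer wage × training hours per
  conversion × annual conversion probability; in-person = visits/year ×
  (roundtrip miles × mileage rate + time-savings/60 × caregiver wage),
  with time savings = roundtrip drive + (in-person visit − telehealth
  visit) minutes. The ingredient values behind the published totals are
  not published; package defaults are realistic 2022 values (IRS mileage
  rate 0.585 USD/mile, 60-minute roundtrip, 30- vs 15-minute visits) and
  the scenario fixtures always use the published totals directly.
- Inflation: multiplicative compounding over per-year healthcare inflation
  rates supplied by the caller (no rate table is bundled).
- Sample size: the standard conservative-proportion formula
  z²·0.25/margin² with finite-population correction. Note the published
  cohort sizes (58 urban, 33 rural) are *not* recovered by this formula at
  the stated confidence/margin; the function implements the standard
  formula and makes no claim to reproduce them.

## Numerical choices

- All arithmetic in double precision; no rounding before presentation.
- Transition-matrix diagonals take the exact residual so rows sum to 1 to
  machine precision; traces are validated for conservation (1e-12) and
  non-decreasing dead occupancy on construction.
- An incremental effect below 1e-9 point-years marks the ICER undefined
  (dominance is then decided by cost alone) to avoid reporting
  floating-noise ratios.
- The microsimulation cross-check (100,000 independent walkers) is
  compared cell-wise to the cohort trace with a simultaneous criterion —
  every cell within 4 binomial SE, at most one beyond 3 SE — which
  controls the familywise false-rejection rate (~0.5%) that a naive
  3-SE-per-cell rule at 33 cells would not (~8%).
- Problem sizes in the test and acceptance runs (5,000–10,000 simulated
  person-years; 100,000 walkers) are chosen so that 3-SE recovery bands
  are a few percent of the target values while the whole suite runs in
  seconds.

## Known limitations

- Transition and mortality probabilities are time-homogeneous: no age
  dependence, no tunnel states, no within-cohort heterogeneity.
- The strategy-level reward attribution that reproduces the published
  ICERs treats delivery cost and burden as properties of the assigned
  strategy rather than the occupied state; the state-attributed totals
  are reported alongside precisely because the two constructions diverge.
- The ZBI-12 rescaling is assumed linear; the published modification
  matrix is not available.
- Synthetic charges are independent across events and persons; no
  hospital- or diagnosis-level clustering.
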