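# telehealth-cea

A decision-analytic pipeline for comparing **telehealth vs. in-person
primary care** for community-dwelling people living with Alzheimer's
Disease-Related Disorders (ADRD, ICD-10-CM F01/F02/F03), using informal
**caregiver burden** — the 12-item Zarit Burden Interview (ZBI-12) rescaled
to a 0–100 "less burden is better" scale — as the effectiveness measure in
place of QALYs.

It is written for health-services and health-economics researchers who
want to run, stress or extend this style of analysis when the underlying
payor claims and statewide discharge data cannot be shared: a synthetic
data generator reproduces the statistical structure of those sources, so
the entire pipeline runs end to end with no external data.

## The model

A closed cohort moves through three health states — *in-person* primary
care, *telehealth* primary care, *dead* — in 1-year cycles over a 10-year
horizon. With annual mortality $m_i$ and switch probability $s_i$ for live
state $i$ (death applied first, switching among survivors):

$$P(i \to \text{dead}) = m_i,\quad P(i \to \text{other}) = s_i(1-m_i),\quad P(i \to i) = (1-s_i)(1-m_i).$$

Each live state carries a per-cycle delivery cost $c_i$ (USD/year) and
effectiveness $e_i$ (modified ZBI-12 points); both are discounted at 3%
per year. A strategy is the starting delivery mode, and the incremental
comparison (telehealth − in-person) yields the incremental
cost-effectiveness ratio (ICER). The headline scenario ICER is computed on
outcomes **per discounted alive person-year**, which for constant
per-cycle rewards reduces to

$$\text{ICER}_{\text{reported}} = -\,\frac{c_{\text{tele}} - c_{\text{in}}}{e_{\text{tele}} - e_{\text{in}}},$$

the sign convention under which a negative value reads "cost saving with
telehealth per burden point" (see `docs/methods.md` for why this
construction, and the standard trace-total ICER it is reported alongside).

The package also contains the upstream stages: a synthetic cohort /
discharge-record generator, the ADRD diagnostic filter, sample-size
arithmetic, and estimators that recover every model input (transition
probabilities with Wilson intervals, Poisson utilization rates,
age-and-gender-standardized per-event ED/hospital costs from
length-of-stay × daily charges, delivery-mode costs, inflation
adjustment, burden rescaling) from person-level records.

## Worked example

Three scenarios ship with the package: `model_a` (urban non-Hispanic
White), `model_b` (urban racial minorities), `model_c` (rural residents).

```bash
telehealth-cea reproduce-paper --out output/
```

prints the scenario table and, per scenario:

```
model_a: reported ICER -9.56 (published -9.44, deviation +1.2%)
model_b: reported ICER 27.87 (published 29.26, deviation -4.8%)
model_c: reported ICER -319.05 (published -320.93, deviation -0.6%)
```

Telehealth is cost saving per caregiver-burden point for the urban
non-Hispanic White and rural scenarios (negative reported ICER), while for
urban racial minorities in-person care is the cost-saving option
(positive). Deviations from the published values reflect the inputs being
printed at 2-decimal precision.

A full synthetic run — generate records, re-estimate parameters, evaluate —
looks like:

```bash
telehealth-cea simulate --fixture model_a --n-persons 5000 --seed 11 --out output/
telehealth-cea estimate --person-years output/person_years.csv \
    --discharges output/discharges.csv --out output/
telehealth-cea run --params output/estimated_parameters.yaml --out output/
telehealth-cea sensitivity --fixture model_b --param c_delivery_tele \
    --low 180 --high 260 --steps 9 --out output/
```

Every command is importable as a library function
(`telehealth_cea.generate_cohort`, `estimate_all`, `run_strategy`,
`compute_icer`, `one_way_sensitivity`, ...).

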