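# tremorcma

A cost-minimisation model comparing **magnetic resonance-guided focussed
ultrasound (MRgFUS)** with **unilateral deep brain stimulation (DBS)** for
medication-refractory essential tremor in the Japanese healthcare setting.

Both procedures target the ventral intermediate nucleus of the thalamus and
deliver comparable tremor relief over 12 months, so the economic question
reduces to costs. The model is a staged direct-cost account from the
payer's perspective, in 2018 Japanese yen, over a 12-month horizon with no
discounting:

```
T(proc) = C_pre + C_procedure + C_post + Σ_e  p_e · T(ref_e)
```

where each stage cost is a sum of tariff-priced line items
(`unit_cost × quantity`, plus day-indexed hospitalisation fees), and each
downstream event `e` contributes its probability times the full cost of the
procedure it triggers: re-treatment by radiofrequency thalamotomy (RFT)
after tremor recurrence following MRgFUS (p = 0.089 × 0.40 = 0.0356) and
DBS electrode extraction (p = 0.01/year). Around the base case the package
provides

- **tariff scenarios** — 2018 fee-for-service (FFS) tariffs (small
  hospitals) versus Diagnosis Procedure Combination (DPC) per-diem tariffs
  (large hospitals) substituted for pre-, post- and day-of-procedure
  hospitalisation costs;
- **JHIFS labour add-ons** — hourly healthcare-professional labour costs
  (2016 or 2018 rates), with a 0.7 correction on day-of-procedure labour
  and uncorrected pre-procedure labour;
- **one-way deterministic sensitivity analyses** over the re-treatment
  proportion, extraction rate, DBS hospitalisation duration and MRgFUS
  procedure duration, with a tornado summary;
- **probabilistic sensitivity analysis** — Monte Carlo with moment-matched
  gamma (costs/quantities) and beta (percentages) distributions, SD = 20%
  of the mean, premium quantities linked to their parent activities, and a
  pooled-variance t-test at the 1% level after a variance-homogeneity
  check.

Item-level tariff inputs are not public; the bundled reference model is
*calibrated*: stage subtotals are taken from the published tables and the
hidden constants (RFT and extraction episode costs, per-day hospital fees,
the labour duration slope) are recovered with a linear-consistency oracle
and validated against held-out published cells. See `docs/methods.md`.

## Worked example

```python
from tremorcma import reference_scenario, run_scenario
from tremorcma.report import render_table

result = run_scenario(reference_scenario(mode="ffs"))
print(render_table(result, format="markdown"))
```

```
| row | pre | procedure | post | total |
| ---: | ---: | ---: | ---: | ---: |
| MRgFUS | 50,610 | 2,032,440 | 61,987 | 2,145,037 |
| unilateral_DBS | 50,610 | 2,310,833 | 183,974 | 2,545,417 |
| difference | 0 | -278,393 | -121,987 | -400,380 |
```

MRgFUS costs JPY 2,145,037 per procedure against JPY 2,545,417 for
unilateral DBS — a saving of JPY 400,380, most of it at the procedure stage
(no general anaesthesia, no implanted device) and the rest post-procedure
(one night in hospital instead of eight, no extraction risk). All
arithmetic is exact internally; values are rounded to the nearest yen (ties
away from zero) only when a table is rendered.

The `examples/` directory walks through each capability: base case and DPC
scenario, labour scenarios, one-way sensitivity analyses, the probabilistic
analysis and pricing a custom catalog. A thin CLI mirrors them:

```sh
tremorcma run-scenario --tariff ffs --labour 2018
tremorcma dsa --param rft_proportion --values 0,0.1
tremorcma psa --iterations 1000 --seed 0 --plot psa.png
tremorcma validate my_catalog.csv
tremorcma fixtures export --out fixture.json
```

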