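# Methods

## Model

The package implements a cost-minimisation analysis: MRgFUS and unilateral
DBS are assumed clinically equivalent for medication-refractory essential
tremor over 12 months, so only direct healthcare costs are compared, from
the Japanese payer's perspective, in 2018 JPY. A procedure's total cost is
the exact sum of its pre-procedure, procedure and post-procedure stage
costs plus probability-weighted downstream events:

- stage costs are sums of tariff line items (`unit_cost × quantity`) plus
  day-indexed hospitalisation fees;
- downstream events are depth-1: the expected cost is
  `probability × total cost of the referenced procedure`, and referenced
  procedures (re-treatment RFT, electrode extraction) carry no events of
  their own. The expected event cost is allocated to the POST stage, since
  both events occur after the index procedure; the published stage tables
  are consistent with this allocation (the post-stage cells reproduce
  exactly under it) but do not uniquely determine it.
- the 12-month horizon is short enough that discounting is omitted, and
  event probabilities are applied as plain per-horizon probabilities (no
  half-cycle correction).

Consequences used throughout: the total is **affine in every event
probability** (slope = the referenced procedure's total) and, once labour
is added, **affine in procedure duration** (slope = corrected hourly
staffing cost). These two affinities drive both the calibration and
several property tests.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| tremor recurrence after MRgFUS | 0.089 | probability / 12 mo | published base case |
| re-treatment given recurrence | 0.40 | probability | published base case; product 0.0356 |
| DBS electrode extraction | 0.01 | probability / year | published base case |
| DBS post-procedure stay | 8 | days | clinical-expert assumption in the study |
| procedure duration (both arms) | 4 | hours | clinical-expert assumption |
| extraction surgery duration | 2 | hours | clinical-expert assumption |
| labour correction factor | 0.7 | — | JHIFS tariffs overestimate day-of-procedure costs by ~40% vs FFS; pre-procedure labour left uncorrected (conservative) |
| PSA distribution SD | 20% of mean | — | study convention in the absence of reported SDs |
| PSA iterations | 1,000 | — | study design |

## Calibration of the reference model

The study's item-level inputs (its supplementary tariff tables) are not
available; only stage-level and scenario-level totals are printed. The
bundled reference model is therefore calibrated:

1. **No-event stage subtotals.** The zero-probability sensitivity rows are
   plain sums of integer-yen tariff items, so those printed cells are taken
   as exact. Subtracting the printed pre and procedure cells gives the
   no-event post subtotals (e.g. FFS MRgFUS post = 2,115,300 − 50,610 −
   2,032,440 = 32,250).
2. **Hidden episode costs via the linear-consistency oracle.** Because the
   total is affine in an event probability, the slope between the 0% row
   and the base case equals the hidden referenced-procedure total. The
   base-case cell is rounded to the yen, so the raw two-point fit inherits
   a ±0.5/Δp uncertainty; the fit is therefore **snapped to the coarsest
   10^k-yen grid consistent with that window** (tariff bundles sit on
   coarse yen grids). This recovers RFT = 835,300 (FFS) and 733,310 (DPC),
   extraction = 519,400 (both modes). The snap is not cosmetic: the raw
   FFS fit (835,308.99) would mispredict the held-out 10% cell by 1 yen,
   while the snapped value reproduces it exactly.
3. **Hospitalisation schedule.** The 2/8/10-day rows give non-constant
   marginal day costs (FFS: 102,460/6 ≈ 17,076.67/day for days 1–8, 20,410
   beyond), so stays are priced through a piecewise-constant day-indexed
   schedule; only these marginal rates are identifiable, and the within-
   band allocation is immaterial because all published cells depend on
   day-count differences. The true tier structure below day 2 is unknown.
4. **Labour decomposition (2018, MRgFUS).** The 2-hour sensitivity row
   minus the internal medical total gives the 2-hour labour cost (516,983
   after integer snapping); with the 4-hour value 930,977 this yields the
   corrected slope 206,997 JPY/h, fixed component 102,989 and uncorrected
   hourly staffing cost 295,710. The fixed component aggregates
   pre-procedure labour and the probability-weighted re-treatment labour —
   the published totals cannot separate them, so it is stored (and
   documented) as one aggregate, held constant when the re-treatment
   proportion is varied. The 2016 aggregates and the DBS labour aggregates
   are likewise single pre-corrected entries; DBS labour duration is fixed
   at 4 h and DBS extraction/device-management labour is excluded, as in
   the study design.

Every constant carries a provenance tag (`printed` or `derived` with its
oracle inputs); each derived constant reproduces at least one printed cell
**not** used in its derivation (the 10% re-treatment cell, the 2%
extraction cell, the 6-hour labour cell, ...), which is what makes the
reproduction a test of the model rather than bookkeeping.

Three published cells are internally inconsistent and are resolved by
arithmetic: the 2-day hospitalisation difference (−297,920 implied by its
own totals vs −277,920 printed), the DPC+2018-labour difference (−750,454
vs −750,434 in one table) and the MRgFUS 2018-labour grand total
(3,076,014 vs 3,086,014 in one table). The package reports the arithmetic
values and logs the discrepancies; none of them is used in calibration.

## Tariff substitution

In the DPC scenario, DPC prices replace FFS prices for exactly the
pre-procedure items, post-procedure items and day-of-procedure
hospitalisation; procedure fees, devices and drugs stay on FFS/drug-tariff
prices. Substitutability is a structural default derivable from an item's
stage and category, overridable per item (`dpc_substitutable`) — the
reference model's procedure-stage aggregates are flagged substitutable
because they embed the day-of-procedure hospitalisation fee, and the
extraction episode is flagged non-substitutable (its derived cost is
identical under both modes). The RFT episode is repriced (733,310 under
DPC), consistent with re-treatment following the same pre/post substitution
as an index procedure.

## Probabilistic sensitivity analysis

- **Distributions.** Gamma for costs and quantities, beta for
  probabilities, all moment-matched: gamma `shape = (mean/sd)², scale =
  sd²/mean`; beta via `ν = mean(1−mean)/sd² − 1`. SD defaults to 20% of
  the mean, making every gamma shape 25.
- **Parameter set.** Every sampled item contributes its unit cost; item
  quantities are sampled when ≠ 1, while quantity-1 lines are read as
  per-procedure counts and held fixed (every simulated patient has exactly
  one primary procedure — its price still varies). Hospital stays
  contribute their stay cost; events their probability. Premium quantities
  share their parent activity's draw (linkage groups share one uniform per
  iteration; identical distributions thus receive identical values).
- **RNG.** One root seed; each parameter or linkage group derives a child
  PCG64 stream from `SeedSequence([seed, crc32(key)])`, so results are
  bit-reproducible and adding a parameter does not perturb the others'
  draws.
- **Unbiasedness.** Moment matching preserves means and the model is
  affine in each parameter (independently sampled cost × quantity products
  have mean = product of means), so the expected PSA total equals the
  deterministic total; the suite asserts the sample mean within 3 SE at
  n = 10,000.
- **Decomposition granularity.** The PSA spread depends on how finely the
  model is decomposed into parameters, which the unavailable item tables
  fixed in the original analysis. The reference model defaults to
  stage-level parameters; `granularity="item"` builds a seeded Dirichlet
  decomposition of each aggregate (sums preserved exactly) with linked
  premiums. The share of iterations in which MRgFUS is cheaper moves from
  ≈ 0.75 (stage) to ≈ 0.80 (item) — this quantity is therefore only
  qualitatively reproducible and is reported, not targeted.
- **Inference.** The arm comparison runs a Levene variance-homogeneity
  check (the standard test for the stated intent of confirming equal
  variances), then a pooled-variance two-tailed t-test at the 1% level,
  falling back to Welch's test with a logged warning when the check
  rejects — which it typically does here, since the DBS arm's larger mean
  implies a proportionally larger 20%-CV spread. Both forms are decisively
  significant on the reference model.

## Numerical conventions

- Money is float JPY with no intermediate rounding; rounding to integer
  yen (ties away from zero, matching every published cell checked) happens
  once, at rendering, in `report.round_jpy`.
- Sensitivity overrides rebuild the scenario via immutable replacement;
  rows are order-independent.
- Degenerate inputs fail loudly: zero-variance PSA arms, coincident oracle
  abscissae, negative costs/days, missing tariff variants, uncovered PSA
  parameters.

## What the synthetic generator does and does not emulate

`generate_synthetic_catalog` produces seeded random catalogs with the
structure the analysis assumes — stage-tagged items, premiums linked to
parent activities, a day-indexed stay, depth-1 events — plus brute-force
truth totals computed by an independent flat loop. It emulates structure,
not Japanese tariff realism: prices are uniform draws, not actual tariff
points, and there is no correlation between items. Passing the
equivalence and property tests therefore shows the engine's arithmetic and
invariances are right on arbitrary inputs of the right shape; fidelity to
the actual tariff system rests on the calibrated reference model and its
held-out reproductions.

## Known limitations

- Stage-level calibration cannot recover the true item-level inputs; any
  decomposition consistent with the printed totals is observationally
  equivalent in the deterministic analyses but not in the PSA spread.
- The DPC RFT episode cost and the sub-2-day hospitalisation tiers rest on
  the identification assumptions above (grid snapping; exactness of
  zero-probability cells).
- Adverse-event costs, battery replacement beyond 12 months, repeat
  follow-up visits and bilateral DBS are outside the model's scope by
  design.
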