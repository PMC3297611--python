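# Methods

## The decision problem

`mrcc_cea` re-implements, as a tested library, a lifetime cost-effectiveness
comparison of five first-line strategies for metastatic renal-cell carcinoma
(mRCC) in a health-resource-limited setting: interferon-alfa, interleukin-2,
interleukin-2 plus interferon-alfa, sunitinib, and bevacizumab plus
interferon-alfa.  The perspective is the Chinese healthcare system, costs are
2011 US dollars, and both a standard-pricing scenario and the sunitinib
patient-assistance program (SPAP — patients pay for three cycles, then
receive the drug free) are modelled.

## Survival model

Each trial's interferon-alfa arm is summarised by Weibull fits to its
Kaplan-Meier progression-free-survival (PFS) and overall-survival (OS)
curves,

&nbsp;&nbsp;&nbsp;&nbsp;S(t) = exp(−λ·t^γ),

with *t* in 6-week model cycles.  The cycle time unit is not arbitrary: the
published scale/shape pairs reproduce the trials' printed median survival
times (e.g. exp(−0.0476218·15.9^0.9666) = 0.501 at the 21.8-month ≈
15.9-cycle median OS of the sunitinib trial's interferon arm) only under
cycle units, and the test suite asserts this.

A pooled "average interferon-alfa" reference curve is the patient-number-
weighted mixture Σᵢ wᵢ·Sᵢ(t) over the four interferon arms (weights 142,
322, 375, 503 — the published interferon-arm enrolments; configurable).
Active strategies are obtained by proportional hazards on the whole curve,
S_active = S_ref^HR, using the published PFS and OS hazard ratios of each
strategy versus interferon-alfa.

`fit_weibull` estimates (λ, γ) by ordinary least squares on the
complementary-log-log linearisation ln(−ln S) = ln λ + γ·ln t, reporting
adjusted R², delta-method standard errors, and the (negative) correlation of
the ln-scale and shape estimates — the same diagnostics the consumed fits
carry.  Maximum-likelihood fitting on pseudo-IPD was considered and not
implemented: the package consumes published curve fits, and the linearised
method is what their reported diagnostics correspond to.

## Cohort engine

Three states: progression-free (PFS), progressed (PS), death.  The horizon
is ⌈10 years / 6 weeks⌉ = 87 cycles; membership is counted at cycle start
(cycles 0–86), each contributing 6/52 years; no half-cycle correction by
default (a flag adds one).  Discounting is (1.03)^(−t·6/52) per cycle;
life-years are emitted both discounted and undiscounted, QALYs discounted.
Utilities are 0.60 (PFS) and 0.45 (PS); the alternative published pair
0.65/0.47 can be configured.

Two occupancy constructions are implemented:

* **partitioned** (default): occ_PFS = min(PFS, OS), occ_PS = max(OS − PFS, 0),
  occ_death = 1 − OS.  This is the standard partitioned-survival model; the
  clipping handles HR-adjusted curves that cross.
* **competing** (`engine.state_model: competing`): occ_PFS = PFS·OS,
  occ_PS = OS·(1 − PFS).  A Markov reading in which death competes inside
  the PFS state at the full OS hazard, i.e. PFS-curve events and deaths are
  double-counted as PFS exits.

The competing construction exists because the original analysis' published
state occupancies for the cytokine strategies match it almost exactly
(interferon 0.583 modelled vs 0.59 published undiscounted PFS years; 1.81
vs 1.82 PS years; interleukin-2 ±3%), while the partitioned construction
gives 0.76 PFS years for interferon.  For the HR-adjusted strategies,
however, *neither* construction — nor any uniform HR-application rule we
tested (hazard-power, probability scaling, odds scaling, accelerated-time,
per-trial-before-weighting, and flow Markovs with every assignment of the
HRs to progression and death transitions) — reproduces the published
sunitinib split of 1.71 PFS / 1.00 PS years.  The original engine is
therefore not recoverable from its printed inputs, and the package defaults
to the standard, well-defined partitioned construction.  The residual
differences this leaves against the published base case are quantified
below rather than hidden.

## Costing

All costs are 2011 USD.  Per cycle:

* **Drug acquisition** follows each schedule's dosing (sunitinib 50 mg/day,
  4 weeks on / 2 off; bevacizumab 10 mg/kg for a 65-kg, 1.72-m² patient
  every 2 weeks; interferon 3×/week with 3→6→9 MU titration; interleukin-2
  18 MU/m² daily ×5 every 3 weeks; sorafenib 400 mg twice daily second
  line) with whole-pack discard: packs = ⌈dose/pack size⌉.  Intravenous and
  subcutaneous administrations add an $18.5 fee each; oral drugs none.
* **First-line cost** accrues over PFS occupancy; a one-off expected
  serious-adverse-event cost Σ p(event)·unit cost is charged at entry;
  routine follow-up ($38.5) is charged in both alive states (flag to
  restrict to PFS).
* **Progressed-state cost** is the expected second-line mix per progressed
  patient-cycle: shares 14.2% sunitinib, 17.1% sorafenib (12.2% plus the
  4.9% on other targeted agents, reassigned), 1.7% bevacizumab, 33.5%
  cytokines (costed as an even interferon/interleukin-2 split), and best
  supportive care (morphine 300 mg twice daily) for the remaining 33.5%.
* **SPAP**: first-line sunitinib is bought for three cycles — charged as
  three flat discounted cycle costs, matching the program's buy-in — and
  free afterwards; second-line sunitinib is charged the paid fraction
  3/D of its cycle cost, with D the mean second-line treatment duration.

### Calibration constants

The published analysis does not state the funded treatment duration or the
exact price-unit reading for the cytokine vials (the printed "per 300 MU" /
"per 50 MU" rows are inconsistent with the published strategy costs under
any literal reading).  Rather than guess silently, the engine exposes three
explicit linear calibration knobs, shipped with the values that make the
published discounted stage costs exact under the default occupancy
convention (see `examples/05_recalibrate.py`, which re-derives them):

| constant | shipped value | anchored to |
|---|---|---|
| dose intensity, interferon | 1.9615 | $6,802.82 PFS-stage cost |
| dose intensity, bevacizumab+interferon | 0.8206 | $157,562.65 |
| dose intensity, sunitinib | 0.6117 | $81,728.07 |
| dose intensity, interleukin-2 | 2.5243 | $4,184.96 |
| dose intensity, interleukin-2+interferon | 2.2783 | $10,464.30 |
| second-line intensity | 0.7455 | $25,817.48 interferon PS-stage cost |
| SPAP second-line paid fraction | 0.4097 (D ≈ 7.3 cycles) | $19,297.00 interferon PS-stage cost under SPAP |

Factors above 1 (the cytokine strategies) absorb the price-unit ambiguity;
factors below 1 (the targeted agents) are consistent with dose reductions
and early discontinuation.  Setting all of them to 1 gives fully mechanical
bottom-up costing.

## Economics

The frontier algorithm sorts strategies by cost, removes strictly dominated
ones (another strategy no more costly and no less effective, one strictly),
then iteratively removes extended-dominated ones (incremental ICER above
the next step's), and reports pairwise ICERs Δcost/ΔQALY along the
frontier.  It is tested against an exhaustive-enumeration oracle on random
instances.  Net health benefit is ΔQALY − Δcost/WTP; the default WTP is
$13,290/QALY = 3 × mainland China's 2010 per-capita GDP ($4,430), and every
threshold is an argument, never a constant.

## Sensitivity analysis

* **One-way (tornado)**: each parameter moves to its low/high bound with the
  rest at base — hazard ratios over their 95% CIs, prices over their
  published ranges ("fixed" rows do not move), adverse-event probabilities
  90–110%, utilities over their published ranges, discount rate 0–5% (a
  conventional range; none is published) — and the swing in the
  sunitinib-vs-interleukin-2 incremental NHB is reported.
* **Probabilistic**: 1,000 draws; costs lognormal and utilities/
  probabilities beta, both moment-matched to a 10% coefficient of
  variation; hazard ratios lognormal with median at the point estimate and
  sigma = (ln CI_high − ln CI_low)/(2·1.96); Weibull parameters and the
  discount rate are held fixed.  Each draw re-evaluates the deterministic
  cohort model (the model is patient-count invariant, so "1,000 simulated
  patients" needs no microsimulation).  Reproducibility comes from a master
  `SeedSequence` with per-iteration substreams; the seed is recorded in the
  run manifest.
* **CEAC / regional table**: at each threshold the probability that a
  strategy has the maximal monetary net benefit (ties split equally);
  the regional table evaluates the CEAC at 3× each province's per-capita
  GDP.

## Synthetic data

`generate_ipd` draws Weibull event times by inverse-CDF sampling
t = (−ln U/λ)^(1/γ) with administrative censoring at a stated horizon, and
`km_estimate` wraps the product-limit estimator.  This emulates the *shape*
of trial survival data — it has no accrual period, no dropout censoring, no
covariates and no informative censoring — so passing recovery tests shows
the fitting pipeline is correct, not that real KM extractions are unbiased.
Recovery is validated two ways: single fits within twice the Monte-Carlo
sampling SE, and replicate means within 2% at n = 1,000.

## Residual differences against the published base case

With the shipped calibration the package reproduces the published
strategy costs and the probabilistic headline results, but not the
published state-occupancy split of the targeted strategies (see the cohort
section: the original Markov engine is not recoverable).  Quantified, with
the acceptance-script conventions (discounted survival):

| quantity | published | this package | difference |
|---|---|---|---|
| bevacizumab+IFN total cost (no SPAP) | $178,864.96 | $178,239.82 | −0.3% |
| sunitinib total cost (no SPAP) | $95,978.35 | $94,608.71 | −1.4% |
| sunitinib PFS-stage cost (SPAP) | $15,875.58 | $15,651.49 | −1.4% |
| P(sunitinib CE vs bev+IFN, SPAP, $13,290) | ~100% | 100% | — |
| sunitinib total life-years | 2.71 | 2.65 disc / 2.85 undisc | −2.2% / +5.1% |
| sunitinib QALYs | 1.40 | 1.48 | +5.6% |
| sunitinib PFS years | 1.71 | 1.90 disc / 2.03 undisc | +11% / +18% |
| interferon PFS years | 0.59 | 0.74 disc / 0.76 undisc | +26% / +29% |
| frontier ICER, sunitinib, no SPAP | $220,384 | $174,564 | −21% |
| frontier ICER, sunitinib, SPAP | $16,993 | $12,070 | −29% |
| NHB at sunitinib PFS-HR upper bound | −6.26 QALY | −3.98 QALY | see below |

The ICER differences follow directly from the occupancy differences: this
engine gives sunitinib a larger QALY lead over interleukin-2 (0.41 vs 0.31),
which lowers every ICER involving sunitinib.  The dominance pattern itself
is reproduced (both combination strategies dominated in both scenarios;
sunitinib on the frontier only with the program).

The tornado endpoint differs in sign of response: here a *larger* (worse)
sunitinib PFS hazard ratio improves the NHB, because drug cost is
proportional to time in PFS and the cost saving outweighs the QALY loss at
a $13,290 threshold, whereas the published analysis reports the opposite
direction.  That behaviour would require first-line drug cost not to scale
with time on treatment, which contradicts the same analysis' published SPAP
arithmetic (three paid cycles out of occupancy-proportional funding); no
documented convention reconciles both, so the occupancy-proportional rule
is kept.  The sunitinib PFS hazard ratio is the top tornado bar under
either convention.

## Known limitations

* The default occupancy construction reproduces the published costs but not
  the published PFS/PS split of the targeted arms (above).
* Second-line treatment composition is independent of the first-line
  strategy, as in the source analysis; re-treatment with the first-line
  agent is therefore possible.
* Utilities are time-constant within states; no disutility events.
* No price inflation/deflation outside 2011 USD; no societal costs.
* Weibull is the only supported law; `SurvivalCurve` accepts any
  non-increasing curve, which is the extension point for other
  distributions.
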