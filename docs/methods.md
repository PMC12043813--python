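# Methods

## Model structure

The model is a cohort Markov chain over nine health states: eight bands
of best corrected visual acuity (BCVA) spanning 10 ETDRS letters each
(">85" down to "≤25") and an absorbing death state. Cycles are 3 months;
the cohort enters at age 56 distributed over bands
(0, 0.11, 0.39, 0.27, 0.15, 0.08, 0, 0) and runs to age 100, at which
point any survivors stop accruing value (no terminal valuation). Within
a cycle a patient can move at most one band up or down, die, or stay.
The structure models one (study) eye; second-eye involvement is a
bookkeeping channel that scales drug costs and shifts the utility mix,
not a second state space.

Costs and QALYs are discounted at 3.5% per year. The half-cycle
correction is implemented as trapezoidal state-membership averaging —
each cycle's flows use the mean of the start- and end-of-cycle occupancy
and are discounted at the cycle midpoint. For a constant trace this
changes nothing; a test asserts that property.

## Transition probabilities

Annual BCVA change is modelled as X ~ Normal(μ, σ) in letters. The
threshold for a band change is 5 letters — the minimal band-crossing
change for 10-letter bands. Annual tail probabilities P(X ≥ 5) and
P(X ≤ −5) convert to 3-month probabilities on the rate scale,
1 − (1 − p)^(1/4); simple division by 4 would not reproduce the
published natural-history value. For N(−1.30, 4.90) the method yields
2.5799% (gain) and 6.1764% (loss) per cycle against published figures of
2.57% and 6.10%; the small residual reflects an unknown intermediate
rounding path in the source spreadsheet, and the tests assert agreement
at 0.01 and 0.1 percentage points respectively.

Treatment effects enter as 1-year mean LogMAR differences versus PRP
(negative = better vision), converted at 1 letter = 0.02 LogMAR and
added to the PRP arm's annual mean. The PRP arm's own change
distribution is not published directly; its mean and SD
(−1.3547, 6.8924 letters/year) were calibrated once so that the
derivation above reproduces the published PRP per-cycle probabilities of
4.79% gain and 8.48% loss, and are frozen in `synthetic_inputs` with
provenance `derived`. Because the meta-analysis reports only the
dispersion of mean differences, every arm reuses the PRP arm SD.

Gain/loss probabilities are state-independent (one pair per arm), with
boundary bands folding the blocked move into staying.

### Effect trajectories

* `continued` — the 1-year arm model applies for the whole horizon.
* `stabilised` — PRP-alone freezes (per-cycle gain = loss = 0, mortality
  unaffected) from year 1; anti-VEGF arms decline linearly in annual
  mean toward 0 over year ∈ [1, 2) and freeze at year 2. The frozen
  probabilities are configurable (`stabilised_cycle_probs`) for users
  preferring a small residual churn.
* An optional natural-history onset switches all arms to the
  N(−1.30, 4.90) model from a configured year (5/10/20 in the one-way
  battery).

The trajectory is population-level: it is applied regardless of
individual discontinuation status, which affects costs only.

## Mortality

Annual death probabilities q(age, sex) come from a life table; the
cohort mixes sexes at 57.6% male. The diabetes hazard ratio (1.95,
lognormal μ = 0.668, σ = 0.090 in the PSA) applies on the hazard scale:
q_adj = 1 − (1 − q_mix)^HR; conversion to the 3-month cycle is again on
the rate scale. Ages use the integer floor of the deterministic cohort
age 56 + 0.25·t.

The default life table is synthetic Gompertz–Makeham:
h(age) = 5·10⁻⁴ + 2.5·10⁻⁵·e^(0.092·age), male hazard 1.45× female.
These values give a mixed-sex life expectancy at 56 of ≈ 26.5 years
before the diabetes adjustment, a plausible England & Wales magnitude.
It emulates the age pattern of a national table, not its year-to-year
irregularities; users with real tables load them from a CSV
(age, sex, qx) referenced by the config.

## Discontinuation, fellow eye, costs, utilities

Treatment persistence is a step function: 100% in year 1, 87% years 1–3,
75% years 3–5, 50% thereafter (the ≥5-year value is overridable to 0.25
or 0.75 for sensitivity analysis). Discontinuation scales treatment and
monitoring costs; off-treatment patients incur post-treatment monitoring
(£38.34/visit) instead of on-treatment monitoring (£101.80/visit).

Both-eye involvement starts at 22% and accrues at 5.4% per cycle among
single-eye patients. Drug cost doubles for the both-eye fraction (drugs
are dosed per eye); administration and monitoring are charged once per
visit, both eyes being treated in the same visit. The anti-VEGF
administration cost per visit is OCT + 0.95 × outpatient +
0.05 × day-case = £257.98. PRP administration is inside the £126.77
session cost. Low-vision costs (£421.61 per cycle) apply to occupancy of
the two worst bands (BCVA ≤ 35 letters) of the modelled eye.

Utilities are band-indexed, separately for a treated best-seeing eye
(BSE) and worst-seeing eye (WSE); both-eye patients use BSE values, and
single-eye patients mix 32.8% BSE / 67.2% WSE. The WSE vector keeps the
two best bands at 0.839 and declines linearly by 0.1 in total over the
remaining six bands (0.822, 0.806, 0.789, 0.772, 0.756, 0.739).

Adverse-event costs and disutilities apply during the first treatment
year only (the trial reporting window), scaled by the on-treatment
fraction. After discontinuation, a configurable fraction of each
newly-discontinuing slice switches to a mix of other strategies and
accrues that mix's drug + administration costs for at most 8 cycles
(2 years); this channel is cost-only.

## Placeholder inputs

Quantities published only in supplementary material are shipped as
documented stand-ins, tagged `placeholder` in `config.provenance` and
logged by the CLI so they cannot silently pass as published values:

| input | default | rationale |
|---|---|---|
| anti-VEGF injections/year | 7, 4, 3, 3, 2 (then 2) | front-loaded induction then maintenance; identical across drugs |
| PRP sessions/year | 3, then 0.5 | initial course plus occasional top-up |
| monitoring visits/year | 4 on treatment, 2 post | quarterly review on treatment |
| AE profile | probabilities < 2%, costs ≤ £1,500, disutilities ≤ 0.1 | keeps the AE share of totals very small |
| subsequent treatment | 50% of discontinuers to a 50/50 PRP/bevacizumab mix, 8-cycle cap | switching between classes only |

Absolute per-strategy cost/QALY totals depend on these stand-ins, so the
package does not claim to reproduce published per-strategy totals; the
derivable quantities (transition probabilities, administration cost,
utility interpolation, distribution means, NMB/ICER arithmetic on
published pairs) are reproduced and tested instead.

## Probabilistic sensitivity analysis

Each uncertain parameter carries a distribution keyed by its dotted
config path: beta for probabilities and utilities, gamma (shape, scale)
for costs, normal for treatment effects and the natural-history mean,
lognormal for the mortality hazard ratio, Dirichlet for the baseline
band distribution and the WSE/BSE split. Conventions:

* lognormal point estimates follow exp(μ) (the median), matching the
  printed 1.950 = exp(0.668);
* gamma means are shape × scale (96.036 × 8.497 = 816.02), and the
  recurring shape 96.036 encodes the ±20% convention
  (1.96/√shape ≈ 0.20) used where no dispersion data existed;
* Dirichlet concentrations are proportion × 100 (an effective sample
  size of 100, configurable); zero-proportion bands keep concentration 0
  and remain structurally zero in every draw;
* validation checks every distribution's analytic mean against its point
  estimate to 0.5%.

Draws are independent across parameters (no correlation structure is
published). Sampling is in sorted-path order from a seeded generator, so
a seed fully determines the draw sequence. Sampled utilities are clamped
to [0, 1] and re-monotonised; a draw still failing validation is
rejected and logged, and the run aborts if rejections exceed 1%.
Summaries report per-draw means of cost and QALYs, percentile 95%
intervals of per-draw NMB, and a frontier computed on the mean values.
The default draw count is 5,000 (configurable); a run at that size takes
about 90 s on one CPU. `generate_psa_fixture(config, scale)` rescales
every dispersion (scale 0 collapses to point masses at the current point
estimates, making a PSA reproduce the deterministic run exactly — used
as a test fixture).

## Numerical choices and degenerate inputs

* Probability conversions are always on the rate scale and exactly
  invertible; a property test round-trips to 1e-12.
* Row sums of every transition matrix are exact to 1e-12; occupancy
  conservation is asserted to 1e-10 over the whole trace.
* Equal-cost strategies form one comparison group in the frontier (only
  the higher-QALY one survives); strategies equal in both cost and QALYs
  are both retained. ICERs are computed unrounded.
* Zero-SD acuity models are rejected by validation; "no movement" is
  expressed through `stabilised_cycle_probs` or a vanishing SD such as
  1e-9 where a frozen cohort is wanted.
* The life-table CSV round-trips bit-identically (full-precision write,
  round-trip float parsing on read).

## Verification

The test suite checks every published derivable value at its printed
precision, and backs the engine with independent oracles: an erfc-based
closed form and a 10⁶-draw Monte-Carlo check for the normal tails, a
10⁵-patient microsimulation sharing the cohort engine's matrices
(agreement within 3 Monte-Carlo SEs at cycles 4, 40 and 100), a
per-cycle spreadsheet-style valuation loop against the vectorised
implementation, and a brute-force NMB-sweep oracle for the frontier
algorithm on random instances. Property tests (hypothesis, derandomised)
cover conversion round-trips and matrix structure.

## Known limitations

* One-eye state space: fellow-eye disease affects costs and the utility
  mix but not transitions; a two-eye model would capture bilateral
  progression more faithfully.
* No DMO co-modelling, no within-class treatment switching, no
  societal-perspective costs.
* Supplementary-only resource-use inputs are placeholders (above), so
  absolute totals are illustrative; comparative statics and all
  derivable quantities are the supported outputs.
* The synthetic life table is a smooth parametric stand-in for national
  tables.
* Passing tests on synthetic inputs demonstrate correctness of the
  mechanics and reproduction of derivable published values, not
  predictive validity for real PDR cohorts.
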