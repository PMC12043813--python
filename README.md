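# pdrcea

A Markov cohort cost-effectiveness model comparing anti-VEGF drugs
(ranibizumab, aflibercept, bevacizumab) with panretinal photocoagulation
(PRP), alone or in combination, for treating proliferative diabetic
retinopathy (PDR) without diabetic macular oedema, from a UK NHS
perspective.

It is written for health economists and guideline analysts who want a
transparent, scriptable implementation of this class of model: nine
health states (eight 10-letter bands of best corrected visual acuity,
BCVA, plus death), 3-monthly cycles with a half-cycle correction, a
lifetime horizon from age 56 to 100, and costs and QALYs discounted at
3.5% per year.

## The model

**Transitions.** The annual change in BCVA is assumed normally
distributed, X ~ N(μ, σ) in ETDRS letters. A move of one acuity band
requires at least 5 letters, so the annual probabilities of gaining or
losing one state are

    p_gain = P(X ≥ 5) = 1 − Φ((5 − μ)/σ),   p_loss = P(X ≤ −5) = Φ((−5 − μ)/σ)

converted to 3-month probabilities on the rate scale,
p₃ₘ = 1 − (1 − p)^¼. For the natural-history distribution
N(−1.30, 4.90) this gives 2.58% (gain) and 6.18% (loss) per cycle.
Treatment effects are 1-year mean BCVA differences vs PRP in LogMAR from
a published network meta-analysis; a difference d shifts the arm's annual
mean by −50·d letters (1 letter = 0.02 LogMAR). Two effect trajectories
are modelled: *continued* (the 1-year effect applies for the remaining
lifetime) and *stabilised* (acuity freezes after year 1 for PRP and year
2 for anti-VEGFs, with a linear decline in between).

**Mortality.** National-style life tables mixed over sexes (57.6% male),
adjusted on the hazard scale by a diabetes hazard ratio of 1.95:
q_adj = 1 − (1 − q_mix)^1.95, then converted to the cycle length. A
synthetic Gompertz–Makeham life table is generated by default; real
tables load from CSV.

**Valuation.** QALYs weight band occupancy by utilities indexed to
whether the treated eye is the best- or worst-seeing eye, with
both-eye-treated patients (22% at baseline, growing by 5.4% per cycle)
using best-seeing-eye values. Costs cover drug acquisition (per eye),
administration (£257.98 per anti-VEGF visit), PRP sessions, monitoring,
low-vision care (BCVA ≤ 35 letters), adverse events, and a cost-only
subsequent-treatment channel. Strategies are compared by net monetary
benefit, NMB = QALYs × λ − cost at λ = £20,000/QALY, and by a fully
incremental ICER analysis with dominance and extended dominance.

**Probabilistic sensitivity analysis** samples every uncertain parameter
from its assigned distribution (beta, gamma, normal, lognormal,
Dirichlet) and reruns the pipeline per draw.

Resource-use schedules published only in supplementary material
(injection counts, monitoring visits, PRP sessions, adverse-event
inputs, subsequent-treatment mix) ship as documented placeholder
defaults tagged `placeholder` in the config provenance map; absolute
cost totals therefore depend on these stand-ins. See
`docs/methods.md` for details and limitations.

## Worked example

```python
import pdrcea as P

cfg = P.default_parameter_set()            # base case, continued effects
results = P.run_deterministic(cfg)
frontier = P.incremental_frontier(
    [(r.strategy_name, r.cost, r.qalys) for r in results], threshold=20_000)
for e in frontier.entries:
    print(f"{e.name:16s} {e.cost:10,.0f} {e.qalys:7.3f}  {e.label:12s} {e.nmb:10,.0f}")
```

prints (GBP and QALYs per person, discounted, lifetime horizon):

```
bevacizumab          10,691  11.658  reference       222,462
prp                  11,426  10.183  dominated       192,231
bevacizumab_prp      11,547  11.642  dominated       221,284
ranibizumab          31,126  11.570  dominated       200,267
ranibizumab_prp      32,179  11.392  dominated       195,651
aflibercept          42,043  11.441  dominated       186,769
```

Each row is one strategy's total discounted cost and QALYs; `label` is
its place in the fully incremental analysis and `nmb` its net monetary
benefit at £20,000/QALY. With the placeholder resource-use schedules the
bevacizumab-based strategies lead the ranking under continued effects —
the qualitative pattern expected when a cheap drug carries the same
modelled effect schedule as expensive ones.

The same analyses run from the shell:

```sh
pdrcea run --scenario continued --out out/run          # traces + frontier
pdrcea psa --n-draws 5000 --seed 1 --out out/psa       # probabilistic
pdrcea dsa-battery --out out/dsa                       # 12 one-way analyses
pdrcea make-fixtures --out out/fx                      # config + life table
```

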