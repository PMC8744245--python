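# ipfcea

A Markov cohort cost-effectiveness model of anti-fibrotic therapy —
pirfenidone and nintedanib versus symptom management — for idiopathic
pulmonary fibrosis (IPF) in the United States, built as a tested, reusable
Python package for health-economics researchers who want to rerun,
perturb, or extend the analysis rather than read a single set of printed
tables.

## The model

IPF is a progressive fibrosing lung disease; the model tracks severity as
percent-predicted forced vital capacity (FVC) bands. A cohort enters the
band structure

```
90–110 → 80–89.9 → 70–79.9 → 60–69.9 → 50–59.9 → 40–49.9 → death
```

and every 3-month cycle each living individual may die (baseline hazard ×
treatment odds ratio, × 1.40 after any acute exacerbation), suffer an
acute exacerbation (base probability 0.0197/cycle, tracked by a permanent
flag), or decline one FVC band (3.2–8.9%/cycle by band). Decline is
permanent; dropping below 40% FVC is death. Each cycle accrues costs
(annual drug price and $12,291 follow-up split quarterly; $14,731 per
exacerbation episode) and quality-adjusted life years (band utilities
0.8380 down to 0.6634, minus exacerbation disutilities 0.140 then 0.078),
discounted at 3%/year:

```
total = Σ_k (1.03)^(−k·Δt) · [ c·x_k  or  Δt·u_eff·x_k ],   Δt = 0.25 yr
```

Strategies are ranked by cost, dominated options eliminated, and
incremental cost-effectiveness ratios (ICER = ΔC/ΔQ) judged against a
willingness-to-pay (WTP) of $100,000/QALY. Uncertainty is handled by a
one-way threshold search (bisection on one parameter until the WTP-chosen
strategy switches) and a probabilistic sensitivity analysis (PSA) with
moment-matched beta/lognormal parameter distributions, summarized as
cost-effectiveness acceptability curves (CEAC) and frontier (CEAF).

The one input that is not public is the baseline (untreated) mortality
curve. `ipfcea.baseline_survival` substitutes a synthetic parametric
hazard (exponential by default, Weibull available) calibrated so the
symptom-management arm reproduces 3.78 discounted lifetime QALYs; all
absolute lifetime figures therefore depend on that stand-in (see
`docs/methods.md` for what this does and does not preserve).

## Worked example

```
$ python -c "import ipfcea; ipfcea.save_config(ipfcea.default_config(), 'bc.yaml')"
$ ipfcea run --config bc.yaml --outdir demo
          strategy   cost  delta_cost  qalys  delta_qalys               icer             status  cost_effective
symptom_management  65762         NaN   3.78          NaN                             reference            True
       pirfenidone 835859         NaN   5.06          NaN EXTENDED-DOMINATED extended-dominated           False
        nintedanib 845464    779702.0   5.25         1.47             529925        on-frontier           False
chosen at WTP $100,000/QALY: symptom_management
```

Reading the table: symptom management costs $65,762 over a lifetime for
3.78 QALYs; both anti-fibrotics add hundreds of thousands of dollars of
drug cost for their QALY gains; pirfenidone is eliminated (nintedanib is
cheaper *and* more effective here, so pirfenidone never sits on the
efficiency frontier); and nintedanib's ICER of ~$530,000/QALY is far above
the $100,000 threshold, so symptom management is the cost-effective
choice. The same conclusion — anti-fibrotics are effective but not
cost-effective at US list prices — follows when the ranking arithmetic is
run directly on the published lifetime values, where the nintedanib ICER
is $1.6M/QALY.

Other subcommands: `ipfcea calibrate` (re-fit the baseline hazard),
`ipfcea psa --n 10000 --seed 1 --plot` (CEAC/CEAF curves), and
`ipfcea threshold --param annual_drug_cost:nintedanib --lo 0 --hi 112357`
(break-even annual price at the WTP). Everything is also available as
library functions (`ipfcea.run_cohort`, `ipfcea.dominance_frontier`,
`ipfcea.run_psa`, ...), and the model structure — states, strategies,
costs, probabilities — is plain YAML, so two-arm variants or alternative
tariffs are config edits, not code changes.

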