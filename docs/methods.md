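# Methods

## Model structure

The package implements a cohort state-transition (Markov) model of
idiopathic pulmonary fibrosis with a 3-month cycle. Health states are six
percent-predicted FVC bands (90–110, 80–89.9, 70–79.9, 60–69.9, 50–59.9,
40–49.9) crossed with a binary "any prior acute exacerbation" tracker
flag, plus absorbing death — 13 compartments. Lung function never
improves; decline moves exactly one band per cycle; decline out of the
worst band is death, as is any draw from the baseline mortality hazard.

Within a cycle, events are resolved in a fixed order per living
compartment:

1. **death** — probability `or_to_probability(q0, OR_mort · m_AE)`, where
   `q0` is the baseline per-cycle death probability from the hazard,
   `OR_mort` the strategy's mortality odds ratio, and `m_AE = 1.40` for
   tracker-positive compartments;
2. **acute exacerbation** among survivors — probability
   `or_to_probability(0.0197, OR_AE)`; sets the tracker flag;
3. **one-band decline** among survivors — the band's decline probability
   through `OR_decline`, independent of the exacerbation draw.

The ordering is a modeling choice (it is not observable from published
outputs and changes results in the third decimal); it is fixed here and
documented so it can be audited. Exacerbation and decline may co-occur in
one cycle. A tracker-positive individual may exacerbate again: each event
re-incurs the episode cost and the first-cycle disutility, but the state
space records only the binary flag.

All multiplicative treatment effects are applied on the **odds scale**
(`p' = OR·o/(1+OR·o)`, `o = p/(1−p)`), including the post-exacerbation
mortality multiplier 1.40, because the source quantities are labelled odds
ratios. For the small per-cycle probabilities involved, odds-, risk- and
hazard-scale application differ only slightly; the transform is isolated
in one function (`parameters.or_to_probability`) so a hazard-scale variant
can be swapped in. The 1.40 multiplier applies permanently once the
tracker is set.

## Accrual conventions

State-at-cycle-start accounting with no half-cycle correction: everyone
alive at the start of cycle *k* accrues the full cycle's recurring cost
(annual drug price and follow-up cost divided evenly over the year's four
cycles) and `Δt × utility` of their starting band. Utility is reduced by
0.140 in the cycle an exacerbation occurs and by 0.078 in every later
cycle of a tracker-positive life (floored at zero, which the base-case
values never reach); the $14,731 episode cost is charged once per event.
Death accrues nothing. Both streams are discounted by
`(1.03)^(−k·0.25)` — discounting at cycle start, 3 %/year.

## Parameters

All base-case inputs live in `src/ipfcea/data/base_case.yaml` (2020 USD,
probabilities per cycle):

| parameter | default | notes |
|---|---|---|
| cycle length | 0.25 yr | quarterly cycles |
| discount rate | 0.03 /yr | costs and QALYs alike |
| WTP | $100,000/QALY | decision threshold |
| exacerbation probability | 0.0197 /cycle | baseline, before OR |
| post-AE mortality multiplier | 1.40 (sd 0.20) | permanent once flagged |
| AE episode cost | $14,731 (sd 4,026) | per event |
| follow-up cost | $12,291/yr (sd 710) | sum of nine printed components |
| disutilities | 0.140 (0.047) first cycle, 0.078 (0.032) after | |
| band utilities | 0.8380 … 0.6634 (beta sds) | by FVC band |
| decline probabilities | 0.0320 … 0.0890 | see below |
| drug prices | $113,193 (pirfenidone), $112,357 (nintedanib) /yr | fixed |
| treatment ORs | decline 0.55/0.54, mortality 0.69/0.70, AE 1.10/0.56 | lognormal sds |

Only the range of per-band decline probabilities (3.2–8.9 % per cycle) is
published, not the band assignment. The default linearly interpolates
across the six living bands, increasing as FVC worsens — monotone
worsening is the clinically standard assumption — and every value is
overridable in the config.

The cohort's entry distribution is likewise unpublished. The default puts
the whole cohort in the 80–89.9 % band with no exacerbation history
(mid-range, trial-entry-like lung function), set by `start_band` in the
config. This choice materially affects absolute lifetime costs and QALYs
and should be varied in any serious reanalysis.

## Synthetic baseline hazard and calibration

Baseline (untreated) all-cause mortality in the source analysis came from
unpublished network-meta-analysis survival curves. The package substitutes
a parametric stand-in: an exponential hazard by default (one parameter,
identifiable from a single target), with a Weibull alternative for shape
sensitivity. `baseline_survival.calibrate` bisects the rate on
[10⁻⁴, 10] /yr (relative tolerance 10⁻⁶) until the symptom-management
arm's discounted lifetime QALYs hit the published 3.78; discounted QALYs
are strictly decreasing in the rate, so the bracket argument is valid.
Lifetime *cost* is never fitted — how close it lands to the published
$79,815 is an out-of-sample consistency check, reported alongside the fit.
The calibrated rate is frozen into the packaged config so downstream runs
are deterministic.

**What the stand-in does and does not preserve.** Calibration pins the
reference arm's QALY total, but a constant (memoryless) hazard cannot
reproduce the *shape* of real IPF survival, whose hazard rises steeply
with time and disease duration. That shape governs how much a lifelong
mortality/decline odds ratio extends life: multiplying a constant
per-cycle death odds by OR ≈ 0.7 stretches life expectancy roughly like
1/OR, whereas on a steeply increasing hazard the same OR shifts survival
only modestly. Under the exponential stand-in the treatment arms therefore
gain substantially more QALYs (the acceptance script computes ≈ 1.5
incremental QALYs for nintedanib) than the published ≈ 0.37, the
symptom-management cost lands below the published figure (less lifetime
accrued under a thinner survival tail at matched QALYs), and the
break-even drug prices come out a few-fold higher than the published
≈ $7,000/yr, though of the same order and with every qualitative
conclusion intact: pirfenidone off the frontier, ICERs several-fold above
$100,000/QALY, symptom management the chosen strategy. Tests that depend
on these absolute lifetime figures are written as property checks for
exactly this reason; one consistency check (symptom-management cost within
±15 % and nintedanib's QALY gain within ±0.10 of the published values
after QALY-only calibration) is retained verbatim and fails under the
exponential stand-in — an informative negative result about the
one-parameter family, not a defect of the cohort engine, which the
microsimulation oracle validates independently.

## Numerical choices

- **Lifetime totals.** With a time-invariant hazard the per-cycle kernel
  is a constant substochastic 12×12 matrix `T` over living compartments,
  and infinite-horizon discounted totals are evaluated exactly as
  `w·(I − βT)⁻¹x₀` with `β = 1.03^(−0.25)`. The iterative recursion (used
  for traces, finite horizons, and time-varying hazards) stops when living
  mass < 10⁻⁹ and errors out past 200 years; the two routes agree to
  ~10⁻¹⁰ relative and are cross-checked in the tests. The solve makes a
  10,000-draw PSA a seconds-scale computation.
- **Microsimulation oracle.** A vectorized per-individual walk through the
  identical event tree, fully seeded (`numpy.random.default_rng`),
  reporting Monte-Carlo standard errors; used to validate the cohort
  recursion, never as the primary engine.
- **Dominance.** Strong dominance (costlier, strictly less effective)
  first, then extended dominance (interior frontier points whose ICER is
  not below the next segment's are removed iteratively). Cost ties break
  toward higher QALYs, then name order; an exact duplicate (cost, QALY)
  point is marked dominated. Frontier selection at a WTP uses the
  sequential-ICER rule and is tested to agree with net-monetary-benefit
  maximization on randomized instances.
- **PSA.** Parameters are sampled independently (no correlation structure
  is published) on the natural scale via moment matching: beta
  `α = m(m(1−m)/s² − 1)`, `β = α(1−m)/m` for utilities and disutilities;
  lognormal `σ² = ln(1+s²/m²)`, `μ = ln m − σ²/2` for ORs, costs, and the
  1.40 multiplier. Printed "(sd)" values are taken as natural-scale
  standard deviations. An sd below 10⁻¹² is treated as a point mass.
  Inputs without a published sd (drug prices, decline probabilities, the
  0.0197 exacerbation probability) and the calibrated baseline hazard stay
  fixed — the latter is a documented limitation, since baseline-survival
  uncertainty is surely not zero. Each joint draw is applied to all arms
  simultaneously; invalid draws are redrawn (with an error if >10 % are
  rejected). The default is 10,000 draws; CEAC ties are split equally; the
  default WTP grid is $0–5M in $50k steps.
- **Threshold search.** A 17-point coarse scan verifies the WTP-chosen
  strategy switches at most once over the bracket, then bisection to 10⁻⁴
  relative tolerance on the parameter. Lifetime cost is exactly linear in
  an annual drug price, so price thresholds have a closed form that the
  tests use as an analytic oracle.

## Known limitations

- Absolute lifetime outcomes inherit the synthetic baseline hazard and the
  assumed entry band; only the desk-checkable arithmetic on published
  lifetime values is exact (see the calibration section above).
- Event ordering within a cycle, single-band-per-cycle decline, permanent
  1.40 post-exacerbation mortality, and lifelong 0.078 disutility are all
  fixed interpretations of an under-specified structure; each is isolated
  in code and documented where it is applied.
- No half-cycle correction; no treatment discontinuation, adverse-event
  dropout, transplant, combination therapy, or disease-severity
  stratification; payer-perspective direct medical costs only, in 2020
  USD with no inflation machinery.
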