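# Methods

## The generative model

A simulated trial has an objective and an introspective layer.

**Objective layer (central bottleneck).** Six stage durations per trial —
P1, C1, M1 for Task 1 and P2, C2, M2 for Task 2 — are drawn from lognormal
distributions (RT distributions are right-skewed). Task 2 central
processing cannot start before Task 1 central processing ends:

```
RT1 = P1 + C1 + M1
RT2 = max(SOA + P2, P1 + C1) + C2 + M2 − SOA
```

Event times are anchored to the trial frame: `t_S1 = foreperiod` (1000 ms),
`t_S2 = t_S1 + SOA`; the frame ends 1000 ms after the last response, and
that whole interval is what the timeline represents.

Default stage moments (mean ± SD, ms): P1 90±20, C1 300±60, M1 150±30,
P2 90±20, C2 250±50, M2 150±30. These put simulated RT1 near 550 ms, the
PRP effect near 250 ms at SOA 50 vs 1250 ms, and the inter-response
interval far enough above 100 ms that natural response grouping is rare
(~0.5%), all in the regime the task produces in practice. A 2% chance of
an attentional lapse adds an exponential (mean 300 ms) delay to a central
stage, giving the slow right tail that makes a 3-SD exclusion stage do
real work (~2% of correct trials). Participants differ by a stable
lognormal speed factor (SD 0.08 on the log scale) and a stable
introspective-noise factor (SD 0.25).

**Introspective layer.** Three models turn true event times into marker
placements (all markers are clamped to the timeline ends before encoding
to pixels; positions are continuous, not snapped to ticks):

* `veridical` — true times plus i.i.d. Gaussian noise (scale `sigma`);
  the null model for recovery tests.
* `conscious_bottleneck` — the reported S2 time is
  `max(t_S2, t_S1 + P1 + C1)`: S2 cannot be perceived while Task 1 is
  centrally processed. At short SOA this removes (indeed slightly
  reverses) the SOA effect on iRT2, so the awareness ANOVA returns a
  blind-spot verdict.
* `memory` — marker time = (1−λ)·true + λ·(evenly spaced position over
  the trial), plus Gaussian noise with scale
  `sigma_base(order) · exp(−β_gap·√gap − β_soa·[SOA long])`. The
  compression term produces order-preserving but structure-less reports;
  the noise term encodes the working-memory account: more time between
  the central events, or a long SOA, leaves more room for encoding and
  rehearsal, and an auditory event sequence (VA order: S2, R1, R2 are all
  auditory) is retained better than a mixed-modality one (AV order).

Memory defaults: `sigma_base_AV = 280 ms`, `sigma_base_VA = 90 ms`,
`β_gap = 0.03 per √ms`, `β_soa = 0.35`, `λ_AV = 0.20`, `λ_VA = 0.08`.
Only the *directions* of these effects are empirically constrained, so the
defaults were calibrated once, by simulation, to reproduce the published
sign pattern of the mixed-model estimates (negative modality-order, SOA
and central-gap effects; positive modality-order interactions) at study
scale; magnitudes are not targets. Because the gap/SOA modulation is
multiplicative in the noise scale, the smaller VA base noise automatically
attenuates gap and SOA effects in VA — the interaction pattern — without
extra parameters.

Contamination: per-sub-task errors are independent Bernoulli draws
(default 0.062 per sub-task ≈ 12% of trials with an error in either);
grouped responses force the inter-response interval below 100 ms (possibly
reversed); unmoved-marker trials leave all four markers at the central
pixel. One named RNG per dataset; the seed is recorded in the YAML sidecar.

## What the simulator does and does not emulate

It emulates bottleneck-structured RTs over SOA conditions, two modality
orders, realistic contamination, and introspection noise that depends on
modality order, SOA and central gap. It does **not** emulate the
per-experiment difficulty manipulations, response-key mappings, sequential
effects, learning across blocks, or the (unknown) true generative process
behind human timeline reports. Consequently, passing recovery tests shows
the *pipeline* is correct and the study design is informative for these
models; it does not validate the memory account against human data. Two
known gaps: (1) under the memory model the mean-level ANOVA on AV
simulations still detects the PRP effect (the mean-level blind spot is
produced by the conscious-bottleneck model, not the memory model, whose
marker noise is mean-zero); (2) VA vincentile profiles are attenuated
rather than perfectly flat, again because the gap modulation is
multiplicative.

## Analysis conventions

* **Timeline codec.** Linear map between `[0, timeline_px]` and
  `[0, trial_duration_ms]`; pixel 0 is frame onset. Default timeline
  length 1000 px (the physical length is only known in visual degrees, so
  the pixel scale is a free choice that cancels out of every statistic).
* **Exclusion cascade.** Errors (either sub-task) → RT outliers (RT1 or
  RT2 beyond mean ± 3 sample SD of the participant × condition cell,
  single pass, cells with < 2 trials skipped with a warning) → grouped
  responses (signed IRI < 100 ms, strict). Each stage's percentage is
  reported against the set it saw; the order is enforced. Participant
  screening (error rate > 25%; grouped or unmoved percentage > 3 SD above
  the sample mean, with |IRI| < 100 ms for the grouped screen) flags but
  never drops.
* **Radian statistic.** `rad = atan((iS2 − iR1)/(iR2 − iS1))` in pixel
  space; the objective radian encodes the true times to the same trial's
  timeline so both slopes share one geometry. A vertical line with
  nonzero numerator maps to ±π/2; an undefined line (both points
  coincide, which includes all four markers equal) is degenerate and is
  removed before modelling rather than raised as an error.
* **Awareness ANOVA.** Shortest and longest SOA only; cell means per
  participant are unweighted. The verdict is `awareness` iff the
  SOA × Task interaction has p < .05 *and* the (short − long) effect on
  iRT2 exceeds the one on iRT1. With two-level factors sphericity is
  trivial (ε = 1); a generic Greenhouse–Geisser ε is provided for the
  three-SOA variant. Error bars are Cousineau-normalised cell SEs
  inflated by Morey's √(J/(J−1)); the factor is applied regardless of the
  between-participant spread, per the formula. For designs where S1/R1
  markers were fixed in place, `cell_means(task1_source="objective")`
  substitutes the objective RT1.
* **Mixed model.** Dependent √∆rad; fixed effects: modality order (VA vs
  AV baseline), SOA as a two-level factor (long vs 50 ms baseline),
  √central gap, and all two-way interactions. Random structure: intercept
  and √gap slope with correlation over participant × SOA groups (three
  covariance parameters — the count the random-structure likelihood-ratio
  test, df 3 vs OLS, implies). Estimates are REML; model selection
  compares ML fits with and without each term (χ², df 1). Optimiser:
  statsmodels default (BFGS) with a Powell retry on non-convergence —
  this reproduces lme4/lmerTest optima to ~1e-4 on well-identified data
  (tested against an Rscript oracle). A singular random-effects
  covariance triggers a warned refit with independent intercept and
  slope. CIs are Wald (±1.96 SE); p-values are Wald z — a deliberate
  asymptotic stand-in for Satterthwaite-df t tests, indistinguishable at
  trial-level sample sizes (10⁴ observations, ~160 groups).
* **Vincentiles.** Per participant × modality order × SOA, trials sorted
  by central gap are split into 5 equal-count bins (remainders to the
  leading bins); raw ∆rad and gap are averaged per bin, then across
  participants, with Morey SEs per panel.
* **Clustering.** Shape = marker quadruple / timeline length of
  non-degenerate trials; K-means (scikit-learn) with 50 restarts, k
  chosen by the analyst with an inertia profile over k = 2–10. A cluster
  is flagged "S2 tied to R1" when the median |iS2 − iR1| is below 0.3 of
  the median marker span — below the ~0.33 an evenly spread report
  produces, and comfortably above the ~0.2 a bottleneck-limited report
  leaves (the reported S2 trails R1 by about one motor stage).

## Problem sizes

Study-scale simulations use 5 experiments (2 AV + 3 VA) × 16 participants
× 144 trials (~11.5k trials). The repeated checks use 200 replicate
experiments for ANOVA model discrimination and 100 replicate studies for
mixed-model sign recovery in the test suite, and 50/20 replicates in the
acceptance script; these sizes give stable rate estimates while keeping a
full run in the minutes range on one core.

## Limitations

* No loader for externally deposited datasets is included; analyses run
  on data in the tidy CSV schema (the simulator emits it, and real data
  can be harmonised to it by the user).
* Modality order is between-subjects in the emulated design, so its main
  effect rides on participant-level variance.
* The memory model is one operationalisation of a verbal account; its
  parameter values are package defaults, not estimates from human data.
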