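# Methods

## The screen and its data model

One 96-well plate carries one chemical for one developmental stage: seven
half-log concentrations plus an in-plate water control, one concentration
per row, 12 animals per row, one animal per well. Experiments run in
duplicate with the row assignment cyclically shifted down three rows in
the second run (edge-effect control), giving n = 24 per concentration per
stage. Assessments happen on days 7 and 12 of exposure; the heat
(scrunching) assay only on day 12. The analysis unit is the
`WormRecord` — one animal-day observation with viability, shape and
stickiness labels plus trajectory references — and the `Trajectory`:
uniformly sampled 2-D positions and body lengths inside a circular well,
labeled by assay phase.

Phototaxis assay: 60 s red ("dark 1"), 120 s blue ("light"), 120 s red
("dark 2"); planarians are blind to red light. Heat assay: 510 s on a
peltier set to 65 °C and switched to 54 °C at 330 s (recorded as metadata;
the water temperature itself is not modeled).

## Endpoint definitions

Thresholds follow the screening platform's conventions; where the
platform's exact detector is proprietary to the rig, the definition here
is a documented stand-in with the same semantics (flagged below).

| endpoint | definition | class | default tail |
|---|---|---|---|
| lethality | manual label; dead animals excluded from everything else | binary | increase |
| body_shape | manual abnormal-shape label (pass-through) | binary | increase |
| stickiness A/Z | stuck/unstuck under plate shaking before/after phototaxis; the day-specific RPMs (1097 adult d7 / 1200 regenerating d7 / 1350 d12) are metadata only | binary | increase |
| phototaxis | mean speed in the second light minute ([60 s, 120 s) of the phase, half-open) ÷ mean dark-1 speed, both floored at 0.1 mm/s; scored positive iff the ratio strictly exceeds 1.1 | binary | decrease |
| speed | mean *gliding* speed in dark 2, excluding resting frames (< 0.2 mm/s); 0 + flag when every frame rests. An all-frame-mean mode exists behind a flag | normal | decrease |
| resting (dark, blue) | 100 × fraction of frames < 0.2 mm/s | skewed | increase |
| locomotor_bursts | maximal episodes ≥ 1.5 mm/s sustained ≥ 1 s over the whole assay (stand-in thresholds, config-exposed) | normal | two-sided |
| anxiety | occupancy of the outer annulus (width 25% of the radius) ÷ its area fraction, so 1.0 = no wall preference (stand-in) | skewed | two-sided |
| scrunching | ≥ 3 consecutive body-length oscillation cycles, peak-to-trough ≥ 20% of median length, period 1–6 s, on a 0.6 s moving-average-smoothed series (stand-in detector) | binary | decrease |
| ns_rate | 1 / latency to the first detected oscillation peak; 0 when none | normal | two-sided |
| ns_strength | mean normalized peak-to-trough amplitude over detected cycles; 0 when none | normal | two-sided |

Endpoint → class assignment is a fixed lookup rather than a per-dataset
normality inspection: it is deterministic and testable, and matches the
families the tests assume. Tails are configurable per endpoint; the
defaults encode the expected direction of toxicity (less movement, more
resting, more deaths) and leave exploratory endpoints two-sided.

## Statistical decision tree

Per chemical × stage × day, always against the in-plate control:

1. **Lethality**: one-sided Fisher exact per concentration,
   Benjamini–Hochberg (BH) across the seven concentrations; adjusted
   p < 0.05 defines the *lethal set*, excluded from every other endpoint.
2. **Binary endpoints**: Fisher exact + BH within the endpoint's
   concentration family. The BH family is the concentrations within one
   endpoint × condition (the narrowest reading of per-endpoint
   correction; family scope is a documented choice).
3. **Normal-class endpoints**: Welch's heteroscedastic one-way ANOVA
   (Satterthwaite denominator df). Only when the omnibus p < 0.05 does the
   Tamhane–Dunnett-style post hoc run: Welch t per comparison, family-wise
   adjusted on the Monte-Carlo null of the maximum of independent t
   variates with the per-comparison dfs (default 10⁵ seeded draws; MC
   standard error at p ≈ 0.05 is ~0.0007). Independence across
   comparisons ignores the positive correlation induced by the shared
   control, which makes the adjustment slightly conservative. Groups with
   zero variance (e.g. zero bursts for every animal at a crushing dose)
   cannot be t-tested and are excluded from this branch's family.
4. **Skewed endpoints**: Kruskal–Wallis omnibus (tie-corrected; all-equal
   input defined as H = 0, p = 1), gating a Dunn many-to-one z test on the
   pooled mid-ranks with BH adjustment.

BH is the standard step-up; note it is *not* idempotent (re-adjusting an
adjusted list can change it), so the tested invariants are permutation
invariance, monotonicity in rank order and the cap at 1. Welch's F equals
the classical F exactly only for two equal-sized groups (the k > 2
denominator correction is strictly > 1); the equivalence oracle uses that
construction.

## Relevancy, consistency, dependence, LOEL

Statistical significance alone is not a hit:

* **Relevancy cutoffs** come from 10 independent control populations
  (n = 24 each, per stage). Each population is summarized with the
  class-matched statistic — mean (normal), median (skewed), proportion
  (binary) — and the interval is mean ± 2 SD of those summaries for
  normal-class endpoints, the 5th–95th percentile (linear interpolation)
  otherwise. Whether cutoffs should use per-population summaries or
  pooled per-animal scores is ambiguous in the field; both are
  implemented, per-population is the default (binary endpoints always use
  per-population proportions, since pooled Bernoulli quantiles are
  degenerate). A summary exactly on a bound is *inside* (ties break
  toward exclusion, conservatively).
* **Consistency**: both runs must deviate from their own in-plate control
  in the same direction and (strict default) each run's summary must
  itself be outside the cutoffs; a weaker same-direction-only mode is a
  flag. With a single run the flag is not evaluable and is reported as
  such with a warning.
* **Concentration dependence**: a hit at c counts only if every tested
  sublethal concentration above c is also a hit (or c is the highest).
  Isolated low-dose hits are discarded; the rule is a formalization the
  screen's narrative applies implicitly.

`final_hit` is the conjunction of the four flags; the per-endpoint LOEL is
the lowest final-hit concentration and the overall LOEL the minimum over
endpoints (lethality included, with the filters applied to per-run death
proportions like any binary endpoint).

## Dose arithmetic conventions

Defaults: glyphosate acid 169.07 g/mol, isopropylamine salt 228.18 g/mol
(standard chemistry, configurable). ae conversions report 3 significant
figures. Co-ingredient equivalents *truncate* to 2 significant figures:
truncation — not rounding — reproduces the conventional printed diquat
dibromide series (0.0092 … 0.92 … 9.2 mg/L; rounding would print 0.93 and
9.3). For products whose printed equivalent series is not derivable from
the salt arithmetic (the pelargonic-acid case: the label composition
implies ≈228 mg/L at 1 mM ae where 282 mg/L is printed, an implied ae
fraction of 1.2% rather than the theoretical 1.48%, basis unstated), the
`Formulation` accepts an explicit mg-per-mg-ae equivalence ratio; that
series reproduces verbatim at 3 s.f. when computed from the unrounded
half-log concentrations. Neither behavior is asserted as chemically
correct; both are available.

## Synthetic plate simulator

The generator's defaults *are* the study conditions: 8 × 12 plates, 7
half-log doses (1–1000 µM ae) + control, duplicate runs shifted 3 rows,
n = 24 per concentration per stage, 10-population control banks. Values
the screen's description does not fix are chosen once as field-realistic
defaults and documented here: 5 Hz sampling, 3.2 mm well radius (standard
96-well geometry), adult gliding ≈ 1 mm/s vs ≈ 0.55 mm/s for regenerating
tails, adult rest bouts ≈ 2.5 s every ≈ 25 s of gliding (more rest for
regenerating animals), heading random walk with a moderate wall-following
bias (planarians are thigmotactic), blue-light speed factor 1.6 for
photo-competent animals, body length 4 mm (adult) / 2 mm (tail),
scrunching amplitude 30% peak-to-trough with a 3 s period after a ~90 s
latency.

Mechanics: speed follows a two-state rest/glide Markov chain; position
integrates speed along the heading; the wall reflects both position and
heading. Dose dependence enters through per-effect Hill curves
(baseline, max effect, EC50, Hill slope; per-stage and per-day overrides)
for lethality, shape and stickiness probabilities, photo- and
scrunch-competence, speed/rest multipliers and heat-response latency.
Stickiness is simulated directly as a Bernoulli outcome (no shaking
physics); abnormal shape is a label optionally coupled to reduced speed
to mimic the correlated locomotion defects seen with real formulations.
Everything derives from one integer seed via spawned child generators, so
identical (config, seed) gives identical datasets.

What the simulator does *not* emulate: tracking noise and identity loss,
well-meniscus optics, temperature gradients during the heat ramp,
inter-plate batch effects beyond what independent seeds produce, and any
morphology beyond the body-length scalar. Passing tests therefore
demonstrate that the *analysis* is correct and well-calibrated on data
satisfying its assumptions — not that the rig's detectors are reproduced
numerically.

## Bulk lethality GLM

Well-level dead/total counts are modeled as binomial with logit link in a
full factorial of concentration (ordered categorical — only 3–4 levels
are tested, so no dose-metameter is imposed), stage, and exposure type or
species; wells are the replication unit. Term significance is a
likelihood-ratio test against the model with the term *and every
higher-order interaction containing it* removed — dropping a main effect
alone leaves the design span unchanged (the interaction coding
re-expands) and would make the test vacuous. Complete separation is
detected (fitted probabilities pinned at 0/1 with diverging coefficients)
and a Firth/Jeffreys-penalized IRLS fit is attached as the bias-reduced
fallback, flagged and logged. A Poisson log-linear parameterization is
available behind a flag.

## Enzyme kinetics

The linear portion of a 10-min, 1-min-resolution absorbance trace is the
contiguous window of ≥ 4 points maximizing R² (ties: longer window, then
earlier start) — a documented operationalization of "the linear portion".
Slopes are normalized by protein concentration; technical triplicates are
averaged per biological replicate *before* statistics, so n = 4
experiments are the analysis units (the alternative — entering technical
replicates — is deliberately not the default, as it would treat pipetting
replicates as biological ones). Percent activity is scaled to the
same-experiment control mean (= 100% by construction). Normality uses a
Lilliefors test with a seeded Monte-Carlo null (default 10⁴ draws;
p = (1 + #{D* ≥ D})/(n_mc + 1)); group comparison is a classical one-way
ANOVA gating Dunnett's test (equicorrelated multivariate-t, seeded).

## Problem sizes and numerical tolerances

The test suite and the reproduction script run the pipeline at the full
per-plate geometry (96 wells, duplicate runs, both stages, 10-population
control banks). Replicate counts are chosen for stable statistics at
modest runtime: 500 null replicates per statistical branch for
false-positive calibration (Monte-Carlo s.e. ≈ 0.01 at a 0.05 rate), 50
seeded replicates for the formulation-scenario LOEL recovery and 20 for
the lethality-only scenario, 40 replicates for the positive-control
Dunnett power and the GLM power checks; the reproduction script uses
somewhat smaller counts (12/8/300/25/40) and reports each n alongside the
value. Tamhane–Dunnett uses 10⁵ MC draws in production and 2–4 × 10⁴
inside replicated simulations. Floating-point oracle equivalences
(Fisher vs enumeration, Welch k = 2 vs classical, BH vs hand step-up) are
asserted at 10⁻⁹–10⁻¹² absolute.

## Known limitations

* The Tamhane–Dunnett adjustment ignores the shared-control correlation
  (slightly conservative) and is Monte-Carlo, so adjusted p-values carry
  ~10⁻³-scale jitter across seeds.
* The concentration-dependence rule is strict (suffix-closed hit sets); a
  real non-monotone dose response would be filtered out.
* The simulator's Hill-curve effects act independently per endpoint;
  real toxicants induce correlated syndromes beyond the optional
  shape→speed coupling.
* Separation handling reports Firth coefficients but the term-drop LRT
  still uses the ordinary likelihoods; penalized-likelihood ratio tests
  are not implemented.
* LOEL granularity is the tested half-log grid; no interpolation or
  benchmark-dose modeling is attempted.
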