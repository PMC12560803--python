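# Methods

## Behavioral pipeline

### Protocol and preprocessing

The light–dark transition assay is 3720 s at 1-s resolution: dark
acclimation [0, 1200) at 0 lux, light [1200, 2400) at 13,238 lux (phases
L1 [1200, 1800) and L2 [1800, 2400)), dark [2400, 3720) at 0 lux (phases
D1 [2400, 3000) and D2 [3000, 3600)). Each named phase is summarized as
five consecutive 120-s distance sums; the acclimation period and the final
120 s of the dark period are not binned — the five-sums-per-phase
convention fixes the phase length at 600 s, which leaves the last 2 min of
the 22-min dark period unaccounted, and we take D1/D2 as the first two
600-s blocks. Larvae flagged dead, malformed, or with an uninflated swim
bladder are excluded before any statistics; the exclusion report counts
larvae per reason.

Bins are scaled into (0, 1) by dividing by M = 1.001 × the maximum 2-min
sum over *all* larvae of the experiment. We read the scale as one constant
per experiment rather than one per larva: per-larva scaling would destroy
cross-group comparability of the marginal means (a hyperactive larva's
bins would be shrunk by its own maximum). The per-larva alternative
remains available by grouping the input before calling `compute_scale`.
Exact zeros are nudged to ε = 1e−6 (configurable); values equal to M
cannot occur because of the 1.001 factor.

The visual startle response (VSR) is the summed distance in the 3 s at and
after each transition second: seconds 1200–1202 (dark→light, VSR1) and
2400–2402 (light→dark, VSR2). Sub-second conventions are not meaningful at
1-s resolution.

### The beta mixed model

Scaled bins are modeled as y ~ Beta(μφ, (1 − μ)φ) with

    logit(μ) = f(time) + treatment + phase + treatment:phase + b_animal

* `f`: cubic B-spline smooth, basis size 10, second-order difference
  penalty, sum-to-zero constraint absorbed by an orthonormal null-space
  projection. The penalty null space (linear-in-coefficient-index
  functions) is unpenalized, as usual for P-splines.
* `b_animal ~ N(0, σ_b²)`: random intercepts implemented as
  ridge-penalized coefficients with penalty 1/σ_b² (the
  smooth-as-random-effect equivalence), so the whole model is one
  penalized likelihood.
* Factors use treatment (reference-level) coding with levels in order of
  first appearance.

Coefficients maximize the penalized beta log-likelihood by Fisher scoring
(expected-information Newton steps with step halving; relative tolerance
1e−8, at most 200 iterations; deterministic initialization from the
empirical-logit least-squares fit). A fit that exhausts iterations is
returned flagged `converged=False` and the pipeline refuses to run post
hoc on it. The smoothing parameter λ, the random-intercept variance σ_b²,
and the precision φ are selected by maximizing a Laplace-approximate
(REML-type) marginal likelihood over (log λ, log σ_b², log φ) with
L-BFGS-B (bounds log λ ∈ [−8, 18], log σ_b² ∈ [−10, 5], log φ ∈ [−2, 10]),
warm-starting the inner fit between evaluations. The coefficient
covariance is the inverse penalized expected information (the usual
Bayesian posterior covariance of penalized fits).

Because assay phase is a step function of time, the time smooth and the
phase main effects are partially confounded (concurvity); the smoothing
penalty resolves the ambiguity but phase main effects should be
interpreted jointly with the fitted smooth. The treatment × phase
interactions — the quantities of scientific interest — are unaffected,
since all treatment groups share the same time grid, and the parameter
recovery checks target them.

An optional AR(1) working correlation on within-larva bin sequences
(ordered by time) is available for the serial dependence of consecutive
bins; it replaces the independence working model in the scoring step (the
update becomes a GEE-type quasi-score, converged on step size) and is
recorded in the fit metadata. It is OFF by default.

### Startle model

VSR sums are fitted with `vsr ~ treatment + startle_phase + (1 | animal)`
by REML (statsmodels MixedLM; optimizer fallback chain bfgs → powell →
nm). Rank-deficient fixed-effect designs raise an error naming the aliased
columns.

### Post hoc

EMMs evaluate the linear predictor on the treatment × phase grid with the
smooth at its average over the observed time grid (the centered basis
makes this the data average) and the random intercept at 0; SEs are
L V Lᵀ. For the VSR model the comparisons are between treatments marginal
to startle phase (the model has no interaction, so within-phase and
marginal treatment differences coincide). Inference is on the z scale —
penalized fits do not carry a clean residual df, and this choice is
recorded in the fit metadata.

All pairwise contrasts receive a single-step max-|z| familywise
adjustment: the adjusted p of contrast i is P(max_j |Z_j| ≥ |z_i|) under
the joint normal null with the estimated contrast correlation, evaluated
by Monte Carlo with a fixed internal seed and 1e5 draws. This is the
multivariate-normal analogue of a Tukey HSD and remains valid for
unbalanced families where the studentized-range shortcut is not (the
studentized-range variant is the other defensible choice here). With
a single contrast the raw two-sided p is returned exactly; adjusted p is
floored at raw p. Compact letters are assigned by insert-and-absorb: two
cells share at least one letter iff their adjusted p ≥ α (α = 0.05).

## MEA pipeline

Order of operations: (1) retain units with spike counts > 0 in both
baseline segments 1 and 4; (2) compute the 2.5th/97.5th
linear-interpolation percentiles of each baseline over that active
population and retain units inside both windows, bounds inclusive (integer
counts are compared to the interpolated bounds without rounding); (3)
classify each unit from segments 1–3: a strict decrease under GABA
followed by a strict increase under the well's antagonist → GABA_A
(bicuculline well) or GABA_B (saclofen well); ties are conservatively
unclassified; (4) normalize each unit's counts to its total over the
analyzed segments 4–11 — the 0 µM reference plus the seven PFOS
concentrations; segments 1–3 serve classification only (normalizing over
all 11 segments is available via the paradigm object); (5) per class,
Friedman test over units × 8 conditions (within-unit midranks,
tie-corrected chi-square, df = 7), Conover many-to-one statistics versus
the 0 µM reference on (n−1)(k−1) df, two-sided, and BH adjustment over the
7 comparisons.

Note that total-count normalization is compositional: a genuine rate
increase at high concentrations necessarily depresses the fractions at all
other conditions, so low-concentration "decreases" relative to 0 µM can be
induced by a high-concentration effect. This is a property of
total-count normalization itself, not of this implementation.

## Synthetic data

### Behavior

`simulate_bins` draws from the generative counterpart of the beta model:
logit(μ) = intercept + phase effect + treatment effect + interaction +
sinusoidal time trend + per-larva N(0, σ_b²) intercept, y ~ Beta(μφ,
(1−μ)φ). Defaults encode a two-arm acute-exposure experiment: 24 larvae
per group (replicate counts in such assays typically run 21–45), intercept
−1.0 (activity well below the per-experiment maximum), phase effects
(L1 0, L2 −0.1, D1 +0.8, D2 +0.6) reflecting dark-phase hyperlocomotion,
a +1.0 logit dark-phase interaction for the exposed arm, trend amplitude
0.3, σ_b = 0.5, φ = 20.

`simulate_trace` exists to exercise the binning/VSR/exclusion code: 1-s
gamma-distributed distances (shape 2) whose mean follows the illumination
context (defaults 0.10/0.15/0.35 cm/s for acclimation/light/dark), a
lognormal per-larva activity multiplier, multiplicative treatment effects
per phase, a startle burst summing to 6 cm spread 0.5/0.3/0.2 over the 3 s
after each transition, and viability flags at rate 0.02. Second-level
marginals are not calibrated to the beta bin distribution — trace-level
realism (burst dynamics, thigmotaxis, frame-level noise) is out of scope,
so passing trace-level tests shows the bookkeeping is right, not that the
generator mimics real larvae.

### MEA

`simulate_paradigm` draws NB1 counts (variance = mean × (1 + dispersion),
gamma–Poisson mixture) around per-unit lognormal baseline rates (median
200 spikes/15-min segment, log-SD 0.5, dispersion 5 → Fano factor 6, CV
≈ 0.17 at the median). Responsive units are suppressed to gaba_effect ×
baseline in segment 2 and rebound by antagonist_effect under their
matching antagonist in segment 3 (a mismatched antagonist leaves the
suppression in place); segment 4 returns to baseline; segments 5–11 scale
by the per-concentration PFOS factors (default 1.0 = null). Inactive
units emit zeros to exercise the activity filter. The NB1 count model is
the generator's own assumption (nothing in the assay pins one down) and
is recorded in the output metadata.

A flat-rate non-responsive unit satisfies the decrease-then-increase
classification rule with probability ≈ 1/3 (its segment-2 count is the
minimum of three exchangeable draws), independent of the noise level, so
the classification rule's specificity against such units is bounded near
2/3 no matter how strong the true effects are. This is a property of any
threshold-free decrease-then-increase rule; we keep the rule as the assay
defines it and report specificity honestly rather than adding an
effect-size threshold the rule does not contain.

## Problem sizes and numerical conventions

* Acceptance-style checks: interaction recovery and CI coverage over 50
  simulated experiments (2 × 24 larvae); familywise letter error over 200
  null experiments (2 × 8 larvae); classification on 1000 simulated units;
  null BH discovery rate over 1000 experiments of 20 units; Friedman
  type-I over 2000 such experiments.
* Exact Mann–Whitney enumeration is used for n1 + n2 ≤ 20 tie-free
  samples (dynamic program over rank-sum counts); otherwise a midrank
  normal approximation with tie-corrected variance, without continuity
  correction.
* Sample quantiles use the linear-interpolation estimator with plotting
  position (k−1)/(n−1) (numpy's "linear" method).
* All simulators are bit-reproducible given their seed; the Tukey-style
  adjustment uses a fixed internal seed so letters are deterministic for
  a given fit.
* Iterative fits: relative tolerance 1e−8, ≤ 200 inner iterations, ≤ 100
  outer L-BFGS-B iterations.

## Known limitations

* The beta GAMM supports one smooth and one random-intercept factor — the
  assay's model family — not arbitrary GAMM formulas; no Bayesian fitting.
* z-based (not t-based) post-hoc inference is mildly liberal in very small
  families; the null familywise check bounds the practical effect.
* The Friedman/Conover p-values are chi-square/t approximations; at very
  small block counts (n ≤ 4) they deviate from the exact permutation null
  by up to a few hundredths, as the permutation-oracle tests document.
* The trace-level simulator's per-second marginals are not calibrated to
  the bin-level beta distribution (by design; see above).
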