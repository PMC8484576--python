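# Methods

## The decomposition

A factorial experiment with two drivers E1, E2 is summarised per 2×2
sub-design by the four cell means R(0,0), R(a,0), R(0,b), R(a,b) on a
chosen analysis scale.  The state-space coordinates are the single-driver
effects f1 = R(a,0) − R(0,0) and f2 = R(0,b) − R(0,0) and the interactive
deviation g = R(a,b) − (f1 + f2) − R(0,0).  Algebraically g is the
interaction contrast r11 − r10 − r01 + r00 of the 2×2 table and equals four
times the interaction coefficient of a saturated two-way linear model with
sum-to-zero coding; both identities are enforced by tests against an
independent least-squares oracle.  Multi-level designs are decomposed into
(m−1)(n−1) 2×2 groups sharing one reference cell, enumerated driver1-major
for reproducible output order.

The decomposition is exact and assumption-free; the statistical content
enters through (i) the scale on which means are taken and (ii) the
uncertainty attached to g.  `se_g` is the quadrature sum of the four
cell-mean standard errors, which assumes independently estimated cells; it
is approximate when replicates are paired across cells.

### Scales and boundary proportions

Three scales are supported: raw, natural log and logit.  The log scale
turns a multiplicative joint-effect null model into an additive one, so
exactly multiplicative data give g = 0 on the log scale and g ≠ 0 raw (a
tested property).  Replicate values are transformed first and then
averaged; the alternative order (transform the averaged means) changes g,
and the chosen order keeps cell means consistent with the linear models
used for testing and selection.  Survival proportions of 0 or 1 are outside
the log/logit domain; when per-replicate trial counts n are available each
proportion x is shrunk to (x·n + c)/(n + 2c), c = 0.5 by default — the
empirical adjustment (x·n + 0.5)/(n + 1).  Without trial counts no
adjustment is applied (an n-free version would distort interior values) and
boundary values raise an error naming the offending row.

### Classification

A point is *additive* when the criterion on g includes 0 — by default the
interval |g| ≤ k·se_g with k = 1.96, or an externally supplied
interaction-test p-value against α.  Non-additive points are labelled by
direction: with both single effects positive, g > 0 is synergistic and
g < 0 antagonistic; with both negative the roles reverse (more-negative g
amplifies harm).  When the single effects have opposite signs there is no
canonical amplification direction, so the label compares |r11 − r00| with
|f1 + f2| (combined effect beyond vs short of the additive expectation) and
the decision basis records that this rule was used.  A needed single-effect
sign of exactly 0 yields *indeterminate*; g = 0 exactly is additive.

## Artifact checks

Bounded responses and shared reference noise can fake interactive
structure.  Three checks are provided.

1. **Interaction F-test.**  Two-way fixed-effects model with interaction on
   transformed replicates; the interaction is tested by its Type II sum of
   squares (residual improvement over the main-effects model), computed by
   explicit least squares on the ±1 sum-coded design.  Type II is invariant
   to factor order in unbalanced 2×2 data.  Data with zero residual
   variance and no interaction signal return F = 0, p = 1 with a warning
   (a perfect-fit interaction instead returns p = 0).  statsmodels'
   `anova_lm` serves as an independent oracle in the tests.
2. **Zero-sum refit.**  The saturated sum-coded model is fitted; if the
   interaction fails the α-level test it is dropped and the cell means are
   recomputed from the main-effects fit.  The rebuilt point then has g = 0
   *exactly* — structurally, since the main-effects model contains no
   interaction contrast; the numerically computed value is asserted below
   1e-10 and then zeroed — and the original pattern is flagged as a
   suspected artifact.  When the interaction is retained the saturated fit
   reproduces the observed cell means.
3. **Spurious-correlation screen.**  Because f1, f2 and g all contain the
   reference mean, its estimation error induces correlation even under
   additive truth: with i.i.d. cell noise and no true effect variation,
   cov(g, f1) = −2σ², var(g) = 4σ², var(f1) = 2σ², hence
   corr(g, f1) → −1/√2.  The screen reports Pearson correlations of g with
   f1 and f2 across a point collection and two-sided permutation p-values
   from a seeded shuffle of g (999 permutations by default); zero-variance
   coordinates give a correlation of 0 with a warning.

## Model selection and the heatwave criteria

Factorial fixed-effects Gaussian models on the transformed response are
fitted by maximum likelihood (statsmodels OLS); all factors, including
female of origin, are fixed.  AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k
counting mean parameters plus the residual variance; it is undefined (an
error) for n ≤ k + 1.  Backward elimination proposes dropping each
removable term (one that is not a margin of another included term), orders
candidates by the AICc of the reduced model with ties broken by term label,
and resolves each drop by the hybrid rule: simple retained outright when
its AICc is lowest; otherwise complex retained when ΔAICc > 3; otherwise a
χ² likelihood-ratio test with df = Δk retains the complex model when
p < 0.05.  ΔAICc exactly 3 is routed to the LRT branch.  Every comparison
is recorded; refitting the final term set reproduces the recorded AICc.

Calibration of the null behaviour (200 simulated datasets, 2×2×3
regime×level×female design on the logit scale, no true interaction): the
regime×level interaction is retained in ≈14% of runs — the hybrid rule is
anti-conservative relative to a single α = 0.05 test because several
candidate drops are examined per round.  The property test asserts the
rate stays below 0.25 (the calibrated rate plus three Monte-Carlo standard
errors).

A *heatwave effect* requires two criteria.  Criterion 1: a retained term
couples temperature regime and temperature level, and Welch t contrasts on
transformed replicate responses show the heatwave treatment T4 differing
from both the gradual-increase T2 and the constant-high T3 at α (contrast
type and correction are an implementation choice exposed as parameters).
Criterion 2: the fraction of recorded deaths on or after the day the
temperature step is applied exceeds 0.5 ("primarily after the increase";
threshold configurable).  Missing timing records leave criterion 2 unknown
and force a false verdict with a warning.

## Simulators

**Heatwave experiment.**  Defaults mirror the study conditions: 2 species ×
3 females × 4 temperature treatments × 3 contexts × 5 replicate groups of
10–11 larvae (uniformly drawn), i.e. 180 replicate units per species.
Survivors are binomial with a logit-linear probability
logit(p) = logit(p0) + β_regime·[changing] + β_level·[high] +
γ·[changing∧high]; the logit-linear form keeps probabilities bounded and
matches the logistic analysis option.  The default effect configuration
gives the cold-adapted species a heatwave-specific drop under food
limitation (p0 = 0.80, β = −0.2/−0.3, γ = −1.8, 85% of T4 deaths after the
step) and the warm-adapted species uniformly high survival (p0 = 0.93, no
effects) — chosen so the qualitative pattern (a context-dependent heatwave
effect in one species only, survival > 80% in the other) is reproduced;
the numeric values are the package's own defaults.  Death days are drawn
as a two-point before/after-step mixture for T4 (day 1 vs uniform over the
post-step days) and uniformly over the window elsewhere.

**Temperature profiles.**  T2 ramps linearly 15→18 °C across the 6-day
window (0.5 °C/day), recorded as day-midpoint values so its daily mean is
exactly 16.5 °C, the average of a continuous ramp; T4 is a set-point step
(day 1 at 15 °C, then 18 °C) with a 6-day mean of 17.5 °C.  These two
conventions are the only pair consistent with both printed means over the
same 6-day window.  T1 and T3 are constant at the T2 and T4 means.

**Genotype panel.**  Thirteen genotypes by default, each with an (f1, f2,
g) truth from a fixed table spanning double-negative, double-positive and
opposite-direction effects with both synergistic and antagonistic
deviations (growth in arbitrary units, baseline 1.0, Gaussian noise
σ = 0.05, 3 replicates).  Noiseless output decomposes back to the truths
exactly; under noise ĝ is unbiased and its spread shrinks as 1/√n (both
tested).

**Time evolution.**  A 2×2 temperature × habitat surface over 10 time
points: the good-habitat temperature effect is a small constant (0.5),
while the interactive deviation follows a/(1 + exp(−s·(t − m))) with
asymptote 4, midpoint 5, slope 1.2 — g equals a/2 at the midpoint and is
nondecreasing in time.  Units are arbitrary; the sigmoid parameters are
package defaults.

What the simulators deliberately do not emulate: overdispersion beyond
binomial sampling, within-replicate-group correlation, temperature-
dependent development time, or the real measured survival/growth values of
any particular experiment — passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative models, not
fidelity to any specific dataset.

## Numerical and design notes

- Problem sizes in the test suite and acceptance script (e.g. 2000 null
  simulations for the type-I rate, 1000 recovery replicates, 25+25
  end-to-end repeats) were chosen to keep Monte-Carlo error well inside
  the asserted tolerances while the whole suite runs in well under a
  minute of simulation time.
- All generators consume a single `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical CSV output (tested).
- The reference treatment defaults to the first declared level of each
  driver and is overridable everywhere; classification is reference-
  dependent by construction, which is exactly why the decomposition (not
  the labels) is the primary output.
- Figures are static (PNG via the Agg backend); every figure writes a
  sidecar CSV with exactly the plotted numbers, and all numeric assertions
  in tests run on sidecars, never on pixels.
- Known limitations: no random-effects/REML machinery (all factors are
  treated as fixed), no binomial GLM (survival is analysed as transformed
  proportions in linear models), no state spaces for more than two drivers,
  and no multiplicity correction across groups beyond an optional
  Benjamini–Hochberg flag left off by default.
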