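# Methods

This note documents the models, the numerical choices behind them, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Amyloid gate

CSF abeta 1-42 in a mixed cohort is modelled as a two-component univariate
Gaussian mixture fitted by EM (own implementation: the fit exposes the full
per-iteration log-likelihood trace, which the tests assert is
non-decreasing, and canonicalizes component order by mean; scikit-learn's
mixture serves as an independent cross-check in the test suite, never as
the implementation). Initialization splits the sample at the median and
seeds the means from the 25th/75th percentiles, making the fit
deterministic for given data; convergence is a relative log-likelihood
change below 1e-8, capped at 500 iterations. Variances are floored at 1e-12
to avoid collapse onto single points.

The positivity cut-point is the inverse normal CDF at a percentile
(default 0.99) of a chosen component. Which component and which tail define
the boundary is genuinely open; the default is the 99th percentile of the
lower-mean (abnormal) component, which places the boundary at the upper
tail of the amyloid-positive distribution, consistent with "positive =
strictly below the cut-point". Both the percentile and the component are
configurable. A value exactly at the cut-point is classified negative: the
positive set is kept strict, the boundary case goes to the benign label.

## Group definitions

Reference controls: CSF abeta at or above the cut-point, APOE e4
non-carrier, cognitively normal at baseline and at every recorded follow-up
visit. Subjects with no follow-up visits count as stable (decision: absence
of evidence of progression is treated as stability, the same convention a
cross-sectional analysis necessarily applies at enrollment). Labels for
subjective memory concern count as cognitively normal. Cases: CSF abeta
strictly below the cut-point, any diagnosis. Completeness filtering demands
all nine analysis fields; exclusions are returned with reasons, never
silently dropped.

## Normalization

Markers are mapped to a scale where 0 is the control mean and +1 is one
control SD toward abnormality:

- transform: white-matter hyperintensity (WMH) volume is log2-transformed.
  A WMH volume of exactly 0 mL gets a fixed 0.01 mL offset before the log —
  small enough to leave nonzero volumes essentially untouched, large enough
  to keep the transform total. Configurable.
- direction: logical memory, whole-brain and hippocampal volume worsen
  downwards and are negated before z-scoring (equivalent to score
  inversion).
- scale: plain markers use the control mean and SD (ddof = 1).
  The three imaging volumes use W-scores: ordinary least squares of the
  transformed, aligned marker on total intracranial volume fitted in
  controls only, with the residual SD on denominator n − 2. Cases never
  enter the reference fit. A residual SD below 1e-8 of the marker's scale
  (collinear controls) is an error rather than a division hazard.

The composite Trail Making Test score is min(TMT B, 300 s) − TMT A on the
raw seconds scale; the 300 s ceiling flag is carried per subject for the
semi-partial correlation in evaluation, not used in normalization itself.

## The progression model

An *event* is one marker crossing one of its z thresholds (defaults 1, 2, 3
per marker; 6 markers × 3 thresholds = 18 events). A subtype is a
permutation of all events in which each marker's thresholds appear in
increasing order. Each marker's expected value is piecewise-linear in
stage through (0, 0), its event positions at their thresholds, and
(N, z_max) with z_max = 5 — the ceiling a marker approaches after its last
modelled event. When a marker's final event occupies the last position, the
terminal anchor still takes precedence: stage N evaluates to z_max.

Observation noise is Gaussian per marker with SD fixed at 1 — the data are
z-scored against controls, so unit noise is the natural scale; the SD is
configurable for sensitivity analyses. Stages are discrete with a uniform
prior over {0..N}; the subject likelihood marginalizes stages, and the
cohort likelihood is a C-component mixture over subtype sequences.

### Fitting

- *Greedy ascent*: relocate one event at a time to its best
  constraint-respecting position until no single-event move improves the
  (responsibility-weighted) log-likelihood. The inner loop scores all
  candidate slots of an event in one vectorised pass. Ties keep the current
  position; equal-scoring new slots resolve to the lowest index.
- *Hierarchy*: C = 1 by multi-start greedy (default 25 restarts). C → C+1:
  for each subtype, its maximum-likelihood members are split by the best of
  several random bisections, each half refitted by random-restart greedy
  and the pair polished by a two-cluster EM on the member subset; every
  resulting full-model candidate is then polished by the full-data EM
  before candidates are compared. Polishing before comparison matters: the
  immediate post-split likelihood ranks candidates poorly.
- *EM alternation*: responsibilities update fractions (mean posterior
  membership, floored at 1/(10n) and renormalized to avoid collapse);
  sequences are refitted per subtype under responsibility weights. Each
  M-step also tries one fresh random-start greedy per subtype and keeps it
  if it scores higher — relocation moves alone leave orderings stuck in
  shallow local optima. Alternation stops at a log-likelihood change below
  1e-6 or 100 rounds. A subtype that owns no subjects is re-seeded from the
  subjects worst fit by the rest of the mixture.
- *MCMC*: Metropolis–Hastings over sequences with fractions held at their
  fitted values. A proposal removes a uniformly chosen event from a
  uniformly chosen subtype and reinserts it at a uniformly chosen valid
  slot; the slot set depends only on the sequence minus the event, so the
  proposal is symmetric and acceptance is min(1, exp Δloglik). Defaults:
  100,000 iterations, 10,000 burn-in, thinning 10 (reduced in tests and the
  acceptance script; see "problem sizes"). If the chain finds a better
  basin than the EM optimum, the model is re-polished by EM from the
  chain's best state and the uncertainty samples are re-drawn around the
  refined optimum, so the point estimate never degrades.
- *Determinism*: all randomness flows from one root seed through named
  substreams (start points, splits, MCMC, cross-validation folds), so a
  fixed seed gives bit-identical models and changing one stage's draw count
  does not perturb another's.

### Assignment

Subtype posterior ∝ fraction × stage-marginal likelihood; the stage
posterior is computed within the maximum-likelihood subtype; ties break to
the lowest index everywhere. A maximum-likelihood stage of 0 marks the
subject *unsubtyped* — indistinguishable from the control reference on all
modelled markers — and such subjects carry no subtype. The stage-0 rule
(rather than a posterior-probability threshold) is a recorded decision; it
matches the interpretation of these subjects as control-like.

### Model selection

CVIC = −2 × summed out-of-fold predictive log-likelihood over seeded folds
(default 10; 5 in the reduced acceptance runs), where the predictive
density averages over the retained MCMC samples of each training fit —
an information criterion balancing accuracy against complexity should see
the posterior spread, not just the ML point. The selected C is the smallest
whose CVIC no larger model beats by at least the parsimony margin
(default 6).

### Positional variance diagrams

P[event, position] is the fraction of retained samples placing the event at
that position. The dashed low-support line starts at the first stage s ≥ 1
whose assigned-stage histogram has counts ≤ 2 at both s and s+1.

## Evaluation

Continuous group contrasts use the overall F-test of the linear regression
of the value on group membership (equivalently one-way ANOVA, via
statsmodels OLS). Categorical contrasts use the two-sided Fisher exact
test: scipy for 2×2; for 2×k an exact enumeration over fixed-margin tables
under the probability-mass rule (sum the probabilities of tables no more
probable than the observed one, with a 1e-7 relative tolerance against
float round-off), switching to a seeded multivariate-hypergeometric Monte
Carlo estimate when the candidate-table count exceeds 500,000. R's
fisher.test and scipy's 2×2 implementation served as oracles in the tests.
P-values are raw and two-sided throughout; no multiplicity correction, as
is conventional for descriptive subtype tables.

Stage–marker correlations are Pearson within subtype against the
maximum-likelihood stage; semi-partial variants first regress the marker on
its adjustment covariate (intracranial volume for volumes and WMH, the
TMT-B ceiling flag for the composite TMT) and correlate the residual.

Diagnostic progression within a horizon (default 24 months) classifies each
subject by the *worst* diagnosis recorded at visits inside the horizon:
progressed, reverted, stable, or missing when no visit falls inside. The
worst-diagnosis rule is a recorded decision — with reverting labels
possible, some tie-break is unavoidable and "ever progressed within the
window" is the clinically conservative reading. Fisher tests compare
progressed-vs-not across groups within baseline diagnosis.

## Synthetic cohorts

The generator emulates the study's structure, not its real joint
distributions:

- CSF abeta from a two-component mixture (abnormal mode N(190, 40²),
  normal mode N(343, 50.7²)); cases sample the abnormal mode truncated a
  15 pg/mL safety margin below the implied cut-point and controls the
  normal mode truncated the same margin above it, so both groups pass the
  gate later derived from their own pooled values even though that refitted
  cut-point wobbles around the generating one.
- controls sit at z = 0 with unit z-scale noise; cases get a subtype by the
  mixture fractions (or stage 0 with the configured mass), a stage uniform
  over {1..N} (a truncated-geometric option exists; uniform is the model's
  own prior and the default because the real stage histogram is
  data-determined and unavailable), and z = trajectory + N(0, noise_sd²).
- raw scales invert the normalization maps exactly: direction flips, 2^x
  for WMH, intercept + slope × TIV + residual for volumes. The TMT pair
  draws TMT A around its control anchor and sets TMT B = A + composite,
  shrinking A where needed so B stays within (0, 300]; generated subjects
  therefore never trip the ceiling, which is exercised by direct unit tests
  instead. Physical floors (memory score ≥ 0, p-tau > 0) clip a handful of
  extreme noise draws; the zero-noise round-trip is exact to float
  precision and the noisy round-trip recovers the observed (noise-bearing)
  z wherever no floor binds.
- the generating normalization parameters travel with the ground truth, so
  round-trip tests measure inversion exactly rather than through the
  n = 86 refitted reference.
- demographics (an age offset and elevated hypertension probability for the
  WMH-led-like subtype, stage-linked diagnosis bands and follow-up
  progression rates) exist to exercise the evaluation module, not the model
  core.

The study-shaped configuration plants three orderings qualitatively
matching the reported memory-led, WMH-led and p-tau-led subtypes (the
p-tau-led one completes all three p-tau and memory events before any other
marker changes), with 86 controls, 376 cases, subtyped shares 145:88:100
and a 43/376 stage-0 mass, and control-scale anchors taken from the control
group's summary statistics. Passing recovery tests on these cohorts shows
the estimator recovers planted structure under the model's own assumptions
with realistic marginals; it does not show robustness to real-data features
the generator omits — site effects, non-Gaussian noise, missingness,
correlated marker errors, or subtype trajectories that violate the
piecewise-linear form.

## Problem sizes and tolerances

Default fitting settings (25 start points, 100k MCMC iterations) suit a
full analysis. The test suite and the acceptance script run the same code
at reduced sizes chosen to keep a complete run in minutes on one core:
5–6 start points, 3–5k MCMC iterations for the study-shaped fit, 400 for
each cross-validation fold fit, 5 folds, and a 3-marker × 2-threshold
design for the model-selection experiment. At these sizes the study-shaped
recovery lands around Kendall tau 0.8–0.95 per sequence, assignment
accuracy 0.69–0.82 among non-stage-0 cases (the Bayes ceiling under the
planted model is itself ≈ 0.81–0.83 — early-stage subjects are genuinely
confusable), within-subtype stage Spearman ≥ 0.9, and fraction errors
≤ 0.1. Fraction recovery is judged against the planted shares renormalized
over non-stage-0 cases: a stage-0 subject's likelihood is identical under
every sequence, so mixture fractions estimate the among-subtyped shares.

## Known limitations

- The model orders events but carries no notion of the time between them;
  stages are ordinal, not temporal.
- One sequence per subtype: within-subtype ordering heterogeneity appears
  only as MCMC spread, not as structure.
- The z-score trajectory is piecewise-linear with a fixed ceiling; saturing
  or non-monotone markers would be mis-modelled.
- CVIC refits every fold at every candidate C; its cost grows quickly and
  the reduced in-package settings trade some selection stability for
  runtime.
- The exact 2×k Fisher enumeration is exponential in k; beyond the table
  cap it degrades gracefully to seeded Monte Carlo with the usual
  (count + 1)/(B + 1) estimator.
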