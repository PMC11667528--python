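# amypath

Biomarker-pathway heterogeneity in amyloid-positive individuals: subtype
and stage inference over z-score events.

## The problem

Individuals with abnormal CSF amyloid-beta 1-42 are conventionally treated
as one homogeneous group on the Alzheimer's continuum, yet their downstream
biomarkers — tau pathology, neurodegeneration, cognition, cerebrovascular
burden — can become abnormal in very different orders. `amypath` implements
the full analysis needed to expose that heterogeneity from cross-sectional
data:

1. **Amyloid gate** — a two-component Gaussian mixture fitted by EM to the
   bimodal CSF abeta distribution; the positivity cut-point is a percentile
   (default the 99th) of the abnormal, lower-mean component. Values strictly
   below the cut-point are amyloid-positive.
2. **Control-referenced normalization** — six markers (logical memory,
   composite Trail Making Test = TMT B [300 s ceiling] − TMT A, CSF p-tau181,
   log2 white-matter-hyperintensity volume, whole-brain and hippocampal
   volume) are mapped to z-scores against amyloid-negative, APOE ε4
   non-carrier, diagnostically stable cognitively normal controls.
   Volumetric markers use W-scores: the control-only regression on total
   intracranial volume supplies the expected value, the control residual SD
   the scale. Markers that worsen downwards are inverted so larger z is
   always more abnormal.
3. **Subtype and Stage Inference (SuStaIn, z-score variant)** — disease
   progression as a sequence of *events*, each a marker crossing z = 1, 2 or
   3 (6 markers × 3 thresholds = 18 events, ceiling z_max = 5). Each marker
   follows a piecewise-linear trajectory in stage; a subject at stage k with
   subtype sequence S has likelihood
   `p(z | S, k) = ∏_i N(z_i; traj_i(S, k), σ_i)` with a uniform stage prior,
   and a cohort is a mixture of C such sequences. Fitting is hierarchical
   (split one subtype, EM-polish, repeat), uncertainty comes from
   Metropolis–Hastings MCMC over constrained orderings, and the number of
   subtypes is chosen by the cross-validation information criterion (CVIC)
   with a parsimony margin of ≈ 6.
4. **Evaluation** — per-subtype demographic tables, linear-regression and
   Fisher-exact group contrasts (exact 2×k enumeration with a seeded Monte
   Carlo fallback), stage–marker correlations (plain and semi-partial), and
   24-month diagnostic-progression summaries.
5. **Synthetic cohorts** — a seeded generator plants C subtypes with known
   sequences, stages and covariate structure and inverts the normalization
   maps exactly, so every pipeline stage is testable against ground truth.

It is aimed at researchers building or evaluating event-based progression
models who need a tested, reproducible, pure-Python reference pipeline.

## Worked example

```python
import numpy as np
from amypath import (AmyloidMixtureModel, Cohort, SustainModel, FitSettings,
                     apply_completeness_filter, build_zscore_matrix,
                     default_panel, fit_control_reference, generate_cohort,
                     make_paper_shaped_config, select_cases,
                     select_reference_controls)

# a study-shaped synthetic cohort: 86 controls, 376 amyloid-positive cases,
# three planted subtypes (memory-led / WMH-led / p-tau-led) + stage-0 mass
controls_gen, cases_gen, truth = generate_cohort(make_paper_shaped_config(seed=7))
pool = Cohort(tuple(controls_gen) + tuple(cases_gen), role="combined")

cut = AmyloidMixtureModel([s.csf_abeta for s in pool]).fit().cutpoint()
controls, _ = apply_completeness_filter(select_reference_controls(pool, cut))
cases, _ = apply_completeness_filter(select_cases(pool, cut))

panel = default_panel()
Z = build_zscore_matrix(cases, fit_control_reference(controls, panel), panel)
res = SustainModel(Z, panel).fit(
    3, FitSettings(n_startpoints=5, n_mcmc=3000, burn_in=1000, seed=7))
print(res.summary())
```

prints (orderings abridged):

```
Subtype and Stage Inference results
========================================
subjects: 376   events: 18   subtypes: 3
log-likelihood: -3858.181   MCMC samples retained: 200
unsubtyped (stage 0): 30 (8%)
subtype 0: fraction 0.319, n=108
  lm_score@1 -> wmh_ml@1 -> wbv_ml@1 -> wmh_ml@2 -> wmh_ml@3 -> ...
subtype 1: fraction 0.372, n=129
  csf_ptau181@1 -> lm_score@1 -> lm_score@2 -> lm_score@3 -> hip_ml@1 -> ...
subtype 2: fraction 0.309, n=109
  csf_ptau181@1 -> csf_ptau181@2 -> lm_score@1 -> lm_score@2 -> ...
```

The three recovered orderings are the planted vascular (WMH)-led (early WMH
events, p-tau last), memory-led and p-tau-led sequences — normalized
Kendall tau 0.83–0.87 against the planted truth at this seed. The
unsubtyped group are cases whose maximum-likelihood stage is 0,
i.e. indistinguishable from the control reference. `res.assign()` returns
per-subject subtype posteriors and stages, `res.positional_variance()` the
event-ordering uncertainty matrices with the low-count dashed-line rule.

A command-line interface mirrors the library:

```bash
amypath simulate --seed 7 --out-dir sim/
amypath cutpoint --input sim/cases.csv --out cut.json
amypath run --synthetic --subtypes 3 --seed 7 --out-dir run/
```

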