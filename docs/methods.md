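# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `phenokit`, and what its tests do and do not establish
about real recordings.

## Diagnostic coding

DSM-5 ADHD presentations map deterministically to two binary status flags:
Inattentive → (1, 0), Hyperactive-Impulsive → (0, 1), Combined → (1, 1),
no diagnosis → (0, 0). ADHD other/unspecified does not meet full criteria
for any presentation; such records carry `excluded = 1` and are dropped from
every model fit (they still appear in raw tables). Coding Combined as
positive on both flags lets each flag absorb the variance of its symptom
domain regardless of presentation; the cost is that the two ADHD group
definitions overlap, which descriptive summaries double-count by
construction. "Typically developing" means a negative consensus decision in
every diagnostic category, not merely the absence of the three modeled
flags; the participant table therefore carries an explicit `td` indicator.

Percentages in descriptive tables are rounded half-away-from-zero to
integers (e.g. 60/349 = 17.19% → 17). Missing scale values are excluded
pairwise from that statistic only, never listwise.

## Movement quantification

Input: per-frame 3D landmark coordinates at 30 Hz with presence flags, in
image-normalized units (x, y on a [0, 1] scale, z a unitless relative
depth — documented, not enforced; the jitter thresholds are calibrated to
these units).

**Quality control.** Two sliding-window rules, both stepping one frame, both
applied to the raw coordinates before any normalization:

- *Missing data*: a frame is invalid for a landmark iff any covering window
  of `round(fps × 2 s)` frames has a missing fraction strictly above 0.10.
  A series shorter than the window is one truncated window of its actual
  length.
- *Jitter*: a frame is invalid iff any covering 10-frame window has a sample
  standard deviation (ddof = 1, computed over present frames only) of the
  x-coordinate above 0.1 (face landmarks) or 0.01 (pose landmarks). Windows
  with fewer than two present frames impose no exclusion.

A frame must pass both rules (logical AND). The any-covering-window rule is
the conservative deterministic reading of segment-level exclusion; both
masks are verified against exhaustive all-window scans in the tests.
Tightening either threshold can only shrink the valid set (tested).

**Normalization.** Face landmarks are aligned per frame to a canonical
template by the least-squares affine map `p ↦ A p + b` fitted from the
present face landmarks (≥ 4 required); frames with rank-deficient
(coplanar/collinear) configurations are marked invalid rather than fitted.
The shipped template is a synthetic, roughly face-shaped non-coplanar point
set — an editable config asset, not a claim about any published model.
Body landmarks are divided by the per-frame inter-shoulder Euclidean
distance; frames lacking a shoulder, or with inter-shoulder distance below
1e-9, are flagged invalid (never a crash).

**Displacement.** Per landmark, displacement is ‖p_{t+1} − p_t‖₂ over
consecutive frame pairs whose endpoints are both valid; gaps are skipped,
never interpolated (interpolation would fabricate motion). The region score
averages each landmark's temporal mean across the region's landmarks —
chosen over pooling all pairs because it weights landmarks equally when
their valid-pair counts differ; the two orders coincide for balanced data.
The modeling variable is the natural log of the region score; an exactly
zero score yields a missing value with a warning, not −∞. Region
memberships (face, head, eyes, mouth, body) ship as editable configuration.

## Semantic typicality

The reference for each of the 23 interview questions is the component-wise
median of raw (not unit-normalized) embeddings from typically developing
participants aged 14–22 (both band and TD definition configurable); cosine
similarity handles scale at scoring time. An answer's typicality is its
cosine similarity to the matching reference; missing answers propagate a
missing score, and zero-norm vectors score missing with a warning.

Domain scores average the available (non-missing) per-question similarities;
an all-missing domain is missing. The Fisher-Z transform
`artanh(clip(s, −1 + ε, 1 − ε))` with ε = 1e-7 is applied to the **domain
mean** before regression (|z| ≤ ~8.4, bounding leverage). Averaging raw
similarities first, then transforming, was chosen because similarity scores
are averaged into domains and the transform is a pre-regression
normalization; the per-question-first order is a one-line change at the call
site for users who prefer it. Only the self-emotion domain's membership
(questions 14, 17, 20, 23) is protocol-attested; the other domain
memberships are a plausible placeholder partition of questions 1–23 and are
expected to be overridden per deployment (`domain_map` argument /
`--domains` YAML).

## Statistical models

For each behavioral metric, one model
`metric ~ age + iq + sex + adhd_inatt + adhd_hyper + asd` with intercept,
fitted by iteratively reweighted least squares with Tukey's biweight
(tuning c = 4.685, 95% Gaussian efficiency) and MAD-based robust scale —
the standard bisquare robust fit, provided by statsmodels' RLM. Rows are
deleted listwise per model (missingness varies by metric), and excluded
records are always dropped. Exactly linear data underflows the MAD scale;
the implementation then falls back to the ordinary least-squares solution,
which is the IRLS fixed point in that case.

Effect sizes are `ES = t / √DFE` with `DFE = n_used − p` (intercept counted
in p). For a single binary predictor this equals Cohen's d times
√(p(1 − p)) — proportional to d, equal to d/2 for balanced groups — and for
continuous predictors it is a comparable sample-size-normalized
standardized effect. p-values for robust fits use the t reference
distribution with DFE degrees of freedom (bootstrap alternatives are out of
scope). Binary outcomes use maximum-likelihood logistic regression with
`OR = exp(β)` per unit change (per year for age); separation is a hard
error rather than a silently penalized fit.

Bonferroni control: `p_adj = min(1, m·p)`, flagged when `p_adj < α` with
α = 0.01 and m the number of outcome models in the analysis block (the
language block uses m = 9). Post-hoc age × disorder interaction models add
one product column to the design and report the interaction p uncorrected.
Spearman correlations are computed on pairwise-complete observations with
the t-approximation for p.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes — not
the appearance of real video, audio, or text.

- **Cohort**: age ~ truncated normal (mean 10.1 y, SD 3.39, bounds 5–22);
  female fraction 33.5% (~2:1 male:female). Diagnoses are drawn
  sequentially: inattentive status Bernoulli (55%), hyperactive status via a
  logistic link with OR 0.83 per year of age (marginal 31%), ASD via a
  logistic link with OR 2.3 on inattentive and 1.6 on hyperactive status
  (marginal 15%). Intercepts are solved numerically (Brent root-finding) so
  realized marginal prevalences match the configured targets while the
  configured odds ratios stay exact in the generative model. 3.6% of
  records are other/unspecified (excluded). Full-scale IQ is 106.5 − 8 ×
  any-diagnosis + N(0, 16²), missing at 6.7%; clinical scale scores are
  simple linear-in-flags emulations with noise. All defaults are editable
  `CohortConfig` fields.
- **Features**: `y = Σ_k ES_k · z_k + ε`, z standardized over the analyzable
  sample, ε ~ N(0, sd²) — the generative inverse of the ES definition, with
  standardization constants stored in the ground truth. Because predictors
  are mildly correlated (comorbidity, age→hyperactivity, IQ→diagnosis),
  refitted ES are shrunk by √(1 − R²_j) ≈ 0.97–0.99 relative to truth;
  recovery tolerances (±0.05 on the mean over 50 seeds at n = 2000) absorb
  this. The default feature uses ES (0.40, 0.27, 0.08, 0.00, 0.12, 0.13) —
  a strong age effect, reliable IQ effect, small sex/diagnostic effects and
  a null — the magnitude pattern these models are designed to resolve.
- **Landmarks**: 12 face + 6 pose landmarks; per-landmark Gaussian random
  walks with step SD `base · exp(−0.04·(age − 10) + 0.35·hyper)` (base
  0.002 face / 0.004 body units per frame), a global rigid head wobble that
  alignment must remove, plus injected missing runs (2/min, 0.5–2 s) and
  10-frame x-jitter bursts (1/min, SD 0.5 face / 0.05 pose) at known,
  ground-truth-recorded locations. Defaults: 30 fps, 20 s; end-to-end runs
  at n = 2000 use 10 s series to keep the problem size moderate.
- **Embeddings**: per-question unit-norm prototypes (dimension 32 by
  default; the scoring code is dimension-agnostic and the study-scale 768
  is a config value), answers `prototype + σ·z/√D` with
  `σ = σ₀·exp(−0.04·(age − 10)) · exp(0.30·ASD)` on narrative-type
  questions, missing answers at 10%. Mean typicality is monotone decreasing
  in σ (tested over a σ grid).

Determinism: every generator takes (config, seed); sub-streams are split via
`numpy.random.SeedSequence`, so identical inputs give identical outputs.

**What passing tests do not show.** The generator's noise is Gaussian (a
heavy-tailed option exists to exercise the robust fitter), landmarks move as
independent random walks rather than articulated bodies, embeddings are
isotropic around a single prototype per question, and missingness is
injected at random rather than arising from occlusion or disengagement.
Recovery results therefore validate the *estimators and plumbing* — that the
chain measures what the generative model encodes — not the clinical
sensitivity of any marker on real recordings.

## Problem sizes and numerical choices

- Robust fit: tol 1e-8 on coefficients, max 200 iterations; non-convergence
  is reported with a warning, never silently discarded.
- artanh clipping ε = 1e-7; inter-shoulder degeneracy threshold 1e-9;
  typical-answer ties break to the smallest participant id.
- Acceptance-scale runs: ES recovery at n = 2000 over 50 seeds; family-wise
  error at n = 1000 over 1000 replicates; OR recovery at n = 5000 over 20
  seeds; end-to-end specificity at n = 2000 with 10-s landmark series.
  These sizes give sampling error comfortably inside the stated tolerances
  while keeping a full run in the minutes range on one core.

## Known limitations

- The canonical face template and the question→domain map (beyond
  self-emotion) are synthetic placeholders; both are user-overridable and
  results that depend on them should be interpreted accordingly.
- Only face vs pose jitter thresholds are implemented; hand landmarks and
  gesture/stereotypy classification are out of scope.
- Robust-fit p-values rely on the t reference distribution; no bootstrap.
- Mixed-effects, mediation, and measurement-error models are out of scope;
  an anxiety-comorbidity sensitivity model is expressible by adding a binary
  predictor column but is not separately implemented.
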