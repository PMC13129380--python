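# Methods

`qcmil` implements a slide-level classifier for cytology specimens that
works on *bags of cell features* rather than pixels. One whole-slide image
(WSI) is represented as a bag `X = x_1..x_K` of detected-cell feature
vectors (dimension `M`), each with a patch quality score `s_i ∈ [0,1]` and,
where available, a cell-level label (`normal` / `abnormal` / `unknown`).
The bag carries a binary label (slide normal vs. abnormal). This document
describes the model, the synthetic cohort generator that defines the study
conditions, the numerical choices, and the known limitations.

## Model

The pipeline applies four stages per bag.

**1. Quality initial screening (QISM).** Each patch's composite quality
score is a weighted arithmetic mean of four normalized sub-metrics:

    score = w_c·clarity + w_a·(1 − artifact_fraction)
          + w_u·stain_uniformity + w_n·min(cellularity/saturation, 1)

with nonnegative weights summing to 1 (default 0.25 each) and a cellularity
saturation count (default 50) at which that sub-score reaches 1. The
aggregation rule and weights are this package's design choices; pixel-level
quality estimation (blur, artifact segmentation, stain deconvolution) is
out of scope — the package consumes already-computed sub-metrics.
Screening keeps only instances with `score > threshold` (strictly greater;
default threshold 0.3, a conservative cut exposed in config). Bags may
legally become empty; prediction then falls back to the training class
prior with an `empty_after_screening` flag.

**2. Cell-feature comparison (CFCM).** Baseline cell morphology differs
across patients, so a suspicious cell is judged against prototypical
normal cells *from the same slide*. Per bag, K-means (Lloyd's algorithm,
k-means++ seeding, fixed seed, `K_eff = min(K, n_normals)`) clusters the
normal-labeled features; enhancement modes:

* `difference` (default): `e_i = x_i − r` with `r` the unweighted mean of
  the cluster centers (config alternative `reference=global_mean` uses the
  mean of all normal features). This cancels any per-slide additive
  baseline exactly.
* `concat`: `[x_i ; x_i − r]` (width 2M).
* `nearest_center`: `e_i = x_i − c_(nearest prototype)`. Each cell is
  compared against its most similar prototype, so a larger prototype set
  absorbs more normal-cell diversity. This is the mode under which the
  prototype count `K` is a meaningful hyperparameter: with an *averaged*
  reference, `K` enters only through the center average — a second-order
  effect we measured at ±0.005 AUC with seed-unstable sign — whereas in
  nearest-prototype mode a too-small `K` leaves borderline-normal subtypes
  with large residuals that masquerade as abnormal. The prototype-count
  sweep experiment therefore runs in `nearest_center` mode; the default
  pipeline keeps the averaged difference.

With no normal cells at all, the reference degrades to the zero vector and
enhancement to the identity — the method depends on sufficient normal
cells being present, and the fallback makes that degradation graceful
rather than fatal.

**3. Supervised contrastive loss.** On l2-normalized embeddings `z_i`
(enhanced features by default; a config switch `apply_supcon_to=raw`
exists because either choice is defensible), with
labels from cell-level annotations (`unknown` and zero-norm embeddings are
excluded):

    L_supcon = Σ_{i∈I, P(i)≠∅} 1/|P(i)| Σ_{p∈P(i)}
               −log[ exp(z_i·z_p/τ) / Σ_{a∈A(i)} exp(z_i·z_a/τ) ]

where `P(i)` are the other same-class embeddings, `A(i)` all other
embeddings, and τ the temperature (default 0.1, a standard contrastive
value). Anchors without positives are skipped;
a batch where *every* anchor lacks positives raises a defined error. The
implementation is log-sum-exp stabilized and provides the analytic
gradient with respect to the embeddings (verified against central finite
differences).

*Limitation:* the package deliberately has no trainable encoder below the
embeddings (no projection head beyond l2-normalization; the upstream
feature extractor is out of scope). `L_supcon` is therefore constant with
respect to the trainable parameters: it is computed once per training run
(on a seeded subsample capped at `supcon_batch_cap=1024` instances),
logged every epoch, and enters the reported objective
`L = λ·L_bag + (1−λ)·L_supcon`, but only the cross-entropy term produces
gradients. In the original setting the contrastive term shapes a finetuned
feature backbone; here it is an exact, tested loss whose training-time
role is diagnostic. Note the loss is a *sum* over anchors (as defined
above), so its logged magnitude scales with the subsample size.

**4. Quality-aware attention MIL (QAM + pooling).** Enhanced features are
quality-weighted, `x'_i = s_i · x_i` (raw scores, no recalibration), then
pooled:

    a_k = softmax_k( w^T max(LayerNorm(V x'_k), 0) ),   z = Σ_k a_k x'_k,
    p = softmax(U z + b)

with `V ∈ R^{L×M}`, `w ∈ R^L` (hidden width L, default 128), LayerNorm
over the hidden dimension with learned affine terms, and the softmax taken
across the K instances of the bag — the only axis that yields pooling
weights. Attention weights are a probability vector for every nonempty
bag; predictions are invariant to instance order and to instance
duplication. The bag loss is the regular cross-entropy `−log p_y`
(probabilities floored at 1e−12); the joint objective uses λ = 0.7 by
default (bag loss prioritized).

**Bag composition.** The MIL head consumes *all* instances of the bag by
default (`include_normals_in_bag=True`), with the normal-labeled ones
additionally feeding the reference. The alternative reading — only
suspected-abnormal detections enter the bag — is available as a switch,
but under the synthetic generator (which has no "suspected" detector and
whose bags are overwhelmingly normal cells) it would leave negative bags
empty and the task vacuous.

**Optimization.** The parameter set (V, w, LayerNorm affine, U, b) is
small, so forward and backward passes are written explicitly in NumPy
(bags of a minibatch concatenated, segment reductions via `ufunc.reduceat`)
and optimized with Adam (lr 1e−3, β = 0.9/0.999, 30 epochs, minibatches of
8 bags). All optimizer settings are package defaults chosen for this
problem scale. Gradients are verified against finite differences in the test
suite. All randomness (init, shuffling, subsampling) derives from one
seed; two runs with the same seed are bitwise identical. Training raises
a defined error if a class has no nonempty bags after screening, or if the
loss becomes non-finite.

**Ablation switches.** `use_qism` off → no threshold filtering;
`use_cfcm` off → raw features and λ forced to 1; `use_qam` off → s_i
treated as 1. The ablation experiment runs the six combinations
(baseline; each module alone; screening+comparison; all three) on matched
seeded cohorts.

## Synthetic cohort generator

No clinical data ship with the package; the generator produces cohorts
with exactly the statistical structure the method targets, so every stage
is testable. Per bag `b`:

* patient baseline `μ_b ~ N(0, baseline_sd² I_M)`, shared by all cells of
  the slide;
* normal cells `x = μ_b + c_g + ε`, `ε ~ N(0, noise_sd² I)`, where `c_g`
  is a latent subtype offset (zero when `n_normal_subtypes=1`);
* abnormal cells (positive bags only, at rate `abnormal_instance_rate`,
  with at least one forced per positive bag) additionally offset by
  `effect_size · u` along a cohort-wide unit direction `u`;
* a `quality_corrupt_fraction` of patches is drawn from a "bad"
  metric regime (scores ≲ 0.45, mostly below the 0.3 threshold, with a
  tail that slips past screening) and gets extra feature noise
  (`quality_noise_sd`); a `mimic_fraction` of those corrupted patches are
  *artifact mimics*, additionally offset along `u` at a random partial
  strength `U(0.3, 1.0) × effect_size` — debris that resembles abnormal
  cells, the mechanism by which quality problems inflate false positives.

Bag label = 1 iff the bag contains an abnormal cell. Class allocation is
deterministic (exact counts), abnormal-instance counts binomial with a
floor of one. The first `n_normal_per_bag` normal cells are kept
uncorrupted so the per-slide reference never starves. Cohort-wide
structure (`u`, subtype offsets) is shared across the train/validation/
test splits of one seed; per-split sampling is independent.

Default study conditions: 200 training / 100 test bags of 50–200
instances, M=64, `abnormal_instance_rate=0.05`, `effect_size=36`,
`baseline_sd=0.8`, `noise_sd=1`, `quality_corrupt_fraction=0.2`,
`quality_noise_sd=2`, `mimic_fraction=0.3`, seed 42. The rarity value is a
desk-scale emulation of clinically extreme imbalance (ratios as low as
1:10,000 cannot be realized literally in 200-cell bags). The signal
strength was calibrated once so that a deliberately simple reference
method — L2-regularized logistic regression on bag-mean features
(C=0.03, appropriate for p=64, n=200) — reaches median test AUC ≈ 0.86
across seeds; the full model's recovery bound (≥ 0.90) then tests the MIL
machinery, not an impossible task. Against these conditions the
component ablation is *directional by construction*: mimics are the
dominant error source for quality-blind variants, the patient baseline
for comparison-free variants.

The **prototype-count sweep** uses a separate cohort family:
`n_normal_subtypes=8` (offset scale 6, per-slide Dirichlet(0.3) mixture
proportions), per-subtype *borderline drift* along `u` of
`U(0, 0.7) × effect_size` (borderline-normal morphologies, e.g.
metaplastic cells), shared subtype context for abnormal cells, and
`effect_size=8` so that comparison quality — not raw signal strength — is
the binding constraint. The sweep runs in `nearest_center` mode (see
above).

**What the generator does not emulate.** Feature vectors are Gaussian
with a single linear abnormality direction; real cell embeddings are
non-Gaussian, the abnormal manifold is not one direction, and detector
errors (missed cells, duplicated detections) are absent. Quality
sub-metrics are drawn from two clean regimes rather than estimated from
pixels. Passing recovery/ablation tests therefore shows that the
implementation exploits the structure the method posits — not that the
method attains any particular clinical performance.

## Evaluation suite

* **AUC**: mid-rank Mann–Whitney formulation, ties counted ½; exact
  against exhaustive pair counting and invariant under monotone transforms
  of the scores.
* **DeLong CI**: structural-components variance
  `var = Var(V10)/m + Var(V01)/n`, normal-approximation interval truncated
  to [0,1]; zero variance (e.g. perfect separation) collapses the CI to
  the point estimate with a degeneracy flag. A paired two-model comparison
  (`delong_paired_test`) reports ΔAUC, z, and p. Cross-checked in the
  tests against R's `pROC::ci.auc` and against Monte-Carlo truth.
* **Bootstrap**: percentile case-resampling CIs (default 1,000
  iterations, seeded) for accuracy/sensitivity/specificity; resamples on
  which the metric is undefined (single-class draws) are redrawn, capped
  at 100 retries per resample.
* **Fleiss' kappa**: statsmodels implementation behind the package
  surface, validated against the definitional double loop; the 0/0 case
  (one category ever used, perfect agreement) returns 1.
* Sensitivity is reported as NaN when no positives exist (likewise
  specificity), rather than a silent 0.

## Numerical choices

* LayerNorm ε = 1e−5; probability floor 1e−12 before logs; l2-normalize
  returns the zero vector (flagged) below norm 1e−12.
* Softmaxes are max-shifted; SupCon uses log-sum-exp stabilization.
* K-means ties (equidistant centers) resolve to the lowest center index.
* CSV round-trips store floats at 17 significant digits and read with
  `float_precision="round_trip"`, so write→read is exact.
* Seeds: every stochastic component takes an explicit integer seed;
  derived streams use `SeedSequence(entropy=(seed, stream))`.

## Known limitations

* The contrastive term cannot influence training without a learnable
  encoder (see above); λ < 1 consequently only rescales the effective
  learning rate of the bag loss.
* The averaged-reference enhancement makes the prototype count `K` nearly
  irrelevant; `K`-sensitivity requires `nearest_center` mode.
* The permutation null is implemented as the standard permutation test
  (labels permuted in every split). Training on permuted labels while
  scoring against *true* labels is not chance here: the synthetic features
  nearly separate the classes, so any residual readout orders bags along
  the abnormality axis with an arbitrary sign (measured 0.14–0.88
  regardless of training length).
* Binary slide labels only (no multi-grade reporting); no gated-attention
  or transformer pooling variants.
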