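# Methods

## The problem

Among IDH-mutant diffuse gliomas, codeletion of chromosome arms 1p and
19q separates oligodendroglioma (codeleted) from astrocytoma (intact).
The molecular assays that establish this — FISH signal counting or
arm-level copy-number fold change (FC) from targeted sequencing — are
slow and laborious. This package implements a weakly-supervised imaging
model that regresses the *continuous* arm-level FC of 1p and 19q directly
from an H&E whole-slide image, using only one slide-level label per arm,
and fuses the two estimates into a tumor-type call. All components are
exercisable end to end on synthetic data with known ground truth.

## Model

A slide is a bag of patch feature vectors `x_1..x_P` (one 224×224 patch
each at 20x). Per chromosome arm:

1. **Patch scorer** — a linear map `s_i = w·x_i + b` assigns each patch a
   raw copy-number score. Scores are unbounded at this stage; the
   monotone sigmoid is applied only where a score is *interpreted* as a
   patch-level FC (heatmaps), so selection operates on the raw scale.
2. **Min-max selection** — the N highest and N lowest scores are kept
   (top block then bottom block, each sorted descending; ties prefer the
   lower patch index). This is the min-max (CHOWDER-family) aggregation:
   the slide's diagnosis rests on its most supportive and most
   contradictory patches. Bags with fewer than 2N patches recycle the
   sorted score list cyclically, preserving the bag's score scale rather
   than injecting zeros.
3. **Aggregator** — a three-layer MLP (200, 100, 1 channels, sigmoid
   after every layer) maps the 2N selected scores to the slide FC in
   (0, 1).

Training minimizes the MSE between slide FC estimates and the NGS arm
labels with Adam (learning rate 1e-4, weight decay 5e-4) and dropout 0.5
on the linear layers (scorer input and MLP layer-1/2 inputs; inference is
dropout-free). FC labels live in (0, 1.5]; values ≥ 1 (diploid arms) are
clipped to 0.999 with a warning because the sigmoid output is open at 1.
One independent network is trained per arm.

**Fusion.** The two slide FC estimates enter a logistic regression
`P(oligodendroglioma) = σ(β0 + β1·fc_1p + β2·fc_19q)` fitted by maximum
likelihood (BCE) with a vanishing L2 penalty (λ = 1e-6) for stability on
separable cohorts. Because deletion lowers FC, a well-fitted model has
β1, β2 < 0. A slide is called oligodendroglioma when the probability
reaches the cutoff (ties at the cutoff included).

## Optimization choices

Everything is plain NumPy (forward, backward, Adam, inverted dropout),
verified against central finite differences in the test suite. Gradients
flow through the hard top/bottom selection exactly as through max
pooling: only selected patches receive signal, recycled entries
accumulate.

The min-max selection makes the loss surface rough, and at the fixed
learning rate a fraction of random initializations stall in a plateau
where the scorer never finds an informative direction. Two measures make
training robust, both config-exposed:

* **PC1 warm start** — the first restart initializes the scorer weights
  along the leading principal component of the pooled training features
  (scaled to the norm a Glorot draw would have). A copy-number-relevant
  mean shift across patches inflates variance along its direction, so
  PC1 is a reasonable unsupervised first guess; the MLP resolves the sign
  ambiguity.
* **Restarts** — `n_restarts` (default 2: one warmed, one fully random)
  independent runs, keeping the snapshot with the best validation MSE.

Batches are single slides (`batch_size=1`): with cohorts of a few hundred
slides, per-slide Adam updates provide enough optimizer steps within a
modest epoch budget at the fixed 1e-4 learning rate; larger batches are
available in config. Early stopping monitors validation MSE with patience
10 and returns the best snapshot. All randomness (init, shuffling,
dropout) derives from the config seed; runs are bit-reproducible.

## Synthetic data

The generator emulates the *statistical* structure the model must
exploit, not histology:

* Patch features are isotropic Gaussians (SD `feature_noise_sd`, default
  1) in D dimensions (default 64 at desk scale). A slide has
  `round(t·P)` tumor patches at purity `t`; when an arm is deleted their
  mean is shifted by `effect_size × feature_noise_sd` (default 2.0) along
  a fixed unit direction, one orthogonal direction per arm, so the two
  estimators can learn independently.
* The slide FC label encodes hemizygous loss diluted by purity:
  `fc = 1 − 0.5·t` for a deleted arm (one allele of two lost in tumor
  cells), 1.0 for an intact arm, plus Gaussian label noise (default
  0.02), clipped to (0, 1.5]. Purity uniform on [0.4, 1.0] thus yields
  deleted-arm FCs in [0.5, 0.8] — the range seen in sequencing of
  codeleted tumors — and 1.0 in normal or intact tissue.
* Cohorts alternate oligodendroglioma (both arms deleted) and astrocytoma
  (both intact), balanced to within one slide; per-slide seeds spawn
  deterministically from the master seed.
* Image fixtures for the filters: H&E-like textured tissue, near-uniform
  bright background, and saturated-red blood with brightness speckle and
  sparse bright flecks (so blood is textured rather than blank and is
  caught by the color rule, not the background rule).

What passing on this generator does *not* show: robustness to stain
variation, scanner differences, nonlinear feature geometry of a real
encoder, spatially correlated tissue context, or label error structure of
real NGS panels. It does show that the estimator recovers a planted
bag-level regression target from instance-level evidence it must discover
itself, that the fusion recovers the correct decision geometry, and that
every deterministic rule matches its stated definition exactly.

## Pre-processing rules

* **Tiling** — non-overlapping 224×224 patches at 20x; 40x scans are
  block-averaged ×2 first; remainder strips are dropped (floor tiling).
* **Background** — a patch is background when its Canny edge-pixel count
  on the grayscale patch is strictly below 23 (Canny σ=1, hysteresis
  50/150 on the 8-bit scale; the operator and thresholds are config).
* **Blood** — a patch is blood when ≥ 50% of its pixels fall in an HSV
  box of saturated red: hue ∈ [0,10] ∪ [160,179] (0–179 scale),
  saturation ≥ 100, value ≥ 60. Background is checked first; the
  statuses kept/background/blood partition the grid.
* **Color normalization** — Reinhard-style channel mean/SD matching in
  CIELAB against a reference fitted on kept in-house patches; intended
  for external cohorts only, disabled for same-scanner data. Zero-variance
  patches pass through unchanged with a warning.

## Reference assays

* **NGS rule** — per-gene log2 FCs are averaged per arm on the linear
  scale (`mean(2^log2fc)`) and compared to 0.8: oligodendroglioma iff
  both arm means are strictly below. The 0.8 threshold and the 0.5–0.8
  hemizygous range only cohere on the linear scale; a config switch
  (`scale="log2"`) averages in log2 space instead for users whose
  pipelines define the arm mean that way. Means exactly at 0.8 are routed
  to astrocytoma with a `borderline` flag (stand-in for manual
  copy-number-plot review, which is out of scope).
* **FISH rule** — among nuclei with two centromeric control signals, an
  arm is deleted when strictly more than 50% carry a single target
  signal; strictly more than 60 such nuclei are required, otherwise an
  `InsufficientNucleiError` is raised. Codeletion = both arms deleted.

## Evaluation protocol

Ten (default) independent stratified 60/20/20 train/validation/test
splits; note that disjoint K folds cannot each supply a 20% validation
*and* 20% test part, so the protocol is Monte-Carlo cross-validation,
re-drawing splits that lose a class. Per split: train both arm
estimators, fit the fusion on the *training* partition's outputs, report
on the untouched test partition: R² per arm, ROC AUC per arm (scored by
1 − fĉ) and fused, accuracy/precision/recall/F1 at the Youden-optimal
cutoff (candidate cutoffs are midpoints between consecutive distinct
scores; ties in J resolve to the lower cutoff), and a class-stratified
percentile bootstrap 95% CI (1000 replicates) on the fused AUC.

**Instance localization.** Synthetic cohorts carry the planted
tumor-patch indices, so the protocol also reports how well patch scores
localize them: patches are pooled across a test split and ranked by
|score − pooled median score|; positives are tumor patches on arm-deleted
slides, negatives non-tumor patches everywhere (intact-arm tumor patches
carry no signal and are excluded). The pooled median is used because a
per-slide median sits inside the tumor score mode whenever purity
exceeds 0.5, inverting the ranking. The reported value is the mean over
splits.

## Reference study conditions

The shipped reference experiment (also what `scripts/acceptance.py`
runs) uses 300 slides, 64-dimensional features, 200–600 patches per
slide, purity U(0.4, 1.0), effect size 2.0, label noise 0.02, N=25
extreme patches per side, 50 epochs and 3 protocol splits — a desk-scale
configuration that one CPU completes in about two minutes. Typical
results: per-arm FC R² ≈ 0.9, fused AUC ≈ 1.0, localization AUC ≈ 0.75–0.85,
negative fusion coefficients for both arms.

## Known limitations

* The stub feature extractor is a seeded random projection: it preserves
  linear mean-shift structure but has none of the semantics of a
  pretrained histopathology encoder; plug a real encoder into the
  `ExtractorSpec` registry for real slides.
* Pyramidal scanner formats are not read; plain PNG/TIFF images with a
  declared objective power are.
* The generator's Gaussian geometry makes the planted signal linearly
  recoverable by construction; nonlinear evidence would need a richer
  scorer than the single linear layer.
* Heatmap colors map the per-slide sigmoid of raw scores; scores are not
  calibrated across slides, so identical colors on two slides do not
  imply identical evidence strength.
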