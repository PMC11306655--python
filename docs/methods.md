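# Methods

`pdfe` implements a patch-based deep feature engineering pipeline for
two-class grayscale image screening, in the style used for
large-versus-small cerebral vessel occlusion triage on non-contrast head
CT. The pipeline has four stages: patch tiling, frozen-backbone feature
extraction and fusion, iterative neighborhood-component-analysis feature
selection, and shallow-classifier evaluation under stratified tenfold
cross-validation.

## Pipeline model

Each image is read as intensities in [0, 1], bilinearly resized to a
square grid (default 224 x 224) and tiled into non-overlapping 16 x 16
pixel patches, giving a 14 x 14 grid of 196 patches. Coordinates are
0-based and half-open; ordering is row-major; reassembling the patches
reproduces the resized image bit-for-bit. The tiling follows the
vision-transformer convention of treating fixed 16 x 16 pixel patches as
independent inputs.

The raw resized image and every patch are pushed through a frozen feature
extractor. Two backends satisfy the same contract:

* **AlexNet architecture** (canonical 227-input variant: five
  convolutional layers with grouped conv2/4/5, local response
  normalization after conv1/conv2, 3 x 3 stride-2 max pooling), exposing
  the post-rectifier activations of the fc6 and fc7 fully connected
  layers, 4096 + 4096 = 8192 values per input. The backbone is a NumPy
  forward pass; weights are seeded He-normal by default or loadable from
  an `.npz`. Grayscale inputs are replicated to three channels and
  normalized with the ImageNet channel statistics. With random weights the
  backbone supports every architectural contract (shapes, widths,
  determinism); discriminative quality on real CT of course requires
  pretrained weights.
* **Random projection**: a seeded fixed Gaussian linear map of the
  flattened, resized input (default 32 x 32) followed by a rectifier, no
  bias. It is the fast, fully self-contained default for experiments and
  tests.

Per-input vectors are concatenated — raw image first, then patches
row-major, fc6 before fc7 within each input — into one fused row per
sample: (1 + 196) x 8192 = 1,613,824 features with the defaults. Column
provenance (input, layer, unit) is a pure function of this ordering.

## NCA weighting

Features are weighted by neighborhood component analysis over the
weighted Manhattan distance d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|.
Reference probabilities are the softmax of -d_w/sigma over all other
samples; the objective is the regularized expected leave-one-out
correct-neighbor mass

    xi(w) = sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * sum_r w_r^2,

maximized by gradient ascent from all-ones weights with an adaptive step
(halved until the objective does not decrease, grown 10% after each
accepted step), so the accepted objective trace is non-decreasing. The
analytic gradient is verified against central finite differences in the
test suite.

Parameter defaults, and why:

* `sigma="auto"`: kernel width set to the standard deviation of the
  pairwise distances at the all-ones initialization. This is the one
  numerically load-bearing choice. A fixed width (e.g. 1) collapses the
  softmax to winner-take-all as soon as distances grow with feature count
  (with 1.6M columns, distances are ~1e5-1e6), and in that limit the
  gradient vanishes identically: K_ij = p_ij (p_i - [y_j = y_i]) is zero
  whether the nearest neighbor shares the class or not, so the ranking
  degenerates to numerical noise. A width matched to the spread of the
  initial distances keeps the soft-neighbor probabilities informative at
  any dimensionality.
* `standardize=True`: columns are centered and scaled (zero-variance
  columns zeroed) before weighting, so the gradient ranks features by
  discrimination rather than raw scale; the per-fold scalers inside all
  cross-validated evaluations are fitted on training rows only.
* `lambda_reg=1/n_samples`: the customary penalty scale for this
  objective.
* `max_iters=100`, `learning_rate=0.01`, `tol=1e-4`. The stopping
  tolerance is deliberately loose: the weights feed a ranking, and
  running deep into the saturated regime only lets the penalty erode the
  ordering of mutually redundant informative features while
  chance-correlated noise stays inflated — optimizing the objective
  further measurably degrades ranking quality on planted-feature
  instances.

The pairwise passes stream over fixed 4096-column blocks (numba JIT
kernels, with a blocked NumPy fallback) so the per-block working set
stays in cache; blocking only reorders exact partial sums and the two
backends agree to roundoff. One pass over 80 samples x 1.6M features
takes a few seconds on one CPU core.

## Iterative selection (INCA)

Features are sorted by weight (descending, ties to the lower column
index). For every subset size k in the loop range (default 1..500) the
top-k prefix is scored by the pooled stratified tenfold cross-validated
misclassification of a 1-NN Euclidean classifier; the fold assignment is
fixed once per call and reused for every k so the loss curve is
comparable across k. The chosen k minimizes the loss, ties to the
smallest k. Distances for the whole loop come from one cumulative sum
over the ranked feature axis per fold; the curve is verified against an
exhaustive per-k recomputation in the tests.

## Classification and evaluation

The method classifier is 1-NN with Euclidean distance and plain majority
voting (vacuous at k=1); distance ties go to the lower training index,
even vote splits to the nearest neighbor. Evaluation uses stratified
tenfold cross-validation; per-fold confusions are pooled into a single
matrix from which accuracy, recall, precision and F1 are computed in
percent, with the large-occlusion class (label 0) as positive. Undefined
ratios are reported as NaN with a warning. A nine-classifier comparison
(kNN, DT, RF, LD, QD, LR, NB, SVM, MLP) runs under identical folds; the
eight non-kNN baselines are off-the-shelf scikit-learn estimators, with
LD/QD in their shrinkage forms (`lsqr`/`eigen` + `shrinkage="auto"`) so
they remain defined when the selected panel is wider than a class's
sample count. Their exact settings are recorded in each report but are
not contractual.

Two protocols are available. `selection_scope="full"` performs selection
once on the whole matrix and then cross-validates the selected columns —
the protocol commonly paired with this pipeline, which lets the selector
see the evaluation samples and is therefore optimistic on weak-signal
data. `selection_scope="nested"` re-fits the entire NCA/INCA stage inside
every training fold; it is leakage-free, and at zero class effect its
pooled accuracy stays at chance (the test suite checks it against the
central 99% binomial band around 50%).

## Synthetic phantom generator

Real screening datasets of this kind are rarely shareable, so the
generator emulates the structure the pipeline assumes: an elliptical
"brain" region (semi-axes 0.42 and 0.34 of the image side, intensity
0.45) on a dark background (0.05), plus a bright disk whose radius is the
class difference — default 28 px for the large-occlusion analog, 8 px for
the small one, on a 256 px image — at a location drawn uniformly over the
positions where the disk fits inside the brain, so the discriminating
signal is position-variant and patch-level features matter. The disk adds
`effect_size x lesion_contrast` (defaults 1.0 x 0.25) to the intensity;
i.i.d. Gaussian noise (sd 0.08) is added and the image is clipped to
[0, 1] and written as 8-bit grayscale PNG (quantization is part of the
contract). Lesion placement and noise use separate seeded streams, so at
`effect_size=0` the two classes are identically distributed. The default
class sizes are 159 and 165.

What the phantom does not emulate: anatomy (no skull, ventricles,
windowing, Hounsfield calibration), scanner artifacts, or the texture
statistics of real CT. Passing tests on phantoms therefore demonstrate
the pipeline's mechanics — tiling, fusion, selection, evaluation,
determinism, leakage control — not clinical performance.

`make_planted_features` generates labeled feature matrices directly:
informative unit-variance Gaussian columns with a class-mean shift among
pure-noise columns, either exchangeable (every informative column shifts
every sample) or complementary (each informative column shifts only its
own balanced slice of samples, so each carries unique signal).

## Problem sizes and numerical choices

The bundled experiments run at desk scale, chosen so each completes in
minutes on a single CPU core: the headline surrogate uses 40 images per
class at `effect_size=2` with the random-projection extractor
(80 x 1,613,824 fused features) and 20 NCA ascent iterations; the null
control uses 20 images per class at 64 px with 256-dimensional
projections and nested selection. Feature extraction is streamed
record-by-record; the feature matrix is float32 (about 0.5 GB at headline
scale) and persists as `.npz` with a JSON provenance sidecar (CSV export
exists for small matrices). All randomness — phantom content, extractor
weights, fold assignments — derives from explicit seeds, and the
pipeline's serialized artifacts are byte-identical across repeated runs
of the same configuration.

## Known limitations

* The redundancy/tie-break interaction bounds "select every informative
  feature" guarantees: when planted informative columns are mutually
  redundant, the prefix loss bottoms out before the last one and the
  smallest-k rule stops there (the unit suite asserts the guarantees that
  do hold: at moderate effect, at least 4 of 5 planted columns are always
  selected and all 5 rank in the top 10 in >= 85% of replicates).
* The random-init AlexNet backbone checks architecture, not semantics;
  supply pretrained weights via `alexnet_weights` for real use.
* Binary classification only; the evaluation report is deliberately
  limited to the four confusion-derived metrics.
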