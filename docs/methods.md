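# Methods

## Model overview

`omics-gsn` classifies tumor samples from three per-gene omic
measurements (expression, DNA methylation, copy-number alteration) by
converting each sample into a small RGB image over a fixed 2-D gene map
and training a convolutional network on those images. The gene map is
produced once, from the expression matrix only: each gene is a point in
R^(n_samples) (its normalized expression profile), embedded into 2-D with
PaCMAP. The map therefore encodes gene–gene similarity; the per-sample
image encodes that sample's omic values at each gene's location.

The approach assumes (a) the selected genes carry class-relevant signal
in at least one omic, (b) per-gene min-max normalization puts the three
omics on a comparable [0, 1] scale, and (c) spatial proximity of
correlated genes in the map is a useful inductive bias for convolution.
Nothing in the pipeline uses the labels before the train/test split.

## Preprocessing

* **Variance filter** (expression only, threshold 0.002, sample variance
  with ddof 1). The filter runs on raw values, *before* normalization:
  per-gene min-max scaling maps every non-constant gene onto the full
  [0, 1] range, which would inflate all variances and make an absolute
  threshold meaningless. The threshold is a config knob.
* **Normalization**: min-max per gene (default) or global; constant rows
  map to 0.5. Chosen because the renderer needs values in [0, 1] to color
  channels directly.
* **Symbol filter**: an explicit approved-symbol file (a HUGO snapshot or
  the generator's list) rather than a live service, for reproducibility.
* **Gene subsetting**: the pipeline accepts an externally computed
  significant-gene list (the intended source is a mutation-significance
  tool such as MutSigCV, which is out of scope here); absent a list, the
  top-k genes by variance (k = 14 by default) stand in.
* **Sample alignment**: intersection of the three omics' sample sets with
  the labelled samples. Missing cells on read default to dropping the
  gene (complete-case policy); zero-imputation is available.

The selected-gene count is a parameter (default 14).

## PaCMAP

* **Local scale**: `σ_i` is the mean Euclidean distance from point `i` to
  its 4th–6th nearest neighbors; ranking covers all other points
  (duplicates included) with ties broken by smaller index, making the
  whole construction deterministic. If four or more exact duplicates
  collapse a `σ_i` to zero it is floored at the smallest positive `σ`.
  At least 7 points are required.
* **Pairs** (per anchor): `n_nb = 10` neighbors under the scaled distance
  `‖X_i−X_j‖²/(σ_i σ_j)`; `n_mn = 5` mid-near pairs, each the
  second-closest of 6 uniformly sampled distinct candidates (plain
  Euclidean ranking); `n_fp = 20` uniformly sampled non-neighbors.
  Counts are proportioned 1 : 0.5 : 2 and clamped on small point sets
  (at most `n−1` neighbors, at most `n−1−n_nb` further pairs), which
  matters for the 14-gene default map.
* **Losses and weights**: the three pair losses of the README; weights
  `w_NB = 2`, `w_FP = 1` throughout; `w_MN` anneals linearly 1000 → 3
  over phase 1 (100 iterations), holds at 3 in phase 2 (100), and is 0 in
  phase 3 (250). The phases move the layout from global structure to
  local refinement. Phase counts of zero are accepted (the optimizer then
  returns the initialization, useful for testing); the defaults are
  always positive.
* **Optimization**: full-batch adaptive-moment (Adam-style) updates,
  step 1.0, decay 0.9/0.999, epsilon 1e-7. The gradient is analytic
  (`d(loss)/d(d̃)` in closed form per pair class) and is verified against
  central finite differences in the tests.
* **Initialization**: top-2 PCA projection scaled by 0.01, so early
  attractive forces act on a compact layout.

The scaled distance is used only for neighbor *selection*; all losses are
evaluated on unscaled embedded distances. The embedding is deterministic
given the seed (pair sampling is the only stochastic step).

## Rendering

The embedding is mapped affinely (one isotropic scale, translation
centered) into the pixel rectangle inset by `radius + margin`; embedding
x → column, y → row; a single gene (or fully coincident genes) maps to
the image center. Defaults: 64×64 canvas, radius 4 px, margin 2 px,
black background, `max` blending of overlapping discs (a `mean` option
exists). Channel intensity is `round(255 · value)`; pixels beyond every
disc stay background, so a sample contributes no color away from gene
sites. Discs are hard-edged (no anti-aliasing) so renders are exactly
reproducible byte-for-byte.

## CNN

Three convolutional blocks — 32 filters of 3×3 (valid padding), ReLU,
2×2 max-pool (strides 1, 1, 2), batch normalization, dropout 0.20 / 0.20
/ 0.50 — then flatten and a single dense softmax layer. The loss is
categorical cross-entropy (the only consistent reading of a softmax
classifier); the optimizer Adam with learning rate 0.05 for 80 epochs,
batch size 32, on a 70/30 stratified split. The network is implemented
directly in NumPy (im2col convolutions, equal-split tie gradients in the
pool backward, inverted dropout, per-channel batch norm with running
statistics for inference); the convolution, pooling, batch-norm and
dense backward passes are finite-difference checked in the test suite. Training is deterministic given the seed and
single-threaded BLAS.

With learning rate 0.05 the training loss oscillates late in training
(visible in the per-epoch history); batch normalization keeps the runs
finite and the held-out metrics stable at the default problem sizes.

## Evaluation

Recall, precision, accuracy and F1 are computed from one-vs-rest
confusion counts; micro averaging pools counts before applying the
formulas (so micro precision = micro recall = accuracy for single-label
data), macro averages per-class values; 0/0 is reported as 0 with a
warning. Both averages are always reported; micro is the headline number.
AUC is one-vs-rest per class via the Mann–Whitney rank statistic
(average ranks give ties half credit), macro-averaged; classes absent
from the truth are skipped with a warning.

## Synthetic data

The generator emulates the shape of a three-class prostate-cancer grading
cohort: 387 samples, 2000 raw genes of which 14 carry signal, balanced
classes. For signal gene `g` and omic `o`, class `c` draws from
`N(base(g,o) + c · effect_size, noise_sd²)` truncated to [0, 1], with
`base ~ U(0.25, 0.45)`, `effect_size = 0.2`, `noise_sd = 0.08` — an
adjacent-class separation of 2.5 sd per gene per omic, which across
14 genes × 3 channels makes classes clearly separable, emulating the
near-perfect separability the method targets. 10% of raw genes are
near-constant (sd 0.01, below the variance threshold), 5% carry
probe-style names absent from the approved list, and the methylation
table drops 5% of samples so the complete-case intersection path always
runs. Class sizes follow largest-remainder apportionment of the
proportions.

What the generator does *not* model: CNA discreteness, methylation
beta-value distributions, gene–gene correlation structure, batch effects,
class imbalance beyond the proportion vector. Passing tests therefore
demonstrate that the pipeline recovers planted mean-shift signal and does
not leak labels — not that it reaches any particular accuracy on real
cohort data.

## Numerical choices and degenerate inputs

* Ties in all nearest-neighbor rankings break toward the smaller index
  (stable sorts), making σ, neighbor pairs and mid-near ranking
  deterministic.
* Constant rows normalize to 0.5; all-identical point sets are rejected
  by PCA initialization; fewer than 7 points are rejected by σ.
* The pool backward splits gradient equally among tied window maxima.
* One global seed fans out to per-stage seeds via a SHA-256 hash of the
  stage name, so stages can be re-run in isolation.
* Heavy end-to-end runs (the acceptance script and the two end-to-end
  tests) use 32×32 images with radius 3: the image size is a free
  rendering knob, and 32×32 retains every gene disc while keeping a full
  387-sample, 80-epoch training run at a few minutes on one CPU. The
  library default stays 64×64.

## Known limitations

* Exact (O(n²)) neighbor search: appropriate for the few-dozen-gene maps
  the pipeline targets, not for embedding thousands of points.
* The CNN is CPU-bound NumPy; minutes per run at the default sizes, not
  suited to large image sets.
* Multi-class AUC averaging is fixed to macro one-vs-rest.
* The train/validation curves reported during training use the held-out
  test set as the validation set; there is no third split.
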