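# Methods

## Problem setting

A whole-slide image (WSI) is a gigapixel scan of a stained tissue section.
Only a slide-level diagnosis is available, yet the diagnostic evidence is
carried by a small fraction of the slide's area. We treat the slide as a
*bag* of instances — patch-level feature vectors `x_i ∈ R^D` with level-0
pixel coordinates — and learn a bag classifier by attention pooling
(multiple instance learning, MIL). Feature extraction itself is out of
scope: bags of precomputed descriptors (e.g. from a pathology foundation
model, D = 512) are the input contract, and a toy random-projection
extractor exists only so the image path can be tested end to end.

## Models

All architectures share a fully connected transform with ReLU,
`h_i = relu(W1 x_i + b1)`, `h_i ∈ R^L`, with inverted dropout (rate 0.25)
on `h_i` in training mode.

**SAB (single attention branch).** Gated attention scores

    a_i = w^T ( tanh(V h_i + b_v) ⊙ σ(U h_i + b_u) ) + b_w,

softmax over the instances, `α = softmax(a)`; bag representation
`M = Σ_i α_i h_i`; a linear classifier `R^L → R^C` and softmax give class
probabilities. The sigmoid branch gates the tanh branch multiplicatively,
which lets the score saturate differently per hidden direction.

**MAB (multiple attention branches).** One `(V_c, U_c, w_c)` attention
triple and one scalar-output classifier per class; branch c produces its
own `α_{·,c}` and `M_c`, classifier c maps `M_c` to one logit, and the
final softmax is over the C logits. With all branches tied the logits are
equal and the output is exactly uniform — a structural identity the tests
pin down.

**DIP (dynamic instance pruning).** A two-layer perceptron
(linear → ReLU → linear → scalar) scores each *raw* instance feature;
the K highest-scoring instances (ties broken by lower index, K ≥ N keeps
all) are passed to SAB. The scorer input is raw features by default with a
`score_transformed` switch, because the scoring of untransformed
descriptors is the cheaper and more specific reading of the design; the
hard top-K means the scorer receives no gradient from the bag loss, so its
projection stays at initialization — DIP is a fixed random prefilter
unless K ≥ N. This is a property of the architecture as stated, not a bug,
and is consistent with DIP trailing the attention models empirically.

**SA-k (stochastic attention).** During training only, after computing α,
a subset of k instances is drawn without replacement with probability
proportional to α (Gumbel-top-k keys `log α_i + G_i`, equivalent to
sequential draws proportional to the remaining weights and reproducible
under a seeded generator); the sampled weights are renormalized and the
bag representation is the renormalized weighted average of the subset.
Evaluation reverts exactly to SAB — the eval path is literally the SAB
code, so the equality is bit-for-bit. The sampling acts like dropout on
the attention distribution: the model cannot rely on a few high-attention
instances, which counters attention concentration. A `replacement=True`
variant is available behind a flag. Note the renormalized subset average
is exactly unbiased for the full aggregate only at k = 1 and trivially at
k = N; for intermediate k it is biased (measured at ~10–16% of the
aggregate's scale under near-uniform attention), which is irrelevant to
its role as a regularizer but worth knowing when reasoning about it as an
estimator.

**Decision rule.** `argmax` over the class probabilities, ties broken by
the lowest class index.

**Implementation.** Everything is NumPy (float64) with hand-derived
analytic gradients and a plain Adam optimizer; the test suite checks every
architecture's gradients against central finite differences (max error
< 1e-6 at eps = 1e-6). An optional instance-level clustering term
(cross-entropy of a shared instance classifier on the top-attention
instances, pseudo-labeled with the bag class) exists behind
`clustering_weight` and is OFF by default: the training objective is the
bag-level cross-entropy alone.

Hidden widths default to L = 128 and attention width 64 — desk-scale
choices; both are configurable and nothing in the package depends on them
structurally.

## Training protocol

Repeated random sub-sampling: `n_runs = 10` independent 75 / 12.5 / 12.5
train/validation/test partitions of the slide ids (12.5% fractions use
banker's rounding; the shuffled list is consumed validation first, then
test, then train, making each partition a pure function of (seed,
run_id)). Splits are *not* stratified by class; imbalance is handled by
weighted sampling — each training epoch is `|train|` single-bag draws with
replacement, slide probability proportional to 1/count(class), so
expected draws per class are equal. Adam at learning rate 2e-4, batch
size 1 (a bag's instances must be pooled jointly), at most 50 epochs,
early stopping when the validation loss has not improved for 10
consecutive epochs, best-epoch parameters restored. Model selection uses
the validation loss only. Reported metrics are unweighted means of the
per-run test metrics.

## Metrics

Balanced accuracy (unweighted mean of per-class recall over classes
present in the ground truth), Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e
from the marginal products (κ = 1 by convention when both sides are
constant and identical), and one-vs-rest AUC-ROC / AUC-PR in macro and
micro averages. Macro averages *skip* classes with no positives or no
negatives (with a warning) rather than scoring them zero; micro averaging
flattens the (indicator, probability) pairs. AUC tie handling is by
midranks; average precision is step-interpolated. Confidence intervals
are percentile bootstrap, resampling slides with replacement, 1000
repetitions at the 95% level; resamples on which a metric is undefined
are redrawn and counted.

## Model comparison

The comparison unit is the per-run test metric (paired across models by
shared splits). Pairwise: two-sided Wilcoxon signed-rank with zero
differences dropped and midranks for tied |d|; the p-value is exact for
n ≤ 25 retained pairs — computed by integer convolution over the 2^n sign
assignments conditional on the observed (doubled) ranks, verified against
explicit enumeration for n ≤ 10 — and a tie-corrected normal
approximation beyond. Omnibus: tie-corrected Friedman chi-square
(m ≥ 3 models), which reduces to `12n/(m(m+1)) Σ_j (R̄_j − (m+1)/2)²`
without ties. Post hoc: Nemenyi critical difference
`CD = q_α(m) √(m(m+1)/(6n))` with the two-tailed infinite-df
Studentized-range-derived q table (already divided by √2) embedded for
m ≤ 20 at α ∈ {0.01, 0.05, 0.10}. Ranks run 1 = best = highest metric.
CD-diagram cliques exploit that "within CD on the rank line" is an
interval relation: maximal cliques are maximal windows of the rank-sorted
models.

## Tissue segmentation and tessellation

Pipeline: read the image at a coarse level (for pyramidal TIFFs, the
coarsest level with longest side ≥ 1024 by default; plain images are one
level with downsample 1) → RGB to HSV → saturation channel scaled to
0–255 → median filter (odd kernel, default 7) → binary threshold
(strictly greater than sthresh, default 8, so raising the threshold can
only shrink the mask) → subpixel marching-squares contours with
parent/child nesting (a contour's tissue/hole role is its nesting parity;
parents by polygon containment) → two-stage area filter: tissue contours
kept when shoelace area ≥ athresh (default 100 px at the segmentation
level), holes kept when area ≥ hole_athresh (default 16 px) *and* their
parent survived — both comparisons inclusive, both computed before
scaling → vertices scaled by the downsample and rounded half away from
zero to level-0 integers. The threshold defaults follow the magnitudes of
the common upstream WSI pipeline and are all overridable; none of them is
printed by any source of record, so they are package choices.

Tessellation keeps every grid-aligned `patch_size` (default 256) square
fully inside the image whose *center* lies strictly inside a tissue
polygon and outside every hole — the cheapest deterministic inclusion
rule; patches are pairwise disjoint by grid alignment. The patch manifest
carries a `qc_pass` column as a hook for patch-level quality control
(blur/artifact rejection), which is not implemented.

## Heatmaps

Per-slide min-max normalization of the per-patch scores, each patch
footprint painted with its normalized value at the rendering downsample;
pixels outside every footprint keep a sentinel and pass the thumbnail
through unchanged when the colormapped raster is alpha-blended
(`(1−α)·thumb + α·color`). For MAB the predicted class's branch weights
are rendered; no smoothing between patches. The colormap is configurable;
direction (which end of the map means "high attention") follows the
colormap's own convention.

## Synthetic data

`generate_bag_dataset` emulates the weak-supervision structure: C class
prototypes are near-orthogonal random directions scaled so pairwise
distances equal the separation δ; each bag of class c holds
`ceil(π N)` signal instances `~ Normal(prototype_c, σ² I)` at uniformly
random positions and `N − ceil(π N)` noise instances `~ Normal(0, σ² I)`.
Per-instance ground-truth flags are returned, enabling direct attention
quality measurement. Defaults — C = 5 classes (mirroring the five ovarian
carcinoma histotypes), 20 bags/class, N ∈ [100, 300], D = 64, π = 0.05,
σ = 0.5, δ = 5 — are sized so the full repeated-split study trains in
minutes on one CPU while leaving the per-instance discrimination
non-trivial (signal and noise clouds are 7σ apart along one direction of
a 64-dimensional unit-variance cloud). What the generator does *not*
emulate: spatial correlation between neighboring patches, stain and
scanner variation, class-dependent instance counts, and any instance-level
ambiguity between classes — so passing learning tests demonstrates that
the architectures, gradients and protocol work, not that real-slide
accuracy would match.

`generate_tissue_image` renders saturated disks (tissue), background
colored disks inside them (holes) and tiny saturated speckles (artifacts
meant to fall below the area filter) on a near-white canvas, with exact
rasterized masks.

## Numerical choices and degenerate inputs

Softmaxes subtract the maximum; the sigmoid is evaluated piecewise to
avoid overflow; cross-entropy clamps probabilities at 1e-300. Top-K and
sampling tie-breaks are by lower original index via stable sorts. Argmax
ties break low. Empty scenes segment to empty masks (not errors); empty
bags, NaN features, duplicate coordinates and malformed containers raise
typed validation errors. A NaN training loss aborts with the epoch and
bag named.

## Known limitations

* The DIP scorer is untrained by construction (see above); a
  straight-through or perturbed top-K would be needed to learn it.
* SA-k's convergence is slower than SAB's by roughly N/k in transform
  gradient signal per step; under few-epoch budgets and low signal
  prevalence it can fail to leave the chance plateau where SAB still
  learns — the regularization benefit appears once both models actually
  fit (with enough epochs SA-k overtakes SAB on held-out data in our
  synthetic runs).
* Bootstrap CIs are percentile, not BCa; on tiny test folds the macro
  AUCs may be undefined and are reported as NaN.
* Only plain and multi-page-TIFF pyramids are read; vendor WSI container
  formats are out of scope.
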