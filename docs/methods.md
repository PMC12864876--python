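# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## Synthetic scenes

The generator emulates the three properties of field pest imagery that drive
the architecture: multi-scale objects, cluttered backgrounds, texture-borne
class identity. A scene is a low-frequency green/brown color field (cubic
interpolation of a 6×6 Gaussian grid) with optional high-frequency clutter
(speckle plus randomly oriented "blade" strokes, amount set by
`background_complexity` ∈ [0,1], default 0.5), on which elliptical pest
blobs are placed by rejection sampling so their boxes never overlap. Class
identity is a texture family — spots, stripes, concentric rings, cycling
with a hue rotation for more than three classes — on a reddish body with a
darkened rim. Additive Gaussian pixel noise (`noise_sigma`, default 0.02 on
the [0,1] intensity scale) is applied last.

Defaults: 64×64 px scenes, 3 classes, 1–3 pests per scene, pest diameter
10–22 px. Every scene is a pure function of `(seed, index)` via
`SeedSequence`, so datasets are reproducible across processes. The train/test
split takes `floor(train_fraction · n)` scenes for training, assigned
sequentially by index (scene content is i.i.d. across indices; a seeded
shuffle is available). Persistence uses PNG + COCO-style JSON (boxes stored
as x, y, width, height) with a flat CSV mirror; boxes are 0-based, half-open
pixel rectangles throughout, which makes pixel-counting IoU arithmetic exact.

What the generator does **not** emulate: real insect morphology, occlusion,
lighting/perspective variation, motion blur, and class-imbalanced long tails.
Passing the end-to-end tests therefore shows the pipeline is implemented
correctly and can learn texture-defined classes at multiple scales — not
that it would meet any particular accuracy on field data.

## Detector

Backbone: five 3×3 stride-2 convolutions (ReLU) producing C1..C4 at strides
4/8/16/32 with stage widths `base·(1,2,4,4)`, `base = max(2,
hidden_width // 8)`. The pyramid merge is the standard top-down rule
`D_j = Upsample2x(D_p) + D_h` with 1×1 lateral projections to the common
width `hidden_width` (the detector's tunable gene, [5, 255]). The AdaUp
stage multiplies each level by `sigmoid(gate_l)` with learnable gates
initialized at 0 (scale ½). The head is shared across levels: 1×1 conv to
`min(hidden_width, 64)` channels, ReLU, 1×1 conv to 5 outputs — the 64-cap
keeps the cost of the upper gene range desk-scale while the pyramid itself
still widens with the gene.

Training targets use center sampling: a cell is positive when its center
lies inside a ground-truth box **and** within 0.35·sqrt(area) of the box
center, on every level whose stride lies in [size/8, size] (finest level as
fallback). Center sampling empirically halves the false-positive rate and
improves box regression versus all-cells-inside assignment. The loss is
balanced binary cross-entropy on objectness (positive and negative cells
each normalized separately, negatives weighted 2.0) plus smooth-L1 (β = 0.1,
weight 2.0) on normalized offsets at positive cells. Offsets are
(dx/stride, dy/stride, log w/stride, log h/stride).

Inference thresholds sigmoid objectness at 0.5 and applies greedy NMS at
IoU 0.3 (duplicates across neighbouring cells and pyramid levels overlap
only moderately, so the standard 0.5 leaves duplicates).

## Classifier

Crops are cut with 10% context padding and bilinearly resized to 32×32.
Token scales are (32, 16) with 8×8 patches, embedding dimension 32, 4
attention heads: 16 + 4 = 20 fused tokens. Attention blocks are pre-norm
with residual connections. Fusion weights are softmax-normalized learned
scalars (so they always sum to 1), followed by one cross-scale attention
block whose attention matrix supplies the significance signal: the mean
attention each token receives (column mean over heads and queries),
renormalized to mean ½ per sequence so the logit shift of the input gate is
centered at zero. Significance is treated as a gating signal and not
backpropagated through. The LSTM hidden width is the classifier's tunable
gene ([5, 255], default 48). Ablation switches (`use_attention`,
`use_adaptive`, `use_lstm`) reduce the model to a plain LSTM, an
attention-only classifier (mean-pooled fused tokens), or a fused model
without adaptive gating.

In the pipeline, classifier training crops are augmented with two jittered
copies per annotation (center shift up to 12% of the box size, scale
0.9–1.15×). Detector proposals are never pixel-perfect; without this
proposal-noise emulation, a classifier at 0.99 accuracy on exact crops drops
to ≈ 0.78 on matched detections, with it the pipeline retains 0.95–0.99.

## Training engine

Both models train on `pestpyramid.nn`, a tape-based reverse-mode autodiff
over float64 numpy arrays (dense/conv linear maps via im2col, elementwise
nonlinearities, softmax, nearest-neighbour upsampling), verified against
central finite differences to < 1e-7 in the test suite. The optimizer is
Adam. The learning-rate genes span [0.01, 0.99], far above stable step
sizes for these networks, so the effective rate is `gene × 0.01`: the
search interval is preserved while every gene value remains trainable.
Divergence (non-finite loss) aborts with a diagnostic naming the epoch and
gene value. All initializations and batch shuffles derive from per-stage
`SeedSequence`s of the configured seed, so same-seed runs are bit-identical.

## Metrics

All count metrics are plain ratios of the TP/TN/FP/FN quadruple; undefined
denominators raise a named `UndefinedMetricError` (aggregating reports
substitute 0, the sklearn `zero_division=0` convention). MCC returns 0 when
any marginal is zero. Count-IoU and CSI are the same ratio by definition
and both are exposed. Bookmaker informedness defaults to the literal
sensitivity+specificity form, with `subtract_one=True` for the standard
informedness. Detection matching is greedy in descending score with each
ground-truth box consumed at most once (community default; threshold 0.5).
ROC uses descending unique-score thresholds with ties grouped and
trapezoidal AUC, which equals the Mann–Whitney pair statistic (asserted in
tests against both the pair count and scikit-learn). Multiclass aggregation
is macro (unweighted one-vs-rest mean) by default with micro counts
available.

## Optimizer

The population loop evaluates all members, records best/worst/mean fitness,
and updates each member: with probability `explore_prob` (linear 0.25 → 0.05
over the run) a uniform resample within bounds, otherwise the exploitation
move `x′ = o^t · (x_j − x_i) · cos(2πh) + x_best` with a random distinct
partner j, clipped to bounds. Elitism reinserts the incumbent best verbatim
in place of the worst new member, making the best-so-far trace monotone.
Integer genes are kept real during search and rounded half-up at evaluation.
Candidate evaluation failures score the penalty cap 1e6 and the run
continues.

Two design choices required empirical resolution and are deliberate:

- **Signed span.** With a scalar cosine factor, an absolute span
  |x_j − x_i| confines every exploitation step to the all-same-sign diagonal
  orthant around the attractor; in d > 1 the search then relies entirely on
  uniform exploration and stalls around 1e-1 on the 4-D sphere. The signed
  difference keeps the move isotropic.
- **Step annealing o^t.** Without it the population either collapses onto
  the best point (no refinement) or is held at the exploration scale.
  The default `contraction = 0.94` was calibrated once on the
  sphere/Rosenbrock design study; at population 10 / 50 iterations both
  variants then reach ~5e-3 median on the sphere, with EIGBO-RE at least as
  good as the uniform-h baseline.

`compute_h` returns exactly 0.5 in the all-equal case (its algebraic fixed
point, short-circuited to avoid roundoff) and falls back to 0.5 whenever
the denominator is ≤ 1e-12 — including negative denominators, which occur
when the population mean exceeds worst² + best + current².

The pipeline objective is JK = 1/accuracy + 1/IoU, with classification
accuracy measured on matched detections and count-IoU from the detection
match counts; either term ≤ 1e-9 scores the penalty cap.

## Pipeline and problem sizes

The standard desk-scale condition is 3 classes, 64×64 scenes, 200 train /
50 test, detector 40 epochs, classifier 30 epochs — chosen so a full joint
run takes ~25 s on one CPU and a 3-seed replication stays under two minutes.
Unmatched (false-positive) detections are classified but excluded from the
classification confusion matrix: no ground-truth label exists for them, so
they count only as detection false positives. Gene tuning in the paired
with/without-optimization comparison runs a reduced budget (population 4–6,
5–10 iterations, ~30–60 train scenes, few epochs per candidate) so the
comparison completes in minutes; the published population settings
(10 × 50) are exercised on the analytic sphere benchmark where evaluation
is cheap. k-fold evaluation pools all scenes, partitions them with seeded
folds differing in size by at most one, and flags (but does not fail on)
folds missing a class.

## Known limitations

- The detector's precision (~0.4–0.7 at threshold 0.5) trails its
  sensitivity; the acceptance bars target sensitivity and box quality, and
  residual false positives are excluded from classification scoring by the
  matching step.
- Metaheuristic conclusions are benchmark-scale: 4 genes, cheap objectives.
  Nothing here compares EIGBO-RE against modern Bayesian or bandit tuners.
- The autodiff core is minimal by design (no GPU, float64 only, no
  broadcasting conv); it is sized for the desk-scale problems above.
- Synthetic-data caveats listed in the first section apply to every
  reported score.
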