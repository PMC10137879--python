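# Methods

## Model

The package implements transductive node classification on a cohort
graph.  Nodes are subjects; node features are the M = r(r−1)/2 unique
weights of each subject's symmetric structural connectome (strict upper
triangle, row-major — any fixed order is equivalent for the model, but a
canonical order keeps files interchangeable).  Edges carry the Gaussian
similarity kernel

W_ij = exp(−d(x_i, x_j)² / (2σ²)),

with d the Euclidean distance between raw feature vectors.  The kernel's
published typesetting is ambiguous between exp(−d²/(2σ²)) and
exp(−d/(2σ²)); the Gaussian form is the default (it matches the described
limits W(0)=1, W→0, and the prior population-graph literature), and the
distance-exponential form is available as `kernel="exp_distance"`.  The
graph is fully connected — no k-NN sparsification or thresholding — and
features enter the distance unscaled (connectome weights are already
bounded in [0, 1]); per-feature z-scoring is available behind
`standardize=True`, off by default.

Each GCN layer applies the renormalized propagation rule
S = D̃^{−1/2}(A+I)D̃^{−1/2} (first-order Chebyshev approximation of
spectral graph convolution; all eigenvalues of S lie in [−1, 1]).  The
adjacency diagonal is forced to zero before adding I, so each self-loop
contributes exactly 1.  Block order is graph conv → batch norm → ReLU →
dropout for the hidden blocks, and graph conv → batch norm → softmax for
the output block.  The final graph convolution maps its (by default
128-dimensional) input to 2 output channels: a softmax over binary risk
labels requires a 2-channel head, so the configured filter width is the
block's input width.  Dropout (rate 0.5 by default, unstated in the
source protocol) is applied inside hidden blocks only, not to the input
features.

## Training

Loss is the masked cross-entropy over training nodes,
−mean_i β_i log p(y_i), with inverse-frequency class weights
β_c = N_mask/C_c computed on the training mask only (`loss="weighted"`),
or β ≡ 1 (`loss="unweighted"`).  Probabilities are clamped at 1e−12
inside the log.  A single-class training mask is rejected.  Optimization
is full-graph Adam (lr 0.01, decay rates 0.9/0.999) for up to 2000
epochs with no early stopping by default (an optional patience-based stop
exists, off by default).  Weights are Glorot-uniform from the config
seed; batch norm starts as the identity.  Positive (high-risk) is class 1
everywhere; prediction is the row argmax with exact ties resolved to
positive.

The engine is plain numpy with hand-derived gradients (graph conv, batch
norm, ReLU, inverted dropout, softmax cross-entropy).  Correctness is
pinned in the test suite by (a) a central-difference gradient check at
1e−5 relative tolerance and (b) a per-node brute-force aggregation oracle
for the forward pass at 1e−10.

**Batch normalization in transductive training.**  Batch norm operates
per channel across all graph nodes — the only batch available in
full-graph training — and evaluation mode uses running moments.  Two
numerical points deserve note.  First, on a dense similarity graph S is
close to a global averaging operator, so per-channel variances across
nodes can be small and batch norm's 1/√var amplifies any mismatch between
running and actual moments.  Second, running moments accumulated with
momentum during training trail the continually-updated weights.  Because
the evaluation batch in transductive learning *is* the training batch,
the exact moments are available: after the last epoch the running moments
are recalculated in one dropout-free full-graph pass at the final
weights.  Without this recalibration, evaluation-mode predictions can
diverge arbitrarily from training-mode behavior on dense graphs.

## Evaluation protocol

Labeled subjects are partitioned into 5 near-equal portions per repeat;
unlabeled subjects never appear in a test fold but remain in the training
graph when `include_unlabeled=True`.  Folds are stratified by class by
default (the source protocol says only "partitioned into 5 portions", but
at a 1:2 ratio with ~119 labeled subjects unstratified folds make
fold-level sensitivity unstable; a non-stratified mode exists).  The
allocator places per-class remainders into the folds with the smallest
running totals, so 119 subjects always split as {24, 24, 24, 24, 23} —
note that off-the-shelf stratified splitters put all remainders in the
first folds and would give {25, 25, 23, 23, 23}.  Each repeat
re-randomizes both fold membership and weight initialization (the
protocol does not state which of the two the published 50 repetitions
re-randomize; both is the conservative reading).  Per-fold training seeds
derive from (base seed, repeat, fold, config seed), making every report
byte-reproducible.

Metrics: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
balanced accuracy (their mean, exactly), and AUC via the rank statistic
with midranks for ties (NaN for single-class truth).  Paired model
comparisons collapse each report to repeat-level means and use a paired
t-test (default; the source does not name its test) or Wilcoxon
signed-rank; zero-variance differences short-circuit to p = 1 (identical)
or p = 0 (constant shift).

Baselines run on the labeled subjects' raw feature vectors under the
identical fold assignments: class-weighted logistic regression, ridge
classifier, linear and RBF SVMs (scikit-learn, `class_weight="balanced"`),
and a feed-forward network with weighted cross-entropy.  The network is
realised by the package's own GCN engine with an identity propagation
operator (A = 0 ⇒ S = I), which reduces each block to a dense layer —
i.e., a 2-hidden-layer perceptron of the GCN's width (128 units, ReLU,
dropout 0.5), giving a fair features-only comparison with the same loss
and optimizer.  σ (and filter/layer counts) can be swept as an outer grid
reported per configuration, mirroring the published model selection;
selecting σ on test AUC leaks information, so grid sweeps should be read
as sensitivity analyses rather than unbiased estimates.

## Synthetic cohorts

No public accession exists for the clinical cohort, so all testing runs
on generated data.  `generate()` emulates the study's structure: 119
labeled + 105 unlabeled subjects, labeled prevalence 37/119, 90-ROI
connectomes whose edge means are drawn once per cohort from a
Beta(2.5, 4.5) on [0, 1] (mean ≈ 0.36, the scale of tract-averaged FA;
drawing the base once keeps between-subject similarity high so the kernel
produces a non-trivial weight distribution).  The positive class loses
`effect_size` FA units on a fixed random `affected_fraction` of edges;
every edge receives i.i.d. Gaussian noise and is clipped to [0, 1]
(clipping affects well under 1% of draws at defaults).  Motor scores are
drawn class-conditionally, N(100 − 30·class, 15), clipped to [40, 160]
and dichotomized at 85 = 100 − 15; class first, score second, so the
same cohort tests both label-based and score-based entry points, with
~16% score/class disagreement per class from distribution overlap.
Unlabeled subjects carry a latent class that shapes their connectome but
is withheld.  Default signal parameters (effect 0.005, affected fraction
0.15, noise SD 0.05) are calibrated so cross-validated discrimination on
the default cohort falls in the 0.6–0.8 AUC band typical of
connectome-based outcome prediction rather than a separable regime.

`generate_manifold_cohort()` places the two classes on interleaved
one-dimensional arcs (the two-moons layout, jitter 0.1) in a 2-D latent
space embedded along two orthonormal random edge-space directions scaled
by `effect_size`.  Few labeled points under-determine the boundary while
unlabeled points trace the arcs; this is the construct on which including
unlabeled nodes in the graph demonstrably raises test accuracy.

What the generators do **not** emulate: spatial autocorrelation of edges
within a connectome, site/scanner effects, motion artifacts, non-Gaussian
heavy-tailed edge noise, and any topological (small-world/modular)
organisation of the parcellation.  Passing tests therefore certify the
pipeline's statistical machinery — not clinical performance on real
cohorts, whose published headline numbers are not reproducible without
the restricted data and are not asserted anywhere in this package.

## Problem sizes used in the test suite

Simulation-backed properties run at reduced scale, chosen as the
package's own test design: recovery uses the full 224-subject cohort
shape at 30 ROIs, 32 filters, 200 epochs and 5 repeats; the
semi-supervised-gain property uses 20 labeled + 200 unlabeled manifold
subjects at 10 ROIs over 20 paired repeats; the loss-weighting
equilibrium uses 90 labeled (1:2) + 45 unlabeled subjects at 20 ROIs over
20 paired repeats.  All use the same code paths as full-scale runs; only
cohort, width and epoch counts shrink.

## Known limitations

- Transductive inference: predicting a new subject requires rebuilding
  the graph with the training subjects present and re-running the forward
  pass with saved weights (`predict` enforces this contract).
- Full-graph training is O(N²·M) per epoch in time and memory via the
  dense kernel matrix; fine for cohorts of hundreds, not for thousands.
- The Gaussian kernel on raw 4005-vectors concentrates distances; σ far
  from the data's distance scale yields a near-uniform graph in which
  graph convolution averages away the signal.  The σ grid exists
  precisely to tune this.
- Batch-norm running moments are recalibrated on the training graph; for
  augmented-graph prediction the moments are *not* recomputed on the new
  graph, matching the saved-model contract.
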