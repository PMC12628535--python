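# Methods

## Problem and model

`methylcl` classifies fixed-length RNA windows (default L0 = 41 nt, the
standard window size of public RNA-methylation benchmark sets) as centred on
a methylated site (label 1) or not (label 0). Benchmark collections of this
kind are balanced 1:1 and often sample-limited — hundreds rather than tens of
thousands of positives — which is the regime the architecture targets: a
multi-view encoder regularised by a SimCLR-style contrastive objective so
that useful representations can be learned from few labels.

Each window is represented in two views.

**Primary view (token embedding).** The sequence is decomposed into
overlapping k-mers (stride 1, default k = 6), bracketed by `[CLS]`/`[SEP]`,
giving L0 − k + 3 tokens over a vocabulary of 4^k k-mers plus five special
tokens (`[PAD]`, `[UNK]`, `[CLS]`, `[SEP]`, `[MASK]`). The vocabulary is a
DNA alphabet; U is read as T at lookup time, since RNA and DNA windows differ
only by the thymine/uracil substitution. Gap-containing k-mers map to
`[UNK]`: a gap carries no sequence identity and the vocabulary has a
dedicated unknown token. Tokens are embedded either by a trainable lookup
table (default, D = 32, seeded normal initialisation, weights tied across
positions) or by a frozen pretrained DNA language model (D = 768) loaded
from a local directory; the lookup backend is the self-contained default and
the one all tests exercise. Which hidden layer of a pretrained model to use
is an open choice; we take the final hidden layer, the conventional
feature-extraction surface.

**Auxiliary view (chaos-game representation).** The classic CGR iterated
function system assigns A, C, G, T/U the unit-square corners (0,0), (0,1),
(1,1), (1,0) and walks p_i = p_{i−1} + α (v_{x_i} − p_{i−1}) from the
centroid p_0 = (0.5, 0.5) with α = 0.5. Each position is collapsed to the
scalar state y_i − x_i ∈ [−1, 1], giving an L0 × 1 matrix. Each step halves
the influence of the prefix, so the state carries the current base plus an
exponentially decaying positional memory. Gap-padded positions freeze the
walk (p_i = p_{i−1}, state repeated, 0 if leading): padding must not
fabricate geometry. The handling of gaps is this package's convention — the
standard CGR is defined only over concrete bases.

## Architecture

* **Branch 1** (primary view): same-padded 1-D convolution (64 filters,
  kernel 3, stride 1 — kernel count and width are our defaults, configurable),
  ReLU, batch normalisation, dropout 0.3; a bidirectional LSTM with 64 units
  per direction; group normalisation with 4 groups; dropout 0.3 (applied
  after both the convolutional and recurrent stages); tanh attention pooling
  e_t = v·tanh(W_a h_t + b_a), a = softmax(e), c = Σ_t a_t h_t, giving a
  128-dimensional context vector.
* **Branch 2** (auxiliary view): a bidirectional LSTM (64 units/direction)
  over the CGR states, summarised by concatenating the two directions' final
  hidden states (mean-pooling available by flag); 128 dimensions.
* **Fusion**: h = [c ; branch-2 summary] ∈ R^256.
* **Projection head** g(h): one hidden dense layer (ReLU, dropout 0.1) to
  z ∈ R^P with P = 64 ≪ 256. Computing the pairwise-similarity matrix on z
  costs O(B²P) + O(BDP) instead of O(B²D) on h. The head is used only during
  training; inference consumes h.
* **Classifier**: dense 256 → 128 → 64 → 2, ReLU, dropout 0.1, softmax.

Ablation variants reproduce the reduced models: `cnn` (convolution +
mean-pool), `cnn_bilstm` (final-state summary, no attention), `cba` (full
branch 1), `cba_bil` (dual branch, no contrastive term) and the
contrastive-trained `s_cba`, `s_bil`, `s_cba_bil`.

## Training objective

Per sample the augmentation stage draws two independent operators, each
applying random feature masking to the embedded token matrix (an element
survives when U(0,1) > p_mask; element-level by default, whole-token rows by
flag) and additive Gaussian noise (scale η) to the CGR states. Defaults
p_mask = 0.15, η = 0.01 are the grid-search optimum over
p_mask ∈ {0.05, …, 0.25} × η ∈ {0.005, …, 0.04}; the grid search itself is
re-runnable (`methylcl gridsearch`).

The NT-Xent loss over the 2N projections (temperature τ = 0.5 — unstated in
the source description, so we adopt the original SimCLR small-batch setting)
is combined with categorical cross-entropy on a clean (unaugmented) forward
pass — classification should see uncorrupted inputs; a flag averages the two
augmented views instead — as L_total = L_cls + λ·L_cont. λ starts at 0.5,
is frozen for 10 epochs, then moves by 0.05 (our step size) toward [0.3, 0.5]
bounds following the sign of the least-squares slope of validation accuracy
over a 5-epoch window. Whether training is single-stage joint or two-stage
(contrastive pre-training, then supervised fine-tuning) is ambiguous in the
source description; we default to single-stage joint optimisation and keep a
`two_stage` flag.

Optimisation uses Adam (base LR 1e−3, batch 32 — unstated, our defaults),
a 5-epoch linear warm-up from base_lr/5 followed by per-epoch exponential
decay at 0.9 (the ramp shape and decay granularity are our choices within
the stated 5-epoch/0.9 schedule), early stopping on validation accuracy with
patience 15 and restoration of the best checkpoint. Cross-entropy clamps the
true-class probability at 1e−12.

## Numerical core

No deep-learning framework is used: the network runs on a compact
reverse-mode autodiff engine over dense float64 numpy arrays
(`methylcl.autodiff`), with the LSTM recurrence fused into a single
tape node with a hand-written backpropagation-through-time rule and the
convolution implemented by im2col. Every primitive and the fused recurrence
are verified against central finite differences in the test suite
(tolerances ~1e−6). Softmax and NT-Xent use max-shifted exponentials;
the NT-Xent denominator excludes self-similarity by additive −1e30 masking.

## Evaluation

Threshold metrics (Sn, Sp, Acc, Pre, F1, MCC) are exact formula evaluations
of explicit TP/TN/FP/FN counts at threshold 0.5. Zero denominators yield 0
with a `degenerate` flag rather than an exception so one bad fold cannot
abort a sweep. AUROC integrates the ROC curve by the trapezoid rule
(equivalently: the probability a random positive outscores a random
negative, ties ½ — the test suite checks this equivalence exhaustively);
AUPRC integrates the precision–recall curve by trapezoids. Repeated-run
stability derives per-run seeds deterministically from a master seed; the
cross-modification matrix trains on each dataset and scores every dataset's
test split.

Interpretability utilities: (1) mean absolute gradient of the positive-class
probability with respect to the embedded inputs, aggregated per sequence
position (each token's magnitude spread evenly over the k positions it
covers, since tokens are discrete, plus the CGR branch's per-position
magnitude); (2) perturbation importance — the mean absolute change in the
positive-class probability when a position's base is substituted by each of
the three alternatives (all four for gap positions); the precise
perturbation operator is this package's construction; (3) per-dimension
Welch two-sample t-statistics of h between classes (the Welch form is our
choice; dimensions constant in both classes give NaN sentinels).

## Synthetic data

The generator emulates the structure of the real benchmark sets: balanced
classes, fixed length 41, uniform base composition by default (skewed
compositions configurable). Positives carry an IUPAC-degenerate motif
(default GGACU, the canonical DRACH-like core, planted at the window centre)
with probability `insertion_prob`; negatives are rejection-sampled to be
motif-free at the planted offset only, keeping generation O(n) — a
background occurrence elsewhere in a negative is allowed, as in real data.
Splits are stratified (default 75/25). What passing tests show: the pipeline
can extract a localised, linearly separable signal and does not fabricate
one under the `insertion_prob = 0` null. What they do not show: performance
on real epitranscriptomic contexts, whose k-mer statistics, motif degeneracy
and label noise the generator does not model.

## Problem sizes used by the checks

The end-to-end learnability check trains the full dual-branch contrastive
model on 600 train / 200 test synthetic records (lookup backend, default
hyper-parameters, ≤ 30 epochs); the ablation-ordering check compares
variant medians over 3 seeds at a reduced scale (180/60 records, 16-unit
layers, 8 epochs); statistical checks of the augmentation operators use 10^5
draws. These sizes are the package's chosen desk-scale study conditions.

## Known limitations

* The pretrained DNA language-model backend is optional and untested here;
  all results use the trainable lookup embedding, whose capacity is far
  below a 768-dimensional pretrained transformer.
* CPU-only, float64, batch-level parallelism only; wall-clock is minutes per
  training on desk-scale data, not suited to 10^5-sample corpora.
* Single-stage joint optimisation is the default; true SimCLR two-stage
  pre-training is implemented but not the tested path.
* The adaptive-λ trend test uses a plain least-squares slope with no
  significance filter; noisy validation accuracy can make λ oscillate
  within its bounds.
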