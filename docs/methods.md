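# Methods

## The optimizer

HHO maintains M hawk positions in a box [L, U]^D. Each iteration, per hawk,
an initial energy G0 ~ U[−1, 1] is drawn and the escaping energy
G = 2·G0·(1 − i/I) computed; |G| gates the branch:

| condition            | branch                         |
|----------------------|--------------------------------|
| \|G\| ≥ 1            | exploration (perching)         |
| \|G\| ≥ 0.5, q ≥ 0.5 | soft besiege                   |
| \|G\| < 0.5, q ≥ 0.5 | hard besiege                   |
| \|G\| ≥ 0.5, q < 0.5 | soft besiege with rapid dives  |
| \|G\| < 0.5, q < 0.5 | hard besiege with rapid dives  |

with q ~ U[0, 1] drawn only in exploitation. Because |G| ≤ 2(1 − i/I),
exploration is impossible past the halfway iteration; the branch log
(`track_branches=True`) exposes this for auditing.

Design choices where the formulation is genuinely open:

* **Absolute-value bars** are kept in every update rule (exploration, both
  besieges, both dive anchors), following the original HHO formulation;
  without them the rules are a different algorithm and diverge.
* **Bound handling**: componentwise clipping to [L, U] after every update —
  the de-facto standard for HHO. Dive candidates are clipped *before*
  evaluation so fitness is only ever measured at feasible points.
* **Acceptance**: the plain exploration/besiege rules replace the hawk's
  position unconditionally (as in the original algorithm); the two dive
  strategies are greedy with strict `<`, and a dive whose both candidates
  A and B fail to improve leaves the hawk in place. Ties keep the
  incumbent everywhere, including the best-so-far update, for stability.
* **Lévy flight**: Mantegna construction, `scale·u/|v|^(1/β)` with
  `u ~ N(0, σ(β)²)`, `v ~ N(0, 1)`, default β = 1.5 and scale 0.01.
  σ(1.5) ≈ 0.696575. Uniform draws in (0,1) would destroy the heavy tail
  the dives rely on, so Gaussian draws are used.
* **Randomness**: one `numpy.random.Generator` per run; the draw order is
  fixed and documented per operation (G0, then q, then the branch's own
  draws; inside a dive: n5, then — only if the direct move is rejected —
  V, then the Lévy pair). Identical config + seed gives a bit-identical
  trajectory. Non-finite objective values at dive candidates are treated
  as worse-than-current; at initialization they are a hard error.

Objective evaluations per run are bounded by M·(1 + 2I): one per hawk per
iteration for the plain branches, at most two for a dive, matching the
linear O(M·I·D + M) cost profile.

## Dimensionality reduction

PCA (singular-value route, columns centered) retains the smallest k whose
cumulative explained-variance ratio reaches the threshold, default 0.99 —
the stage's purpose is to retain 99% of the table's variance. The
threshold is configurable in (0, 1].

The subset search runs HHO over [0, 1]^k. A position maps to a mask by an
inclusive 0.5 threshold; an all-below-threshold position falls back to its
single largest component, so masks are never empty. The wrapper fitness is
penalized stratified-CV error with a fast estimator (default KNN, 5 folds,
α = 0.01 size penalty, seeded shuffling) — the standard objective in
wrapper selection. Masks are memoized within a search, so revisits are
free. The pipeline order is PCA first, subset search on the retained
components, so the selector refines an already-reduced representation;
running it on raw features is the same call with a different matrix.

## Classifiers

The dense network is implemented in numpy: Glorot-uniform init, minibatch
training, binary cross-entropy on a single sigmoid output. The reference
schedule is five hidden layers, softsign activations, Adam, 600 epochs,
batch 64. Hidden widths are a free design choice; the default pyramid
(64, 32, 16, 8, 4) matches small-tabular practice and is configurable. The activation family (ReLU, ELU, SELU,
tanh, softplus, softsign, softmax, sigmoid) and optimizer family (SGD,
Adam, NAdam, RMSprop, Adagrad, Adadelta, Adamax — conventional default
learning rates) are implemented so the architecture sweeps run natively.
Inputs are z-scored with training-set statistics inside `fit`; the raw
table mixes counts near 40 with normalized values near 0.1, which stalls
saturating activations otherwise. No early stopping by default (the
reference schedule trains the full budget); a flag exposes it.

Baselines are the standard library implementations (decision tree, KNN,
Gaussian NB, SVC, XGBoost) with library-default hyperparameters, pinned to
one thread and a seed where they accept one; all are wrapped in a uniform
handle returning hard labels plus continuous scores (probability of the
positive class, or the SVM decision function).

## Evaluation protocol

A single seeded stratified holdout, 80/20 by default; repeated splits are
available by varying the seed. Metrics
come from raw TP/TN/FP/FN counts; recall and sensitivity are the same
formula TP/(TP+FN) and are reported identically (comparison tables that
print them differently are footnoted, not reproduced). Zero-denominator
metrics are NaN and flagged `undefined`, never silently zero. The identity
accuracy = (sens·P + spec·N)/(P + N) is asserted numerically in tests.

Reductions are fit on the training rows only and applied to both sides.
Fitting on all rows would leak held-out information into the comparison,
so the leakage-safe order is a deliberate choice and is guarded by a test that
poisons held-out rows with sentinels and checks the fitted PCA is
unchanged.

## Synthetic data

The generator emulates the Debrecen schema per column family: Bernoulli
flags (quality 0.996, pre-screening 0.92, AM/FM 0.35), Poisson
microaneurysm counts with rates (40, 33, 26, 20, 13, 7) non-increasing
along the confidence ladder, exponential exudate features with tapering
scales, uniform [0, 1] geometry columns, labels at the real table's
positive fraction 0.531. Informative columns (default: the four mid-ladder
count columns) get a class-conditional mean shift of `effect_size` column
standard deviations (rate shift for Poisson, scale shift for exponential,
clipped shift for bounded families). A second generator,
`generate_planted_scores`, produces standard-normal score-like matrices
with a planted informative subset for selector benchmarks.

What the synthetic tables do **not** emulate: inter-feature correlation
structure (real microaneurysm counts are strongly correlated across the
ladder), heavy-tailed measurement artifacts, and any image-level
provenance. Passing tests therefore demonstrate correctness of the
machinery and recoverability of a planted signal — not clinical
performance. Headline accuracies reported for the real study (e.g. 97%
for the network with PCA+HHO) depend on the external UCI table and an
architecture that is not fully specified, and are not reproduction
targets here.

## Problem sizes and schedules

The fast schedule — network epochs 50, HHO population 10 with 30
iterations — is the default for the experiment matrix and keeps the full
18-cell run around a second on one CPU at n = 1151; `paper_scale=True`
restores the 600-epoch budget. Benchmarks use: sphere convergence at
M = 30, I = 500, D = 10 over 10 seeds; selector recovery at n = 1000,
12 columns, 4 informative, effect 1.0, population 15, 40 iterations over
10 seeds. These sizes were chosen once as the package's reference
conditions.

## Known limitations

* Box constraints only; no general constraint handling, no parallel or
  island populations, no other metaheuristics.
* Binary masks use a static 0.5 threshold, not a sigmoid transfer
  function; transfer-function variants are out of scope.
* No ROC/AUC (not in the metric set of record) and no significance
  testing between models.
* The network trains on CPU with dense numpy ops; it is sized for tabular
  inputs, not images.
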