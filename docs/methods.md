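# Methods

## Problem setting

The classifier decides whether the adenosine at the center of a
fixed-length RNA segment is N6-methylated. Segments are odd-length strings
over {A, C, G, U} (T is converted to U on input); the center base is
expected to be A, enforced as a warning by default and as an error in
strict mode, since user-supplied candidate lists do not always guarantee
it. Benchmarks in this field use L = 21, 25, 41 and 101; all lengths are
supported.

## Sequence-derived encoders

Seven encoders turn a segment into a numeric block. The stateless ones
(CTD, PseKNC, NPS, NCP-ND, EIIP) are pure functions of the sequence; the
class-conditional ones (NPPS, BPB) have fit/transform semantics and are
fitted on the training split only, so encoding held-out data never touches
held-out labels (a property test deletes held-out samples and checks the
remaining encodings are unchanged).

Conventions that the one-line textbook definitions leave open, fixed here:

* **CTD transition** — for each of the 6 unordered distinct base pairs,
  the count of adjacent occurrences in either order divided by L − 1 (the
  standard nucleotide-CTD transition). **Distribution** — for each base,
  the relative positions (1-based position / L) of its 1st, ⌈0.25n⌉-th,
  ⌈0.5n⌉-th, ⌈0.75n⌉-th and n-th occurrence; five zeros when the base is
  absent.
* **PseKNC** — defaults k = 3, λ = 2, w = 0.1. The six dinucleotide
  properties (Shift, Slide, Rise, Tilt, Roll, Twist) ship as a JSON table
  of the widely used RNA base-step parameters and are z-scored across the
  16 dinucleotides with the population standard deviation, so each
  property row has mean 0 and variance 1 exactly; the table is
  user-replaceable. All 4^k + λ components of the output sum to 1 by
  construction.
* **NPS / NPPS pair convention** — a k-spaced pair occupies positions
  (i, i + k + 1), i.e. k intervening bases; the pair table therefore has
  L − k − 1 start positions and the NPPS output has width L − k − 1. This
  is the only reading consistent with the stated matrix widths; prose
  formulations that say "the (i+k)-th nucleotide" are treated as shorthand
  for it.
* **NPPS division by zero** — if a conditioning base never occurs at a
  position in one class's training data, the conditional probability for
  that class is defined as 0 (the conditioning event carries no
  information). Output features lie in [−1, 1] because each conditional is
  a sub-event ratio in [0, 1]. The default configuration concatenates the
  k = 1 and k = 2 blocks.
* **EIIP constants** — A 0.1260, C 0.0806, G 0.1335, U 0.1340.
* **NCP codes** — A (1,1,1), U (0,1,0), C (0,0,1), G (1,0,0) for
  ring structure, hydrogen bonding and functional group; density of
  position i is the count of that base among positions 1..i divided by i.
* Counting is on the literal segment only, never the reverse complement:
  m6A is a strand-specific RNA mark.

## Similarity graph (FLNSA)

Each sample is reconstructed as a nonnegative weighted combination of its
c nearest neighbors (Euclidean distance; ties broken toward the lower row
index). The objective implemented is

F(W) = ½‖X − (C∘W)X‖²_F + (μ/2)‖(C∘W)e − e‖²,  W ≥ 0 on the support C,

i.e. the row-sum constraint is enforced as a quadratic penalty. Written
with the constraint substituted, the penalty term is constant, which is
why the formulation is sometimes displayed without the "− e"; the
multiplicative update

W ← W ∘ (XXᵀ + μeeᵀ) / ((C∘W)XXᵀ + μ(C∘W)eeᵀ)

is exactly the majorize–minimize update of the penalized form and
provably never increases F when X is elementwise nonnegative. Features
are therefore min–max rescaled to [0, 1] per column before learning
(NPPS features can be negative). At exit the rows of C∘W are renormalized
to sum exactly 1. A per-iteration monotonicity assertion (slack 1e−9) and
a comparison against an independent per-row simplex quadratic program
(SLSQP) guard the solver; the oracle comparison uses μ = 5 because the
oracle enforces the row-sum constraint exactly and a loose penalty would
compare two different optimization problems.

Defaults: c = 10, μ = 1.0, max_iter = 200, tol = 1e−6 on the objective
decrease, threshold t = median of the positive symmetrized weights. W is
row-oriented; the undirected graph uses max(W, Wᵀ) so a strong
one-directional neighbor relation survives, then thresholds, binarizes and
zeroes the diagonal. If the graph is disconnected, c doubles (capped at
m − 1) and learning reruns; at c = m − 1 with t = 0 the graph is complete,
so the escalation terminates.

The graph is built over training and test samples jointly (the
transductive protocol of this method family — no labels are involved). An
inductive mode restricts the graph to training samples and assigns each
test sample the embedding of its nearest training neighbor, for users who
prefer a stricter separation.

## Graph embeddings

* **SocDim** — eigenvectors of the d algebraically largest eigenvalues of
  the modularity matrix B = A − ddᵀ/(2|E|). The edge-count normalizer is
  the one that makes B's rows sum to zero (a descriptions-vary point; a
  switch provides the literal node-count variant). For large graphs B is
  applied implicitly as a sparse matvec plus a rank-one correction
  (ARPACK); columns are unit-norm with the largest-magnitude entry made
  positive for sign stability.
* **Node2Vec** — second-order walks with return parameter p and in-out
  parameter q (weight 1/p to the previous node, 1 to common neighbors of
  the previous node, 1/q otherwise), then skip-gram with negative sampling
  over the walk corpus. Both the walk sampler and the SGNS trainer are
  implemented in-package with numba-compiled inner loops: dynamic window,
  unigram^0.75 negative table, linearly decaying learning rate, one shared
  seed. Defaults: p = q = 1, 20 walks of length 30 per node, window 5,
  5 negatives, 3 epochs, dimension 16.
* **GraRep** — for k = 1..k_max, the positive log matrix
  max(log(Tᵏ_ij / colmean_j(Tᵏ)), 0) of the row-stochastic transition
  matrix T is factorized by seeded randomized truncated SVD; the k-step
  representation is U_d√S_d with the same sign convention; defaults
  k_max = 2, 16 dimensions per step.

Embedding widths default to 16 per method so roughly 48–64 embedding
columns supplement the few-hundred-column sequence blocks rather than
dominating them.

## Classifier

Gradient-boosted decision trees behind a two-backend interface: LightGBM
(default: 500 iterations, depth 6, 2^depth leaves, learning rate 0.05,
logloss, deterministic single-threaded mode) and scikit-learn
GradientBoostingClassifier with matched hyperparameters. Class imbalance
is handled with per-sample weights; "auto" gives class y the weight
N/(2·N_y), so the two classes carry equal total weight. Feature
importances use the backend's gain importance; per-block aggregates sum a
block's columns, and the report states the fraction of the top-20 columns
contributed by embedding blocks. Automatic block selection trains a probe
model on an internal stratified 75/25 split of the training data and keeps
the n blocks with the largest aggregate importance; an explicit block list
in the configuration always wins.

## Evaluation

ACC, SEN, SPE (percent), F1, and MCC from the confusion counts; MCC is 0
by convention when a denominator factor vanishes, keeping degenerate folds
defined. AUC uses the Mann–Whitney rank formulation with half credit for
ties; the ROC curve enumerates every distinct score threshold, and its
trapezoidal area equals the rank AUC to machine precision (asserted at
1e−12). A brute-force per-sample tally and scikit-learn serve as
independent cross-checks in the tests.

## Synthetic benchmark generator

Emulates the published datasets' shape: odd-length segments, forced
center A in both classes, positives carrying an RRACH-style IUPAC
consensus centered on the site, each motif position following the
consensus with probability `motif_strength` (ambiguity codes resolved
uniformly), everything else drawn from the background distribution
(uniform by default; a skewed preset mimics mRNA composition). Class
ratio is free, covering the 1:1 and ~1:4 protocols. An optional secondary
off-center motif copy gives spaced-pair features signal beyond the center
window.

What the generator does not emulate: genomic context and co-transcriptional
covariates, sequence redundancy/homology between samples, the clustered
positional structure of real peak-derived negatives, and non-uniform motif
usage across transcripts. Passing tests on this data therefore demonstrate
that the machinery recovers planted sequence signal under controlled
conditions, not field performance on any particular organism.

## Problem sizes and reproducibility

The end-to-end checks use 1,000 + 1,000 segments at L = 41 (balanced) and
400 + 1,600 at L = 21 (imbalanced) — large enough that held-out AUC has a
standard error of about 0.02 or less, and the null-control benchmark
(motif strength 0) uses a 50/50 split so its chance-level band (±0.05) is
several standard errors wide. One global seed drives four stage seeds
(split, similarity learning, embeddings, booster) derived through a seed
sequence; the run manifest records the configuration and seeds, and
replaying it reproduces the metrics report bit-for-bit (tested).

## Known limitations

* The ordered-boosting variant of gradient boosting described for this
  method family is not among the available backends; LightGBM's leaf-wise
  trees are used instead, and headline numbers differ accordingly.
* The published benchmark FASTA files are not bundled; the presets pair
  each published feature-block list with a synthetic dataset of matching
  length and class ratio. On real data, users should supply the FASTA
  pair and expect the published block lists to be starting points, not
  optima.
* The skip-gram trainer is single-threaded by design (determinism over
  speed); embedding very large graphs (>10^5 nodes) would need a faster
  backend.
* FLNSA's dense m×m Gram matrix bounds the transductive graph to a few
  tens of thousands of samples in 8 GiB of memory.
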