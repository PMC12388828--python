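# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `rnaensemble`.

## Representations

A secondary structure is a set of base pairs `(i, j)`, `i < j`, 0-based,
with each position in at most one pair; equivalently an `n×n` binary
symmetric contact matrix `Z` with zero diagonal and row sums ≤ 1. The two
views are kept consistent by construction (`ContactMap`). File formats
(dot-bracket, CT, BPSEQ) use their native 1-based conventions; pseudoknots
are carried on input and output through additional bracket alphabets
(`[]`, `{}`, `<>`, then `Aa`, `Bb`, …), with the writer assigning each pair
greedily to the first layer it does not cross. Non-ACGU residues are kept
in sequences but excluded from pairing at the constraint-mask level.

## Ensemble models

Input is the stack `A ∈ {0,1}^{l×n×n}` of `l` base-learner contact maps.

**Attention ensemble.** Channel attention computes per-learner descriptors
by average- and max-pooling each slice over both spatial axes, passes both
through a shared two-layer perceptron (`l → max(l/r, 1) → l`, ReLU hidden),
and squashes the sum: `F_p = σ(MLP(avg) + MLP(max))`, `A′ = F_p ⊗ A`.
Spatial attention pools `A′` across the learner axis into a 2-channel
descriptor (per-cell mean and max), convolves it with a learned 7×7 kernel
(same zero padding, scalar bias) and squashes: `F_d = σ(conv₇(D))`,
`A″ = F_d ⊗ A′`. A learned channel-reduction head produces the pair
probability map `Y = σ(Σ_c w_c A″_c + b)`.

Choices that were genuinely open:

- *Reduction ratio* `r` defaults to 1 (no bottleneck): the usual CBAM
  default of 16 is meaningless for `l = 4` learners; `r` is configurable.
- *Channel-reduction head*: a learned linear mix across the `l` refined
  channels plus sigmoid is the minimal end-to-end way to turn the `l×n×n`
  refined stack into one per-pair probability; no residual connection from
  `A` is added.
- The head weights start at 1 and the bias at −0.5, so the untrained
  network is already a soft vote count; attention MLP and conv weights
  start small (`0.1·N(0,1)`).

**Lite ensemble.** One raw weight per learner; `π = softmax(raw)`
(max-subtracted for stability) and `Y = Σ_v π(v) A(v)`. Since `π` lies on
the simplex and the slices are binary, `Y ∈ [0,1]` with no extra squashing.
The model is affine in `π` and monotone: raising a learner's weight never
lowers a cell that learner predicts.

Because the whole parameter set is tiny (≈150 numbers for `l = 4`), both
models run in numpy with hand-derived backpropagation. Max-pool gradients
route to the first arg-max on ties; the convolution backward pass is the
standard correlate/convolve pair; all gradients are verified against
central finite differences (tolerance 1e-4, observed ≲1e-9) in the tests.

## Training

Weighted binary cross-entropy over contact-map cells,
`−[w·y·log p + (1−y)·log(1−p)]`, with positive-class weight `w = 300`
(the positive:negative cell ratio is ~1:2n); probabilities at the exact
0/1 boundary are clamped to 1e-7. Optimization is Adam (β₁=0.9, β₂=0.999,
ε=1e-8) at learning rate 1e-3 by default, batch size 4, sequences longer
than 500 nt excluded. Examples in a batch are zero-padded to the batch
maximum with validity masks; the forward pass runs on the unpadded block
(every mask is a top-left block), so pooling statistics never see padding
and padding provably leaves per-example losses unchanged.

Model selection: after every epoch the validation set is predicted, decoded
under the default decoder settings, and scored; the checkpoint with the
best median validation F1 is returned, ties resolved in favor of the later
epoch (training loss is still descending). F1 was chosen as the selection
metric because it is the primary evaluation metric throughout; cell-wise
accuracy is useless at this class imbalance.

Checkpoints are JSON (parameters, learner names and order, `l`, `r`, seed,
format version); loading refuses a checkpoint whose learner order differs
from the supplied stack.

## Constrained decoding

Hard validity rules: canonical + G-U pairs only; symmetry; `|i−j| ≥ 4`; at
most one partner per base. The sequence-derived mask `M` enforces the
first and third; `φ(Y) = ½(Y+Yᵀ) ⊙ M` the second. The one-partner rule is
the matching program `argmax ⟨Ŷ, φ⟩ − ρ‖Ŷ‖₁` s.t. row sums ≤ 1,
`Ŷ ∈ [0,1]`, symmetric — the penalty `‖Ŷ‖₁` is read entrywise (it controls
sparsity), which makes the integral problem a maximum-weight matching on
the edges with `φ > ρ`.

- **Exact solver (default).** Blossom maximum-weight matching
  (networkx) on edges `{(i,j): φ_{ij} > ρ}` with weights `φ − ρ`. The
  returned soft assignment carries the `φ` scores on the support of the
  optimal matching: the support is the arg-max (the optimum sets Ŷ = 1
  there), but retaining the scores lets the final threshold prune matched
  pairs the model is not confident about. This matters: a sigmoid-output
  network is strictly positive wherever the mask allows, so a decoder that
  kept *every* matched edge would return a near-maximal matching regardless
  of the model. Carrying confidence into the threshold step reproduces the
  role thresholding plays after a soft relaxation, and makes `P`
  meaningful for both solvers.
- **Relaxation solver.** Primal-dual hybrid gradient (PDHG) on the LP
  relaxation over the positive-gain upper-triangle entries, with one
  multiplier per base pricing its partner budget. Step sizes respect the
  incidence-operator norm (`1/√(2·max degree)`), the dual step uses the
  extrapolated primal iterate, and the second-half iterate average is
  returned after a row-scaling feasibility projection. Default budget
  2000 iterations. Because the LP upper-bounds the integral matching
  optimum and PDHG provably converges, the solver empirically attains
  ≥ 99.9% of the exact optimum on random instances. A plain fixed-step
  projected ascent was tried first and stalled near 95% on degenerate
  instances, which motivated this scheme.
- **Thresholding.** Entries strictly greater than `P` (default 0.5) become
  pairs; an entry exactly equal to `P` is excluded. The decoded structure
  is asserted (not repaired) against all four rules.

Defaults `ρ = 0` and `P = 0.5` are exposed; no published values exist for
either.

## Synthetic data

The generator defines the study conditions for all training experiments.

**Structures.** A stochastic stem/loop grammar: the exterior is a run of
stems with short unpaired spacers; each stem opens a pair and extends
inward with probability 0.75 per additional pair (mean stem ≈ 4 bp), then
closes with a hairpin of ≥ `min_loop` = 3 unpaired bases, continues through
an interior loop, or branches into a multiloop with probability 0.15.
Paired positions get Watson-Crick complements, or G-U with probability 0.1;
loops are uniform random bases. Every generated pair satisfies the hard
constraints by construction. Lengths are drawn uniformly from the
configured range (40–80 nt for the benchmark experiments).

**Learners.** Each simulated learner keeps every true pair independently
with probability `sensitivity` and adds `Poisson(rate·n/100)` spurious
pairs drawn from the constraint-valid, currently-unpaired pairs, weighted
by its `bias_mode`: uniform, span-proportional (`long_range`),
inverse-span (`short_range`), or 50× preference for ±1–2 register shifts
of true helices (`shift`). The benchmark default is four learners at
sensitivity 0.8 and 8 spurious pairs per 100 nt with the four distinct
biases — single-learner median F1 ≈ 0.72 and pairwise Jaccard distances
within the 0.3–0.65 band observed for real predictors. Per-learner RNG
substreams are derived from `(global seed, seed_offset)`, so adding a
learner never perturbs the others' draws.

**What the simulator does not capture.** Real predictor errors are
correlated with sequence family, length and pairing context, not
conditionally independent given the truth; real learners also share
training data and therefore share systematic errors. Passing the synthetic
benchmark shows the ensemble machinery works when learners have partially
independent error modes — it does not bound performance on real predictor
panels, where inter-learner correlation will shrink the ensemble gain.

## Evaluation

Scoring is over the `n(n−1)/2` unordered position pairs `i < j`, not the
full matrix: symmetric cells would double-count every decision. This
halves TN relative to full-matrix counting and therefore changes INF
magnitudes; the choice is stated here because conventions differ silently
in the literature. Scores: precision, recall, F1 (0/0 → 0), and
INF = (TP·TN − FP·FN)/√((TP+FP)(TN+FP)(TP+FN)(TN+FN)) (0 on a zero
factor), which equals the Matthews correlation coefficient — asserted
against an independent MCC implementation in the tests. Pair scoring is
exact-match only (no ±1 slipped-pair tolerance). Concordance between two
predictions is the Jaccard distance of their pair sets (both-empty → 0);
ROC curves pool upper-triangle scores across sequences with trapezoidal
area. The subset search trains a lite ensemble on every nonempty learner
subset (refusing `l > 10` without force) and reports per-subset and
best-by-size F1. The PCA embedding concatenates each algorithm's flattened
squared-error maps against the truth into one feature vector and takes the
first two components across algorithms; this concatenated-error reading is
one of several possible constructions and is flagged as such.

## Problem sizes in the verification battery

The acceptance battery uses: 200 random decodes (n ∈ [10,100]) for
constraint satisfaction; 50 instances (n ≤ 14) against brute-force matching
enumeration; 1000 random confusion vectors for INF ≡ MCC; 100 structure
pairs for metric oracles; 100 structures for I/O round-trips; 300
structures (240 fit / 60 held out, 12 epochs) for the ensemble-gain
benchmark; 60 structures (40 epochs, learning rate 0.1) for oracle-weight
recovery; 100 structures (15 subsets, 6 epochs) for the subset search; and
a 14-structure end-to-end pipeline run twice for determinism. These sizes
were chosen so the full battery completes in about a minute on one CPU
while keeping every comparison statistically unambiguous.

## Known limitations

- The attention ensemble consumes only base-learner matrices; no
  sequence-derived features (one-hot outer products, thermodynamic priors)
  are used.
- Decoding permits crossing pairs (matching imposes no planarity), but no
  pseudoknot-specific machinery is included; training data may optionally
  drop crossing pairs.
- The numpy training loop is single-threaded and intended for the small
  models shipped here, not for re-training large predictors.
- Statistical comparison between algorithms is limited to the reported
  score tables; no significance testing is built in.
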