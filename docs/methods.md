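# Methods

## Problem setting

`interlink` predicts a binary clinical outcome (for example short- versus
long-term survival of a tumor cohort, coded −1/+1) for patients profiled on
two expression layers — genes and miRNAs — plus a catalogue of known
miRNA → target-gene relations. Patients are nodes of a similarity graph;
labels propagate over edges by graph-based semi-supervised learning (SSL).
The package's specific contribution is a *cross-layer* similarity measure:
when part of the gene-expression similarity structure is missing, a graph
reconstructed from the miRNA→target coupling can stand in for it.

## Graphs

**Intra-relation graph.** For one expression matrix, edge weights are a
Gaussian kernel on Euclidean distance,

    w_ij = exp(−‖x_i − x_j‖² / σ²),

restricted to pairs where either patient lists the other among its k
nearest neighbours (the OR rule, which keeps W symmetric). Features are
standardized (zero mean, unit variance per feature) before distances so no
feature dominates through scale. Defaults: k = 5; σ² equals the median of
the nonzero squared pairwise distances (the median heuristic). Both are
exposed in every constructor; neither value is sharply critical at desk
scale, but very small k fragments the graph and very large σ flattens the
weights. k-NN ties are broken by patient order so graph construction is
deterministic.

**Inter-relation (reconstructed) graph.** The two layers have different
dimensions, so no ordinary vector metric applies across them. Instead, for
patients i and j,

    f_ij = Σ_{(l,m) ∈ targets} miRNA(i, l) · gene(j, m),

summing the product of a miRNA's (standardized) expression in patient i and
its target gene's expression in patient j over exactly the catalogued
pairs. The raw scores are z-normalized over all N² entries (population
standard deviation), passed through a logistic, symmetrized by arithmetic
mean with the transpose, and the diagonal zeroed. Constant scores (an
uninformative target map) are a hard error rather than a silent all-0.5
graph.

**Orientation of the logistic.** The logistic can be applied as σ(Z)
(`orientation="positive"`) or σ(−Z) (`"repression"`, the default for the
target-pair measures). The default matters: miRNAs *repress* their
targets, so for a patient pair sharing the same regulatory state the sum
couples high miRNA values with low target values and comes out strongly
*negative* — coherence lives in the lower tail of the score distribution.
With centered (standardized) expression one can make this exact: writing
gene(·, m) ≈ −ρ · miRNA(·, l) + noise for a repression pair with strength
ρ > 0, the class-relevant part of f_ij is −ρ Σ_l miRNA(i, l)·miRNA(j, l),
which is negative precisely when i and j have aligned miRNA profiles.
Under σ(+Z) the most coherent pairs would therefore receive the *lowest*
weights, producing a graph that actively connects opposite-outcome
patients; empirically such a graph drives the fused prediction to
chance-or-worse. σ(−Z) turns repression coherence into similarity. Both
orientations are kept because a target catalogue mixing activating and
repressing relations, or uncentered positive-valued expression data, can
shift where coherence lands.

**Alternative measures.** For comparison, four other cross-layer measures
are implemented: GR1, the Hadamard product of the two patient–patient
Pearson correlation matrices (element-wise, since a matrix product of
correlation matrices is not symmetric), pushed through the same
normalization; GR2, a Gaussian k-NN graph on concatenated standardized
gene + miRNA profiles; GR3, GR2 restricted to features that occur in the
target map; GR4, a gene-centric variant of the pair sum that averages the
miRNAs targeting each gene (equal to the main measure when every gene has
exactly one targeting miRNA). The main miRNA-centric sum is tagged GR5.

## Semi-supervised solver and graph fusion

Scores solve min_f (f−y)ᵀ(f−y) + μ fᵀLf with L = D − W the unnormalized
Laplacian and y the label vector with zeros for unlabeled patients; the
unique minimizer f = (I + μL)⁻¹y is computed by a Cholesky-backed SPD
solve, never an explicit inverse. ‖f‖ ≤ ‖y‖ always (the resolvent's
eigenvalues lie in (0, 1]), which the tests assert.

Several Laplacians are fused by minimizing the convex objective
yᵀ(I + Σ_k α_k L_k)⁻¹ y over α ≥ 0, Σα ≤ budget, via projected gradient
descent with backtracking line search (Euclidean projection onto the capped
simplex; stop when the objective decrease falls below 1e−10 or after 1,000
iterations). The gradient in α_k is −fᵀL_k f with f the current solve. The
objective is non-increasing in every coordinate, so the budget is generally
exhausted; with identical graphs the split is non-unique and only the
objective value is determined. Prediction then uses f = (I + Σα_k L_k)⁻¹y.
The smoothness trade-off (`mu_smooth`, default 1.0) and the coefficient
budget (`mu_budget`, default 1.0) are deliberately separate parameters even
though both control total regularization.

## Evaluation protocol

- **Feature selection:** per-feature two-sample t statistic on training
  labels only, Welch's unequal-variance form by default (pooled variance is
  a switch); top features by |t| with ties broken by feature order.
  Zero-variance features get |t| = ∞ if the class means differ, 0 if not.
  Defaults keep 11 genes and 19 miRNAs.
- **Cross-validation:** stratified 5-fold, 3 repeats, fold shuffles and all
  damage draws seeded from one root seed through fixed derivation paths, so
  a configuration is exactly reproducible. Stratification matters because
  a 28-patient minority class over 5 folds can otherwise yield single-class
  folds. Selection and fusion coefficients are refit inside every fold.
- **Graph kinds:** GO (intra graph on selected genes), GD (GO with an
  exact round(fraction·E) of undirected edges removed uniformly at random),
  GR (reconstructed), GA (fusion of GD and GR). Damage fractions default to
  {0, 0.1, 0.3, 0.5, 0.7, 0.9}.
- **Metrics:** AUC on the raw test-patient scores (rank form of the
  Mann–Whitney statistic, ties counted ½); GD and GA are compared per
  damage fraction with a two-sided Wilcoxon signed-rank test on the
  15 paired per-fold AUCs. The signed-rank p-value is exact for up to 25
  nonzero differences — computed by convolving the rank-count
  distribution, which handles tied absolute differences via average ranks,
  a case standard exact implementations refuse — and uses the tie- and
  continuity-corrected normal approximation above that.
- **Importance:** AUC_diff(g) = AUC(selected set) − AUC(set minus g) under
  the identical CV protocol; large positive values mark features whose
  removal hurts.

## Synthetic cohorts

The generator emulates a two-layer tumor cohort at desk scale: 82 patients
(54 vs 28 classes), 200 genes, 60 miRNAs, 120 target pairs of which 15 are
informative — dimensions small enough that the full experiment runs in
seconds, while a cohort-scale configuration (tens of thousands of genes) is
just a config change. Marginals are Gaussian: the method consumes
already-normalized expression, so no attempt is made to mimic raw
microarray distributions. Class signal is planted through informative
miRNA–target pairs (each on its own miRNA and gene): the miRNA gains a mean
shift of `effect_size` (default 1.5, in noise-SD units) in the +1 class and
the target gene is −`repression_strength` (default 0.8) times the miRNA
signal plus independent noise, so the pair is anticorrelated like a real
repression pair and the gene inherits an attenuated class shift. Vote
counts are uniform on 1..11, mirroring an 11-program prediction catalogue,
so vote-threshold filtering is exercisable; the threshold has no privileged
default and the CLI requires it explicitly. All randomness flows from one
seed; identical configurations are bitwise reproducible.

What the generator does *not* emulate: heavy-tailed and nonnegative
expression marginals, gene–gene co-expression blocks, batch structure,
label noise, and target-catalogue errors (planted pairs are always true
pairs). Passing tests therefore show the machinery is correct and the
qualitative damage/augmentation behaviour holds under clean planted
signal; they do not certify performance on real cohorts, where the central
question — how much a target catalogue can compensate for missing
expression similarity — depends on data idiosyncrasies the generator does
not model. At the default effect size the desk-scale task is easy (AUCs
near 1), which is intended: the experiment's object is the *gap* between
damaged and augmented graphs, not absolute AUC.

## Numerical and degenerate-input choices

- Constant features standardize to all-zero columns instead of dividing by
  zero; duplicate patients get distance 0 and weight 1.
- A Laplacian is validated structurally (symmetry, zero row sums,
  nonnegative degrees); the SPD solve itself is the final arbiter and
  raises if I + μL is not positive definite.
- `predict_labels` maps a score exactly at the threshold to +1.
- Sign thresholding never enters evaluation; AUC always uses raw scores.
- Patients must appear in identical order across all inputs; mismatches are
  hard alignment errors, not silent reindexing.

## A note on "leakage" under transduction

The solver is transductive: test patients' *features* are always visible
(they shape the graph), only their labels are masked. One consequence is
worth knowing: with imbalanced labels the global score mean is nonzero, and
any structure that perturbs test-node degrees — including class clusters
formed by the test patients among themselves — modulates how strongly each
score shrinks toward that mean. This moves AUC away from 0.5 without any
label information flowing. It is a property of unnormalized-Laplacian SSL,
not a bug; the leakage test in the suite therefore uses balanced classes,
where this pathway vanishes and any residual AUC shift would indicate
genuine label leakage. A complementary exact check asserts that flipping
test-fold labels changes no score bit.

## Known limitations

- The cross-layer pair sum is a global measure; it cannot express that only a
  subgraph of target relations is outcome-relevant, and an overwhelmingly
  noisy catalogue dilutes it (the null-calibration test shows the pipeline
  then falls back to chance rather than hallucinating signal).
- The fusion objective always rewards additional smoothing, so a dense
  uninformative graph can attract coefficient mass; the damaged graph's
  information survives through the fused solve but is not explicitly
  protected.
- Exact signed-rank p-values are limited to ≤ 25 nonzero differences
  (beyond that the corrected normal approximation is used).
- Coefficient optimization is O(K · iterations · N³); fine for cohorts of
  hundreds of patients, untested beyond that.
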