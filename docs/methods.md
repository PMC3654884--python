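# Methods

## The model

`rawalk` classifies feature vectors — typically protein descriptors, with
(sub)cellular compartment as the class — by label propagation through a
lazy random walk on a complete similarity graph.

**Graph.** The n labeled training vectors are the nodes of a complete
graph with RBF edge weights

    w_ij = exp(-γ ‖x_i − x_j‖²),     γ = 1/(2σ²) > 0.

The diagonal keeps w_ii = 1 (the formula yields it for identical points)
and the degree matrix D = diag(W·1) includes that self-weight.

**Walk.** The one-step transition operator is the row normalization
P = D⁻¹W. Labeled nodes are *not* absorbing: a walk that reaches a
labeled node keeps moving. Instead the walk is lazy — at each step it
stays put with probability α and otherwise moves by P:

    Q = αI + (1−α)P,     t steps → Qᵗ.

Qᵗ is the fixed operator Q applied t times (the recursive definition with
an identity base case reduces to exactly this). α is meaningful on (0, 1);
the endpoints are accepted as degenerate cases (α = 1 freezes the walk, so
results become t-independent).

**States and prediction.** Labels are one-hot columns of an m×n state
matrix Y (column order = sample order, row order = sorted class names).
A test point x receives the per-class walk-arrival scores

    F(x) = Ỹ Qᵗ (K + λI)⁺ k(X, x),

where K is the RBF kernel matrix over the training set (identical to W —
the kernel *is* the similarity), k(X, x) the kernel column of the test
point, λ the kernel regularizer guarding against singular K, (·)⁺ the
Moore–Penrose pseudo-inverse, and Ỹ the split-weighted state matrix below.
Entry f_j of F(x) is the t-step arrival mass of class j; the predicted
class is the argmax, ties broken toward the lowest class index for
determinism.

**Complementary-split training weights.** The training set is split into
two stratified halves S and T (per class, members are shuffled with the
seeded generator and dealt alternately). Each half predicts the other
with the same rule and the same hyperparameters as the deployed model:

    ε_S = ‖ Y_S Q_Sᵗ (W_S + λI)⁺ w(S,T) − Y_T ‖²_F      (and symmetrically ε_T).

The half weights are α_S = ε_T/(ε_S+ε_T), α_T = ε_S/(ε_S+ε_T) — the half
that generalizes better (smaller loss) weighs more — and Ỹ scales column i
of Y by α_S or α_T according to i's membership, preserving column order.
The combined loss ε_S·ε_T/(ε_S+ε_T) is logged as a training diagnostic.
When both losses vanish the weights default to (0.5, 0.5). A single seeded
split is the default; `n_splits > 1` averages the weights over several
independent splits.

## Protein descriptor

A protein of length L with a PSI-BLAST PSSM M (L×20, columns remapped to
alphabetical amino-acid order, log-odds block) is encoded as the
89-dimensional vector

    F = [ M̄_1..M̄_20 , p_1..p_{20+λ} ],   M̄_j = (1/L) Σ_i M_{i→j},

whose second block is the type-1 pseudo-amino-acid composition with
λ = 49 tiers and weight w = 0.05:

    θ_k = 1/(L−k) Σ_i Θ(R_i, R_{i+k}),
    Θ(a,b) = ⅓ Σ_p (prop_p(b) − prop_p(a))²,
    p_u = f_u / (Σf + wΣθ)  (u ≤ 20),    p_{20+k} = wθ_k / (Σf + wΣθ),

with f_u the residue frequencies and prop_p the three classical property
scales (hydrophobicity, Hopp–Woods hydrophilicity, side-chain mass), each
standardized to mean 0 / unit population SD over the 20 amino acids. The
tables ship as `src/rawalk/data/pseaa_properties.tsv` and can be swapped.
The PseAA block is a probability vector (non-negative, sums to 1); Θ is
symmetric, so θ_k is invariant under sequence reversal, and scaling all
three tables by c scales every θ_k by c². Sequences with L ≤ λ cannot
populate every tier and are excluded (the featurizer logs them).

Design choices here that were genuinely open: the log-odds block of the
PSSM (not the percentage block) is averaged; frequencies rather than raw
counts enter the PseAA numerator (identical after normalization); no
z-scoring is applied to the combined descriptor — the γ search absorbs
scale, and an optional flag exists for callers who want it.

## Evaluation protocol

Stratified k-fold cross-validation (default k = 10) fits on k−1 folds and
scores the held-out fold; predictions are pooled into one confusion
matrix. Folds are built by dealing each class's shuffled members
round-robin with a running pointer, which keeps fold sizes and class
proportions within rounding and stays defined for leave-one-out even when
a class has fewer members than k (warned). Reported metrics:

- per class: sensitivity TP/(TP+FN), precision TP/(TP+FP), specificity
  TN/(TN+FP). Both precision and specificity are reported because the two
  are easy to conflate in this setting; a class never predicted has
  undefined precision, rendered `-` in the TSV report.
- total accuracy = pooled trace / n, with the "±" figure defined as the
  sample standard deviation of per-fold accuracies.
- one-vs-rest ROC and trapezoidal AUC per class on the raw arrival scores
  (no calibration); classes absent from the truth get NaN AUC.

Hyperparameter studies: `parameter_sweep` grids CV accuracy over laziness
values (default {0.05, 0.25, 0.5, 0.75, 0.95}) and steps t = 1..30;
`gamma_grid_search` evaluates the 12 odd powers of two 2⁻¹¹..2¹¹ and
returns the best (ties to the smaller γ, no nested CV).

## Defaults

| parameter | default | meaning |
|---|---|---|
| γ | 1.0 (grid 2⁻¹¹..2¹¹ for searches) | RBF bandwidth 1/(2σ²), in inverse squared feature units |
| α | 0.75 | walk laziness; >0.5 suits imperfectly reliable labels |
| t | 5 | walk steps; small values work best before Qᵗ mixes toward stationarity |
| λ (regularization) | 1e-4 | kernel ridge added before pseudo-inversion |
| λ (PseAA tiers) | 49 | sequence-order correlation depth |
| w | 0.05 | PseAA tier weight |
| k | 10 | CV folds |

The two λ's are unrelated; code and CLI keep them apart as `lambda_reg`
and `lambda_seq`.

## Numerical choices

- (K + λI)⁺ via symmetric eigendecomposition (`scipy.linalg.pinvh`) with
  the standard relative cutoff; tests cross-check the Penrose conditions
  and an SVD pseudo-inverse.
- Qᵗ by `matrix_power`; row sums verified conserved to 1e-10 under
  randomized chains.
- Degenerate cases are defined, not special-cased away: a singleton split
  half uses W = [1]; a single-class fit warns and predicts that class;
  α endpoints and t = 0 are legal.
- All randomness flows from a single integer seed; per-stage seeds are
  derived by fixed offsets, so fits, splits, folds and simulations are
  individually reproducible and identical runs are bit-identical.

## Synthetic benchmarks, and what they do not show

`rawalk.synthetic` generates the inputs the test-suite and acceptance
script use: labeled Gaussian mixtures with class means `separation`
within-class SDs apart on coordinate axes (orthogonal up to d, then
random directions), unit isotropic noise; random protein sequences; and
PSI-BLAST-formatted synthetic PSSM files (integer scores in [−10, 10],
real column layout) so the parser is exercised against the genuine
dialect. The acceptance runs use 150-sample, 8-feature, 3-class mixtures
at separations 6 (recoverable: CV accuracy ≥ 0.95) and 0 (chance).

These fixtures validate the machinery, not the biology: synthetic PSSMs
carry no evolutionary conservation signal, mixture classes are isotropic
and balanced where real localization classes are heavily skewed (some
with a handful of members), and no sequence redundancy structure is
modeled. Accuracy on real yeast or gram-negative benchmark sets must be
measured on those sets; they are supported as external inputs but never
bundled.

## Known limitations

- The complete dense graph costs O(n³) per fit (pseudo-inverse dominated);
  no sparse/k-NN variant is provided.
- Scores are raw arrival masses, not calibrated probabilities.
- Only type-1 (parallel-correlation) PseAA with the three classical
  property scales; no amphiphilic variant.
- PSSM generation (running PSI-BLAST) is out of scope; only parsing.
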