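# rawalk

Random-walk-on-graph classification of protein (sub)cellular
localization.

Knowing which cellular compartment a protein occupies constrains its
function and interactions, and experimental annotation lags far behind
sequencing. `rawalk` predicts the compartment from numeric protein
descriptors by **label propagation through a lazy random walk** on a
complete similarity graph: labeled proteins are nodes, RBF similarities
`w_ij = exp(-γ‖x_i−x_j‖²)` are edge weights, and a query point is
assigned the class whose t-step walk-arrival probability is largest.

The fitted classifier is

```
F(x) = Ỹ Qᵗ (K + λI)⁺ k(X, x),    Q = αI + (1−α)D⁻¹W
```

where `K = W` is the RBF kernel matrix over the training set, `α` the walk
laziness, `λ` a small ridge making the pseudo-inverse robust, and `Ỹ` the
one-hot state matrix with each column weighted by how well its stratified
training half predicted the complementary half (the half with the smaller
cross-prediction loss gets the larger weight). Predictions are the
per-class argmax of `F(x)`.

The package also builds the classical 89-dimensional protein descriptor —
20 position-averaged PSSM scores concatenated with the 69-entry type-1
pseudo-amino-acid composition (20 residue frequencies + 49 sequence-order
correlation tiers, weight 0.05) — from FASTA files and PSI-BLAST ASCII
PSSMs, and ships a full evaluation harness: stratified k-fold CV,
per-class sensitivity/precision/specificity, one-vs-rest ROC/AUC, and
(α, t) and γ hyperparameter sweeps. Synthetic generators (Gaussian
mixtures, random proteins, PSI-BLAST-formatted PSSM files) make every
pipeline runnable without downloads; the standard yeast and gram-negative
bacteria benchmark tables are supported as external inputs.

## Worked example

```python
import rawalk

spec = rawalk.MixtureSpec(n_per_class=(50, 50, 50), d=8, separation=6.0, seed=1)
table = rawalk.gaussian_mixture_dataset(spec)
result = rawalk.cross_validate(table, k=10, gamma=2**-3, alpha=0.75, t=3, seed=1)
print(result.metrics.to_tsv())
```

prints

```
class	sensitivity	precision	specificity	support
c1	1.0000	1.0000	1.0000	50
c2	1.0000	1.0000	1.0000	50
c3	1.0000	1.0000	1.0000	50
total_accuracy	1.0000±0.0000
```

Three Gaussian classes whose means sit 6 within-class standard deviations
apart are fully recoverable: every held-out sample is classified
correctly in 10-fold cross-validation, so each class's recall
(sensitivity), positive predictive value (precision) and true-negative
rate (specificity) are 1, and the fold-to-fold accuracy spread (the ±
figure) is zero. Shrinking `separation` toward 0 drives total accuracy to
chance (1/3). The `examples/` directory holds runnable scripts for each
capability: cross-validation, protein featurization, fit/predict with the
split-weight diagnostics, and the hyperparameter sweeps.

The same workflows are available from the shell:

```bash
rawalk simulate mixture --n 50,50,50 --d 8 --sep 6 --seed 1 --out toy.tsv
rawalk cv --train toy.tsv --k 10 --gamma 0.125 --alpha 0.75 --steps 3 \
          --seed 1 --report report.tsv
rawalk featurize --fasta prot.fa --pssm-dir pssms/ --out features.tsv
```

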