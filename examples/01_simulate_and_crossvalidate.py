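"""Cross-validate the random-walk classifier on a synthetic benchmark.

Builds a 3-class Gaussian mixture (150 samples, 8 features, class means
6 within-class SDs apart), runs 10-fold stratified cross-validation with
the default hyperparameters (gamma=2^-3, laziness alpha=0.75, t=3 walk
steps, kernel regularization 1e-4), and prints the per-class report.
"""

import rawalk

spec = rawalk.MixtureSpec(n_per_class=(50, 50, 50), d=8, separation=6.0, seed=1)
table = rawalk.gaussian_mixture_dataset(spec)

result = rawalk.cross_validate(table, k=10, gamma=2**-3, alpha=0.75, t=3, seed=1)

print(result.metrics.to_tsv())
print("per-class one-vs-rest AUC:",
      {c: round(a, 3) for c, a in result.roc.auc.items()})

# With well-separated classes the walk-arrival scores recover essentially
# every label: expect total accuracy near 1.0 and AUCs of 1.0.  A
# separation of 0 would drop accuracy to chance (~1/3).
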