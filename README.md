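# aesurv — autoencoder-based multi-omics survival subtyping

`aesurv` discovers survival-sensitive molecular subtypes from paired bulk
RNA-seq expression and DNA-methylation matrices, transfers the subtype
labels to new cohorts, and characterizes the subtypes through
methylation-driven genes.  It is aimed at cancer-genomics analysts working
with TCGA/CGGA-style glioma cohorts (or any feature-by-sample omics pair
with right-censored survival), and ships a synthetic-cohort generator so
the entire pipeline is testable without any data download.

## The method

1. **Preprocessing** — features with median absolute deviation (MAD) at or
   below a threshold are dropped, each omic is robust-scaled per feature
   (median/IQR fitted on the training cohort and reused on validation
   cohorts), and, for the autoencoder only, min-max squashed into
   [ε, 1−ε].
2. **Latent features** — a five-layer autoencoder (input → 500 → 100 → 500
   → output) with tanh hidden layers,

   γ = f_i(x) = tanh(W_i·x + b_i),

   reconstructs the concatenated omics through the 100-unit bottleneck.
   The loss is the summed logistic reconstruction error
   −Σ_k [x_k log x′_k + (1−x_k) log(1−x′_k)] plus an L1 penalty a_w on each
   W_i and an L2 activity penalty a_a on each layer's activations, trained
   with plain SGD (hand-derived backpropagation, verified against finite
   differences).
3. **Survival screen** — each bottleneck feature is tested in a univariate
   Cox proportional-hazards model (Breslow ties, Newton–Raphson, Wald
   test); features with p < 0.05 survive.
4. **Subtypes** — K-means over k = 2..6 on the surviving features; the
   Calinski–Harabasz score picks k (silhouette reported, used for ties);
   clusters are renamed G1..Gk by decreasing median survival, so G2 is the
   poorer-prognosis group in the two-cluster case.
5. **Label transfer** — per omic, the top-100 features by ANOVA F between
   subtypes feed an RBF-SVM; robustness is measured with 10 repeated
   random 60/40 splits (C-index with risk = P(poor class), binary Brier
   score, log-rank between predicted groups).  External cohorts are
   predicted after refitting the SVM on the features both cohorts share.
6. **Drivers** — a gene is methylation-driven when Spearman r(methylation,
   expression) < −0.3 across samples **and** its methylation differs
   between subtypes (Wilcoxon rank-sum p < 0.05); driver lists can be
   tested for over-representation against GMT gene sets with a
   hypergeometric tail + Benjamini–Hochberg.
7. **Baseline** — the same screen→cluster→classify machinery run on 100
   principal components instead of the bottleneck features.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from aesurv import (
    SyntheticConfig, generate_cohort, mad_filter, fit_scaler, apply_scaler,
    squash_to_unit, Autoencoder, encode, cox_screen, kmeans_select,
    name_subtypes, logrank_test, crossvalidate,
)

cohort = generate_cohort(SyntheticConfig(n_samples=400, seed=1))

scaled, squashed = {}, {}
for name, m in (("expr", cohort.expr), ("meth", cohort.meth)):
    m = mad_filter(m)
    scaled[name] = apply_scaler(m, fit_scaler(m, mode="robust"))
    squashed[name] = squash_to_unit(scaled[name])

stacked = pd.concat([squashed["expr"], squashed["meth"]])
model = Autoencoder(hidden_sizes=(500, 100, 500), learning_rate=1e-3,
                    epochs=20, random_state=1).fit(stacked.T.to_numpy())
latent = encode(model, stacked)

screen = cox_screen(latent, cohort.clinical, alpha=0.05)
kept = latent.loc[:, screen["selected"].to_numpy()]
selection = kmeans_select(kept, k_min=2, k_max=6, seed=1)
result = name_subtypes(selection, cohort.clinical)
report = crossvalidate(scaled, cohort.clinical, result.labels, seed=1)
```

which prints, with the intermediate `print` statements included:

```
survival-associated latent features: 70/100
chosen k = 2 (CH = 163.5, silhouette = 0.25)
subtype sizes: {'G1': 236, 'G2': 164}
log-rank chi2 = 38.1, p = 6.57e-10
ARI vs planted subtypes = 0.90
10x60/40 CV: C-index 0.67 (0.03), Brier 0.37, log-rank p geo.mean 6.5e-05
```

Reading: 70 of the 100 bottleneck features carry survival signal; K-means
prefers two clusters; the discovered G2 group (164 samples) has sharply
worse survival (log-rank p ≈ 7·10⁻¹⁰) and agrees strongly with the planted
subtypes (ARI 0.90); the transferred labels remain predictive on held-out
40% splits.  On synthetic cohorts the cross-validated C-index is bounded
well below 1 because nearly all of the hazard signal is the two-group
split itself — see `docs/methods.md` for the ceiling argument.

## Command line

Every stage is a subcommand of `aesurv` driven by one YAML config:

```sh
aesurv run --config config.yaml        # simulate → … → drivers + manifest
aesurv baseline-pca --config config.yaml
aesurv enrich --gmt sets.gmt --query drivers.txt --universe genes.txt
```

A run writes a `manifest.json` with SHA-256 digests of every stage output;
two runs with the same seed are digest-identical.

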