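# fmkldr

Fast multiple kernel learning with graph-embedding dimensionality
reduction (fMKL-DR) for stratifying patients from heterogeneous
multi-view data — multi-omic profiles (gene expression, DNA
methylation, miRNA expression) or ROI-network features derived from
per-region anatomical MRI measures.

## Who this is for

Researchers who have several sample-by-feature matrices over one cohort
(with a binary clinical label such as case/control or converter/
non-converter) and want a single fused low-dimensional representation
that (a) integrates views with very different scales and dimensions and
(b) feeds a standard SVM classifier.

## The method

Each preprocessed view is turned into one or more N x N kernel matrices
K_1, ..., K_M (Gaussian over a bandwidth grid by default). fMKL-DR
learns kernel weights beta in R^M and sample coefficients A in R^{N x P}
so that sample i is embedded as

    z_i = A^T K^(i) beta,     K^(i)[n, m] = K_m(x_n, x_i),

minimizing the within-class distortion of a Linear Discriminant
Analysis affinity graph (w_ij = 1/n_c for same-class pairs) relative to
a global constraint graph (w'_ij = 1/N), in the graph-embedding
formulation. A and beta are optimized alternately; each step is a
generalized eigenproblem over scatter matrices of the form

    S_W^A  = sum_ij w_ij (K^(i) - K^(j))^T A A^T (K^(i) - K^(j)),
    S_W^b  = sum_ij w_ij (K^(i) - K^(j)) beta beta^T (K^(i) - K^(j))^T.

Each summand is a 4-matrix chain; the optimal multiplication order is
found once per training run by the classic dynamic program over
F(i, j) = min_t F(i, t) + F(t+1, j) + d_{i-1} d_t d_j (the "fast" in
fMKL-DR), and the pairwise sum itself is collapsed through the graph
Laplacian, S = 2 U (D - W) U^T, giving an O(N^3) update. Classification
uses a C-SVC (cost 1) on the inner-product kernel of the embeddings,
evaluated by repeated random 2/3-holdout with best-of-20 and a
one-sample t lower confidence bound reported.

## Worked example

```python
import numpy as np
from fmkldr import (SimSpec, make_multiview_cohort, SplitScheme, PipelineConfig,
                    repeated_holdout, kernel_grid, train_fmkldr, minmax_rescale,
                    drop_incomplete_features)

# two views over 90 patients: view 0 carries a 4-sd class shift, view 1 is noise
spec = SimSpec(class_sizes=(45, 45), n_views=2, dims=(20, 20),
               effect_size=(4.0, 0.0), scale=(1.0, 1000.0),
               missing_rate=0.03, seed=7)
views, labels = make_multiview_cohort(spec)

report = repeated_holdout(views, labels,
                          SplitScheme(train_fraction=2/3, n_reps=20, seed=7),
                          PipelineConfig(P=5, n_iter=10))
print(f"mean accuracy : {report.mean_accuracy:.4f}")
print(f"best of 20    : {report.best_accuracy:.4f}")
print(f"t lower bound : {report.ci_lower:.4f}")
print(f"mean AUC      : {report.mean_auc:.4f}")

clean = [minmax_rescale(drop_incomplete_features(v)) for v in views]
stack = kernel_grid(clean, (1.0,))
model = train_fmkldr(stack, labels, P=5, n_iter=10)
print("kernel weights:", np.round(model.beta, 3))
```

Output:

```
mean accuracy : 1.0000
best of 20    : 1.0000
t lower bound : 1.0000
mean AUC      : 1.0000
kernel weights: [1. 0.]
```

The informative view separates the classes cleanly, so every holdout
repetition classifies perfectly, and with one Gaussian kernel per view
the learned weights put all mass on the informative view — the noise
view (despite its 1000x larger raw scale) is zeroed out.

The same pipeline is available from the shell:

```
fmkldr simulate --spec cohort.yaml --out data/
fmkldr evaluate --views data/view0.tsv --views data/view1.tsv \
    --labels data/labels.tsv --reps 20 --p 5 --seed 1 --out results/
```

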