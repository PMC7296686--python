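# Methods

## Model

The package fuses M base kernels over one cohort of N labelled samples
into a single P-dimensional embedding. Writing K^(i) for the N x M
matrix whose (n, m) entry is kernel m evaluated between training sample
n and sample i, the embedding of sample i is z_i = A^T K^(i) beta with
sample coefficients A (N x P) and kernel weights beta (M,). The loss is
the graph-embedding distortion sum_ij w_ij ||z_i - z_j||^2 under the
LDA intrinsic graph (w_ij = 1/n_c for same-class pairs in class c, so
each row sums to 1) subject to unit distortion under the constraint
graph w'_ij = 1/N. With these graphs the embedding is a kernelized
Fisher discriminant over the fused kernel sum_m beta_m K_m.

Assumptions: class structure is shared across views; each view's
information is expressible through sample-pair similarity (the kernel);
two or more samples per class (the within-class graph is degenerate for
singleton classes, and training raises on them).

## Optimization

A and beta are optimized alternately. For fixed beta, A solves the
generalized eigenproblem S_W^beta a = lambda S_W'^beta a (N x N pencil,
P smallest eigenpairs, normalized so A^T S' A = I); for fixed A, beta
is the smallest eigenpair of the M x M pencil S_W^A b = lambda S_W'^A b.
The scatter matrices are the pairwise double sums over (K^(i) - K^(j))
chains given in the module docstring of `fmkldr.mkldr`.

Two implementation layers make this fast:

1. **Chain ordering.** Each scatter summand is a 4-matrix chain
   (M x N)(N x P)(P x N)(N x M) or (N x M)(M x 1)(1 x M)(M x N). The
   minimal-scalar-multiplication parenthesization is found by the
   classic dynamic program (`fmkldr.mcmo`), run exactly twice per
   training call — once per chain shape, before the iteration loop.
   Ties between split points go to the smallest split for determinism,
   and costs are Python integers, so cubic-scale counts cannot overflow.
2. **Laplacian collapse.** The literal double sum costs O(N^2) chain
   products. Because both graphs are symmetric, the sum rewrites as
   S = 2 U (D - W) U^T with u_i = K^(i) beta (respectively U_i =
   K^(i)T A) and D the degree diagonal, which brings a full update to
   O(N^3). The pairwise path is retained (`method="pairwise"`) as a
   slow reference and is required by the tests to agree with the
   collapsed path to 1e-8 relative Frobenius error.

### Numerical choices

- **Rank restriction.** The constraint scatter is rank-deficient by
  construction: the all-equal graph annihilates the constant direction,
  and a base kernel with (near-)identical columns — e.g. a Gaussian
  kernel whose bandwidth dwarfs the data diameter, which is numerically
  the all-ones matrix — contributes no constraint scatter at all. In
  such directions the Rayleigh quotient is 0/0 and a plain ridge makes
  the smallest-eigenvalue criterion chase noise. The solver therefore
  whitens on the eigenspace of S' with eigenvalues above 1e-8 of the
  largest and solves the reduced symmetric problem there; requesting
  more dimensions than that rank raises a numerical error (the
  dimension scan skips such settings with a warning).
- **beta canonicalization.** The weight vector is scaled to unit
  Euclidean norm, its sign fixed so the entry sum is nonnegative, and —
  by default — negative entries are clipped to zero and the vector
  renormalized, so the weights read as convex-combination-style
  coefficients over the base kernels. The raw smallest eigenvector is
  available with `nonneg_beta=False`.
- **Initialization.** `init="A"` (default) starts from the P leading
  eigenvectors of the summed kernel and updates beta first;
  `init="beta"` starts from the uniform vector 1/sqrt(M) and updates A
  first. The default follows the observation that initializing A
  converges faster; it also matters structurally: on symmetric two-view
  problems the uniform beta is an exact stationary point of the
  alternating scheme, so `init="beta"` can leave beta uniform where
  `init="A"` identifies the informative view.
- **Stopping.** A fixed iteration count (default 10); no early-stop
  tolerance. The per-iteration trace-ratio objective
  trace(A^T S_W A) / trace(A^T S_W' A) is recorded in
  `model.history` for diagnostics.
- **Degeneracy of the embedding.** With c classes the bottom of the
  spectrum has multiplicity ~c (directions collapsing each class to a
  point), so for P > 1 only the spanned subspace is identified, not the
  individual components; permutation invariance of components is exact
  only for a simple bottom eigenvalue (P = 1, two classes).

## Preprocessing

Features missing in any sample are removed (no imputation); per-feature
min-max rescaling maps each column onto [-1, 1], with constant columns
sent to the midpoint so sample dimensionality is stable across views.
Scaling statistics are learned on the training split of each repetition
only and re-applied to held-out samples with clipping into the range —
fitting them globally would leak test statistics into the holdout
protocol.

## Kernels

Default protocol: a Gaussian kernel per (view, bandwidth) pair over the
grid sigma in {1e-6, 1e-3, 1, 1e3, 1e6} (12 views x 5 bandwidths = 60
kernels for the imaging representation). On [-1, 1]-rescaled data the
grid's extremes are saturated — sigma = 1e-6 is numerically the identity
matrix and sigma = 1e6 the all-ones matrix; they are retained for
fidelity to the protocol, and the rank restriction above keeps them from
destabilizing the optimization, but their weights carry no view-level
information. Polynomial ((x.x' + 1)^2), linear (x.x') and sigmoid
(tanh(x.x'/D)) families are provided for the single-view expression
protocol; sigmoid kernels may be indefinite and are only checked
symmetric, the other families are PSD by construction.

## ROI-network features

For imaging cohorts, each anatomical measure (cortical gray-matter
volume, thickness, surface area, curvature, folding index, sub-cortical
volume) gives a subjects x regions table. Per subject, a complete graph
over regions is formed with edge weight 1/(|m_i - m_j| + 1) in (0, 1];
the vertex table V (the measures) and edge table E (C(n_regions, 2)
columns, pairs ordered lexicographically by region position) become two
feature views per measure — 78 cortical regions give 3003 edge features,
12 sub-cortical regions give 66.

## Classification and evaluation

The stratifier is a C-SVC with cost 1 and equal class weights on the
precomputed kernel Z Z^T of the embeddings (Z_test Z_train^T for
held-out samples). Training embeddings are centered on their mean and
scaled to unit RMS norm, with the same affine map applied to queries:
the embedding's location and scale are arbitrary (they depend on the
constraint normalization, and training slices contain the
self-similarity entry K[i, i] that held-out cross-slices lack, which
otherwise induces a common-mode train/test offset along near-null
embedding directions), and C = 1 is only meaningful on a normalized
Gram matrix.

Evaluation: repeated random holdout, default 20 repetitions at training
fraction 2/3, plain (unstratified) splits redrawn — at most 100 times —
if either side lacks both classes. Every stage (feature dropping aside,
which is label-free and applied once up front) is fitted on the
repetition's training split only. Reported: per-repetition accuracy and
AUC, the best repetition, the mean, and the one-sided lower confidence
bound mean - t_{level, n-1} s / sqrt(n) (default level 0.95; the level
is a parameter). AUC is the Mann-Whitney rank statistic with ties
counted 1/2; ROC points come from every distinct threshold of the best
repetition. The reduced-dimension scan reruns the protocol for each
requested f (= P), skipping values beyond the training-split size, with
smallest-f tie-breaking for the argmax.

## Synthetic cohorts

`fmkldr.simdata` draws class-conditional Gaussian views: per view, a
mean shift of `effect_size` (in noise-sd units) on a random
`informative_frac` subset of features, a per-view magnitude `scale`, and
feature-level missingness (`missing_rate` is the probability a feature
is hit in at least one sample — matching the downstream drop-if-missing-
anywhere policy, so it approximates the fraction of features removed).
Class-conditional Gaussians are the simplest structure under which a
discriminant embedding is Bayes-consistent, which keeps recovery
experiments interpretable. The generator does **not** emulate realistic
omics marginals (counts, beta-values), feature correlation structure,
batch effects or survival outcomes, so passing recovery and null tests
shows the pipeline's statistical machinery is sound — not that any
particular accuracy transfers to real cohorts.

Test and acceptance problem sizes are desk-scale by design: recovery and
null-control runs use a 90-sample, 2-view cohort (20 features per view,
20 holdout repetitions, P = 5, 10 iterations); fast-path equivalence
uses 50 random instances with N <= 12, M <= 3; DP optimality checks 200
random chains of up to 6 matrices against exhaustive enumeration.

Null-control note: on effect-free cohorts the mean holdout accuracy sits
slightly below 0.5 (anti-learning: the embedding overfits the training
split, and a finite test set re-drawn from the same cohort is weakly
anticorrelated with it). The chance band is computed with binomial n
equal to the number of distinct samples, since repetitions resample one
cohort and their test predictions are correlated.

## Known limitations

- The reduced dimension is exposed as a single parameter P (default 5),
  also called f in the dimension scan; headline runs elsewhere use P = 5
  while scans explore much larger f. The package treats them as the same
  quantity and leaves the choice to the user.
- AUC/ROC are defined for binary tasks only; multi-class problems should
  be decomposed into the binary contrasts of interest (accuracy is still
  reported).
- Kernel weights on the extreme bandwidth-grid kernels are not
  interpretable (see Kernels); weight-based view ranking should use one
  well-scaled kernel per view.
- No imputation, batch correction or stratified splitting; missing data
  is handled by feature removal only.
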