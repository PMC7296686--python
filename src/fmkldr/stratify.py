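"""SVM stratification on the fused embedding and the evaluation protocol.

The classifier is a C-SVC (cost 1, equal class weights) on the kernel
the trained embedding defines: Z Z^T between training samples and
Z_test Z_train^T for held-out samples, where Z are the fMKL-DR
projections. Evaluation follows a repeated random holdout: in each of
n_reps repetitions (default 20) a random 2/3 of the cohort trains the
whole pipeline — feature dropping, rescaling, kernels, fMKL-DR, SVM —
and the rest is scored. Both the best repetition and a one-sample
t lower confidence bound of the mean accuracy are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .kernels import SIGMA_GRID, cross_kernel_slices, kernel_grid
from .mkldr import project, project_training, train_fmkldr
from .preprocess import FeatureMatrix, MinMaxRescaler, drop_incomplete_features

__all__ = [
    "SplitScheme",
    "PipelineConfig",
    "EvalReport",
    "svm_train",
    "repeated_holdout",
    "one_sample_ttest_lower_bound",
    "roc_auc",
    "dimension_scan",
]


@dataclass
class SplitScheme:
    """Repeated random holdout: train_fraction per repetition."""

    train_fraction: float = 2.0 / 3.0
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters for one evaluation run."""

    sigmas: tuple[float, ...] = SIGMA_GRID
    P: int = 5
    n_iter: int = 10
    init: str = "A"
    svm_cost: float = 1.0
    confidence: float = 0.95
    nonneg_beta: bool = True


@dataclass
class EvalReport:
    """Per-repetition accuracies/AUCs plus the summary rows.

    ``ci_lower`` is the one-sided lower confidence bound of the mean
    accuracy from the one-sample t statistic; ``roc_points`` belong to
    the best repetition.
    """

    per_rep: list[tuple[float, float]]
    best_accuracy: float
    mean_accuracy: float
    ci_lower: float
    roc_points: list[tuple[float, float]]
    n_reps: int
    mean_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "mean_accuracy": self.mean_accuracy,
            "best_accuracy": self.best_accuracy,
            "ci_lower": self.ci_lower,
            "mean_auc": self.mean_auc,
            "per_rep": [{"accuracy": a, "auc": u} for a, u in self.per_rep],
            "roc_points": [{"fpr": f, "tpr": t} for f, t in self.roc_points],
        }


class FusedKernelSVC:
    """C-SVC on the inner-product kernel of embedded samples.

    The embedding's location and overall scale are arbitrary (they depend
    on the constraint-scatter normalization, and near-null embedding
    directions can carry a large common-mode offset), so training rows
    are centered on their mean and rescaled to unit RMS norm before
    forming the Gram matrix; the same affine map is applied to query
    samples. This keeps the fixed cost C = 1 meaningful across runs
    without changing the embedding geometry.
    """

    def __init__(self, Z_train: np.ndarray, labels, cost: float = 1.0):
        labels = np.asarray(labels)
        if np.unique(labels).shape[0] < 2:
            raise ValueError("training labels contain a single class")
        Z_train = np.asarray(Z_train, dtype=float)
        self.center_ = Z_train.mean(axis=0)
        centered = Z_train - self.center_
        rms = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
        self.scale_ = rms if rms > 0 else 1.0
        self.Z_train = centered / self.scale_
        self.svc = SVC(C=cost, kernel="precomputed")
        self.svc.fit(self.Z_train @ self.Z_train.T, labels)
        self.classes_ = self.svc.classes_

    def _gram(self, Z: np.ndarray) -> np.ndarray:
        Zq = (np.asarray(Z, dtype=float) - self.center_) / self.scale_
        return Zq @ self.Z_train.T

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._gram(Z))

    def decision_function(self, Z: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._gram(Z))


def svm_train(Z, labels, cost: float = 1.0, precomputed: bool = False) -> FusedKernelSVC | SVC:
    """Train the C-SVC stratifier (cost 1, equal class weights by default).

    Given the fused representation Z, the precomputed kernel is Z Z^T;
    pass ``precomputed=True`` to supply a Gram matrix directly.
    """
    if precomputed:
        labels = np.asarray(labels)
        if np.unique(labels).shape[0] < 2:
            raise ValueError("training labels contain a single class")
        svc = SVC(C=cost, kernel="precomputed")
        svc.fit(np.asarray(Z, dtype=float), labels)
        return svc
    return FusedKernelSVC(Z, labels, cost=cost)


def one_sample_ttest_lower_bound(values, level: float = 0.95) -> float:
    """One-sided lower confidence bound of the mean: m - t_{level,n-1} s/sqrt(n).

    With zero variance the common value is returned.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 values")
    m = values.mean()
    s = values.std(ddof=1)
    if s == 0:
        return float(m)
    t = scipy.stats.t.ppf(level, n - 1)
    return float(m - t * s / np.sqrt(n))


def roc_auc(decision_values, truth, pos_label=None) -> tuple[float, list[tuple[float, float]]]:
    """AUC as the rank statistic, plus ROC points at every threshold.

    AUC is the probability that a random positive outscores a random
    negative, with ties counted 1/2 (the Mann-Whitney statistic).
    """
    scores = np.asarray(decision_values, dtype=float)
    truth = np.asarray(truth)
    classes = np.unique(truth)
    if classes.shape[0] != 2:
        raise ValueError("truth must contain exactly two classes")
    if pos_label is None:
        pos_label = classes[1]
    pos = truth == pos_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = scipy.stats.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(pos.astype(int), scores)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def _draw_split(rng: np.random.Generator, labels: np.ndarray, train_fraction: float,
                max_redraws: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Plain random split, redrawn until train and test both see 2 classes."""
    n = labels.shape[0]
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    for _ in range(max_redraws):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if np.unique(labels[tr]).shape[0] >= 2 and np.unique(labels[te]).shape[0] >= 2:
            return tr, te
    raise RuntimeError("could not draw a two-class split in 100 attempts")


def _run_one_split(
    views: list[FeatureMatrix],
    labels: np.ndarray,
    tr: np.ndarray,
    te: np.ndarray,
    config: PipelineConfig,
) -> tuple[float, float, list[tuple[float, float]]]:
    train_scaled, test_scaled = [], []
    for X in views:
        scaler = MinMaxRescaler().fit(X.subset_samples(tr))
        train_scaled.append(scaler.transform(X.subset_samples(tr)))
        test_scaled.append(scaler.transform(X.subset_samples(te)))
    stack = kernel_grid(train_scaled, config.sigmas)
    P = min(config.P, len(tr))
    model = train_fmkldr(
        stack,
        labels[tr],
        P=P,
        n_iter=config.n_iter,
        init=config.init,
        nonneg_beta=config.nonneg_beta,
    )
    Z_train = project_training(model, stack)
    specs_per_view = [
        [s for s in stack.specs if s.view_id == f"view{v}"] for v in range(len(views))
    ]
    slices = cross_kernel_slices(train_scaled, test_scaled, specs_per_view)
    Z_test = project(model, slices)

    clf = FusedKernelSVC(Z_train, labels[tr], cost=config.svm_cost)
    pred = clf.predict(Z_test)
    acc = float(np.mean(pred == labels[te]))
    if np.unique(labels).shape[0] == 2:
        scores = clf.decision_function(Z_test)
        auc, points = roc_auc(scores, labels[te], pos_label=clf.classes_[1])
    else:
        auc, points = float("nan"), []
    return acc, auc, points


def repeated_holdout(
    views: list[FeatureMatrix],
    labels,
    scheme: SplitScheme | None = None,
    config: PipelineConfig | None = None,
) -> EvalReport:
    """Run the full pipeline over repeated random holdout splits.

    Features missing in any sample are removed once up front (a label-
    free operation); scaling, kernels, the embedding and the SVM are all
    fitted on each repetition's training split only.
    """
    scheme = scheme or SplitScheme()
    config = config or PipelineConfig()
    labels = np.asarray(labels)
    views = [drop_incomplete_features(X) for X in views]
    rng = np.random.default_rng(scheme.seed)

    per_rep: list[tuple[float, float]] = []
    best_points: list[tuple[float, float]] = []
    best_acc = -1.0
    for _ in range(scheme.n_reps):
        tr, te = _draw_split(rng, labels, scheme.train_fraction)
        acc, auc, points = _run_one_split(views, labels, tr, te, config)
        per_rep.append((acc, auc))
        if acc > best_acc:
            best_acc, best_points = acc, points

    accs = np.array([a for a, _ in per_rep])
    aucs = np.array([u for _, u in per_rep])
    if scheme.n_reps >= 2:
        ci = one_sample_ttest_lower_bound(accs, level=config.confidence)
    else:
        ci = float(accs.mean())
    return EvalReport(
        per_rep=per_rep,
        best_accuracy=float(accs.max()),
        mean_accuracy=float(accs.mean()),
        ci_lower=ci,
        roc_points=best_points,
        n_reps=scheme.n_reps,
        mean_auc=float(np.nanmean(aucs)) if not np.isnan(aucs).all() else float("nan"),
    )


def dimension_scan(
    views: list[FeatureMatrix],
    labels,
    f_values,
    scheme: SplitScheme | None = None,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Mean holdout accuracy as a function of the reduced dimension f.

    Each f runs the full repeated holdout with P = f. Values of f larger
    than the training-split size are skipped with a warning; accuracy is
    not expected to be monotone in f. Returns the (f, mean_accuracy)
    table and the argmax f (smallest f on ties).
    """
    scheme = scheme or SplitScheme()
    config = config or PipelineConfig()
    labels = np.asarray(labels)
    n = labels.shape[0]
    n_train = int(round(scheme.train_fraction * n))
    rows = []
    for f in f_values:
        if f > n_train:
            warnings.warn(f"f={f} exceeds the training split size {n_train}; skipped")
            continue
        cfg = PipelineConfig(**{**config.__dict__, "P": int(f)})
        report = repeated_holdout(views, labels, scheme, cfg)
        rows.append({"f": int(f), "mean_accuracy": report.mean_accuracy})
    table = pd.DataFrame(rows, columns=["f", "mean_accuracy"])
    if table.empty:
        raise ValueError("no feasible f values")
    best_f = int(table.loc[table["mean_accuracy"].idxmax(), "f"])  # idxmax = first max
    return table, best_f
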