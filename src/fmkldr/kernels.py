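"""Kernel matrix construction and stacking for multiple kernel learning.

Each preprocessed view is turned into one or more N x N kernel matrices.
The default protocol evaluates a Gaussian kernel

    k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))

on every view over the bandwidth grid sigma in {1e-6, 1e-3, 1, 1e3, 1e6};
12 views x 5 bandwidths gives the 60-kernel stack used for the imaging
cohort. Polynomial, linear and sigmoid families are available for the
single-view expression protocol. All kernels over a cohort share one
sample ordering and are stacked into a :class:`KernelStack`, the unit the
MKL-DR optimizer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

from .preprocess import FeatureMatrix

__all__ = [
    "KernelSpec",
    "KernelStack",
    "gaussian_kernel",
    "named_kernel",
    "kernel_grid",
    "kernel_slice",
    "cross_kernel_slices",
    "SIGMA_GRID",
]

#: Default Gaussian bandwidth grid for the multi-view imaging protocol.
SIGMA_GRID: tuple[float, ...] = (1e-6, 1e-3, 1.0, 1e3, 1e6)

_FAMILY_PARAMS = {
    "gaussian": {"sigma"},
    "polynomial": {"degree", "offset"},
    "linear": {"offset"},
    "sigmoid": {"alpha", "offset"},
}


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its numeric parameters.

    Families and parameters: gaussian (sigma), polynomial (degree,
    offset), linear (offset), sigmoid (alpha, offset).
    """

    family: str
    params: dict = field(default_factory=dict)
    view_id: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(
                f"unknown kernel family {self.family!r}; "
                f"expected one of {sorted(_FAMILY_PARAMS)}"
            )
        missing = _FAMILY_PARAMS[self.family] - set(self.params)
        if missing:
            raise ValueError(f"{self.family} kernel missing parameters {sorted(missing)}")

    def __hash__(self) -> int:
        return hash((self.family, tuple(sorted(self.params.items())), self.view_id))


@dataclass
class KernelStack:
    """M kernel matrices over a common sample ordering.

    Every matrix is checked symmetric (within 1e-10). Gaussian, linear
    and polynomial kernels are positive semidefinite by construction;
    sigmoid kernels may be indefinite and are only checked symmetric.
    """

    kernels: list[np.ndarray]
    specs: list[KernelSpec]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.kernels) != len(self.specs):
            raise ValueError("one spec per kernel matrix is required")
        for m, K in enumerate(self.kernels):
            K = np.asarray(K, dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"kernel {m} has shape {K.shape}, expected ({n}, {n})")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError(f"kernel {m} is not symmetric")
            self.kernels[m] = 0.5 * (K + K.T)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_kernels(self) -> int:
        return len(self.kernels)

    def as_array(self) -> np.ndarray:
        """Stack as an (M, N, N) array."""
        return np.stack(self.kernels)

    def combined(self, beta: np.ndarray) -> np.ndarray:
        """The fused kernel sum_m beta_m K_m."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_kernels,):
            raise ValueError("beta length must equal the number of kernels")
        return np.einsum("m,mij->ij", beta, self.as_array())


def _pairwise_sq_dists(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    D = euclidean_distances(X, X if Y is None else Y)
    return D**2


def gaussian_kernel(
    X: FeatureMatrix | np.ndarray, sigma: float, Y: FeatureMatrix | np.ndarray | None = None
) -> np.ndarray:
    """Gaussian (RBF) kernel exp(-||x - x'||^2 / (2 sigma^2)).

    With ``Y`` given, returns the cross-kernel between the rows of X and
    the rows of Y (used to embed held-out samples against the training
    cohort).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    Yv = None if Y is None else (Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, float))
    K = np.exp(-_pairwise_sq_dists(Xv, Yv) / (2.0 * sigma**2))
    if Yv is None:
        np.fill_diagonal(K, 1.0)
    return K


def named_kernel(
    X: FeatureMatrix | np.ndarray,
    spec: KernelSpec,
    Y: FeatureMatrix | np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate one kernel family on a view (optionally a cross-kernel).

    gaussian: exp(-||x-x'||^2 / 2 sigma^2); polynomial: (x.x' + offset)^degree;
    linear: x.x' + offset; sigmoid: tanh(alpha x.x' + offset).
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    Yv = Xv if Y is None else (Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, float))
    p = spec.params
    if spec.family == "gaussian":
        return gaussian_kernel(Xv, p["sigma"], None if Y is None else Yv)
    G = Xv @ Yv.T
    if spec.family == "linear":
        K = G + p["offset"]
    elif spec.family == "polynomial":
        K = (G + p["offset"]) ** p["degree"]
    else:  # sigmoid
        K = np.tanh(p["alpha"] * G + p["offset"])
    return K


def default_specs_for_view(X: FeatureMatrix, view_id: str = "") -> list[KernelSpec]:
    """The four-family spec set for a single view.

    Defaults follow the expression protocol: Gaussian bandwidth = number
    of samples, polynomial degree 2 with offset 1, linear offset 0,
    sigmoid alpha = 1/n_features with offset 0.
    """
    n, d = X.values.shape
    return [
        KernelSpec("gaussian", {"sigma": float(n)}, view_id),
        KernelSpec("polynomial", {"degree": 2.0, "offset": 1.0}, view_id),
        KernelSpec("linear", {"offset": 0.0}, view_id),
        KernelSpec("sigmoid", {"alpha": 1.0 / d, "offset": 0.0}, view_id),
    ]


def kernel_grid(
    views: list[FeatureMatrix],
    sigmas: tuple[float, ...] | list[float] = SIGMA_GRID,
    view_ids: list[str] | None = None,
) -> KernelStack:
    """Gaussian kernels for every (view, sigma) pair, stacked.

    All views must share the same sample ordering; M = n_views x n_sigmas.
    """
    if not views:
        raise ValueError("at least one view is required")
    if view_ids is None:
        view_ids = [f"view{v}" for v in range(len(views))]
    ref_ids = views[0].sample_ids
    for vid, X in zip(view_ids, views):
        if X.sample_ids != ref_ids:
            raise ValueError(f"view {vid!r} does not share the common sample ordering")
    kernels: list[np.ndarray] = []
    specs: list[KernelSpec] = []
    for vid, X in zip(view_ids, views):
        for s in sigmas:
            kernels.append(gaussian_kernel(X, s))
            specs.append(KernelSpec("gaussian", {"sigma": float(s)}, vid))
    return KernelStack(kernels, specs, list(ref_ids))


def kernel_slice(stack: KernelStack, i: int) -> np.ndarray:
    """The N x M per-sample slice: column m is the i-th column of K_m."""
    if not 0 <= i < stack.n_samples:
        raise IndexError(f"sample index {i} out of range for N={stack.n_samples}")
    return np.column_stack([K[:, i] for K in stack.kernels])


def cross_kernel_slices(
    train_views: list[FeatureMatrix],
    test_views: list[FeatureMatrix],
    specs_per_view: list[list[KernelSpec]],
) -> list[np.ndarray]:
    """Per-test-sample slices against the training cohort.

    For test sample i, slice[i][n, m] is kernel m evaluated between
    training sample n and test sample i, with kernels enumerated in the
    same (view, spec) order used for the training stack.
    """
    if len(train_views) != len(test_views) or len(train_views) != len(specs_per_view):
        raise ValueError("train views, test views and spec lists must align")
    n_test = test_views[0].n_samples
    cross = []  # one (n_test, N_train) matrix per kernel
    for Xtr, Xte, specs in zip(train_views, test_views, specs_per_view):
        for spec in specs:
            cross.append(named_kernel(Xte, spec, Xtr))
    return [np.column_stack([C[i] for C in cross]) for i in range(n_test)]
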