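"""The fMKL-DR core: kernel fusion with discriminant graph embedding.

Given M base kernels K_1..K_M over N training samples, MKL-DR learns a
kernel weight vector beta (M,) and a sample-coefficient matrix A (N, P)
so that sample i is embedded as

    z_i = A^T  K^(i)  beta,        K^(i)[n, m] = K_m[n, i],

minimizing the graph-embedding distortion of an intrinsic affinity graph
W subject to a constraint graph W'. With the LDA graphs (w_ij = 1/n_c
within class c, w'_ij = 1/N everywhere) the embedding is a kernelized
Fisher discriminant over the fused kernel.

The alternating optimization solves two generalized eigenproblems per
iteration, built from scatter matrices

    S_W^A   = sum_ij w_ij  (K^(i)-K^(j))^T A A^T (K^(i)-K^(j))   (M x M)
    S_W^b   = sum_ij w_ij  (K^(i)-K^(j)) beta beta^T (K^(i)-K^(j))^T  (N x N)

(and the W' analogues). Each summand is a 4-matrix chain; the optimal
multiplication order for each of the two chain shapes is found once per
training run by dynamic programming (:mod:`fmkldr.mcmo`). The default
assembly additionally collapses the pairwise sum through the graph
Laplacian, S = 2 U (D - W) U^T, which brings the whole update to O(N^3);
the literal pair-by-pair sum is retained as a slow reference path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import scipy.linalg

from . import mcmo
from .kernels import KernelSpec, KernelStack, kernel_slice

__all__ = [
    "AffinityPair",
    "ScatterSet",
    "MKLDRModel",
    "lda_affinities",
    "scatter_A",
    "scatter_beta",
    "optimize_A",
    "optimize_beta",
    "train_fmkldr",
    "project",
]


@dataclass
class AffinityPair:
    """Intrinsic (W) and constraint (W') affinity graphs over N samples."""

    W: np.ndarray
    W_prime: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.W_prime = np.asarray(self.W_prime, dtype=float)
        for name, M in (("W", self.W), ("W_prime", self.W_prime)):
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(M, M.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")


@dataclass
class ScatterSet:
    """The four scatter matrices of one alternating-optimization state."""

    S_A: np.ndarray
    S_A_prime: np.ndarray
    S_beta: np.ndarray
    S_beta_prime: np.ndarray


@dataclass
class MKLDRModel:
    """A trained fMKL-DR embedding.

    ``A`` holds the sample coefficients (N_train, P); ``beta`` the kernel
    weights (M,), unit Euclidean norm. ``history`` records the trace-ratio
    objective per iteration.
    """

    A: np.ndarray
    beta: np.ndarray
    P: int
    train_sample_ids: list[str]
    specs: list[KernelSpec]
    history: list[float] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        """Serialize as a JSON manifest plus an .npz matrix archive."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "model.npz", A=self.A, beta=self.beta)
        manifest = {
            "P": self.P,
            "train_sample_ids": self.train_sample_ids,
            "specs": [
                {"family": s.family, "params": s.params, "view_id": s.view_id}
                for s in self.specs
            ],
            "history": self.history,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "MKLDRModel":
        directory = Path(directory)
        arrays = np.load(directory / "model.npz")
        manifest = json.loads((directory / "manifest.json").read_text())
        specs = [
            KernelSpec(s["family"], s["params"], s.get("view_id", ""))
            for s in manifest["specs"]
        ]
        return cls(
            A=arrays["A"],
            beta=arrays["beta"],
            P=manifest["P"],
            train_sample_ids=manifest["train_sample_ids"],
            specs=specs,
            history=manifest["history"],
        )


def lda_affinities(labels) -> AffinityPair:
    """LDA graph-embedding affinities from a class label vector.

    Intrinsic graph: w_ij = 1/n_c when samples i and j share class c
    (including i = j), 0 otherwise; each row sums to 1. Constraint graph:
    w'_ij = 1/N for every pair.
    """
    labels = np.asarray(labels)
    N = labels.shape[0]
    classes, counts = np.unique(labels, return_counts=True)
    if classes.shape[0] < 2:
        raise ValueError("at least 2 classes are required")
    if (counts < 2).any():
        bad = classes[counts < 2]
        raise ValueError(f"singleton class(es) {bad.tolist()}: within-class graph degenerate")
    W = np.zeros((N, N))
    for c, n_c in zip(classes, counts):
        mask = labels == c
        W[np.ix_(mask, mask)] = 1.0 / n_c
    W_prime = np.full((N, N), 1.0 / N)
    return AffinityPair(W=W, W_prime=W_prime)


def _laplacian(W: np.ndarray) -> np.ndarray:
    return np.diag(W.sum(axis=1)) - W


def _scatter_A_one(stack: KernelStack, A: np.ndarray, W: np.ndarray,
                   order: mcmo.ChainOrder | None, method: str) -> np.ndarray:
    N, M = stack.n_samples, stack.n_kernels
    if method == "pairwise":
        S = np.zeros((M, M))
        slices = [kernel_slice(stack, i) for i in range(N)]
        for i in range(N):
            for j in range(N):
                if W[i, j] == 0:
                    continue
                diff = slices[i] - slices[j]
                chain = [diff.T, A, A.T, diff]
                term = (
                    mcmo.multiply_chain(chain, order)
                    if order is not None
                    else diff.T @ A @ A.T @ diff
                )
                S += W[i, j] * term
        return S
    # Laplacian fast path: with V_i = K^(i)^T A (M, P),
    # sum_ij w_ij (V_i-V_j)(V_i-V_j)^T = 2 sum_i d_i V_i V_i^T - 2 sum_ij w_ij V_i V_j^T
    T = np.stack([K @ A for K in stack.kernels], axis=1)  # (N, M, P); T[i] = V_i
    deg = W.sum(axis=1)
    S_diag = np.einsum("i,imp,inp->mn", deg, T, T)
    Q = np.einsum("ij,imp->jmp", W, T)
    S_cross = np.einsum("jmp,jnp->mn", Q, T)
    S = 2.0 * (S_diag - S_cross)
    return 0.5 * (S + S.T)


def scatter_A(
    stack: KernelStack,
    A: np.ndarray,
    aff: AffinityPair,
    order: mcmo.ChainOrder | None = None,
    method: str = "fast",
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter matrices (M x M) for the kernel-weight eigenproblem.

    ``method="fast"`` uses the Laplacian-collapsed assembly; ``"pairwise"``
    evaluates the literal double sum term by term (under ``order`` if
    given) and serves as the slow reference.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    return (
        _scatter_A_one(stack, A, aff.W, order, method),
        _scatter_A_one(stack, A, aff.W_prime, order, method),
    )


def _scatter_beta_one(stack: KernelStack, beta: np.ndarray, W: np.ndarray,
                      order: mcmo.ChainOrder | None, method: str) -> np.ndarray:
    N = stack.n_samples
    if method == "pairwise":
        S = np.zeros((N, N))
        b = beta.reshape(-1, 1)
        slices = [kernel_slice(stack, i) for i in range(N)]
        for i in range(N):
            for j in range(N):
                if W[i, j] == 0:
                    continue
                diff = slices[i] - slices[j]
                chain = [diff, b, b.T, diff.T]
                term = (
                    mcmo.multiply_chain(chain, order)
                    if order is not None
                    else diff @ b @ b.T @ diff.T
                )
                S += W[i, j] * term
        return S
    # u_i = K^(i) beta is column i of the fused kernel; S = 2 U L U^T
    U = stack.combined(beta)
    S = 2.0 * U @ _laplacian(W) @ U.T
    return 0.5 * (S + S.T)


def scatter_beta(
    stack: KernelStack,
    beta: np.ndarray,
    aff: AffinityPair,
    order: mcmo.ChainOrder | None = None,
    method: str = "fast",
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter matrices (N x N) for the sample-coefficient eigenproblem."""
    beta = np.asarray(beta, dtype=float).ravel()
    return (
        _scatter_beta_one(stack, beta, aff.W, order, method),
        _scatter_beta_one(stack, beta, aff.W_prime, order, method),
    )


#: Relative eigenvalue cut below which a constraint-scatter direction is
#: treated as null and excluded from the pencil (unidentifiable ratio 0/0).
_RANK_TOL = 1e-8


def _generalized_eigh(S: np.ndarray, S_prime: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of S v = lambda S' v, restricted to the range of S'.

    The constraint scatter S' is rank-deficient by construction: the
    all-equal constraint graph annihilates the constant direction, and a
    base kernel whose columns are (near-)identical contributes no scatter
    at all. Directions where S' has no mass carry an unidentifiable 0/0
    Rayleigh quotient, so the pencil is whitened on the retained
    eigenspace of S' and solved there; returned eigenvectors satisfy
    V^T S' V = I. Eigenvalues are ascending.
    """
    S_prime = 0.5 * (S_prime + S_prime.T)
    w, Q = scipy.linalg.eigh(S_prime)
    wmax = w.max() if w.size else 0.0
    keep = w > _RANK_TOL * max(wmax, 0.0)
    if not keep.any() or wmax <= 0:
        raise np.linalg.LinAlgError("constraint scatter numerically singular")
    R = Q[:, keep] / np.sqrt(w[keep])  # whitening map onto range(S')
    C = R.T @ (0.5 * (S + S.T)) @ R
    vals, vecs = scipy.linalg.eigh(0.5 * (C + C.T))
    return vals, R @ vecs


def optimize_A(S_beta: np.ndarray, S_beta_prime: np.ndarray, P: int) -> np.ndarray:
    """Sample coefficients: generalized eigenvectors of the N x N pencil.

    Columns are the eigenvectors of S_beta a = lambda S_beta' a for the P
    smallest eigenvalues, normalized so A^T S_beta' A = I.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if P > S_beta.shape[0]:
        raise ValueError(f"P={P} exceeds pencil size {S_beta.shape[0]}")
    w, V = _generalized_eigh(S_beta, S_beta_prime)
    if P > V.shape[1]:
        raise np.linalg.LinAlgError(
            f"P={P} exceeds the rank {V.shape[1]} of the constraint scatter"
        )
    return V[:, :P]


def optimize_beta(
    S_A: np.ndarray, S_A_prime: np.ndarray, nonneg: bool = True
) -> np.ndarray:
    """Kernel weights: the smallest generalized eigenvector of the M x M pencil.

    The vector is scaled to unit Euclidean norm with its sign chosen so
    the entry sum is nonnegative. With ``nonneg`` (default), negative
    entries are clipped to zero and the vector renormalized, so the
    weights read as convex-combination coefficients over the base kernels.
    """
    M = S_A.shape[0]
    if M == 1:
        return np.ones(1)
    w, V = _generalized_eigh(S_A, S_A_prime)
    beta = V[:, 0]
    if beta.sum() < 0:
        beta = -beta
    if nonneg:
        beta = np.clip(beta, 0.0, None)
    nrm = np.linalg.norm(beta)
    if nrm == 0:  # pathological: all mass on negative entries
        beta = np.abs(V[:, 0])
        nrm = np.linalg.norm(beta)
    return beta / nrm


def train_fmkldr(
    stack: KernelStack,
    labels,
    P: int = 5,
    n_iter: int = 10,
    init: str = "A",
    seed: int | None = None,
    nonneg_beta: bool = True,
    scatter_method: str = "fast",
) -> MKLDRModel:
    """Alternating optimization of A and beta over a kernel stack.

    Each iteration performs one sample-coefficient update (N x N pencil)
    and one kernel-weight update (M x M pencil); ``init`` selects whether
    the uniform-beta step or the A step runs first. The two chain
    multiplication orders (one per scatter shape) are computed exactly
    once before the loop. A fixed iteration count is used; the trace-
    ratio objective per iteration is recorded in ``model.history``.
    """
    labels = np.asarray(labels)
    N, M = stack.n_samples, stack.n_kernels
    if labels.shape[0] != N:
        raise ValueError("labels length must equal the stack's sample count")
    if not 1 <= P <= N:
        raise ValueError(f"P must be in [1, {N}]")
    if init not in ("beta", "A"):
        raise ValueError("init must be 'beta' or 'A'")
    aff = lda_affinities(labels)

    # the two 4-matrix chain shapes, ordered once per run
    order_A = mcmo.chain_order((M, N, P, N, M))
    order_beta = mcmo.chain_order((N, M, 1, M, N))

    if init == "beta":
        beta = np.full(M, 1.0 / np.sqrt(M))
        A = None
    else:
        Ksum = np.sum(stack.as_array(), axis=0)
        w, V = scipy.linalg.eigh(Ksum)
        A = V[:, ::-1][:, :P]  # leading eigenvectors of the summed kernel
        beta = None

    history: list[float] = []
    for _ in range(n_iter):
        if init == "A":
            S_A, S_Ap = scatter_A(stack, A, aff, order_A, scatter_method)
            beta = optimize_beta(S_A, S_Ap, nonneg=nonneg_beta)
            S_b, S_bp = scatter_beta(stack, beta, aff, order_beta, scatter_method)
            A = optimize_A(S_b, S_bp, P)
        else:
            S_b, S_bp = scatter_beta(stack, beta, aff, order_beta, scatter_method)
            A = optimize_A(S_b, S_bp, P)
            S_A, S_Ap = scatter_A(stack, A, aff, order_A, scatter_method)
            beta = optimize_beta(S_A, S_Ap, nonneg=nonneg_beta)
        num = float(np.trace(A.T @ S_b @ A))
        den = float(np.trace(A.T @ S_bp @ A))
        history.append(num / den if den != 0 else np.inf)

    return MKLDRModel(
        A=A,
        beta=beta,
        P=P,
        train_sample_ids=list(stack.sample_ids),
        specs=list(stack.specs),
        history=history,
    )


def project(model: MKLDRModel, stack_slices: list[np.ndarray]) -> np.ndarray:
    """Embed samples given their per-sample kernel slices.

    Slice i must be N_train x M over the training sample ordering (for a
    held-out sample: kernel evaluations against every training sample,
    under the training specs). Row i of the result is (A^T K^(i) beta)^T.
    """
    N, P = model.A.shape
    M = model.beta.shape[0]
    Z = np.empty((len(stack_slices), P))
    for i, Ki in enumerate(stack_slices):
        Ki = np.asarray(Ki, dtype=float)
        if Ki.shape != (N, M):
            raise ValueError(f"slice {i} has shape {Ki.shape}, expected ({N}, {M})")
        Z[i] = model.A.T @ (Ki @ model.beta)
    return Z


def project_training(model: MKLDRModel, stack: KernelStack) -> np.ndarray:
    """Embed the training cohort directly from its own kernel stack."""
    if stack.sample_ids != model.train_sample_ids:
        raise ValueError("stack sample ordering differs from the trained model")
    U = stack.combined(model.beta)  # column i = K^(i) beta
    return U.T @ model.A
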