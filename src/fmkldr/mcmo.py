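"""Matrix-chain multiplication ordering (MCMO) by dynamic programming.

Multiplying a chain A_1 A_2 ... A_n is associative: the parenthesization
changes the scalar-multiplication count but not the product. The classic
DP finds the cheapest order: with matrix A_i of shape d_{i-1} x d_i,

    F(i, i)   = 0
    F(i, j)   = min_{i <= t < j}  F(i, t) + F(t+1, j) + d_{i-1} d_t d_j

and the argmin split t is recorded to reconstruct the order. Costs are
kept as Python integers, which are arbitrary precision, so cubic-scale
counts at large N cannot overflow.

The scatter-matrix updates of the MKL-DR optimizer each reduce to a
4-matrix chain, whose optimal order is computed once per training run
(one order for each of the two scatter shapes).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = ["ChainDims", "ChainOrder", "chain_order", "multiply_chain"]


@dataclass(frozen=True)
class ChainDims:
    """Dimensions of a matrix chain: matrix i is dims[i-1] x dims[i]."""

    dims: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if len(self.dims) < 2:
            raise ValueError("a chain needs at least one matrix (two dims)")
        if any(d < 1 for d in self.dims):
            raise ValueError("all dimensions must be >= 1")

    @property
    def n_matrices(self) -> int:
        return len(self.dims) - 1


@dataclass
class ChainOrder:
    """DP cost table, split points and minimal total cost for one chain.

    ``cost_table[i][j]`` (0-based, i <= j) is the minimal scalar-
    multiplication count for the sub-chain A_i ... A_j; ``split_table``
    holds the argmin split t, with ties broken toward the smallest t for
    determinism.
    """

    dims: ChainDims
    cost_table: list[list[int]]
    split_table: list[list[int]]

    @property
    def total_cost(self) -> int:
        return self.cost_table[0][self.dims.n_matrices - 1]

    def left_to_right_cost(self) -> int:
        """Cost of the naive ((A_1 A_2) A_3) ... evaluation."""
        d = self.dims.dims
        cost, lead = 0, d[0]
        for k in range(1, len(d) - 1):
            cost += lead * d[k] * d[k + 1]
        return cost

    def to_json(self) -> str:
        return json.dumps(
            {
                "dims": list(self.dims.dims),
                "cost_table": self.cost_table,
                "split_table": self.split_table,
                "total_cost": self.total_cost,
            }
        )


def chain_order(dims: ChainDims | tuple[int, ...] | list[int]) -> ChainOrder:
    """Optimal multiplication order of a matrix chain.

    Returns the full DP tables; ``total_cost`` is the minimum over all
    parenthesizations of the scalar-multiplication count.
    """
    if not isinstance(dims, ChainDims):
        dims = ChainDims(tuple(dims))
    d = dims.dims
    n = dims.n_matrices
    F = [[0] * n for _ in range(n)]
    split = [[-1] * n for _ in range(n)]
    for length in range(2, n + 1):
        for i in range(n - length + 1):
            j = i + length - 1
            best, best_t = None, -1
            for t in range(i, j):
                c = F[i][t] + F[t + 1][j] + d[i] * d[t + 1] * d[j + 1]
                if best is None or c < best:  # strict: smallest t wins ties
                    best, best_t = c, t
            F[i][j] = best
            split[i][j] = best_t
    return ChainOrder(dims=dims, cost_table=F, split_table=split)


def multiply_chain(mats: list[np.ndarray], order: ChainOrder) -> np.ndarray:
    """Multiply a chain of matrices following a precomputed order.

    The result equals the naive left-to-right product (associativity);
    only the operation count differs.
    """
    mats = [np.asarray(M, dtype=float) for M in mats]
    d = order.dims.dims
    if len(mats) != order.dims.n_matrices:
        raise ValueError("number of matrices does not match the order's dims")
    for k, M in enumerate(mats):
        if M.shape != (d[k], d[k + 1]):
            raise ValueError(
                f"matrix {k} has shape {M.shape}, expected ({d[k]}, {d[k + 1]})"
            )

    def rec(i: int, j: int) -> np.ndarray:
        if i == j:
            return mats[i]
        t = order.split_table[i][j]
        return rec(i, t) @ rec(t + 1, j)

    return rec(0, len(mats) - 1)
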