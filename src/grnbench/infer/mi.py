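"""Plug-in mutual information estimation on discretized expression.

Each gene is discretized into B equal-frequency bins (default
``B = ceil(sqrt(N))``) using midranks, so tied values always land in the
same bin and the estimate is invariant under strictly monotone per-gene
transforms.  Pairwise MI is the plug-in estimate

    M_ij = sum_ab p(a, b) * log2( p(a, b) / (p(a) p(b)) )

over the joint bin counts.  A constant gene occupies a single bin and has
zero MI with every partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .. import types

__all__ = ["MIMatrix", "discretize", "estimate_mi", "pairwise_mi", "mi_from_joint"]


@dataclass
class MIMatrix:
    """Symmetric nonnegative matrix of pairwise MI in bits, zero diagonal."""

    values: np.ndarray
    gene_ids: list[str]
    n_bins: int
    scheme: str = "equal-frequency"


def default_bins(n: int) -> int:
    return max(2, math.ceil(math.sqrt(n)))


def discretize(values: np.ndarray, n_bins: int | None = None) -> tuple[np.ndarray, int]:
    """Equal-frequency midrank binning; returns (labels N x G, n_bins)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    b = default_bins(n) if n_bins is None else int(n_bins)
    if b < 2:
        raise types.ParameterError("need at least 2 bins")
    labels = np.empty(values.shape, dtype=np.int64)
    for j in range(values.shape[1]):
        r = rankdata(values[:, j], method="average")  # ties share a midrank
        labels[:, j] = np.clip(((r - 0.5) / n * b).astype(np.int64), 0, b - 1)
    return labels, b


def mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI in bits from a table of joint counts.

    Terms are summed in sorted order so the result is bit-identical for a
    table and its transpose — downstream greedy selections must not see
    1-ulp asymmetries.
    """
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    if n <= 0:
        return 0.0
    p = joint / n
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (pi * pj))
    finite = term[np.isfinite(term)]
    finite.sort()
    return float(finite.sum())


def pairwise_mi(labels: np.ndarray, n_bins: int) -> np.ndarray:
    """All-pairs plug-in MI from bin labels via one-hot cross products."""
    n, g = labels.shape
    b = n_bins
    # one-hot encode every gene; joint counts for all pairs come from a
    # single (G*B x N) @ (N x G*B) product
    onehot = np.zeros((n, g * b))
    cols = np.arange(g) * b
    onehot[np.arange(n)[:, None], cols[None, :] + labels] = 1.0

    m = np.zeros((g, g))
    # BLAS-friendly blocking keeps the cross-product under control for
    # larger gene counts
    block = max(1, int(2.0e7 // max(1, g * b)))
    for start in range(0, g, block):
        stop = min(g, start + block)
        cross = onehot[:, start * b : stop * b].T @ onehot  # (gb x G*B)
        for ii, i in enumerate(range(start, stop)):
            for j in range(i + 1, g):
                joint = cross[ii * b : (ii + 1) * b, j * b : (j + 1) * b]
                m[i, j] = m[j, i] = mi_from_joint(joint)
    return m


def estimate_mi(
    expr: "types.ExpressionMatrix | np.ndarray",
    n_bins: int | None = None,
) -> MIMatrix:
    """Pairwise plug-in MI matrix of an expression matrix."""
    if isinstance(expr, types.ExpressionMatrix):
        values = expr.values
        gene_ids = list(expr.gene_ids)
    else:
        values = np.atleast_2d(np.asarray(expr, dtype=float))
        gene_ids = [f"G{i + 1}" for i in range(values.shape[1])]
    if values.shape[0] < 2:
        raise types.ParameterError("MI estimation needs at least 2 experiments")
    labels, b = discretize(values, n_bins)
    m = pairwise_mi(labels, b)
    np.fill_diagonal(m, 0.0)
    # clip the tiny negative values that finite-precision log sums produce
    np.clip(m, 0.0, None, out=m)
    return MIMatrix(values=m, gene_ids=gene_ids, n_bins=b)
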