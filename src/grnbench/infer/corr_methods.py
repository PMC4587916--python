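"""Correlation-driven inference methods: MutRank, Zscore, PCIT and a
shrinkage partial-correlation network (GeneNet-style, undirected)."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from ..types import ExpressionMatrix, ParameterError, ScoreMatrix
from .params import MethodParams

__all__ = [
    "mutrank",
    "zscore",
    "pcit",
    "genenet_simplified",
    "mutrank_scores",
    "zscore_matrix",
    "pcit_from_correlation",
    "partial_correlation_from",
    "shrunk_correlation",
]


def _correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; undefined entries (constant
    genes) become 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(values, rowvar=False)
    c = np.atleast_2d(c)
    c[~np.isfinite(c)] = 0.0
    return c


def mutrank_scores(corr: np.ndarray) -> np.ndarray:
    """MutRank confidences from a correlation matrix.

    Per gene i, partners are ranked by decreasing |corr| (best rank 1,
    ties by average rank) giving r_ij; the combined score is
    ``s_ij = r_ij * r_ji / 2``, where small means confident, so the
    emitted confidence is ``-s_ij``.
    """
    g = corr.shape[0]
    r = np.zeros((g, g))
    for i in range(g):
        others = np.arange(g) != i
        r[i, others] = rankdata(-np.abs(corr[i, others]), method="average")
    s = r * r.T / 2.0
    out = -s
    np.fill_diagonal(out, 0.0)
    return out


def mutrank(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    if expr.n_experiments < 3:
        raise ParameterError("mutrank needs at least 3 experiments")
    corr = _correlation(expr.values)
    return ScoreMatrix(
        mutrank_scores(corr), list(expr.gene_ids), method="mutrank", symmetric=True
    )


def zscore_matrix(values: np.ndarray) -> np.ndarray:
    """Directed knockout z-scores.

    The knocked-out gene of experiment k is detected as the argmin of the
    experiment's row (first index on ties); its row of scores is
    ``|x_jk - mean_j| / sd_j``.  A gene detected in several experiments
    gets the mean of its per-experiment rows; never-detected genes emit
    zero rows, and constant genes score 0 as targets.
    """
    n, g = values.shape
    mu = values.mean(axis=0)
    sd = values.std(axis=0)  # population std of the empirical distribution
    z = np.zeros((g, g))
    counts = np.zeros(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        zk = np.abs(values - mu[None, :]) / sd[None, :]
    zk[~np.isfinite(zk)] = 0.0
    for k in range(n):
        i = int(np.argmin(values[k]))
        z[i] += zk[k]
        counts[i] += 1
    nz = counts > 0
    z[nz] /= counts[nz, None]
    np.fill_diagonal(z, 0.0)
    return z


def zscore(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    if expr.n_experiments < 2:
        raise ParameterError("zscore needs at least 2 experiments")
    return ScoreMatrix(
        zscore_matrix(expr.values),
        list(expr.gene_ids),
        method="zscore",
        symmetric=False,
    )


def _first_order_partials(corr: np.ndarray) -> np.ndarray:
    """Tensor P[k, i, j] = partial correlation of (i, j) given k."""
    g = corr.shape[0]
    c = np.clip(corr, -1.0 + 1e-12, 1.0 - 1e-12)
    np.fill_diagonal(c, 1.0 - 1e-12)
    p = np.empty((g, g, g))
    for k in range(g):
        ck = c[k]
        denom = np.sqrt(np.outer(1.0 - ck**2, 1.0 - ck**2))
        p[k] = (c - np.outer(ck, ck)) / denom
    return p


def pcit_from_correlation(corr: np.ndarray) -> np.ndarray:
    """PCIT: DPI-style triplet filtering with first-order partial
    correlations.

    For every triplet (i, j, k) a local tolerance ``eps_ijk`` is the mean
    of the three |partial| / |raw| correlation ratios; the pair (i, j) is
    flagged non-significant in that triplet when
    ``|r_ij| <= eps_ijk * |r_ik|`` and ``|r_ij| <= eps_ijk * |r_jk|``.
    An edge flagged in any triplet is zeroed; survivors keep |r_ij|.
    """
    g = corr.shape[0]
    absr = np.abs(corr)
    p = np.abs(_first_order_partials(corr))
    # ratio[k, i, j] = |partial r_ij.k| / |r_ij|; uninformative (zero raw
    # correlation) ratios count as 1 in the tolerance average
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / absr[None, :, :]
    ratio[~np.isfinite(ratio)] = 1.0

    removed = np.zeros((g, g), dtype=bool)
    for k in range(g):
        # eps[i, j] for this third gene k: ratios of (i,j|k), (j,k|i), (i,k|j)
        s = ratio[:, :, k]  # s[a, b] = |partial(b,k|a)| / |r_bk|
        eps = (ratio[k] + s + s.T) / 3.0
        flag = (absr <= eps * absr[:, k][:, None]) & (
            absr <= eps * absr[k, :][None, :]
        )
        flag[k, :] = False
        flag[:, k] = False
        removed |= flag
    out = np.where(removed, 0.0, absr)
    np.fill_diagonal(out, 0.0)
    return out


def pcit(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    if expr.n_experiments < 4:
        raise ParameterError("pcit needs at least 4 experiments")
    corr = _correlation(expr.values)
    return ScoreMatrix(
        pcit_from_correlation(corr), list(expr.gene_ids), method="pcit", symmetric=True
    )


def shrunk_correlation(values: np.ndarray, min_shrinkage: float = 1e-6):
    """Correlation matrix shrunk toward the identity.

    The shrinkage intensity is the analytic variance-over-signal ratio
    ``lambda = sum var(r_ij) / sum r_ij**2`` (off-diagonal sums), clipped
    to [min_shrinkage, 1]; the result ``(1 - lambda) R + lambda I`` is
    positive definite for any lambda > 0.
    """
    n, g = values.shape
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x = (values - values.mean(axis=0)) / sd
    r = (x.T @ x) / (n - 1)
    np.fill_diagonal(r, 1.0)
    # var of each r_ij from the products of standardized scores
    # w_kij = x_ki * x_kj; sum_k (w_kij - mean_k w_ij)^2 expanded so no
    # n x G x G tensor is materialized
    w_mean = (x.T @ x) / n
    w_sq_sum = (x**2).T @ (x**2)
    var_r = n / (n - 1.0) ** 3 * (w_sq_sum - n * w_mean**2)
    off = ~np.eye(g, dtype=bool)
    denom = float((r[off] ** 2).sum())
    lam = float(var_r[off].sum()) / denom if denom > 0 else 1.0
    lam = float(np.clip(lam, min_shrinkage, 1.0))
    shrunk = (1.0 - lam) * r
    np.fill_diagonal(shrunk, 1.0)
    return shrunk, lam


def partial_correlation_from(corr: np.ndarray) -> np.ndarray:
    """Full-order partial correlations ``-W_ij / sqrt(W_ii W_jj)`` from the
    inverse (precision) of a correlation matrix."""
    omega = np.linalg.inv(corr)
    d = np.sqrt(np.diag(omega))
    p = -omega / np.outer(d, d)
    np.fill_diagonal(p, 0.0)
    return p


def genenet_simplified(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Undirected shrinkage partial-correlation network.

    Confidence is |full-order partial correlation| computed from the
    shrunk correlation matrix.  The causal-orientation step of the
    original heuristic is deliberately not implemented.
    """
    if expr.n_experiments < 3:
        raise ParameterError("partial-correlation network needs >= 3 experiments")
    p = params or MethodParams()
    shrunk, _ = shrunk_correlation(expr.values, p.genenet_min_shrinkage)
    scores = np.abs(partial_correlation_from(shrunk))
    np.fill_diagonal(scores, 0.0)
    return ScoreMatrix(
        scores, list(expr.gene_ids), method="genenet", symmetric=True
    )
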