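"""Inference methods built on the pairwise mutual-information matrix:
relevance network, CLR, ARACNE, C3NET, MRNET and MRNETB."""

from __future__ import annotations

import zlib

import numpy as np

from ..types import ExpressionMatrix, ScoreMatrix
from .mi import estimate_mi
from .params import MethodParams

__all__ = [
    "relnet",
    "clr",
    "aracne",
    "c3net",
    "mrnet",
    "mrnetb",
    "clr_from_mi",
    "aracne_from_mi",
    "mrnet_from_mi",
    "mrnetb_from_mi",
]


def _mi_values(expr: ExpressionMatrix, params: MethodParams | None) -> np.ndarray:
    p = params or MethodParams()
    return estimate_mi(expr, n_bins=p.mi_bins).values


def relnet(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Relevance network: the raw MI matrix, thresholded only at evaluation."""
    m = _mi_values(expr, params)
    return ScoreMatrix(m, list(expr.gene_ids), method="relnet", symmetric=True)


def clr_from_mi(m: np.ndarray) -> np.ndarray:
    """Context likelihood of relatedness over an MI matrix.

    Each gene's MI row (all G entries, the zero diagonal included) is
    summarized by its mean and its standard deviation with a G-1
    denominator; the score is ``sqrt(ci^2 + cj^2)`` with
    ``ci = max(0, (M_ij - mu_i) / sd_i)``, and 0 when a row is constant.
    """
    g = m.shape[0]
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zi = (m - mu[:, None]) / sd[:, None]
    zi[~np.isfinite(zi)] = 0.0
    zi = np.maximum(zi, 0.0)
    c = np.sqrt(zi**2 + zi.T**2)
    np.fill_diagonal(c, 0.0)
    return c


def clr(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    m = _mi_values(expr, params)
    return ScoreMatrix(
        clr_from_mi(m), list(expr.gene_ids), method="clr", symmetric=True
    )


def aracne_from_mi(m: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Data-processing-inequality pruning: zero M_ij when some third gene k
    has ``min(M_ik, M_jk) - eps > M_ij`` (the weakest edge of the triplet).

    All removals are decided on the original matrix simultaneously.
    """
    g = m.shape[0]
    out = m.copy()
    removed = np.zeros((g, g), dtype=bool)
    for i in range(g):
        # weakest[j, k] = min(M_ik, M_jk); the diagonal zeros of M make
        # k = i and k = j harmless (min is then 0 <= M_ij + eps)
        weakest = np.minimum(m[i][None, :], m)
        removed[i] = np.any(weakest - eps > m[i][:, None], axis=1)
    out[removed] = 0.0
    np.fill_diagonal(out, 0.0)
    return out


def aracne(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    p = params or MethodParams()
    m = _mi_values(expr, p)
    return ScoreMatrix(
        aracne_from_mi(m, p.aracne_eps),
        list(expr.gene_ids),
        method="aracne",
        symmetric=True,
    )


def _stable_seed(*parts) -> int:
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def _canonical_rank(gene_ids: list[str]) -> np.ndarray:
    """rank[i] = position of gene i when genes are sorted by id; used as a
    column-order-independent tie-break."""
    order = sorted(range(len(gene_ids)), key=lambda i: gene_ids[i])
    rank = np.empty(len(gene_ids), dtype=np.int64)
    for pos, i in enumerate(order):
        rank[i] = pos
    return rank


def c3net(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Conservative causal core: keep, per gene, only its strongest MI
    partner among the pairs that beat a permutation null at level alpha.

    The null is built from MI values of column-permuted gene pairs (one
    pair per permutation draw); pair choice and shuffling are driven by a
    canonical gene-id ordering so the result does not depend on column
    order.  At most G nonzero connections can survive.
    """
    p = params or MethodParams()
    m = _mi_values(expr, p)
    g = len(expr.gene_ids)
    values = expr.values

    canonical = np.argsort(np.asarray(expr.gene_ids, dtype=object))
    rng = np.random.default_rng(
        _stable_seed(seed, "c3net", *sorted(expr.gene_ids))
    )
    from .mi import default_bins, discretize, mi_from_joint

    b = p.mi_bins or default_bins(values.shape[0])
    labels, b = discretize(values, b)
    null = np.empty(p.c3net_permutations)
    for t in range(p.c3net_permutations):
        ci, cj = rng.choice(g, size=2, replace=False)
        i, j = canonical[ci], canonical[cj]
        perm = rng.permutation(values.shape[0])
        joint = np.zeros((b, b))
        np.add.at(joint, (labels[perm, i], labels[:, j]), 1.0)
        null[t] = mi_from_joint(joint)
    threshold = float(np.quantile(null, 1.0 - p.c3net_alpha))

    sig = np.where(m > threshold, m, 0.0)
    keep = np.zeros_like(sig)
    rank = _canonical_rank(list(expr.gene_ids))
    for i in range(g):
        j = _argmax_canonical(sig[i], rank)
        if sig[i, j] > 0:
            keep[i, j] = sig[i, j]
    out = np.maximum(keep, keep.T)
    np.fill_diagonal(out, 0.0)
    return ScoreMatrix(out, list(expr.gene_ids), method="c3net", symmetric=True)


def _argmax_canonical(u: np.ndarray, rank: np.ndarray | None) -> int:
    """Index of the maximum; exact ties go to the lowest canonical rank.

    Discretized MI takes few distinct values, so exact ties are common;
    a positional tie-break would make greedy selections depend on column
    order.
    """
    j = int(np.argmax(u))
    if rank is None:
        return j
    tied = np.flatnonzero(u == u[j])
    if len(tied) > 1:
        j = int(tied[np.argmin(rank[tied])])
    return j


def mrnet_from_mi(m: np.ndarray, rank: np.ndarray | None = None) -> np.ndarray:
    """Forward minimum-redundancy maximum-relevance selection per target.

    For target t the candidate score is ``u_j = M_jt - mean_s M_js`` over
    the already-selected set s; selection stops when no candidate has a
    positive score.  A gene's confidence for t is its u at selection time;
    the directed matrix is symmetrized by max.  ``rank`` is the canonical
    tie-break order.
    """
    g = m.shape[0]
    directed = np.zeros((g, g))
    for t in range(g):
        rel = m[:, t].copy()
        rel[t] = -np.inf
        redsum = np.zeros(g)
        available = np.ones(g, dtype=bool)
        available[t] = False
        n_sel = 0
        while True:
            u = rel - (redsum / n_sel if n_sel else 0.0)
            u[~available] = -np.inf
            j = _argmax_canonical(u, rank)
            if not np.isfinite(u[j]) or u[j] <= 0:
                break
            directed[j, t] = u[j]
            available[j] = False
            redsum += m[:, j]
            n_sel += 1
    return np.maximum(directed, directed.T)


def mrnet(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    m = _mi_values(expr, params)
    rank = _canonical_rank(list(expr.gene_ids))
    return ScoreMatrix(
        mrnet_from_mi(m, rank), list(expr.gene_ids), method="mrnet", symmetric=True
    )


def _mrmr_objective(rel_sum: float, red_sum: float, size: int) -> float:
    """Set objective: total relevance minus mean pairwise redundancy."""
    if size < 2:
        return rel_sum
    return rel_sum - red_sum / (size * (size - 1))


def mrnetb_from_mi(
    m: np.ndarray,
    max_moves: int = 200,
    rank: np.ndarray | None = None,
    return_sets: bool = False,
):
    """Backward-elimination MRMR with sequential replacement per target.

    Starting from all candidates, repeatedly drop the gene whose removal
    most improves the set objective (sum of relevances minus mean pairwise
    redundancy); then run a replacement phase — swap an in-set for an
    out-set gene, drop a gene, or re-add one — accepting the best strictly
    improving move until none exists (each move raises the objective, so
    the phase terminates).  The confidence of an in-set gene is its
    relevance minus its mean redundancy with the rest of the set, floored
    at 0; symmetrized by max.
    """
    g = m.shape[0]
    order_rank = rank if rank is not None else np.arange(g)
    directed = np.zeros((g, g))
    final_sets: list[list[int]] = []
    for t in range(g):
        rel = m[:, t].copy()
        in_set = np.ones(g, dtype=bool)
        in_set[t] = False
        rel[t] = 0.0
        # rowsum[j] = sum of M_jk over k currently in the set
        rowsum = m @ in_set.astype(float)
        rel_sum = float(rel[in_set].sum())
        red_sum = float(rowsum[in_set].sum())  # ordered-pair double count
        size = int(in_set.sum())
        obj = _mrmr_objective(rel_sum, red_sum, size)

        def removal_candidates():
            idx = np.flatnonzero(in_set)
            rs = rel_sum - rel[idx]
            ds = red_sum - 2.0 * rowsum[idx]
            if size - 1 >= 2:
                cand = rs - ds / ((size - 1) * (size - 2))
            else:
                cand = rs.copy()
            return idx, rs, ds, cand

        # backward elimination
        while size > 1:
            idx, rs, ds, cand = removal_candidates()
            k = _argmax_canonical(cand, order_rank[idx])
            if cand[k] <= obj:
                break
            j = int(idx[k])
            in_set[j] = False
            rel_sum, red_sum = float(rs[k]), float(ds[k])
            rowsum -= m[:, j]
            size -= 1
            obj = _mrmr_objective(rel_sum, red_sum, size)

        # sequential replacement: best of {swap, add, remove} while improving
        for _ in range(max_moves):
            best = (obj + 1e-12, None)  # (objective, move)
            ins = np.flatnonzero(in_set)
            outs = np.flatnonzero(~in_set)
            outs = outs[outs != t]
            if len(ins) and len(outs):
                rs = rel_sum - rel[ins][:, None] + rel[outs][None, :]
                ds = (
                    red_sum
                    - 2.0 * rowsum[ins][:, None]
                    + 2.0 * (rowsum[outs][None, :] - m[np.ix_(ins, outs)])
                )
                cand = (
                    rs - ds / (size * (size - 1)) if size >= 2 else rs.copy()
                )
                k = int(np.argmax(cand))
                ii, oo = np.unravel_index(k, cand.shape)
                if cand[ii, oo] > best[0]:
                    best = (
                        float(cand[ii, oo]),
                        ("swap", int(ins[ii]), int(outs[oo]),
                         float(rs[ii, oo]), float(ds[ii, oo])),
                    )
            if len(outs):
                rs_a = rel_sum + rel[outs]
                ds_a = red_sum + 2.0 * rowsum[outs]
                cand_a = np.array(
                    [
                        _mrmr_objective(rs_a[k], ds_a[k], size + 1)
                        for k in range(len(outs))
                    ]
                )
                k = _argmax_canonical(cand_a, order_rank[outs])
                if cand_a[k] > best[0]:
                    best = (
                        float(cand_a[k]),
                        ("add", int(outs[k]), None,
                         float(rs_a[k]), float(ds_a[k])),
                    )
            if size >= 2:
                idx, rs_r, ds_r, cand_r = removal_candidates()
                k = _argmax_canonical(cand_r, order_rank[idx])
                if cand_r[k] > best[0]:
                    best = (
                        float(cand_r[k]),
                        ("remove", int(idx[k]), None,
                         float(rs_r[k]), float(ds_r[k])),
                    )
            if best[1] is None:
                break
            obj, (kind, a, b, rel_sum, red_sum) = best[0], best[1]
            if kind == "swap":
                in_set[a] = False
                in_set[b] = True
                rowsum += m[:, b] - m[:, a]
            elif kind == "add":
                in_set[a] = True
                rowsum += m[:, a]
                size += 1
            else:
                in_set[a] = False
                rowsum -= m[:, a]
                size -= 1

        idx = np.flatnonzero(in_set)
        final_sets.append(idx.tolist())
        if len(idx):
            mean_red = (
                rowsum[idx] / (size - 1) if size >= 2 else np.zeros(len(idx))
            )
            directed[idx, t] = np.maximum(rel[idx] - mean_red, 0.0)
    sym = np.maximum(directed, directed.T)
    if return_sets:
        return sym, final_sets
    return sym


def mrnetb(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    p = params or MethodParams()
    m = _mi_values(expr, p)
    rank = _canonical_rank(list(expr.gene_ids))
    return ScoreMatrix(
        mrnetb_from_mi(m, p.mrnetb_max_swaps, rank),
        list(expr.gene_ids),
        method="mrnetb",
        symmetric=True,
    )
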