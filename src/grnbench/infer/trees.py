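"""Tree-ensemble inference (GENIE3-style) and the random baseline."""

from __future__ import annotations

import zlib

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ..types import ExpressionMatrix, ScoreMatrix
from .params import MethodParams

__all__ = ["genie3", "random_baseline"]


def _stable_seed(*parts) -> int:
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def genie3(
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Random-forest regression of each target gene on all other genes.

    score(i, j) is the variance-reduction importance of gene i in gene
    j's forest (each forest's importances sum to 1).  Candidate
    regressors are presented in gene-id-sorted order and each forest is
    seeded from (seed, target gene id), so the output only depends on the
    gene set, not on column order.  Directed.
    """
    p = params or MethodParams()
    values = expr.values
    n, g = values.shape
    gene_ids = list(expr.gene_ids)
    max_features = p.genie3_max_features or max(1, round(np.sqrt(g - 1)))
    scores = np.zeros((g, g))
    order = sorted(range(g), key=lambda i: gene_ids[i])
    for j in range(g):
        predictors = [i for i in order if i != j]
        x = values[:, predictors]
        y = values[:, j]
        if np.all(y == y[0]):
            continue  # constant target: no variance to explain
        rf = RandomForestRegressor(
            n_estimators=p.genie3_trees,
            max_features=min(max_features, g - 1),
            random_state=_stable_seed(seed, "genie3", gene_ids[j]),
            n_jobs=1,
        )
        rf.fit(x, y)
        scores[predictors, j] = rf.feature_importances_
    np.fill_diagonal(scores, 0.0)
    return ScoreMatrix(scores, gene_ids, method="genie3", symmetric=False)


def random_baseline(
    expr: "ExpressionMatrix | int",
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """I.i.d. uniform scores for every ordered gene pair: the benchmark's
    floor reference.  Expected precision at any cut equals the gold
    standard's edge density.

    Scores are a deterministic hash of (seed, regulator id, target id), so
    they are reproducible and equivariant under column permutation.
    """
    if isinstance(expr, ExpressionMatrix):
        gene_ids = list(expr.gene_ids)
    else:
        gene_ids = [f"G{i + 1}" for i in range(int(expr))]
    g = len(gene_ids)
    scores = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            h = zlib.crc32(f"{seed}:{gene_ids[i]}->{gene_ids[j]}".encode())
            scores[i, j] = h / 2**32
    return ScoreMatrix(scores, gene_ids, method="random", symmetric=False)
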