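"""Top-edges evaluation of an inferred network against a gold standard.

A score matrix is turned into a ranked list of candidate edges
(self-pairs excluded); the best ``t = round(x * P)`` candidates are
evaluated, where P is the number of possible connections (``G^2 - G``
directed, ``(G^2 - G)/2`` undirected) and x the top fraction (default
20%).  Confusion counts at every rank give precision/recall and ROC
polylines; the headline metrics are the areas under the truncated curves,
normalized so a perfect ranking scores exactly 1 within the evaluated
span, plus the mean precision over the t ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GoldStandard, ScoreMatrix, check_gene_match

__all__ = [
    "EvaluationSpec",
    "EvaluationResult",
    "evaluate",
    "aupr_top",
    "auroc_top",
    "mean_precision_top",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class EvaluationSpec:
    """Evaluation protocol: fraction of possible connections kept and
    whether edge direction is scored.  Self-interactions are never
    considered."""

    top_fraction: float = 0.20
    directed: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")

    def n_top(self, n_genes: int) -> int:
        possible = n_genes * (n_genes - 1)
        if not self.directed:
            possible //= 2
        return max(1, _round_half_up(self.top_fraction * possible))


@dataclass
class EvaluationResult:
    """Per-rank confusion counts over the top t predictions."""

    thresholds: np.ndarray  # rank cutoffs 1..t
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_true: int  # positives in the candidate universe
    n_candidates: int  # size of the candidate universe
    directed: bool
    degenerate: bool = False  # all-constant score matrix: order is tie-break only

    @property
    def precision(self) -> np.ndarray:
        return self.tp / self.thresholds

    @property
    def recall(self) -> np.ndarray:
        return self.tp / self.n_true

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / (self.n_candidates - self.n_true)


def _candidate_table(
    scores: ScoreMatrix, gold: GoldStandard, directed: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(score, truth) arrays over the candidate universe, in lexicographic
    edge order (the recorded tie-break)."""
    s = scores.values
    a = gold.adjacency != 0
    g = scores.n_genes
    if directed:
        mask = ~np.eye(g, dtype=bool)
        return s[mask], a[mask]
    iu = np.triu_indices(g, k=1)
    s_u = np.maximum(s, s.T)[iu]
    a_u = (a | a.T)[iu]
    return s_u, a_u


def evaluate(
    scores: ScoreMatrix,
    gold: GoldStandard,
    spec: EvaluationSpec | None = None,
) -> EvaluationResult:
    """Confusion counts at each of the top t ranks.

    Candidates are sorted by decreasing score with ties broken by the
    fixed lexicographic edge order; in undirected mode the pair score is
    the max over the two directions and a pair is true if either
    direction is a gold edge.
    """
    spec = spec or EvaluationSpec()
    check_gene_match(scores.gene_ids, gold.genes)
    g = scores.n_genes
    cand_scores, cand_truth = _candidate_table(scores, gold, spec.directed)
    n_cand = len(cand_scores)
    n_true = int(cand_truth.sum())
    if n_true == 0:
        raise ValueError("gold standard has no true edges in the evaluated universe")
    t = min(spec.n_top(g), n_cand)

    degenerate = bool(np.all(cand_scores == cand_scores[0]))
    order = np.argsort(-cand_scores, kind="stable")  # stable = lexicographic ties
    top_truth = cand_truth[order[:t]]

    ranks = np.arange(1, t + 1)
    tp = np.cumsum(top_truth)
    fp = ranks - tp
    fn = n_true - tp
    tn = n_cand - n_true - fp
    return EvaluationResult(
        thresholds=ranks,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_true=n_true,
        n_candidates=n_cand,
        directed=spec.directed,
        degenerate=degenerate,
    )


def aupr_top(result: EvaluationResult) -> float:
    """Area under precision vs recall over the evaluated ranks, normalized
    by the recall span actually reachable so a perfect ranking scores 1."""
    recall = result.recall
    precision = result.precision
    if recall[-1] == 0:
        return 0.0
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[precision[0]], precision])
    area = np.trapezoid(p, r)
    return float(area / recall[-1])


def auroc_top(result: EvaluationResult) -> float:
    """Area under TPR vs FPR over the evaluated ranks, normalized by the
    FPR span covered."""
    tpr = result.recall
    fpr = result.fpr
    if fpr[-1] == 0:
        # no false positive among the evaluated ranks
        return 1.0 if tpr[-1] > 0 else 0.5
    x = np.concatenate([[0.0], fpr])
    y = np.concatenate([[0.0], tpr])
    area = np.trapezoid(y, x)
    return float(area / fpr[-1])


def mean_precision_top(result: EvaluationResult) -> float:
    """Arithmetic mean of precision over ranks 1..t."""
    return float(result.precision.mean())
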