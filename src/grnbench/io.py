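"""Readers and writers for the benchmark's plain-text formats.

Expression matrices are tab-separated with a header row of gene names and
one row per experiment (row label = experiment id).  Gold standards are
accepted either as a full adjacency matrix (square, header row and index
column of gene names) or as an edge list of two columns
(regulator, target) with an optional third weight column, which is parsed
but ignored for truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationResult
from .types import ExpressionMatrix, GoldStandard, ScoreMatrix

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gold_adjacency_tsv",
    "write_gold_edgelist_tsv",
    "read_gold_tsv",
    "write_score_matrix_tsv",
    "write_ranked_edges_tsv",
    "read_score_matrix_tsv",
    "write_confusion_tsv",
    "write_metrics_json",
]


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.experiment_ids, columns=expr.gene_ids)
    df.to_csv(path, sep="\t", index_label="experiment")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(c) for c in df.columns],
        experiment_ids=[str(i) for i in df.index],
    )


def write_gold_adjacency_tsv(gold: GoldStandard, path: str | Path) -> None:
    df = pd.DataFrame(gold.adjacency.astype(int), index=gold.genes, columns=gold.genes)
    df.to_csv(path, sep="\t", index_label="gene")


def write_gold_edgelist_tsv(gold: GoldStandard, path: str | Path) -> None:
    rows, cols = np.nonzero(gold.adjacency)
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\n")
        for i, j in zip(rows, cols):
            fh.write(f"{gold.genes[i]}\t{gold.genes[j]}\n")


def read_gold_tsv(path: str | Path, genes: list[str] | None = None) -> GoldStandard:
    """Read a gold standard in either dialect.

    A square numeric table whose header equals its index column is an
    adjacency matrix; anything with 2 or 3 columns is an edge list
    (regulator, target[, weight]).  For an edge list the gene universe is
    taken from ``genes`` when given, else from the union of mentioned
    genes in order of first appearance.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    header = [str(c) for c in df.columns]
    index = [str(i) for i in df.index]
    if len(header) >= 2 and df.shape[0] == df.shape[1] and header == index:
        return GoldStandard(genes=header, adjacency=(df.to_numpy() != 0).astype(np.int8))

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] not in (2, 3):
        raise ValueError(
            f"{path}: expected an adjacency matrix or a 2/3-column edge list, "
            f"got {df.shape[1]} columns"
        )
    regs = df.iloc[:, 0].astype(str).tolist()
    tgts = df.iloc[:, 1].astype(str).tolist()
    if genes is None:
        seen: dict[str, None] = {}
        for gname in regs + tgts:
            seen.setdefault(gname, None)
        genes = list(seen)
    pos = {gname: k for k, gname in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for r, t in zip(regs, tgts):
        if r not in pos or t not in pos:
            raise ValueError(f"{path}: edge {r}->{t} mentions a gene outside the universe")
        adj[pos[r], pos[t]] = 1
    return GoldStandard(genes=list(genes), adjacency=adj)


def write_score_matrix_tsv(scores: ScoreMatrix, path: str | Path) -> None:
    df = pd.DataFrame(scores.values, index=scores.gene_ids, columns=scores.gene_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def read_score_matrix_tsv(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(c) for c in df.columns],
        symmetric=bool(np.allclose(df.to_numpy(), df.to_numpy().T)),
    )


def write_ranked_edges_tsv(scores: ScoreMatrix, path: str | Path) -> None:
    """Ranked edge list (regulator, target, score, rank), best first."""
    g = scores.n_genes
    mask = ~np.eye(g, dtype=bool)
    rows, cols = np.nonzero(mask)
    vals = scores.values[rows, cols]
    order = np.argsort(-vals, kind="stable")
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tscore\trank\n")
        for rank, k in enumerate(order, start=1):
            fh.write(
                f"{scores.gene_ids[rows[k]]}\t{scores.gene_ids[cols[k]]}"
                f"\t{vals[k]:.10g}\t{rank}\n"
            )


def write_confusion_tsv(result: EvaluationResult, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rank": result.thresholds,
            "tp": result.tp,
            "fp": result.fp,
            "tn": result.tn,
            "fn": result.fn,
            "precision": result.precision,
            "recall": result.recall,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_metrics_json(metrics: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
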