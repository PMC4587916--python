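"""Core data containers shared by every stage of the benchmark.

The pipeline moves through four containers: a :class:`GoldStandard`
(the true regulatory adjacency), an :class:`ExpressionMatrix` (experiments
by genes), a :class:`Datasource` (a large noise-free simulated expression
collection paired with its gold standard), and a :class:`Dataset` (a
subsampled, noise-contaminated slice of a datasource).  Inference methods
emit a :class:`ScoreMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ParameterError(ValueError):
    """Raised when a generator or method parameter is infeasible."""


class TopologyError(ValueError):
    """Raised when a network topology violates a simulator precondition."""


@dataclass
class GoldStandard:
    """True regulatory network: ``adjacency[i, j] == 1`` means gene *i*
    (row, regulator) regulates gene *j* (column, target)."""

    genes: list[str]
    adjacency: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        g = len(self.genes)
        if self.adjacency.shape != (g, g):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{g} genes"
            )
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("gold standard must have a zero diagonal (no self-loops)")
        e = int(self.adjacency.sum())
        if not (1 <= e <= g * (g - 1)):
            raise ValueError(f"edge count {e} outside [1, G*(G-1)]")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int((self.adjacency != 0).sum())

    def undirected_adjacency(self) -> np.ndarray:
        """Symmetrized adjacency: an unordered pair is true if either
        direction is a true edge."""
        a = self.adjacency != 0
        return (a | a.T).astype(np.int8)


@dataclass
class ExpressionMatrix:
    """N experiments x G genes, column order identical to the gold standard."""

    values: np.ndarray
    gene_ids: list[str]
    experiment_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, g = self.values.shape
        if g != len(self.gene_ids):
            raise ValueError("column count does not match gene_ids")
        if n < 1:
            raise ValueError("need at least one experiment")
        if not self.experiment_ids:
            self.experiment_ids = [f"E{k + 1}" for k in range(n)]
        if len(self.experiment_ids) != n:
            raise ValueError("row count does not match experiment_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Datasource:
    """A large noise-free expression collection plus its gold standard.

    ``kind`` records how the expression was produced: ``"knockout"`` (one
    experiment per single-gene knockout) or ``"multifactorial"`` (every
    experiment perturbs all basal rates slightly).
    """

    name: str
    expr: ExpressionMatrix
    gold: GoldStandard
    kind: str
    seed: int

    def __post_init__(self) -> None:
        if self.expr.gene_ids != self.gold.genes:
            raise ValueError("expression and gold standard gene sets differ")
        if self.kind not in ("knockout", "multifactorial"):
            raise ValueError(f"unknown datasource kind {self.kind!r}")
        if self.kind == "knockout" and self.expr.n_experiments != self.gold.n_genes:
            raise ValueError("knockout datasource needs one experiment per gene")


@dataclass
class Dataset:
    """A subsampled (and possibly noise-contaminated) view of a datasource."""

    expr: ExpressionMatrix
    source_name: str
    experiment_indices: np.ndarray
    noise: "object | None" = None  # NoiseSpec actually applied, if any
    seed: int = 0

    def __post_init__(self) -> None:
        self.experiment_indices = np.asarray(self.experiment_indices, dtype=int)
        if len(np.unique(self.experiment_indices)) != len(self.experiment_indices):
            raise ValueError("experiment indices must be unique within a dataset")
        if self.expr.n_experiments != len(self.experiment_indices):
            raise ValueError("row count does not match experiment_indices")


@dataclass
class ScoreMatrix:
    """G x G edge-confidence matrix; entry (i, j) is the confidence that
    gene i regulates gene j.  Higher means more confident; zero diagonal."""

    values: np.ndarray
    gene_ids: list[str]
    method: str = ""
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValueError("score matrix shape does not match gene_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def check_gene_match(a: Sequence[str], b: Sequence[str]) -> None:
    if list(a) != list(b):
        raise ValueError("gene sets do not match between the two objects")
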