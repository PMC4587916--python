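"""Shared fixtures: small gold standards and datasources generated at
test time."""

from __future__ import annotations

import numpy as np
import pytest

from grnbench import (
    ExpressionMatrix,
    GoldStandard,
    generate_powerlaw_topology,
    simulate_knockouts,
    simulate_multifactorial,
)


@pytest.fixture(scope="session")
def chain_gold() -> GoldStandard:
    """Three-gene chain G1 -> G2 -> G3."""
    adj = np.zeros((3, 3), dtype=np.int8)
    adj[0, 1] = 1
    adj[1, 2] = 1
    return GoldStandard(genes=["G1", "G2", "G3"], adjacency=adj)


@pytest.fixture(scope="session")
def small_gold() -> GoldStandard:
    return generate_powerlaw_topology(20, 30, seed=11)


@pytest.fixture(scope="session")
def knockout_source(small_gold):
    return simulate_knockouts(small_gold, seed=5)


@pytest.fixture(scope="session")
def multifactorial_source(small_gold):
    return simulate_multifactorial(small_gold, 60, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_expression(n: int, g: int, seed: int) -> ExpressionMatrix:
    r = np.random.default_rng(seed)
    return ExpressionMatrix(
        values=r.normal(size=(n, g)), gene_ids=[f"G{i + 1}" for i in range(g)]
    )
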