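"""Network inference methods behind one contract: expression matrix in,
weighted score matrix out (higher score = more confident edge).

The registry keys follow the wrapper names of the original benchmark
(``aracne``, ``c3net``, ``clr``, ``genenet``, ``genie3``, ``mutrank``,
``mrnet``, ``mrnetb``, ``pcit``, ``zscore``, ``random``); user methods
with the same ``fn(expr, params, seed) -> ScoreMatrix`` signature can be
plugged in with :func:`register_method`.
"""

from __future__ import annotations

from typing import Callable

from ..types import ExpressionMatrix, ScoreMatrix
from .corr_methods import genenet_simplified, mutrank, pcit, zscore
from .mi import MIMatrix, estimate_mi
from .mi_methods import aracne, c3net, clr, mrnet, mrnetb, relnet
from .params import MethodParams
from .trees import genie3, random_baseline

__all__ = [
    "MIMatrix",
    "MethodParams",
    "estimate_mi",
    "relnet",
    "clr",
    "aracne",
    "c3net",
    "mrnet",
    "mrnetb",
    "mutrank",
    "zscore",
    "pcit",
    "genenet_simplified",
    "genie3",
    "random_baseline",
    "METHODS",
    "register_method",
    "get_method",
    "list_methods",
    "run_method",
]

MethodFn = Callable[..., ScoreMatrix]

METHODS: dict[str, MethodFn] = {
    "aracne": aracne,
    "c3net": c3net,
    "clr": clr,
    "genenet": genenet_simplified,
    "genie3": genie3,
    "mutrank": mutrank,
    "mrnet": mrnet,
    "mrnetb": mrnetb,
    "pcit": pcit,
    "relnet": relnet,
    "zscore": zscore,
    "random": random_baseline,
}


def register_method(name: str, fn: MethodFn, overwrite: bool = False) -> None:
    """Add a user method to the registry."""
    if name in METHODS and not overwrite:
        raise ValueError(f"method {name!r} already registered")
    METHODS[name] = fn


def get_method(name: str) -> MethodFn:
    try:
        return METHODS[name]
    except KeyError:
        known = ", ".join(sorted(METHODS))
        raise KeyError(f"unknown method {name!r}; registered methods: {known}")


def list_methods() -> list[str]:
    return sorted(METHODS)


def run_method(
    name: str,
    expr: ExpressionMatrix,
    params: MethodParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Run a registered method on an expression matrix."""
    return get_method(name)(expr, params, seed)
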