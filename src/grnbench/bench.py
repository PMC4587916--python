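"""Benchmark orchestration: replicate datasets per datasource, run every
method, tabulate mean/variance of the top-edges AUPR, flag statistical
winners (rank-sum test, Bonferroni-corrected), aggregate method ranks,
and run the noise- and sample-size-sensitivity sweeps.

All randomness is derived from one master seed through stable per-stage
hashes, so two runs of the same configuration are bit-identical, and the
noise sweep reuses exactly the same subsampled experiment draws at every
noise level (only the noise stream varies).
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .evaluation import EvaluationSpec, aupr_top, auroc_top, evaluate, mean_precision_top
from .infer import MethodParams, run_method
from .perturb import NoiseSpec, add_noise, subsample
from .types import Datasource

__all__ = [
    "BenchmarkConfig",
    "BenchmarkTable",
    "run_benchmark",
    "ranksum_pvalue",
    "flag_winners",
    "aggregate_ranks",
    "noise_sweep",
    "experiments_sweep",
    "derive_seed",
]

log = logging.getLogger("grnbench")


def derive_seed(*parts) -> int:
    """Stable sub-stream seed (< 2**31) from a master seed and labels."""
    return zlib.crc32(":".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


@dataclass
class BenchmarkConfig:
    """Study configuration; the defaults mirror the benchmark's reference
    setup: 10 datasets of 150 experiments per datasource, 20% local
    normal noise plus 10% global lognormal noise, undirected evaluation
    of the top 20% of possible connections."""

    datasources: list[Datasource]
    methods: list[str]
    datasets_per_source: int = 10
    experiments_per_dataset: int = 150
    noise: NoiseSpec = field(
        default_factory=lambda: NoiseSpec(kappa_local=20.0, kappa_global=10.0)
    )
    eval_spec: EvaluationSpec = field(default_factory=EvaluationSpec)
    master_seed: int = 42
    alpha: float = 0.05
    method_params: MethodParams = field(default_factory=MethodParams)


@dataclass
class BenchmarkTable:
    """Methods x datasources grid of per-dataset metrics and summaries."""

    sources: list[str]
    methods: list[str]
    metrics: dict  # (source, method) -> np.ndarray of per-dataset AUPR (NaN = failed)
    winners: dict  # source -> set of flagged method names
    pvalues: dict  # (source, method) -> Bonferroni-corrected p vs the top method
    ranks: "pd.DataFrame"  # sources x methods, 1 = best
    records: list  # long-format dicts (datasource, method, dataset, metric, value)

    def mean(self, source: str, method: str) -> float:
        return float(np.nanmean(self.metrics[(source, method)]))

    def variance(self, source: str, method: str) -> float:
        v = self.metrics[(source, method)]
        v = v[~np.isnan(v)]
        return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0

    def to_long_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_wide_frame(self) -> pd.DataFrame:
        """Table of per-source means with variance (x 10^3) columns."""
        rows = {}
        for s in self.sources:
            row = {}
            for m in self.methods:
                row[f"{m}_mean"] = self.mean(s, m)
                row[f"{m}_var_e3"] = self.variance(s, m) * 1e3
            rows[s] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation enumeration (midranks, symmetric-tail counting)
    when both samples have at most 10 observations; otherwise the normal
    approximation with tie correction.  Identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return float("nan")
    if n1 <= 10 and n2 <= 10:
        pooled = np.concatenate([x, y])
        ranks = rankdata(pooled, method="average")
        mu = n1 * (n1 + n2 + 1) / 2.0
        w_obs = float(ranks[:n1].sum())
        combos = np.array(
            list(itertools.combinations(range(n1 + n2), n1)), dtype=np.intp
        )
        w_all = ranks[combos].sum(axis=1)
        extreme = np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-9
        return float(extreme.sum() / len(w_all))
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def flag_winners(
    per_method_metrics: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[set[str], dict[str, float]]:
    """Winner set for one datasource: the top-mean method plus every
    method not significantly different from it (two-sided rank-sum,
    Bonferroni over the number of comparisons)."""
    means = {
        m: np.nanmean(v) if np.any(~np.isnan(np.asarray(v, dtype=float))) else -np.inf
        for m, v in per_method_metrics.items()
    }
    top = max(means, key=lambda m: means[m])
    others = [m for m in per_method_metrics if m != top]
    n_tests = max(1, len(others))
    winners = {top}
    pvalues: dict[str, float] = {top: 1.0}
    for m in others:
        a = np.asarray(per_method_metrics[top], dtype=float)
        b = np.asarray(per_method_metrics[m], dtype=float)
        ok = ~np.isnan(a) & ~np.isnan(b) if len(a) == len(b) else None
        if ok is not None:
            a, b = a[ok], b[ok]
        else:
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            pvalues[m] = float("nan")
            continue
        p = min(1.0, ranksum_pvalue(a, b) * n_tests)
        pvalues[m] = p
        if p > alpha:
            winners.add(m)
    return winners, pvalues


def aggregate_ranks(
    means: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-datasource method ranks (1 = best, average on ties) plus a
    five-number summary per method for boxplotting.

    ``means`` is a sources x methods table of mean metrics.
    """
    ranks = means.apply(
        lambda row: rankdata(-row.to_numpy(), method="average"), axis=1,
        result_type="expand",
    )
    ranks.columns = means.columns
    summary = pd.DataFrame(
        {
            "min": ranks.min(),
            "q1": ranks.quantile(0.25),
            "median": ranks.median(),
            "q3": ranks.quantile(0.75),
            "max": ranks.max(),
        }
    )
    return ranks, summary


def _metric_value(name: str, result) -> float:
    if name == "aupr":
        return aupr_top(result)
    if name == "auroc":
        return auroc_top(result)
    if name == "mean_precision":
        return mean_precision_top(result)
    raise ValueError(f"unknown metric {name!r}")


def run_benchmark(config: BenchmarkConfig, metric: str = "aupr") -> BenchmarkTable:
    """Full study: subsample, contaminate, infer, evaluate, tabulate.

    A method raising on a dataset is recorded as a missing value (NaN)
    with a logged error; the run continues.
    """
    sources = [ds.name for ds in config.datasources]
    metrics: dict = {}
    records: list[dict] = []
    for ds in config.datasources:
        n_exp = min(config.experiments_per_dataset, ds.expr.n_experiments)
        sub_seed = derive_seed(config.master_seed, ds.name, "subsample", n_exp)
        datasets = subsample(ds, n_exp, config.datasets_per_source, sub_seed)
        noisy = [
            add_noise(
                d,
                config.noise,
                np.random.default_rng(
                    derive_seed(config.master_seed, ds.name, "noise", k)
                ),
            )
            for k, d in enumerate(datasets)
        ]
        for m in config.methods:
            vals = np.full(len(noisy), np.nan)
            for k, d in enumerate(noisy):
                try:
                    sm = run_method(
                        m,
                        d.expr,
                        config.method_params,
                        seed=derive_seed(config.master_seed, ds.name, m, k),
                    )
                    res = evaluate(sm, ds.gold, config.eval_spec)
                    vals[k] = _metric_value(metric, res)
                except Exception:  # noqa: BLE001 - record and continue
                    log.exception(
                        "method %s failed on dataset %d of %s", m, k, ds.name
                    )
                records.append(
                    {
                        "datasource": ds.name,
                        "method": m,
                        "dataset": k,
                        "metric": f"{metric}_top",
                        "value": vals[k],
                    }
                )
            metrics[(ds.name, m)] = vals

    winners: dict = {}
    pvalues: dict = {}
    for s in sources:
        per_method = {m: metrics[(s, m)] for m in config.methods}
        w, p = flag_winners(per_method, config.alpha)
        winners[s] = w
        for m, pv in p.items():
            pvalues[(s, m)] = pv

    def _safe_mean(v: np.ndarray) -> float:
        v = v[~np.isnan(v)]
        return float(v.mean()) if len(v) else float("nan")

    means = pd.DataFrame(
        {
            m: [_safe_mean(metrics[(s, m)]) for s in sources]
            for m in config.methods
        },
        index=sources,
    )
    ranks, _ = aggregate_ranks(means)
    return BenchmarkTable(
        sources=sources,
        methods=list(config.methods),
        metrics=metrics,
        winners=winners,
        pvalues=pvalues,
        ranks=ranks,
        records=records,
    )


def noise_sweep(
    config: BenchmarkConfig,
    kappas: list[float] | None = None,
    metric: str = "aupr",
) -> dict[float, BenchmarkTable]:
    """Benchmark at increasing local-noise intensity.

    Only local (normal) noise is applied during the sweep; the subsample
    seeds do not depend on the noise level, so every level sees exactly
    the same experiment draws.
    """
    kappas = [0.0, 25.0, 50.0, 75.0, 100.0] if kappas is None else list(kappas)
    out: dict[float, BenchmarkTable] = {}
    for kappa in kappas:
        spec = replace(
            config.noise, kappa_local=float(kappa), kappa_global=0.0,
            local_type="normal",
        )
        out[float(kappa)] = run_benchmark(replace_config(config, noise=spec), metric)
    return out


def experiments_sweep(
    config: BenchmarkConfig,
    n_experiments_list: list[int] | None = None,
    metric: str = "aupr",
) -> dict[int, BenchmarkTable]:
    """Benchmark at increasing dataset size, with 20% local noise.

    A requested size larger than a datasource's experiment pool marks
    that datasource infeasible at that size (it is dropped from the
    grid's table); the sweep continues.
    """
    sizes = [20, 50, 200, 800] if n_experiments_list is None else list(n_experiments_list)
    noise = replace(
        config.noise, kappa_local=20.0, kappa_global=0.0, local_type="normal"
    )
    out: dict[int, BenchmarkTable] = {}
    for n in sizes:
        feasible = [ds for ds in config.datasources if ds.expr.n_experiments >= n]
        skipped = [ds.name for ds in config.datasources if ds.expr.n_experiments < n]
        if skipped:
            log.warning("n=%d infeasible for datasources %s; skipped", n, skipped)
        if not feasible:
            continue
        cfg = replace_config(
            config,
            datasources=feasible,
            experiments_per_dataset=int(n),
            noise=noise,
        )
        out[int(n)] = run_benchmark(cfg, metric)
    return out


def replace_config(config: BenchmarkConfig, **kwargs) -> BenchmarkConfig:
    return replace(config, **kwargs)
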