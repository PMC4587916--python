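"""Subsampling and controlled noise contamination.

A datasource is turned into many homogeneous datasets by (i) drawing
experiments without replacement and (ii) adding a mixture of "local" and
"global" noise:

* local noise — additive, zero mean, per-gene standard deviation
  ``sigma_g * U(0.8*kappa, 1.2*kappa) / 100`` where ``sigma_g`` is the
  gene's own standard deviation in the dataset, so every gene keeps a
  similar signal-to-noise ratio;
* global noise — additive, zero mean, one dataset-wide standard deviation
  ``mean(sigma_g) * U(0.8*kappa_g, 1.2*kappa_g) / 100`` shared by all
  genes.

Either component may be drawn from a normal or a (mean-centred) lognormal
distribution.  The uniform band of width 40% around kappa gives replicate
datasets slightly different signal-to-noise ratios, emulating batch
variability between laboratories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Dataset, Datasource, ExpressionMatrix, ParameterError

__all__ = ["NoiseSpec", "subsample", "local_noise_sd", "global_noise_sd", "add_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise intensities in percent of the (per-gene or mean) std.

    ``range_fraction`` is the half-width of the uniform band as a fraction
    of kappa: the default 0.2 draws the realized intensity from
    ``U(0.8*kappa, 1.2*kappa)``.  ``lognormal_shape`` is the sigma of the
    underlying normal for lognormal noise (scale is set from the target
    std; the draw is shifted to zero mean).
    """

    kappa_local: float = 0.0
    kappa_global: float = 0.0
    range_fraction: float = 0.2
    local_type: str = "normal"
    global_type: str = "lognormal"
    lognormal_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa_local < 0 or self.kappa_global < 0:
            raise ParameterError("noise percentages must be >= 0")
        if not 0 <= self.range_fraction < 1:
            raise ParameterError("range_fraction must lie in [0, 1)")
        for t in (self.local_type, self.global_type):
            if t not in ("normal", "lognormal"):
                raise ParameterError(f"unknown noise type {t!r}")


def subsample(
    ds: Datasource,
    n_experiments: int,
    n_datasets: int,
    seed: int,
) -> list[Dataset]:
    """Draw ``n_datasets`` datasets of ``n_experiments`` distinct rows each.

    Rows are drawn without replacement within a dataset; the same row may
    appear in different datasets.  Deterministic given ``seed``.
    """
    n = ds.expr.n_experiments
    if n_experiments > n:
        raise ParameterError(
            f"cannot draw {n_experiments} experiments from a datasource of {n}"
        )
    if n_experiments < 1 or n_datasets < 1:
        raise ParameterError("n_experiments and n_datasets must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for d in range(n_datasets):
        idx = rng.choice(n, size=n_experiments, replace=False)
        expr = ExpressionMatrix(
            values=ds.expr.values[idx].copy(),
            gene_ids=list(ds.expr.gene_ids),
            experiment_ids=[ds.expr.experiment_ids[i] for i in idx],
        )
        out.append(
            Dataset(
                expr=expr,
                source_name=ds.name,
                experiment_indices=idx,
                noise=None,
                seed=seed,
            )
        )
    return out


def _realized_kappa(kappa: float, range_fraction: float, rng, size=None) -> np.ndarray:
    lo = kappa * (1.0 - range_fraction)
    hi = kappa * (1.0 + range_fraction)
    return rng.uniform(lo, hi, size=size)


def local_noise_sd(
    sigma_g: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    range_fraction: float = 0.2,
) -> np.ndarray:
    """Per-gene noise std ``sigma_g * U((1-f)k, (1+f)k) / 100``.

    One independent uniform draw per gene; a constant gene (sigma 0) gets
    noise std 0 and passes through unchanged.
    """
    sigma_g = np.asarray(sigma_g, dtype=float)
    if np.any(sigma_g < 0):
        raise ParameterError("per-gene std must be >= 0")
    if kappa < 0:
        raise ParameterError("kappa must be >= 0")
    u = _realized_kappa(kappa, range_fraction, rng, size=sigma_g.shape)
    return sigma_g * u / 100.0


def global_noise_sd(
    sigma_g: np.ndarray,
    kappa_g: float,
    rng: np.random.Generator,
    range_fraction: float = 0.2,
) -> float:
    """Single dataset-wide noise std ``mean(sigma_g) * U((1-f)k, (1+f)k) / 100``."""
    if kappa_g < 0:
        raise ParameterError("kappa_g must be >= 0")
    sigma_bar = float(np.mean(np.asarray(sigma_g, dtype=float)))
    u = float(_realized_kappa(kappa_g, range_fraction, rng))
    return sigma_bar * u / 100.0


def _noise_draw(
    shape: tuple[int, ...],
    std: np.ndarray | float,
    kind: str,
    rng: np.random.Generator,
    lognormal_shape: float,
) -> np.ndarray:
    """Zero-mean noise with the requested elementwise std.

    Lognormal noise is ``scale * exp(s*Z)`` shifted by its mean; the scale
    is set so the shifted draw has the target std.
    """
    if kind == "normal":
        return rng.standard_normal(shape) * std
    s = lognormal_shape
    raw = np.exp(s * rng.standard_normal(shape))
    raw_std = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    scale = std / raw_std
    return scale * (raw - np.exp(0.5 * s * s))


def add_noise(
    dataset: Dataset,
    spec: NoiseSpec,
    rng: np.random.Generator | int,
) -> Dataset:
    """Contaminate a dataset with local + global noise per ``spec``.

    Per-gene stds are computed on the rows actually present in the dataset.
    With both kappas zero the output equals the input bitwise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    values = dataset.expr.values
    if spec.kappa_local == 0 and spec.kappa_global == 0:
        noisy = values.copy()
    else:
        noisy = values.copy()
        sigma_g = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(
            values.shape[1]
        )
        if spec.kappa_local > 0:
            sd_local = local_noise_sd(
                sigma_g, spec.kappa_local, rng, spec.range_fraction
            )
            noisy = noisy + _noise_draw(
                values.shape, sd_local, spec.local_type, rng, spec.lognormal_shape
            )
        if spec.kappa_global > 0:
            sd_global = global_noise_sd(
                sigma_g, spec.kappa_global, rng, spec.range_fraction
            )
            noisy = noisy + _noise_draw(
                values.shape, sd_global, spec.global_type, rng, spec.lognormal_shape
            )
    expr = ExpressionMatrix(
        values=noisy,
        gene_ids=list(dataset.expr.gene_ids),
        experiment_ids=list(dataset.expr.experiment_ids),
    )
    return Dataset(
        expr=expr,
        source_name=dataset.source_name,
        experiment_indices=dataset.experiment_indices.copy(),
        noise=spec,
        seed=dataset.seed,
    )
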