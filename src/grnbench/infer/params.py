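"""Per-method tuning knobs with documented defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class MethodParams:
    """Knobs shared by the inference method registry.

    mi_bins
        Bin count for MI discretization; ``None`` means ``ceil(sqrt(N))``.
    aracne_eps
        DPI tolerance; an edge (i, j) is removed when
        ``M_ij < min(M_ik, M_jk) - eps`` in some triplet.  0 is strict DPI.
    c3net_alpha / c3net_permutations
        Significance level and number of column-permutation null draws for
        the C3NET significance filter.
    genie3_trees / genie3_max_features
        Forest size (500 by default) and features tried per split
        (``None`` means ``sqrt(G - 1)``).
    zscore_min_detection
        Detect the knocked-out gene of each experiment as the minimum of
        the experiment's row (the generalization that makes the method
        applicable without intervention labels).
    mrnetb_max_swaps
        Cap on sequential-replacement swaps per target.
    """

    mi_bins: int | None = None
    aracne_eps: float = 0.0
    c3net_alpha: float = 0.05
    c3net_permutations: int = 100
    genie3_trees: int = 500
    genie3_max_features: int | None = None
    zscore_min_detection: bool = True
    mrnetb_max_swaps: int = 200
    genenet_min_shrinkage: float = 1e-6

    def to_dict(self) -> dict:
        return asdict(self)
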