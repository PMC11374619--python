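"""Robustness protocol: rank correlations across stage variants, partition
agreement, and year-over-year achievement decomposition.

The core question is whether the final ranking is an artifact of one
methodological choice.  Each check holds two pipeline stages fixed and swaps
the third (normalization, weighting or aggregation), then compares the
resulting rankings with Spearman's rank correlation.  Groupings are compared
with the adjusted Rand index (ARI), which is 1 exactly for identical
partitions and near 0 for chance agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DecisionMatrix, PipelineConfig

_AXIS_VARIANTS = {
    "normalization": ("minmax", "vector", "zscore"),
    "weighting": ("entropy", "critic", "std"),
    "aggregation": ("promethee2", "topsis", "rsr"),
}


@dataclass
class VariantGrid:
    """One robustness axis (which stage to vary) and its variants."""

    axis: str
    variants: list[str]

    def __post_init__(self) -> None:
        if self.axis not in _AXIS_VARIANTS:
            raise ValueError(f"unknown axis {self.axis!r}")
        if not self.variants:
            raise ValueError("variants must be non-empty")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variants must be distinct")
        unknown = set(self.variants) - set(_AXIS_VARIANTS[self.axis])
        if unknown:
            raise ValueError(f"unknown {self.axis} variants: {sorted(unknown)}")

    @classmethod
    def full(cls, axis: str) -> "VariantGrid":
        return cls(axis=axis, variants=list(_AXIS_VARIANTS[axis]))


def spearman_rho(ranks_a, ranks_b) -> float:
    """Spearman rank correlation with midrank tie handling."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("rankings must cover the same alternatives")
    if a.size < 2:
        raise ValueError("need at least 2 alternatives")
    return float(stats.spearmanr(a, b).statistic)


def robustness_matrix(R: DecisionMatrix, grid: VariantGrid,
                      cfg: PipelineConfig) -> pd.DataFrame:
    """Pairwise Spearman table of rankings across one stage's variants.

    Runs the pipeline once per variant with the other two stages held at
    ``cfg``; the result is a symmetric DataFrame with unit diagonal indexed
    by variant name.
    """
    from .pipeline import run_pipeline  # local import to avoid a cycle

    rankings = {}
    for variant in grid.variants:
        try:
            result = run_pipeline(R, cfg.with_stage(grid.axis, variant))
        except Exception as exc:
            raise RuntimeError(
                f"robustness run failed for {grid.axis}={variant}: {exc}"
            ) from exc
        rankings[variant] = result.ranks
    table = pd.DataFrame(1.0, index=grid.variants, columns=grid.variants)
    for i, va in enumerate(grid.variants):
        for vb in grid.variants[i + 1:]:
            rho = spearman_rho(rankings[va], rankings[vb])
            table.loc[va, vb] = rho
            table.loc[vb, va] = rho
    return table


def grouping_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions of the same alternatives.

    1 iff the partitions are identical (up to label names); 0 expected for
    independent random partitions.  Defined as 1 when both partitions are
    degenerate in the same way (denominator zero).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same alternatives")
    n = a.size
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    contingency = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(contingency, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def decompose_changes(R_t1: DecisionMatrix,
                      R_t2: DecisionMatrix) -> pd.DataFrame:
    """Per-cell signed achievement change between two labeled matrices.

    The raw difference r_t2 - r_t1 is negated for cost indicators so that a
    positive entry always means an improvement.  Rows are alternatives,
    columns indicator ids.
    """
    if R_t1.alternatives != R_t2.alternatives:
        raise ValueError("matrices must share the same alternatives")
    if R_t1.indicator_ids != R_t2.indicator_ids:
        raise ValueError("matrices must share the same indicators")
    if [s.direction for s in R_t1.indicators] != \
            [s.direction for s in R_t2.indicators]:
        raise ValueError("indicator directions differ between matrices")
    delta = R_t2.values - R_t1.values
    sign = np.where(R_t1.cost_mask(), -1.0, 1.0)
    return pd.DataFrame(delta * sign, index=R_t1.alternatives,
                        columns=R_t1.indicator_ids)
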