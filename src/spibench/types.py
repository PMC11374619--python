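"""Domain types shared across the pipeline.

The central object is the :class:`DecisionMatrix`: ``m`` alternatives (rows,
e.g. countries) scored on ``n`` indicators (columns) in their native units.
Every indicator carries a direction — ``benefit`` (larger is better, e.g.
seat-belt use rate) or ``cost`` (smaller is better, e.g. fatalities per
100,000 inhabitants) — and one of three hierarchy categories (``product``,
``people``, ``system``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("product", "people", "system")
DIRECTIONS = ("benefit", "cost")
NORMALIZATIONS = ("minmax", "vector", "zscore")
WEIGHTINGS = ("entropy", "critic", "std")
AGGREGATIONS = ("promethee2", "topsis", "rsr")


@dataclass(frozen=True)
class IndicatorSpec:
    """One safety performance indicator: id, label, hierarchy category, direction."""

    id: str
    name: str = ""
    category: str = "system"
    direction: str = "benefit"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("indicator id must be a non-empty string")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"indicator {self.id!r}: category must be one of {CATEGORIES}, "
                f"got {self.category!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"indicator {self.id!r}: direction must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class DecisionMatrix:
    """Raw m x n panel of indicator values in native units."""

    alternatives: list[str]
    indicators: list[IndicatorSpec]
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = len(self.alternatives), len(self.indicators)
        if m < 2:
            raise ValueError(f"need at least 2 alternatives, got {m}")
        if n < 1:
            raise ValueError("need at least 1 indicator")
        if self.values.shape != (m, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{m} alternatives x {n} indicators"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at alternative {self.alternatives[i]!r}, "
                f"indicator {self.indicators[j].id!r}"
            )
        _check_unique(self.alternatives, "alternative")
        _check_unique([s.id for s in self.indicators], "indicator")

    @property
    def m(self) -> int:
        return len(self.alternatives)

    @property
    def n(self) -> int:
        return len(self.indicators)

    @property
    def indicator_ids(self) -> list[str]:
        return [s.id for s in self.indicators]

    def cost_mask(self) -> np.ndarray:
        """Boolean mask over columns, True where the indicator is a cost."""
        return np.array([s.direction == "cost" for s in self.indicators])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alternatives,
                            columns=self.indicator_ids)


@dataclass
class NormalizedMatrix:
    """Direction-folded, unit-free matrix: larger is always better."""

    values: np.ndarray
    method: str
    alternatives: list[str]
    indicators: list[IndicatorSpec]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization method {self.method!r}")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightVector:
    """Non-negative criterion weights summing to one."""

    weights: np.ndarray
    method: str
    entropies: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        s = float(self.weights.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {s}")


@dataclass
class PreferenceMatrix:
    """Pairwise aggregated preference index Pi(a_i, a_k), zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("preference matrix must be square")


@dataclass
class FlowTriple:
    """Leaving (Phi+), entering (Phi-) and net (Phi) outranking flows."""

    leaving: np.ndarray
    entering: np.ndarray
    net: np.ndarray


@dataclass
class RankingTable:
    """Scores plus competition ranks (1 = best; ties share the smallest rank)."""

    alternatives: list[str]
    scores: np.ndarray
    ranks: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        """Rows ordered by rank then lexicographic alternative id."""
        df = pd.DataFrame({
            "alternative": self.alternatives,
            "score": np.asarray(self.scores, dtype=float),
            "rank": np.asarray(self.ranks, dtype=int),
            "method": self.method,
        })
        return df.sort_values(["rank", "alternative"]).reset_index(drop=True)


@dataclass
class DistanceMatrix:
    """Euclidean pairwise distances between alternatives."""

    values: np.ndarray
    metric: str = "euclidean"


@dataclass
class GridSearchReport:
    eps_best: Optional[float]
    minpts_best: Optional[int]
    silhouette_best: Optional[float]
    n_valid_combos: int
    n_total_combos: int


@dataclass
class ClusterResult:
    """Final grouping into exactly K groups with a best-in-class per group.

    ``labels`` are group ids in 1..K (group 1 holds the top scorer);
    ``source`` records whether the grid-searched density clustering was
    adopted or the small-sample two-round merge decided the partition.
    """

    labels: np.ndarray
    source: str
    report: GridSearchReport
    benchmarks: dict[int, str]


@dataclass
class PipelineConfig:
    """Stage choices and clustering grid for one end-to-end evaluation.

    Defaults reproduce the primary configuration: min-max normalization,
    entropy weighting, PROMETHEE II aggregation, an epsilon grid of
    1e-6..0.01 in steps of 1e-6, minPts 2..10 and three target groups.
    """

    normalization: str = "minmax"
    weighting: str = "entropy"
    aggregation: str = "promethee2"
    eps_start: float = 1e-6
    eps_stop: float = 0.01
    eps_step: float = 1e-6
    minpts_min: int = 2
    minpts_max: int = 10
    target_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if not (self.eps_start > 0 and self.eps_step > 0):
            raise ValueError("eps_start and eps_step must be positive")
        if self.eps_start > self.eps_stop:
            raise ValueError("eps_start must not exceed eps_stop")
        if not (2 <= self.minpts_min <= self.minpts_max):
            raise ValueError("need 2 <= minpts_min <= minpts_max")
        if self.target_k < 1:
            raise ValueError("target_k must be >= 1")

    def eps_grid(self) -> np.ndarray:
        count = int(math.floor((self.eps_stop - self.eps_start) / self.eps_step + 1e-9)) + 1
        return self.eps_start + self.eps_step * np.arange(count)

    def minpts_grid(self) -> range:
        return range(self.minpts_min, self.minpts_max + 1)

    def with_stage(self, axis: str, variant: str) -> "PipelineConfig":
        """Copy of this config with one stage (normalization/weighting/aggregation) swapped."""
        if axis not in ("normalization", "weighting", "aggregation"):
            raise ValueError(f"unknown stage axis {axis!r}")
        return replace(self, **{axis: variant})


@dataclass
class EvaluationResult:
    """End-to-end output: weights, flows, scores, ranks and the grouping."""

    alternatives: list[str]
    weights: WeightVector
    flows: Optional[FlowTriple]
    scores: np.ndarray
    ranks: np.ndarray
    clusters: ClusterResult
    config: PipelineConfig
    metadata: dict = field(default_factory=dict)

    def ranking(self) -> RankingTable:
        return RankingTable(self.alternatives, self.scores, self.ranks,
                            self.config.aggregation)

    def to_frame(self) -> pd.DataFrame:
        """Per-alternative result table: score, rank, group, benchmark flag."""
        bench_ids = set(self.clusters.benchmarks.values())
        df = pd.DataFrame({
            "alternative": self.alternatives,
            "score": np.asarray(self.scores, dtype=float),
            "rank": np.asarray(self.ranks, dtype=int),
            "group": np.asarray(self.clusters.labels, dtype=int),
            "is_benchmark": [a in bench_ids for a in self.alternatives],
        })
        return df.sort_values(["rank", "alternative"]).reset_index(drop=True)
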