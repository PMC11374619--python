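"""End-to-end pipeline: normalize -> weight -> aggregate -> cluster -> benchmark.

The stages are pure functions over in-memory types; this module wires them
together in the configured order, logs each stage, and attaches the failing
stage's name to any propagated error.  Clustering always consumes the
normalized *unweighted* matrix: weights shape the ranking, while the
grouping reflects raw similarity between alternatives.
"""

from __future__ import annotations

import logging

import numpy as np

from .aggregate import promethee_scores, rank_alternatives, rsr_scores, topsis_scores
from .cluster import cluster_alternatives
from .normalize import normalize
from .types import (DecisionMatrix, EvaluationResult, NormalizedMatrix,
                    PipelineConfig)
from .weighting import entropy_weights, variant_weights

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure wrapper carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _shift_nonnegative(X: NormalizedMatrix) -> NormalizedMatrix:
    """Columns containing negative entries are shifted to a zero minimum.

    Entropy weights are undefined on negative values; z-score (and, for
    negative raw data, vector) normalization can produce them.  The shift
    preserves each column's spread while making the entropy proportions
    well defined, and is logged when applied.
    """
    V = X.values
    col_min = V.min(axis=0)
    if np.all(col_min >= 0):
        return X
    shifted = V - np.minimum(col_min, 0.0)
    logger.info("entropy stage: shifted %d column(s) with negative values "
                "to a zero minimum", int((col_min < 0).sum()))
    return NormalizedMatrix(values=shifted, method=X.method,
                            alternatives=X.alternatives,
                            indicators=X.indicators, provenance=X.provenance)


def run_pipeline(R: DecisionMatrix, cfg: PipelineConfig) -> EvaluationResult:
    """Execute the full evaluation for one decision matrix.

    Deterministic for a fixed config and input; the only randomness in the
    package lives in the synthetic generator.
    """
    logger.info("pipeline start: %d alternatives x %d indicators (%s)",
                R.m, R.n, R.label or "unlabeled")

    try:
        X = normalize(R, cfg.normalization)
        logger.info("normalize[%s]: value range [%.4g, %.4g]",
                    cfg.normalization, X.values.min(), X.values.max())
    except Exception as exc:
        raise PipelineError("normalize", exc) from exc

    try:
        if cfg.weighting == "entropy":
            w = entropy_weights(_shift_nonnegative(X))
        else:
            w = variant_weights(X, cfg.weighting)
        logger.info("weighting[%s]: max weight %.4f on %s", cfg.weighting,
                    w.weights.max(),
                    R.indicators[int(np.argmax(w.weights))].id)
    except Exception as exc:
        raise PipelineError("weighting", exc) from exc

    try:
        flows = None
        if cfg.aggregation == "promethee2":
            flows, table = promethee_scores(X, w)
        elif cfg.aggregation == "topsis":
            table = topsis_scores(X, w)
        else:
            table = rsr_scores(X, w)
        logger.info("aggregation[%s]: score range [%.4g, %.4g]",
                    cfg.aggregation, table.scores.min(), table.scores.max())
    except Exception as exc:
        raise PipelineError("aggregation", exc) from exc

    try:
        clusters = cluster_alternatives(X, table.scores, cfg)
    except Exception as exc:
        raise PipelineError("clustering", exc) from exc

    return EvaluationResult(alternatives=list(R.alternatives), weights=w,
                            flows=flows, scores=table.scores,
                            ranks=table.ranks, clusters=clusters, config=cfg,
                            metadata={"label": R.label,
                                      "normalization": cfg.normalization,
                                      "weighting": cfg.weighting,
                                      "aggregation": cfg.aggregation})


__all__ = ["PipelineError", "run_pipeline", "rank_alternatives"]
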