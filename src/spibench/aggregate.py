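"""Score aggregation and ranking.

Primary aggregator: PROMETHEE II with the usual-criterion preference
function (no indifference/preference thresholds).  For alternatives a_i, a_k
and weights w_j on a direction-folded matrix X:

    P_j(a_i, a_k) = max(x_ij - x_kj, 0)
    Pi(a_i, a_k)  = sum_j w_j P_j(a_i, a_k)
    Phi+(a_i) = sum_k Pi(a_i, a_k),  Phi-(a_i) = sum_k Pi(a_k, a_i)
    Phi(a_i)  = Phi+(a_i) - Phi-(a_i)

Flows are plain sums over the other alternatives (no division by m-1), so
net flows over all alternatives sum to zero exactly.  A higher net flow
means better overall performance.

TOPSIS (closeness to the ideal point) and RSR (weighted rank-sum ratio) are
provided as robustness variants.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .types import (FlowTriple, NormalizedMatrix, PreferenceMatrix,
                    RankingTable, WeightVector)


def preference_degree(d: float) -> float:
    """Usual-criterion preference: 0 for d <= 0, else d itself."""
    return float(d) if d > 0 else 0.0


def preference_index_matrix(X: NormalizedMatrix,
                            w: WeightVector) -> PreferenceMatrix:
    """Weighted pairwise preference indices Pi(a_i, a_k)."""
    V = np.asarray(X.values, dtype=float)
    weights = np.asarray(w.weights, dtype=float)
    if V.shape[1] != weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: {V.shape[1]} indicators vs "
            f"{weights.shape[0]} weights")
    diff = V[:, None, :] - V[None, :, :]
    P = np.maximum(diff, 0.0)
    return PreferenceMatrix(values=P @ weights)


def outranking_flows(P: PreferenceMatrix) -> FlowTriple:
    """Leaving, entering and net flows from a preference-index matrix."""
    Pi = np.asarray(P.values, dtype=float)
    leaving = Pi.sum(axis=1)
    entering = Pi.sum(axis=0)
    return FlowTriple(leaving=leaving, entering=entering,
                      net=leaving - entering)


def rank_alternatives(scores: np.ndarray, alternatives: list[str],
                      method: str = "promethee2") -> RankingTable:
    """Competition ranking by descending score (ties share the smallest rank)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    ranks = rankdata(-scores, method="min").astype(int)
    return RankingTable(alternatives=list(alternatives), scores=scores,
                        ranks=ranks, method=method)


def promethee_scores(X: NormalizedMatrix, w: WeightVector
                     ) -> tuple[FlowTriple, RankingTable]:
    """Full PROMETHEE II pass: preference indices -> flows -> ranking."""
    flows = outranking_flows(preference_index_matrix(X, w))
    table = rank_alternatives(flows.net, X.alternatives, "promethee2")
    return flows, table


def topsis_scores(X: NormalizedMatrix, w: WeightVector) -> RankingTable:
    """Closeness coefficient C_i = d- / (d+ + d-) to the weighted ideal point.

    Direction is assumed already folded into X.  If all alternatives are
    identical the coefficient is conventionally 0.5 for everyone.
    """
    V = np.asarray(X.values, dtype=float) * np.asarray(w.weights, dtype=float)
    ideal = V.max(axis=0)
    anti = V.min(axis=0)
    d_plus = np.sqrt(((V - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    C = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 0.5)
    return rank_alternatives(C, X.alternatives, "topsis")


def rsr_scores(X: NormalizedMatrix, w: WeightVector) -> RankingTable:
    """Weighted rank-sum ratio: RSR_i = sum_j w_j R_ij / m.

    R_ij is the within-column midrank with rank m for the best (largest)
    value, so an alternative that is best on every criterion scores 1.
    """
    V = np.asarray(X.values, dtype=float)
    m = V.shape[0]
    if m < 2:
        raise ValueError("rank-sum ratio needs at least 2 alternatives")
    R = np.column_stack([rankdata(V[:, j], method="average")
                         for j in range(V.shape[1])])
    rsr = (R @ np.asarray(w.weights, dtype=float)) / m
    return rank_alternatives(rsr, X.alternatives, "rsr")
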