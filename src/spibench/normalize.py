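"""Direction-aware normalization of a decision matrix.

All three methods fold the indicator direction into the output so that a
larger normalized value always means better performance:

* ``minmax``  — benefit: (r - min)/(max - min); cost: (max - r)/(max - min).
  Output lies in [0, 1] and each non-constant column attains both endpoints.
* ``vector``  — benefit: r / ||r||_2 (column norm); cost: 1 - r / ||r||_2.
* ``zscore``  — (r - mean)/sd with the sample (n-1) standard deviation,
  negated for cost columns.

A constant column carries no discriminating information; under every method
it maps to all zeros (with a logged warning) and the weighting stage will
assign it weight zero.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import DecisionMatrix, NormalizedMatrix

logger = logging.getLogger(__name__)


def normalize(R: DecisionMatrix, method: str = "minmax") -> NormalizedMatrix:
    """Normalize ``R`` with the given method, folding cost directions.

    Raises ``ValueError`` for an unknown method or non-finite input.
    """
    if method not in ("minmax", "vector", "zscore"):
        raise ValueError(f"unknown normalization method {method!r}")
    V = np.asarray(R.values, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("decision matrix contains non-finite values")
    cost = R.cost_mask()
    X = np.zeros_like(V)

    col_min = V.min(axis=0)
    col_max = V.max(axis=0)
    constant = col_max == col_min
    if np.any(constant):
        ids = [R.indicators[j].id for j in np.flatnonzero(constant)]
        logger.warning("constant column(s) %s mapped to zeros under %s",
                       ids, method)

    live = ~constant
    if method == "minmax":
        rng = np.where(live, col_max - col_min, 1.0)
        X = np.where(cost, (col_max - V) / rng, (V - col_min) / rng)
    elif method == "vector":
        norm = np.sqrt((V ** 2).sum(axis=0))
        zero_norm = norm == 0.0
        live = live & ~zero_norm
        safe = np.where(norm == 0.0, 1.0, norm)
        frac = V / safe
        X = np.where(cost, 1.0 - frac, frac)
    else:  # zscore
        mean = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1)
        safe = np.where(live, sd, 1.0)
        Z = (V - mean) / safe
        X = np.where(cost, -Z, Z)

    X[:, ~live] = 0.0
    return NormalizedMatrix(values=X, method=method,
                            alternatives=list(R.alternatives),
                            indicators=list(R.indicators),
                            provenance=R.label)
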