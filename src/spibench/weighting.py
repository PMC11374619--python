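"""Objective criterion weights.

The primary scheme is the entropy weight method (EWM): indicators whose
value distribution across alternatives is farther from uniform have lower
Shannon entropy and are considered more informative, so they receive more
weight.  Two variants are provided for robustness checks:

* ``std``    — weight proportional to the column's sample standard deviation;
* ``critic`` — weight proportional to sigma_j * sum_k (1 - rho_jk), combining
  contrast intensity (standard deviation) with decorrelation from the other
  criteria (Pearson rho).
"""

from __future__ import annotations

import numpy as np

from .types import NormalizedMatrix, WeightVector


def entropy_weights(X: NormalizedMatrix) -> WeightVector:
    """Entropy weights from a non-negative normalized matrix.

    For column j: p_ij = x_ij / sum_i x_ij, e_j = -(1/ln m) sum_i p_ij ln p_ij
    with 0*ln 0 := 0, and w_j = (1 - e_j) / sum_j (1 - e_j).  An all-zero
    column gets e_j = 1 and weight 0.

    Raises ``ValueError`` on negative entries (entropy undefined) or when
    every column is constant ("no informative indicator").
    """
    V = np.asarray(X.values, dtype=float)
    m, n = V.shape
    if m < 2:
        raise ValueError("entropy weights need at least 2 alternatives")
    if np.any(V < 0):
        raise ValueError("entropy weights are undefined for negative values; "
                         "normalize to a non-negative scale first")
    col_sum = V.sum(axis=0)
    e = np.ones(n)
    for j in np.flatnonzero(col_sum > 0):
        p = V[:, j] / col_sum[j]
        nz = p > 0
        e[j] = -(p[nz] @ np.log(p[nz])) / np.log(m)
    e = np.clip(e, 0.0, 1.0)
    d = 1.0 - e
    total = d.sum()
    if total <= 0:
        raise ValueError("no informative indicator: all columns are constant")
    return WeightVector(weights=d / total, method="entropy", entropies=e)


def variant_weights(X: NormalizedMatrix, method: str) -> WeightVector:
    """Standard-deviation or CRITIC weights (robustness variants).

    Constant columns receive weight zero; Pearson correlation with a
    constant column is defined as zero.  CRITIC needs m >= 3 alternatives.
    """
    if method not in ("std", "critic"):
        raise ValueError(f"unknown weighting variant {method!r}")
    V = np.asarray(X.values, dtype=float)
    m, n = V.shape
    sd = V.std(axis=0, ddof=1)
    if method == "std":
        total = sd.sum()
        if total <= 0:
            raise ValueError("no informative indicator: all columns are constant")
        return WeightVector(weights=sd / total, method="std")

    if m < 3:
        raise ValueError("CRITIC weights need at least 3 alternatives")
    live = sd > 0
    rho = np.zeros((n, n))
    idx = np.flatnonzero(live)
    if idx.size >= 2:
        rho[np.ix_(idx, idx)] = np.corrcoef(V[:, idx], rowvar=False)
    elif idx.size == 1:
        rho[idx[0], idx[0]] = 1.0
    # information content: contrast * decorrelation from all other criteria
    info = sd * (1.0 - rho).sum(axis=1)
    info[~live] = 0.0
    total = info.sum()
    if total <= 0:
        raise ValueError("no informative indicator: all columns are constant")
    return WeightVector(weights=info / total, method="critic")
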