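import numpy as np
import pytest

from spibench import DecisionMatrix, IndicatorSpec, NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240822)


def make_matrix(values, directions=None, label=""):
    """Build a DecisionMatrix from a plain array and per-column directions."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    directions = directions or ["benefit"] * n
    indicators = [IndicatorSpec(id=f"c{j + 1}", direction=directions[j])
                  for j in range(n)]
    return DecisionMatrix(alternatives=[f"a{i + 1}" for i in range(m)],
                          indicators=indicators, values=values, label=label)


def make_normalized(values, method="minmax"):
    """Wrap a plain array as a NormalizedMatrix (already direction-folded)."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return NormalizedMatrix(
        values=values, method=method,
        alternatives=[f"a{i + 1}" for i in range(m)],
        indicators=[IndicatorSpec(id=f"c{j + 1}") for j in range(n)])
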