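"""Decompose achievement differences between two time points.

Generates the same panel at two 'years' (second year = first plus drift),
then breaks the overall change down per alternative and indicator.  Cost
indicators are sign-flipped so a positive entry always reads as an
improvement, which lets a policymaker see which indicators drove a rise or
fall in the composite ranking.
"""

import numpy as np

from spibench import SyntheticSpec, decompose_changes, generate_decision_matrix
from spibench.types import DecisionMatrix

R1, _, _ = generate_decision_matrix(SyntheticSpec(seed=1))
rng = np.random.default_rng(2)

# year 2: alternative A01 improves, A11 deteriorates, others drift mildly
drift = rng.normal(0.0, 0.01, size=R1.values.shape) * np.abs(R1.values)
cost = R1.cost_mask()
direction = np.where(cost, -1.0, 1.0)
drift[0] += 0.05 * np.abs(R1.values[0]) * direction
drift[10] -= 0.05 * np.abs(R1.values[10]) * direction
R2 = DecisionMatrix(alternatives=R1.alternatives, indicators=R1.indicators,
                    values=R1.values + drift, label="year 2")

delta = decompose_changes(R1, R2)
net = delta.sum(axis=1).sort_values(ascending=False)
print("net signed achievement change per alternative (positive = improved):")
print(net.round(2).to_string())
print()
worst = delta.loc["A11"].sort_values()
print("A11's three most deteriorated indicators:")
print(worst.head(3).round(2).to_string())
print()
print("Every cell is the raw change with cost indicators negated, so "
      "positive means progress; swapping the two years negates the table.")
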