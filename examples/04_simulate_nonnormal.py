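"""Simulate correlated non-normal variables with exact moment targets.

The Fleishman power method writes a non-normal variable as a cubic
polynomial of a standard normal; the Vale-Maurelli extension draws the
underlying normals with adjusted ("intermediate") correlations so the
transformed variables hit the requested correlations too. Here: a skewed
glucose-like variable and a milder HDL-like one, correlated at -0.3.
"""

import numpy as np

from detanon import (
    MomentSpec,
    fleishman_coefficients,
    intermediate_correlation,
    simulate_nonnormal,
)
from scipy import stats

specs = [
    MomentSpec("glucose", mean=5.4, sd=0.9, skewness=1.5, kurtosis=4.0),
    MomentSpec("hdl", mean=1.5, sd=0.4, skewness=0.8, kurtosis=1.0),
]
rho = np.array([[1.0, -0.3], [-0.3, 1.0]])

c0 = fleishman_coefficients(specs[0].skewness, specs[0].kurtosis)
c1 = fleishman_coefficients(specs[1].skewness, specs[1].kurtosis)
print(f"glucose polynomial coefficients (a,b,c,d): "
      f"({c0.a:.4f}, {c0.b:.4f}, {c0.c:.4f}, {c0.d:.4f})")
print(f"intermediate correlation for target -0.3: "
      f"{intermediate_correlation(-0.3, c0, c1):.4f}")

X = simulate_nonnormal(specs, rho, n=200_000, seed=1)
for j, spec in enumerate(specs):
    col = X[:, j]
    print(f"{spec.name}: mean {col.mean():.3f} (target {spec.mean}), "
          f"sd {col.std(ddof=1):.3f} (target {spec.sd}), "
          f"skew {stats.skew(col):.3f} (target {spec.skewness}), "
          f"ex.kurt {stats.kurtosis(col):.3f} (target {spec.kurtosis})")
print(f"sample correlation: {np.corrcoef(X.T)[0, 1]:.3f} (target -0.3)")
print("\nLarge-sample moments land on the targets: the generator reproduces "
      "skewed biomarker-like data without access to any real records.")
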