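"""Rank the morphometric determinants of condition separation.

Builds a feature matrix with a single strongly discriminative feature
planted among noise, fits the seeded gradient-boosted classifier and ranks
features by exact interventional tree-Shapley attribution magnitude.
"""

import numpy as np
import pandas as pd

from fibromorph import FEATURE_NAMES, rank_features_shap

rng = np.random.default_rng(0)
n = 60
X = rng.normal(size=(2 * n, 12))
X[n:, 7] += 3.0  # plant a 3-SD shift in one feature for the second condition
df = pd.DataFrame(X, columns=FEATURE_NAMES[:12])
df.insert(0, "condition", ["control"] * n + ["patterned"] * n)

report = rank_features_shap(df, control="control", seed=0)
print("cross-validated accuracy:",
      {k: round(v, 3) for k, v in report.accuracy.items()},
      "(chance %.2f)" % list(report.chance.values())[0])
print("ranking reliable:", report.reliable)
print("\ntop 5 features by mean |phi| (log-odds units):")
print(report.importance.head(5).round(4).to_string())
print(f"\nthe planted feature was {FEATURE_NAMES[7]!r}; it should rank first")
print("with an attribution far above the noise features.")
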