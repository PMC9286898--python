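"""Rank descriptors that separate candidate actives from the background.

Builds a labeled feature matrix with two informative descriptors planted
among noise, runs linear-SVM recursive feature elimination (F_i = w_i^2,
remove the smallest each round), and summarizes the ranking by category.
"""

import numpy as np
import pandas as pd

from cdrscreen import categorize_features, select_top_k, svm_rfe

rng = np.random.default_rng(0)
n = 200
labels = rng.integers(0, 2, n)  # 1 = candidate active, 0 = background
data = pd.DataFrame({
    "logp":  rng.standard_normal(n) + 2.0 * labels,   # informative (ADME)
    "tpsa":  rng.standard_normal(n) - 1.5 * labels,   # informative (ADME)
    "nring": rng.standard_normal(n),                  # noise (structure)
    "mw":    rng.standard_normal(n),                  # noise (ADME)
    "chi0":  rng.standard_normal(n),                  # noise (structure)
})
categories = {"logp": "ADME", "tpsa": "ADME", "mw": "ADME",
              "nring": "structure", "chi0": "structure"}

ranking = svm_rfe(data, labels)
print("rank  feature  score(w^2 at elimination)")
for i, feature in enumerate(ranking.features, 1):
    print(f"  {i}   {feature:7s} {ranking.scores[feature]:.4f}")

top2 = select_top_k(ranking, k=2)
print(f"\ntop-2 selection: {top2}")
summary = categorize_features(ranking, categories)
for cat, info in summary.items():
    print(f"{cat}: {info['count']} features, best rank {info['best_rank']}")
# The planted descriptors (logp, tpsa) should occupy the top ranks; their
# scores are the squared SVM weights at the round they survived longest.
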