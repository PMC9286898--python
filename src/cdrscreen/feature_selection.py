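"""SVM recursive feature elimination for descriptor ranking.

A linear support-vector machine is fitted on all surviving features; each
feature's importance is the squared component of the weight vector,
``F_i = w_i**2``.  The single feature with the smallest ``F_i`` is removed
(ties broken by column order, first wins), its score and elimination index
are recorded, and the loop repeats until the feature set is empty.  The final
ranking is the reverse elimination order, so the last-surviving feature ranks
first.  Because each feature's score is only well-defined at the fit in which
it was eliminated, that is the score reported.

Features are z-scored before the loop (the linear kernel makes weights
scale-dependent); the SVM uses C = 1.0 and no class reweighting by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = ["RFERanking", "svm_rfe", "categorize_features", "select_top_k"]


@dataclass
class RFERanking:
    """Features ordered most-important-first with elimination-time scores."""

    features: list[str]           # rank order, best first
    scores: dict[str, float]      # F_i = w_i^2 at elimination time
    elimination_order: list[str]  # first-removed first

    def __post_init__(self) -> None:
        if sorted(self.features) != sorted(self.elimination_order):
            raise ValueError("ranking must be a permutation of the eliminated set")
        if any(s < 0 for s in self.scores.values()):
            raise ValueError("importance scores must be non-negative")

    def rank_of(self, feature: str) -> int:
        """1-based rank."""
        return self.features.index(feature) + 1


def svm_rfe(
    data: pd.DataFrame,
    labels,
    C: float = 1.0,
    standardize: bool = True,
    step: int = 1,
    class_weight: str | None = None,
) -> RFERanking:
    """Rank features by backward elimination with a linear SVM.

    ``data`` has one row per compound and one named column per feature;
    ``labels`` is binary.  ``step`` > 1 removes that many lowest-scoring
    features per iteration — faster on wide matrices, but a departure from
    strict one-at-a-time elimination.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    X = data.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("data rows and labels must align")
    if X.shape[1] == 0 or X.shape[0] == 0:
        raise ValueError("empty feature matrix")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if data.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    surviving = list(range(X.shape[1]))
    names = list(data.columns)
    eliminated: list[str] = []
    scores: dict[str, float] = {}
    while surviving:
        if len(surviving) == 1:
            # nothing to fit against; the sole survivor keeps its last score
            last = names[surviving[0]]
            if last not in scores:
                scores[last] = _fit_scores(X[:, surviving], y, C, class_weight)[0]
            eliminated.append(last)
            break
        f = _fit_scores(X[:, surviving], y, C, class_weight)
        # ascending by score; column order breaks ties (stable sort)
        order = np.argsort(f, kind="stable")
        n_drop = min(step, len(surviving) - 1)
        drop_positions = sorted(order[:n_drop].tolist(), reverse=True)
        # record in ascending-score order so elimination_order stays meaningful
        for pos in order[:n_drop]:
            name = names[surviving[pos]]
            scores[name] = float(f[pos])
            eliminated.append(name)
        for pos in drop_positions:
            surviving.pop(pos)
    # the sole survivor's score is its w^2 from the last 2+-feature fit
    last = eliminated[-1]
    if last not in scores:
        scores[last] = float("nan")
    return RFERanking(
        features=list(reversed(eliminated)),
        scores=scores,
        elimination_order=eliminated,
    )


def _fit_scores(X: np.ndarray, y: np.ndarray, C: float,
                class_weight: str | None) -> np.ndarray:
    clf = SVC(kernel="linear", C=C, class_weight=class_weight)
    clf.fit(X, y)
    w = clf.coef_.ravel()
    return w ** 2


def categorize_features(
    ranking: RFERanking, category_map: dict[str, str]
) -> dict[str, dict]:
    """Group a ranking by descriptor category.

    Returns, per category, the member count and the members in rank order.
    Every ranked feature must be mapped.
    """
    unmapped = [f for f in ranking.features if f not in category_map]
    if unmapped:
        raise ValueError(f"features missing from category map: {unmapped[:5]}")
    out: dict[str, dict] = {}
    for rank, feature in enumerate(ranking.features, start=1):
        cat = category_map[feature]
        entry = out.setdefault(cat, {"count": 0, "members": [], "best_rank": rank})
        entry["count"] += 1
        entry["members"].append(feature)
    return out


def write_ranking(
    ranking: RFERanking,
    path,
    category_map: dict[str, str] | None = None,
) -> None:
    """Ranking as CSV with columns rank, feature, score[, category]."""
    frame = pd.DataFrame(
        {
            "rank": range(1, len(ranking.features) + 1),
            "feature": ranking.features,
            "score": [ranking.scores[f] for f in ranking.features],
        }
    )
    if category_map is not None:
        frame["category"] = [category_map[f] for f in ranking.features]
    frame.to_csv(path, index=False)


def select_top_k(
    ranking: RFERanking,
    k: int | None = None,
    score_threshold: float | None = None,
) -> list[str]:
    """First ``k`` ranked features, or all with score above a threshold."""
    if (k is None) == (score_threshold is None):
        raise ValueError("pass exactly one of k or score_threshold")
    if k is not None:
        if not 1 <= k <= len(ranking.features):
            raise ValueError(
                f"k must lie in [1, {len(ranking.features)}], got {k}"
            )
        return ranking.features[:k]
    return [f for f in ranking.features if ranking.scores[f] > score_threshold]
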