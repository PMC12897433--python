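"""Random-forest importance ranking of the window-level features.

A forest of CART-style trees (Gini impurity, bootstrap resampling, sqrt(p)
features considered per split, unlimited depth by default) ranks the seven
window statistics plus the mean-to-std ratio by mean decrease in impurity.
Window rows inherit the label of their parent image.

The forest here is deliberately self-contained so its split and importance
conventions are fully specified; an established implementation serves only
as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Window-level features ranked by default: the seven statistics + Mean/Std.
RANKED_FEATURES = ("mean", "std", "skewness", "kurtosis", "mode", "sum",
                   "frac_above", "mean_over_std")


@dataclass
class ImportanceRanking:
    """Normalized impurity importances and the implied rank order."""

    feature_names: tuple[str, ...]
    importances: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def ranks(self) -> np.ndarray:
        """Rank per feature, 1 = most important."""
        order = np.argsort(-self.importances, kind="stable")
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        return ranks

    @property
    def ranked_names(self) -> list[str]:
        order = np.argsort(-self.importances, kind="stable")
        return [self.feature_names[i] for i in order]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "importance": self.importances,
            "rank": self.ranks,
        }).sort_values("rank").reset_index(drop=True)


def _gini(n1: float, n: float) -> float:
    p1 = n1 / n
    return 1.0 - p1 * p1 - (1.0 - p1) ** 2


def _best_split(X: np.ndarray, y: np.ndarray, feat: int):
    """Best Gini split on one feature: (weighted_impurity, threshold) or None."""
    x = X[:, feat]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    n = xs.size
    cum1 = np.cumsum(ys)
    i = np.arange(1, n)
    valid = xs[1:] > xs[:-1]
    if not valid.any():
        return None
    i = i[valid]
    n_l = i.astype(float)
    n_r = n - n_l
    n1_l = cum1[i - 1].astype(float)
    n1_r = cum1[-1] - n1_l
    p1l = n1_l / n_l
    p1r = n1_r / n_r
    gini_l = 1.0 - p1l**2 - (1.0 - p1l) ** 2
    gini_r = 1.0 - p1r**2 - (1.0 - p1r) ** 2
    weighted = (n_l * gini_l + n_r * gini_r) / n
    j = int(np.argmin(weighted))
    thr = 0.5 * (xs[i[j] - 1] + xs[i[j]])
    return float(weighted[j]), float(thr)


def _grow_tree(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
               importances: np.ndarray, max_depth: int | None,
               max_features: int) -> None:
    """Grow one CART tree, accumulating weighted impurity decreases."""
    n_total = X.shape[0]
    p = X.shape[1]
    stack: list[tuple[np.ndarray, int]] = [(np.arange(n_total), 0)]
    while stack:
        idx, depth = stack.pop()
        n = idx.size
        node_gini = _gini(float(y[idx].sum()), n)
        if node_gini == 0.0 or n < 2 or (max_depth is not None
                                         and depth >= max_depth):
            continue
        candidates = rng.choice(p, size=max_features, replace=False)
        best = None
        for f in candidates:
            res = _best_split(X[idx], y[idx], f)
            if res is not None and (best is None or res[0] < best[0]):
                best = (res[0], res[1], f)
        if best is None:
            # sampled features all constant at this node: fall back to the rest
            for f in np.setdiff1d(np.arange(p), candidates):
                res = _best_split(X[idx], y[idx], f)
                if res is not None and (best is None or res[0] < best[0]):
                    best = (res[0], res[1], f)
        if best is None or best[0] >= node_gini:
            continue
        w_imp, thr, f = best
        left = idx[X[idx, f] <= thr]
        right = idx[X[idx, f] > thr]
        if left.size == 0 or right.size == 0:
            # the midpoint threshold rounded onto a data value
            continue
        importances[f] += (n / n_total) * (node_gini - w_imp)
        stack.append((left, depth + 1))
        stack.append((right, depth + 1))


def rank_features(feature_table: pd.DataFrame, labels: np.ndarray,
                  feature_names: tuple[str, ...] = RANKED_FEATURES,
                  n_trees: int = 100, max_depth: int | None = None,
                  seed: int = 0) -> ImportanceRanking:
    """Rank features by mean decrease in Gini impurity over a forest.

    Rows with undefined values (e.g. ``mean_over_std`` of a constant
    window) are dropped and logged. Importances are normalized per tree,
    averaged over trees, and renormalized to sum to one.
    """
    X = feature_table.loc[:, list(feature_names)].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("empty feature table")
    if X.shape[0] != y.size:
        raise ValueError("labels length does not match the feature table")
    keep = ~np.isnan(X).any(axis=1)
    if not keep.all():
        logger.info("dropping %d rows with undefined feature values",
                    int((~keep).sum()))
    X, y = X[keep], y[keep]
    if np.unique(y).size < 2:
        raise ValueError("need both classes present to rank features")

    p = X.shape[1]
    n = X.shape[0]
    max_features = max(1, int(round(math.sqrt(p))))
    ss = np.random.SeedSequence(seed)
    total = np.zeros(p)
    effective_trees = 0
    for child in ss.spawn(n_trees):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, n, size=n)
        imp = np.zeros(p)
        _grow_tree(X[boot], y[boot], rng, imp, max_depth, max_features)
        s = imp.sum()
        if s > 0:
            total += imp / s
            effective_trees += 1
    if effective_trees == 0:
        raise ValueError("no tree found a valid split")
    importances = total / effective_trees
    importances /= importances.sum()
    return ImportanceRanking(
        feature_names=tuple(feature_names), importances=importances,
        params={"n_trees": n_trees, "max_depth": max_depth,
                "max_features": max_features, "min_samples_leaf": 1},
        seed=seed,
    )
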