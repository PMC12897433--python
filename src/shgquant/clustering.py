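"""From-scratch K-means for unsupervised label validation.

Clustering the four image-level features (mean, std, mode, above-threshold
fraction) into k=2 groups checks that the specialist's fibrotic /
non-fibrotic labels correspond to structure the features actually carry.

Algorithm: Forgy initialization (k distinct data points drawn uniformly),
then alternate nearest-Euclidean-centroid assignment and centroid
recomputation as cluster means, until the largest centroid displacement
falls below ``tol`` or ``max_iter`` (default 500) is reached. An emptied
cluster is reseeded to the point farthest from its assigned centroid.
Within-cluster sum of squares (inertia) is checked to be non-increasing on
every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CLUSTER_FEATURE_NAMES


@dataclass
class ClusterAssignment:
    """Final labels, centroids and the convergence trace of one k-means run."""

    labels: np.ndarray
    centroids: np.ndarray
    iterations: int
    converged: bool
    inertia: float
    inertia_history: list[float] = field(default_factory=list)
    seed: int | None = None
    standardized: bool = False


def _inertia(points: np.ndarray, centroids: np.ndarray,
             labels: np.ndarray) -> float:
    return float(((points - centroids[labels]) ** 2).sum())


def kmeans(points: np.ndarray, k: int = 2, max_iter: int = 500,
           tol: float = 1e-6, seed: int | np.random.Generator = 0,
           ) -> ClusterAssignment:
    """Cluster *points* (n x d) into k groups by Lloyd iteration."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if not np.isfinite(points).all():
        raise ValueError("features must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)

    # Forgy: k data points, distinct as vectors when the data allows it
    unique = np.unique(points, axis=0)
    if unique.shape[0] >= k:
        centroids = unique[rng.choice(unique.shape[0], size=k, replace=False)]
    else:
        centroids = points[rng.choice(n, size=k, replace=False)].copy()

    labels = np.zeros(n, dtype=int)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # reseed empty clusters to the point farthest from its own centroid
        for c in range(k):
            if not (labels == c).any():
                far = int(np.sqrt(d2[np.arange(n), labels]).argmax())
                centroids[c] = points[far]
                labels[far] = c
        inertia = _inertia(points, centroids, labels)
        if history and inertia > history[-1] + 1e-9 * max(1.0, history[-1]):
            raise RuntimeError(
                f"inertia increased at iteration {it}: "
                f"{history[-1]:.6g} -> {inertia:.6g}"
            )
        history.append(inertia)
        new_centroids = centroids.copy()
        for c in range(k):
            members = points[labels == c]
            if members.shape[0]:
                new_centroids[c] = members.mean(axis=0)
        shift = float(np.linalg.norm(new_centroids - centroids, axis=1).max())
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    final_inertia = _inertia(points, centroids, labels)
    return ClusterAssignment(
        labels=labels, centroids=centroids, iterations=it, converged=converged,
        inertia=final_inertia, inertia_history=history,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def label_agreement(assignment: ClusterAssignment | np.ndarray,
                    labels: np.ndarray) -> float:
    """Best match rate over the two cluster-to-label mappings (in [0.5, 1])."""
    cl = assignment.labels if isinstance(assignment, ClusterAssignment) \
        else np.asarray(assignment)
    labels = np.asarray(labels)
    if cl.shape != labels.shape:
        raise ValueError("assignment and labels must have equal length")
    direct = float(np.mean(cl == labels))
    return max(direct, 1.0 - direct)


def cluster_image_features(table: pd.DataFrame,
                           feature_names: tuple[str, ...] = CLUSTER_FEATURE_NAMES,
                           standardize: bool = True, k: int = 2,
                           max_iter: int = 500, tol: float = 1e-6,
                           seed: int = 0, n_init: int = 1) -> ClusterAssignment:
    """K-means over an image-level feature table.

    Features are z-scored by default (sum- and fraction-valued features
    differ by orders of magnitude); with ``n_init > 1`` the run with the
    lowest inertia wins.
    """
    X = table.loc[:, list(feature_names)].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    ss = np.random.SeedSequence(seed)
    best: ClusterAssignment | None = None
    for child in ss.spawn(max(1, n_init)):
        res = kmeans(X, k=k, max_iter=max_iter, tol=tol,
                     seed=np.random.default_rng(child))
        if best is None or res.inertia < best.inertia:
            best = res
    assert best is not None
    best.seed = seed
    best.standardized = standardize
    return best
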