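"""Target-space clustering: restarted k-means++ and the elbow rule for K.

Targets are clustered on their column-scaled activity profiles.  k-means
is restarted many times from k-means++ seeds and the partition with the
lowest within-cluster sum of squares is kept, which makes the outcome
deterministic given the seed and empirically very stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .matrix import BioactivityMatrix, TargetPartition

__all__ = ["kmeans_multi_restart", "elbow_K", "ElbowTrace", "cluster_centroids"]


def kmeans_multi_restart(
    Xs: BioactivityMatrix, K: int, restarts: int = 100, seed: int = 0
) -> TargetPartition:
    """Best-of-``restarts`` k-means++ partition of the targets.

    Returns the partition minimizing the within-cluster sum of squared
    distances over all restarts.  Deterministic given ``seed``.
    """
    if not 2 <= K <= Xs.m:
        raise ValueError(f"K must be in [2, m={Xs.m}], got {K}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=restarts,
        random_state=int(seed) % (2**31),
    ).fit(Xs.values)
    raw = km.labels_
    # relabel blocks by first occurrence so the partition is canonical
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        labels[i] = remap[lab]
    return TargetPartition(
        K=K,
        labels={t: int(l) for t, l in zip(Xs.target_ids, labels)},
        objective=float(km.inertia_),
    )


def cluster_centroids(
    X: BioactivityMatrix, partition: TargetPartition
) -> np.ndarray:
    """(K, n) matrix of per-cluster mean activity profiles."""
    labels = partition.label_array(X.target_ids)
    out = np.empty((partition.K, X.n))
    for k in range(partition.K):
        out[k] = X.values[labels == k].mean(axis=0)
    return out


@dataclass
class ElbowTrace:
    """Objective-vs-K trace with the K chosen by the relative-drop rule."""

    L_K: dict[int, float]
    chosen_K: int
    epsilon: float
    stopped_at_zero: bool = False
    hit_K_max: bool = False


def elbow_K(
    Xs: BioactivityMatrix,
    epsilon: float = 0.02,
    K_max: int | None = None,
    restarts: int = 100,
    seed: int = 0,
) -> ElbowTrace:
    """Choose K as the smallest value where the objective stops improving.

    Computes the restarted k-means objective L_K for K = 2, 3, ... and
    returns the first K with |1 - L_{K+1}/L_K| <= epsilon.  A zero
    objective ends the scan (the ratio is undefined beyond a perfect
    fit); if no K satisfies the rule by ``K_max``, K_max is returned with
    a warning.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    if K_max is None:
        K_max = min(40, Xs.m - 1)
    K_max = min(K_max, Xs.m)
    if K_max < 2:
        raise ValueError("need at least 2 targets to cluster")

    rng = np.random.default_rng(seed)
    seeds = {K: int(rng.integers(2**31)) for K in range(2, K_max + 2)}
    L: dict[int, float] = {}

    def obj(K: int) -> float:
        if K not in L:
            L[K] = kmeans_multi_restart(Xs, K, restarts=restarts, seed=seeds[K]).objective
        return L[K]

    for K in range(2, K_max + 1):
        LK = obj(K)
        if LK == 0.0:
            return ElbowTrace(L_K=dict(L), chosen_K=K, epsilon=epsilon, stopped_at_zero=True)
        if K + 1 > Xs.m:
            break
        ratio = obj(K + 1) / LK
        if abs(1.0 - ratio) <= epsilon:
            return ElbowTrace(L_K=dict(L), chosen_K=K, epsilon=epsilon)
    warnings.warn(
        f"elbow rule not satisfied by K_max={K_max}; returning K_max",
        UserWarning,
        stacklevel=2,
    )
    return ElbowTrace(L_K=dict(L), chosen_K=K_max, epsilon=epsilon, hit_K_max=True)
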