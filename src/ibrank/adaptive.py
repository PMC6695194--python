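"""Adaptive Selection (AS).

AS fixes the cluster count with an elbow rule on the restarted k-means
objective, selects a base informer set of n0 compounds by finding the
group-lasso penalty at which exactly n0 compound groups enter the
multinomial model, and then grows the set one compound at a time: each
step adds the compound whose inclusion minimizes the total squared
distance between the remaining non-informer columns and the centroid of
the enlarged informer columns (computed on the raw inhibition matrix).

Ranking reuses the CS code-word machinery: the new target's informer
readouts pick the nearest code-word centroid and non-informers are
ranked by activity rates among the matched targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .base import InformerStrategy, RankingResult
from .cluster import ElbowTrace, elbow_K, kmeans_multi_restart
from .coding import (
    activity_rate_ranking,
    assign_code_word,
    build_code_word_table,
)
from .grouplasso import fit_multinomial_group_lasso, lambda_max
from .matrix import (
    BioactivityMatrix,
    InformerSet,
    TargetPartition,
    binarize_matrix,
    scale_columns_unit_interval,
)

__all__ = [
    "base_informers_path",
    "augment_informers",
    "AugmentationTrace",
    "AdaptiveSelector",
]

_NORM_TOL = 1e-10  # a group is "in the model" when its norm exceeds this


_PATH_RIDGE = 1e-8  # bounds the fit under separation so groups keep entering


def _nonzero_groups(Xs, y, K, lam, warm=None) -> tuple[np.ndarray, tuple]:
    model = fit_multinomial_group_lasso(
        Xs, y, K, lam, ridge=_PATH_RIDGE, warm=warm
    )
    norms = model.group_norms()
    return norms > _NORM_TOL, (model.intercepts, model.weights)


def base_informers_path(
    Xs: BioactivityMatrix,
    partition: TargetPartition,
    n0: int = 8,
    grid_size: int = 100,
    bisect_steps: int = 30,
) -> InformerSet:
    """First n0 informers from the group-lasso regularization path.

    Scans a decreasing log-spaced grid of penalties from the critical
    value (all groups zero) downward and returns the compounds active at
    the largest penalty admitting exactly n0 groups, bisecting between
    bracketing grid points when no grid point hits n0 exactly.  When
    groups enter in a batch that skips n0, the first path point with >=
    n0 groups is truncated to the n0 largest-norm groups (flagged in
    diagnostics).  Compounds are ordered by entry point along the path.
    """
    if not 1 <= n0 < Xs.n:
        raise ValueError(f"n0 must be in [1, n), got {n0}")
    y = partition.label_array(Xs.target_ids)
    K = partition.K
    X = Xs.values
    lam_hi = lambda_max(X, y, K) * (1.0 + 1e-6)
    grid = np.geomspace(lam_hi, lam_hi * 1e-7, grid_size)

    warm = None
    entry_lam = np.full(Xs.n, -np.inf)
    prev_lam, prev_count = lam_hi, 0
    hit = None  # (lam, mask)
    over = None
    for lam in grid:
        mask, warm = _nonzero_groups(X, y, K, lam, warm=warm)
        newly = mask & (entry_lam == -np.inf)
        entry_lam[newly] = lam
        count = int(mask.sum())
        if count == n0:
            hit = (lam, mask)
            break
        if count > n0:
            over = (lam, mask, warm)
            break
        prev_lam, prev_count = lam, count

    truncated = False
    if hit is None and over is not None:
        # bisect between the last under-n0 penalty and the first over-n0 one
        lo_lam, lo_mask = over[0], over[1]
        hi_lam = prev_lam
        warm_b = over[2]
        for _ in range(bisect_steps):
            mid = float(np.sqrt(lo_lam * hi_lam))
            mask, warm_b = _nonzero_groups(X, y, K, mid, warm=warm_b)
            newly = mask & (entry_lam == -np.inf)
            entry_lam[newly] = mid
            count = int(mask.sum())
            if count == n0:
                hit = (mid, mask)
                break
            if count < n0:
                hi_lam = mid
            else:
                lo_lam, lo_mask = mid, mask
        if hit is None:
            # groups enter in a batch: keep the n0 largest-norm groups at
            # the first penalty with >= n0 active groups
            model = fit_multinomial_group_lasso(X, y, K, lo_lam)
            norms = model.group_norms()
            idx = np.where(lo_mask)[0]
            idx = sorted(idx, key=lambda j: (-norms[j], Xs.compound_ids[j]))[:n0]
            mask = np.zeros(Xs.n, dtype=bool)
            mask[list(idx)] = True
            hit = (lo_lam, mask)
            truncated = True
    if hit is None:
        raise RuntimeError(
            f"regularization path never reached {n0} active groups; "
            "the clusters may be unpredictable from any compound"
        )

    lam_star, mask = hit
    idx = np.where(mask)[0]
    # order by entry point on the path (largest entry penalty first)
    order = sorted(idx, key=lambda j: (-entry_lam[j], Xs.compound_ids[j]))
    return InformerSet(
        compound_ids=[Xs.compound_ids[j] for j in order],
        method="as-base",
        diagnostics={
            "lambda": float(lam_star),
            "K": K,
            "truncated_batch_entry": truncated,
            "n0": n0,
        },
    )


@dataclass
class AugmentationTrace:
    """Order and criterion values of the greedy centroid-distance additions."""

    order: list[str] = field(default_factory=list)
    objective_values: list[float] = field(default_factory=list)


def augment_informers(
    X: BioactivityMatrix, base: InformerSet, n_A: int
) -> tuple[InformerSet, AugmentationTrace]:
    """Grow the informer set to n_A by the centroid-distance criterion.

    Each step adds the compound j minimizing

        sum_{k not in A+{j}} || x_.k - c ||^2,

    where c is the centroid of the raw informer columns including j.
    Ties break lexically on compound ID.
    """
    if not len(base) < n_A <= X.n:
        raise ValueError(f"need |base|={len(base)} < n_A={n_A} <= n={X.n}")
    cols = X.values.T  # (n, m): column vectors per compound
    current = list(X.compound_indices(base.compound_ids))
    in_set = np.zeros(X.n, dtype=bool)
    in_set[current] = True
    trace = AugmentationTrace()
    col_sum = cols[current].sum(axis=0)
    while in_set.sum() < n_A:
        best_j, best_val = None, np.inf
        for j in range(X.n):
            if in_set[j]:
                continue
            c = (col_sum + cols[j]) / (in_set.sum() + 1)
            rest = ~in_set
            rest_idx = np.where(rest)[0]
            rest_idx = rest_idx[rest_idx != j]
            diffs = cols[rest_idx] - c[None, :]
            val = float((diffs * diffs).sum())
            if val < best_val - 1e-12 or (
                abs(val - best_val) <= 1e-12
                and best_j is not None
                and X.compound_ids[j] < X.compound_ids[best_j]
            ):
                best_j, best_val = j, val
        in_set[best_j] = True
        col_sum += cols[best_j]
        trace.order.append(X.compound_ids[best_j])
        trace.objective_values.append(best_val)
    informers = InformerSet(
        compound_ids=list(base.compound_ids) + trace.order,
        method="as",
        diagnostics={**base.diagnostics, "augmented": len(trace.order)},
    )
    return informers, trace


class AdaptiveSelector(InformerStrategy):
    """AS strategy as a scikit-learn style estimator.

    Parameters
    ----------
    n_informers : final informer set size (default 16).
    n0 : base set size from the regularization path (default 8).
    epsilon : elbow tolerance on the relative k-means objective drop
        (default 0.02).
    K_max : largest cluster count scanned by the elbow rule
        (default min(40, m - 1)).
    restarts : k-means++ restarts (default 100).
    path_grid_size : penalties in the regularization-path scan.
    seed : drives the clustering restarts.
    """

    method = "as"

    def __init__(
        self,
        n_informers: int = 16,
        n0: int = 8,
        epsilon: float = 0.02,
        K_max: int | None = None,
        restarts: int = 100,
        path_grid_size: int = 100,
        seed: int = 0,
    ):
        self.n_informers = n_informers
        self.n0 = n0
        self.epsilon = epsilon
        self.K_max = K_max
        self.restarts = restarts
        self.path_grid_size = path_grid_size
        self.seed = seed

    def _fit(self, X: BioactivityMatrix) -> InformerSet:
        rng = np.random.default_rng(self.seed)
        elbow_seed = int(rng.integers(2**31))
        km_seed = int(rng.integers(2**31))
        self.Xs_, self.scaler_ = scale_columns_unit_interval(X)
        self.elbow_ = elbow_K(
            self.Xs_,
            epsilon=self.epsilon,
            K_max=self.K_max,
            restarts=self.restarts,
            seed=elbow_seed,
        )
        self.partition_ = kmeans_multi_restart(
            self.Xs_, self.elbow_.chosen_K, restarts=self.restarts, seed=km_seed
        )
        base = base_informers_path(
            self.Xs_, self.partition_, n0=self.n0, grid_size=self.path_grid_size
        )
        informers, self.trace_ = augment_informers(X, base, self.n_informers)
        self.Z_ = binarize_matrix(X)
        self.table_ = build_code_word_table(self.Z_, X, informers)
        return informers

    def _rank(self, values: np.ndarray) -> RankingResult:
        word = assign_code_word(values, self.table_)
        self.rate_ranking_, ids, scores = activity_rate_ranking(
            self.Z_, self.informers_, word, self.table_
        )
        return self._result(ids, scores, values)
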