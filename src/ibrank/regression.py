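"""Regression Selection (RS).

RS clusters the targets on their scaled activity profiles, then picks
informer compounds greedily with a group-lasso multinomial regression of
cluster labels on compound activities: at each step the compound group
with the largest Euclidean coefficient norm (among groups still under the
penalty) is moved into the informer set and the model is re-solved with
that group exempted.  After selection the model is refitted on the chosen
compounds alone with the penalty removed.

For a new target, the refitted model turns the informer readouts into
cluster-membership probabilities, and each non-informer compound is
scored by the probability-weighted mixture of cluster-centroid
activities.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import KFold

from . import metrics as _metrics
from .base import InformerStrategy, RankingResult, rank_descending
from .cluster import cluster_centroids, kmeans_multi_restart
from .grouplasso import MultinomialModel, fit_multinomial_group_lasso
from .matrix import (
    BioactivityMatrix,
    InformerSet,
    TargetPartition,
    binarize_row,
    scale_columns_unit_interval,
)

__all__ = [
    "greedy_group_lasso_informers",
    "refit_unpenalized",
    "predict_cluster_probabilities",
    "rs_rank_compounds",
    "select_K_by_cv",
    "RegressionSelector",
]

RS_LAMBDA = 1e-6  # fixed penalty weight for the greedy selection fits
REFIT_RIDGE = 1e-8  # keeps the unpenalized refit bounded under separation


def greedy_group_lasso_informers(
    Xs: BioactivityMatrix,
    partition: TargetPartition,
    n_A: int,
    lam: float = RS_LAMBDA,
) -> tuple[InformerSet, MultinomialModel]:
    """Select informers one at a time by largest penalized group norm.

    Starting from an empty set, repeatedly fit the group-lasso model with
    already-selected groups exempt from the penalty, then admit the
    unselected compound whose coefficient group has the largest Euclidean
    norm.  Stops at ``n_A`` compounds or when every remaining group is
    exactly zero (recorded in diagnostics).  Norm ties break lexically on
    compound ID.
    """
    if n_A < 1:
        raise ValueError("n_A must be >= 1")
    y = partition.label_array(Xs.target_ids)
    X = Xs.values
    n = Xs.n
    selected_idx: list[int] = []
    unpenalized = np.zeros(n, dtype=bool)
    warm = None
    model = None
    exhausted = False
    for _ in range(min(n_A, n)):
        model = fit_multinomial_group_lasso(
            X, y, partition.K, lam, unpenalized=unpenalized, warm=warm
        )
        warm = (model.intercepts, model.weights)
        norms = model.group_norms()
        norms = np.where(unpenalized, -np.inf, norms)
        max_norm = norms.max()
        if max_norm <= 0.0:
            exhausted = True
            break
        ties = [j for j in range(n) if norms[j] == max_norm]
        best = min(ties, key=lambda j: Xs.compound_ids[j])
        selected_idx.append(best)
        unpenalized[best] = True

    ids = [Xs.compound_ids[j] for j in selected_idx]
    info = InformerSet(
        compound_ids=ids,
        method="rs",
        diagnostics={
            "K": partition.K,
            "lambda": lam,
            "exhausted_nonzero_groups": exhausted,
            "requested_n_A": n_A,
        },
    )
    if exhausted and len(ids) < n_A:
        warnings.warn(
            f"greedy selection exhausted nonzero groups at {len(ids)} < {n_A}",
            UserWarning,
            stacklevel=2,
        )
    return info, model


def refit_unpenalized(
    Xs: BioactivityMatrix, partition: TargetPartition, informers: InformerSet
) -> MultinomialModel:
    """Refit the multinomial model on the selected compounds only.

    Coefficients outside the informer set are exactly zero; the penalty
    is dropped and a tiny ridge term keeps the problem well posed when
    the clusters are linearly separable on the informers.
    """
    if len(informers) == 0:
        raise ValueError("informer set must be non-empty for refit")
    cols = Xs.compound_indices(informers.compound_ids)
    y = partition.label_array(Xs.target_ids)
    sub = fit_multinomial_group_lasso(
        Xs.values[:, cols], y, partition.K, lam=0.0, ridge=REFIT_RIDGE
    )
    weights = np.zeros((partition.K, Xs.n))
    weights[:, cols] = sub.weights
    return MultinomialModel(
        intercepts=sub.intercepts,
        weights=weights,
        K=partition.K,
        lam=0.0,
        compound_ids=list(Xs.compound_ids),
        selected=list(informers.compound_ids),
        objective=sub.objective,
        n_iter=sub.n_iter,
        diagnostics={"ridge": REFIT_RIDGE},
    )


def predict_cluster_probabilities(
    model: MultinomialModel, assay_values: np.ndarray, informers: InformerSet, Xs_like
) -> np.ndarray:
    """Cluster probabilities for a new target from its informer readouts.

    ``assay_values`` must already be on the training column scale; they
    are embedded at the informer positions of a zero profile, which is
    equivalent to evaluating the refitted model (all other coefficients
    are zero).
    """
    x = np.zeros(model.weights.shape[1])
    cols = Xs_like.compound_indices(informers.compound_ids)
    x[cols] = assay_values
    probs = model.predict_proba(x)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):  # pragma: no cover
        raise AssertionError("cluster probabilities must normalize")
    return probs


def rs_rank_compounds(
    probs: np.ndarray,
    partition: TargetPartition,
    X: BioactivityMatrix,
    informers: InformerSet,
) -> tuple[list[str], np.ndarray]:
    """Score non-informers by the probability-weighted cluster centroids.

    Centroids are means of the *raw* inhibition values: the expected
    activity of the new target on compound j under the cluster mixture.
    (Column scaling is a clustering device only; a uniformly active
    compound would be flattened to noise on the scaled scale.)
    """
    centroids = cluster_centroids(X, partition)  # (K, n)
    mu = probs @ centroids
    informer_cols = set(X.compound_indices(informers.compound_ids).tolist())
    ids = [c for j, c in enumerate(X.compound_ids) if j not in informer_cols]
    scores = np.array([mu[j] for j in range(X.n) if j not in informer_cols])
    return rank_descending(ids, scores)


def _score_holdout(
    criterion: str,
    ranked_ids: list[str],
    scores: np.ndarray,
    informers: InformerSet,
    raw_row: np.ndarray,
    X: BioactivityMatrix,
) -> float:
    """Metric value for one held-out target given its full raw activity row."""
    labels_vec, _thr = binarize_row(raw_row)
    labels = {c: int(z) for c, z in zip(X.compound_ids, labels_vec)}
    cols = X.compound_indices(informers.compound_ids)
    ranking = RankingResult(
        compound_ids=ranked_ids,
        scores=scores,
        informer_ids=list(informers.compound_ids),
        informer_activities={c: float(raw_row[j]) for c, j in zip(informers.compound_ids, cols)},
        method="rs-cv",
    )
    evalset = _metrics.build_evaluation_set(ranking, labels)
    if criterion == "nef10":
        val = _metrics.nef10(evalset)
    elif criterion == "rocauc":
        val = _metrics.rocauc(evalset)
    else:
        raise ValueError(f"unknown CV criterion {criterion!r}")
    return val


def select_K_by_cv(
    X: BioactivityMatrix,
    K_grid: list[int],
    n_A: int,
    folds: int = 5,
    seed: int = 0,
    criterion: str = "nef10",
    lam: float = RS_LAMBDA,
    restarts: int = 100,
) -> tuple[int, dict]:
    """Pick K by target-wise cross-validation of the full RS pipeline.

    Targets are split into ``folds`` folds.  For each candidate K the RS
    pipeline is trained on the in-fold targets and each held-out target
    is ranked from its informer readouts; the mean ``criterion`` score
    (default NEF10 against the target's own activity threshold) selects
    K, ties to the smaller value.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if X.m < folds:
        raise ValueError(f"cannot split m={X.m} targets into {folds} folds")
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    km_seed = int(rng.integers(2**31))
    mean_scores: dict[int, float] = {}
    for K in K_grid:
        vals: list[float] = []
        for train_idx, test_idx in kf.split(np.arange(X.m)):
            if K > len(train_idx):
                continue
            sub = BioactivityMatrix(
                values=X.values[train_idx],
                target_ids=[X.target_ids[i] for i in train_idx],
                compound_ids=list(X.compound_ids),
            )
            Xs, scaler = scale_columns_unit_interval(sub)
            part = kmeans_multi_restart(Xs, K, restarts=restarts, seed=km_seed)
            informers, _ = greedy_group_lasso_informers(Xs, part, n_A, lam=lam)
            if len(informers) == 0:
                continue
            model = refit_unpenalized(Xs, part, informers)
            cols = X.compound_indices(informers.compound_ids)
            for i in test_idx:
                raw_row = X.values[i]
                if raw_row.std(ddof=1) == 0.0:
                    warnings.warn(
                        f"degenerate held-out target {X.target_ids[i]!r} skipped",
                        UserWarning,
                        stacklevel=2,
                    )
                    continue
                assays = {c: float(raw_row[j]) for c, j in zip(informers.compound_ids, cols)}
                scaled_vals = np.array(
                    [scaler.transform_assays(assays)[c] for c in informers.compound_ids]
                )
                probs = predict_cluster_probabilities(model, scaled_vals, informers, Xs)
                ids, scores = rs_rank_compounds(probs, part, sub, informers)
                val = _score_holdout(criterion, ids, scores, informers, raw_row, X)
                if np.isfinite(val):
                    vals.append(val)
        mean_scores[K] = float(np.mean(vals)) if vals else -np.inf
    best = max(sorted(K_grid), key=lambda K: (mean_scores[K], -K))
    return best, {"criterion": criterion, "mean_scores": mean_scores, "folds": folds}


class RegressionSelector(InformerStrategy):
    """RS strategy as a scikit-learn style estimator.

    Parameters
    ----------
    n_informers : size of the informer set (default 16).
    n_clusters : fixed K; when None, K is chosen by cross-validation
        over ``K_grid``.
    K_grid : candidate cluster counts for the CV search.
    restarts : k-means++ restarts per clustering (default 100).
    folds : CV folds for the K search (default 5).
    lam : group-lasso weight for the greedy selection fits.
    criterion : CV scoring metric, 'nef10' (default) or 'rocauc'.
    seed : master seed; child streams drive clustering and fold splits.
    """

    method = "rs"

    def __init__(
        self,
        n_informers: int = 16,
        n_clusters: int | None = None,
        K_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
        restarts: int = 100,
        folds: int = 5,
        lam: float = RS_LAMBDA,
        criterion: str = "nef10",
        seed: int = 0,
    ):
        self.n_informers = n_informers
        self.n_clusters = n_clusters
        self.K_grid = K_grid
        self.restarts = restarts
        self.folds = folds
        self.lam = lam
        self.criterion = criterion
        self.seed = seed

    def _fit(self, X: BioactivityMatrix) -> InformerSet:
        rng = np.random.default_rng(self.seed)
        cv_seed = int(rng.integers(2**31))
        km_seed = int(rng.integers(2**31))
        self.Xs_, self.scaler_ = scale_columns_unit_interval(X)
        if self.n_clusters is None:
            K_grid = [K for K in self.K_grid if K <= X.m]
            K, cv_diag = select_K_by_cv(
                X,
                K_grid,
                n_A=self.n_informers,
                folds=self.folds,
                seed=cv_seed,
                criterion=self.criterion,
                lam=self.lam,
                restarts=self.restarts,
            )
        else:
            K, cv_diag = int(self.n_clusters), {"criterion": "fixed"}
        self.partition_ = kmeans_multi_restart(
            self.Xs_, K, restarts=self.restarts, seed=km_seed
        )
        informers, self.penalized_model_ = greedy_group_lasso_informers(
            self.Xs_, self.partition_, self.n_informers, lam=self.lam
        )
        informers.diagnostics["cv"] = cv_diag
        self.model_ = refit_unpenalized(self.Xs_, self.partition_, informers)
        return informers

    def _rank(self, values: np.ndarray) -> RankingResult:
        assays = dict(zip(self.informers_.compound_ids, values))
        scaled = self.scaler_.transform_assays(assays)
        scaled_vals = np.array([scaled[c] for c in self.informers_.compound_ids])
        self.cluster_probabilities_ = predict_cluster_probabilities(
            self.model_, scaled_vals, self.informers_, self.Xs_
        )
        ids, scores = rs_rank_compounds(
            self.cluster_probabilities_, self.partition_, self.train_matrix_,
            self.informers_,
        )
        return self._result(ids, scores, values)
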