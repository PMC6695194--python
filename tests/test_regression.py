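"""Regression selection: clustering, greedy group-lasso informers,
unpenalized refit, probability-weighted ranking, K selection."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ibrank.cluster import cluster_centroids, elbow_K, kmeans_multi_restart
from ibrank.grouplasso import MultinomialModel, fit_multinomial_group_lasso
from ibrank.matrix import (
    BioactivityMatrix,
    InformerSet,
    TargetPartition,
    scale_columns_unit_interval,
)
from ibrank.regression import (
    RegressionSelector,
    greedy_group_lasso_informers,
    predict_cluster_probabilities,
    refit_unpenalized,
    rs_rank_compounds,
    select_K_by_cv,
)


def exhaustive_kmeans_2(values):
    """Minimum 2-cluster within-SS over all bipartitions (m <= 10)."""
    m = values.shape[0]
    best = np.inf
    best_labels = None
    for bits in itertools.product([0, 1], repeat=m - 1):
        labels = np.array((0,) + bits)
        if labels.min() == labels.max():
            continue
        ss = 0.0
        for k in (0, 1):
            block = values[labels == k]
            ss += ((block - block.mean(axis=0)) ** 2).sum()
        if ss < best:
            best, best_labels = ss, labels
    return best, best_labels


class TestKmeans:
    def test_K_equals_m_gives_zero_objective(self, crisp_small):
        X = crisp_small["X"]
        Xs, _ = scale_columns_unit_interval(X)
        small = BioactivityMatrix(
            values=Xs.values[:6], target_ids=Xs.target_ids[:6],
            compound_ids=Xs.compound_ids,
        )
        part = kmeans_multi_restart(small, 6, restarts=5, seed=0)
        assert part.objective == pytest.approx(0.0, abs=1e-9)
        assert len(set(part.labels.values())) == 6

    def test_matches_exhaustive_bipartition_minimum(self):
        rng = np.random.default_rng(3)
        values = np.vstack(
            [rng.normal(0, 0.1, (4, 6)), rng.normal(3, 0.1, (4, 6))]
        )
        X = BioactivityMatrix(
            values=values,
            target_ids=[f"T{i}" for i in range(8)],
            compound_ids=[f"C{j}" for j in range(6)],
        )
        part = kmeans_multi_restart(X, 2, restarts=30, seed=1)
        best, best_labels = exhaustive_kmeans_2(values)
        assert part.objective == pytest.approx(best, rel=1e-9)
        got = part.label_array(X.target_ids)
        assert adjusted_rand_score(best_labels, got) == 1.0

    def test_planted_partition_recovered(self, crisp_small):
        X, truth = crisp_small["X"], crisp_small["truth"]
        Xs, _ = scale_columns_unit_interval(X)
        part = kmeans_multi_restart(Xs, 3, restarts=50, seed=4)
        true = [truth.cluster_labels[t] for t in X.target_ids]
        assert adjusted_rand_score(true, part.label_array(X.target_ids)) >= 0.95

    def test_deterministic_given_seed(self, crisp_small):
        Xs, _ = scale_columns_unit_interval(crisp_small["X"])
        p1 = kmeans_multi_restart(Xs, 4, restarts=10, seed=7)
        p2 = kmeans_multi_restart(Xs, 4, restarts=10, seed=7)
        assert p1.labels == p2.labels and p1.objective == p2.objective

    def test_objective_non_increasing_in_restarts(self, crisp_small):
        Xs, _ = scale_columns_unit_interval(crisp_small["X"])
        objs = [
            min(
                kmeans_multi_restart(Xs, 5, restarts=r, seed=s).objective
                for s in range(3)
            )
            for r in (1, 5, 20)
        ]
        assert objs[0] >= objs[1] >= objs[2]

    def test_K_out_of_range_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            kmeans_multi_restart(toy_matrix, 5, seed=0)


class TestElbow:
    def test_crisp_three_clusters_recovered(self):
        from ibrank.synthetic import SyntheticSpec, generate_matrix

        spec = SyntheticSpec(
            m=150, n=60, K=3, n_informative=6, noise_sd=2.0,
            active_fraction_range=(3.0 / 60, 3.9 / 60), seed=2,
        )
        X, _ = generate_matrix(spec)
        Xs, _ = scale_columns_unit_interval(X)
        trace = elbow_K(Xs, epsilon=0.02, K_max=8, restarts=20, seed=0)
        assert trace.chosen_K == 3

    def test_large_epsilon_stops_immediately(self, crisp_small):
        Xs, _ = scale_columns_unit_interval(crisp_small["X"])
        trace = elbow_K(Xs, epsilon=0.99, K_max=8, restarts=5, seed=0)
        assert trace.chosen_K == 2

    def test_zero_objective_stops_scan(self):
        # duplicate-pair targets: K = m/2 fits perfectly
        base = np.eye(3)
        values = np.repeat(base, 2, axis=0) * 10.0
        X = BioactivityMatrix(
            values=values,
            target_ids=[f"T{i}" for i in range(6)],
            compound_ids=["C0", "C1", "C2"],
        )
        trace = elbow_K(X, epsilon=1e-6, K_max=5, restarts=10, seed=0)
        assert trace.stopped_at_zero
        assert trace.L_K[trace.chosen_K] == pytest.approx(0.0, abs=1e-12)


class TestGroupLasso:
    def test_one_hot_indicator_column_selected_first(self):
        rng = np.random.default_rng(0)
        m = 20
        labels = np.array([0] * 10 + [1] * 10)
        values = np.full((m, 5), 0.5) + rng.normal(0, 0.01, (m, 5))
        values[:, 2] = labels  # perfect cluster indicator
        X = BioactivityMatrix(
            values=values,
            target_ids=[f"T{i:02d}" for i in range(m)],
            compound_ids=list("ABCDE"),
        )
        part = TargetPartition(
            K=2, labels={f"T{i:02d}": int(labels[i]) for i in range(m)}
        )
        informers, model = greedy_group_lasso_informers(X, part, n_A=1)
        assert informers.compound_ids == ["C"]
        norms = model.group_norms()
        assert norms[2] == max(norms)

    def test_zero_n_A_rejected(self, crisp_small):
        Xs, _ = scale_columns_unit_interval(crisp_small["X"])
        part = kmeans_multi_restart(Xs, 3, restarts=5, seed=0)
        with pytest.raises(ValueError):
            greedy_group_lasso_informers(Xs, part, n_A=0)

    def test_planted_informative_columns_selected(self, crisp_small):
        X, truth = crisp_small["X"], crisp_small["truth"]
        Xs, _ = scale_columns_unit_interval(X)
        part = kmeans_multi_restart(Xs, 3, restarts=50, seed=1)
        informers, _ = greedy_group_lasso_informers(Xs, part, n_A=5)
        overlap = set(informers.compound_ids) & set(truth.informative_compounds)
        assert len(overlap) >= 4

    def test_prefix_property_of_greedy_selection(self, crisp_small):
        Xs, _ = scale_columns_unit_interval(crisp_small["X"])
        part = kmeans_multi_restart(Xs, 3, restarts=20, seed=2)
        small, _ = greedy_group_lasso_informers(Xs, part, n_A=3)
        large, _ = greedy_group_lasso_informers(Xs, part, n_A=6)
        assert large.compound_ids[:3] == small.compound_ids

    def test_refit_zeroes_off_set_groups_and_improves_likelihood(self, crisp_small):
        X = crisp_small["X"]
        Xs, _ = scale_columns_unit_interval(X)
        part = kmeans_multi_restart(Xs, 3, restarts=20, seed=3)
        informers, penalized = greedy_group_lasso_informers(Xs, part, n_A=4)
        refit = refit_unpenalized(Xs, part, informers)
        cols = Xs.compound_indices(informers.compound_ids)
        off = np.ones(Xs.n, dtype=bool)
        off[cols] = False
        assert np.all(refit.weights[:, off] == 0.0)
        y = part.label_array(Xs.target_ids)
        assert refit.log_likelihood(Xs.values, y) >= penalized.log_likelihood(
            Xs.values, y
        ) - 1e-6


class TestPrediction:
    def test_zero_model_gives_uniform_probabilities(self, toy_matrix):
        model = MultinomialModel(
            intercepts=np.zeros(3), weights=np.zeros((3, 5)), K=3, lam=0.0
        )
        informers = InformerSet(compound_ids=["C1", "C2"])
        probs = predict_cluster_probabilities(
            model, np.array([0.3, 0.8]), informers, toy_matrix
        )
        np.testing.assert_allclose(probs, 1 / 3)

    def test_scaled_weights_approach_argmax(self, toy_matrix):
        w = np.zeros((2, 5))
        w[0, 0], w[1, 0] = 1.0, -1.0
        informers = InformerSet(compound_ids=["C1"])
        for t, expect in ((1.0, 0.881), (50.0, 1.0)):
            model = MultinomialModel(
                intercepts=np.zeros(2), weights=t * w, K=2, lam=0.0
            )
            probs = predict_cluster_probabilities(
                model, np.array([1.0]), informers, toy_matrix
            )
            assert probs[0] == pytest.approx(expect, abs=0.01)

    def test_hand_computed_softmax(self, toy_matrix):
        model = MultinomialModel(
            intercepts=np.array([0.5, -0.5]),
            weights=np.array([[1.0, 2.0, 0, 0, 0], [0.5, -1.0, 0, 0, 0]]),
            K=2,
            lam=0.0,
        )
        informers = InformerSet(compound_ids=["C1", "C2"])
        x = np.array([0.2, 0.7])
        probs = predict_cluster_probabilities(model, x, informers, toy_matrix)
        logits = np.array([0.5 + 0.2 + 1.4, -0.5 + 0.1 - 0.7])
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(probs, expected, rtol=1e-12)


class TestRanking:
    def _setup(self, toy_matrix):
        part = TargetPartition(
            K=2, labels={"T1": 0, "T2": 0, "T3": 1, "T4": 1}
        )
        informers = InformerSet(compound_ids=["C1"])
        return part, informers

    def test_one_hot_probs_rank_by_cluster_centroid(self, toy_matrix):
        part, informers = self._setup(toy_matrix)
        ids, scores = rs_rank_compounds(
            np.array([0.0, 1.0]), part, toy_matrix, informers
        )
        centroid = toy_matrix.values[2:].mean(axis=0)[1:]
        order = np.argsort(-centroid, kind="stable")
        expected = [["C2", "C3", "C4", "C5"][i] for i in order]
        assert ids == expected

    def test_uniform_probs_match_brute_force_average(self, toy_matrix):
        part, informers = self._setup(toy_matrix)
        ids, scores = rs_rank_compounds(
            np.array([0.5, 0.5]), part, toy_matrix, informers
        )
        cent0 = toy_matrix.values[:2].mean(axis=0)
        cent1 = toy_matrix.values[2:].mean(axis=0)
        mu = 0.5 * cent0 + 0.5 * cent1
        expected = {c: mu[j] for j, c in enumerate(toy_matrix.compound_ids) if c != "C1"}
        for c, s in zip(ids, scores):
            assert s == pytest.approx(expected[c])

    def test_scores_bounded_by_data_range(self, planted):
        X = planted["X"]
        Xs, _ = scale_columns_unit_interval(X)
        part = kmeans_multi_restart(Xs, 3, restarts=10, seed=0)
        informers = InformerSet(compound_ids=X.compound_ids[:4])
        probs = np.array([0.2, 0.3, 0.5])
        _, scores = rs_rank_compounds(probs, part, Xs, informers)
        assert scores.min() >= Xs.values.min() - 1e-12
        assert scores.max() <= Xs.values.max() + 1e-12


class TestKSelection:
    def test_recovers_planted_K(self):
        # K must matter for ranking quality: under-clustering blends two
        # clusters' informative compounds, over-clustering changes nothing,
        # so the CV score peaks (then ties) at the planted K
        from ibrank.synthetic import SyntheticSpec, generate_matrix

        spec = SyntheticSpec(
            m=60, n=50, K=3, n_informative=9, cluster_sep=80.0, noise_sd=2.0,
            active_fraction_range=(0.06, 0.0899), seed=13,
        )
        X, _ = generate_matrix(spec)
        K, diag = select_K_by_cv(
            X, K_grid=[2, 3, 4], n_A=4, folds=3, seed=1, restarts=10
        )
        assert K == 3
        assert diag["mean_scores"][2] < diag["mean_scores"][3]

    def test_too_many_folds_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            select_K_by_cv(toy_matrix, [2], n_A=2, folds=5, seed=0)

    def test_deterministic_given_seed(self, crisp_small):
        args = dict(K_grid=[2, 3], n_A=4, folds=3, restarts=5)
        K1, d1 = select_K_by_cv(crisp_small["X"], seed=9, **args)
        K2, d2 = select_K_by_cv(crisp_small["X"], seed=9, **args)
        assert K1 == K2 and d1["mean_scores"] == d2["mean_scores"]


class TestEstimator:
    def test_fit_rank_contract(self, crisp_small):
        X, truth = crisp_small["X"], crisp_small["truth"]
        rs = RegressionSelector(n_informers=5, n_clusters=3, restarts=20, seed=0)
        rs.fit(X)
        assert len(rs.informers_) == 5
        from ibrank.synthetic import generate_new_target

        assays = generate_new_target(truth, 0, crisp_small["spec"].noise_sd, seed=5)
        revealed = {c: assays[c] for c in rs.informers_.compound_ids}
        result = rs.rank(revealed)
        assert set(result.compound_ids).isdisjoint(rs.informers_.compound_ids)
        assert len(result.compound_ids) == X.n - 5
        assert rs.cluster_probabilities_.sum() == pytest.approx(1.0)

    def test_missing_informer_assay_rejected(self, crisp_small):
        rs = RegressionSelector(n_informers=3, n_clusters=3, restarts=5, seed=0)
        rs.fit(crisp_small["X"])
        with pytest.raises(ValueError, match="missing"):
            rs.rank({rs.informers_.compound_ids[0]: 1.0})

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        rs = RegressionSelector(n_informers=7, seed=3)
        rs2 = clone(rs)
        assert rs2.get_params() == rs.get_params()
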