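"""Coding selection: code words, the pair-distance objective vs a
brute-force oracle, Monte-Carlo search consistency, activity-rate ranking."""

import itertools

import numpy as np
import pytest

from ibrank.coding import (
    activity_rate_ranking,
    assign_code_word,
    asymmetric_binary_distance,
    build_code_word_table,
    choose_kappa,
    cs_informer_scores,
    cs_objective,
    estimate_fdr,
    sample_candidate,
    CodingSelector,
)
from ibrank.matrix import BinaryActivityMatrix, BioactivityMatrix, InformerSet


def brute_force_objective(Zvals, informer_cols, word_blocks, lam):
    """Independent O(m^2) double loop over unordered within-block pairs."""
    m, n = Zvals.shape
    informer_cols = set(informer_cols)
    comp = [j for j in range(n) if j not in informer_cols]

    # code word index per target, in first-occurrence order
    seen = {}
    word_of = []
    for i in range(m):
        key = tuple(Zvals[i, sorted(informer_cols)])
        if key not in seen:
            seen[key] = len(seen)
        word_of.append(seen[key])
    L_A = len(seen)
    blocks = [word_blocks[w] for w in word_of]

    total = 0.0
    for i in range(m):
        for i2 in range(i + 1, m):
            if blocks[i] != blocks[i2]:
                continue
            inter = sum(Zvals[i, j] and Zvals[i2, j] for j in comp)
            union = sum(Zvals[i, j] or Zvals[i2, j] for j in comp)
            total += 0.0 if union == 0 else 1.0 - inter / union
    return total - lam * L_A


def exhaustive_best(Z, n_A, K, lam):
    """Minimum objective over every informer set and word partition."""
    best = np.inf
    for cols in itertools.combinations(range(Z.n), n_A):
        sub = Z.values[:, list(cols)]
        L_A = len({tuple(r) for r in sub})
        k_eff = min(K, L_A)
        for assignment in itertools.product(range(k_eff), repeat=L_A):
            val = brute_force_objective(Z.values, cols, list(assignment), lam)
            best = min(best, val)
    return best


def binary(rows, target_prefix="T", compound_prefix="C"):
    rows = np.array(rows, dtype=np.int8)
    m, n = rows.shape
    return BinaryActivityMatrix(
        values=rows,
        thresholds=np.zeros(m),
        target_ids=[f"{target_prefix}{i}" for i in range(m)],
        compound_ids=[f"{compound_prefix}{j}" for j in range(n)],
    )


class TestCodeWords:
    def test_patterns_grouped_by_identity(self):
        Z = binary([[0, 0, 1], [0, 0, 0], [0, 1, 1], [1, 1, 0]])
        X = BioactivityMatrix(
            values=np.arange(12, dtype=float).reshape(4, 3),
            target_ids=Z.target_ids,
            compound_ids=Z.compound_ids,
        )
        A = InformerSet(compound_ids=["C0", "C1"])
        table = build_code_word_table(Z, X, A)
        # patterns on (C0, C1): 00, 00, 01, 11
        assert table.L_A == 3
        assert [len(mem) for mem in table.members] == [2, 1, 1]
        # centroid of the 00 word = mean raw informer activities of T0, T1
        np.testing.assert_allclose(table.centroids[0], [(0 + 3) / 2, (1 + 4) / 2])

    def test_all_identical_single_word(self):
        Z = binary([[1, 0, 1]] * 4)
        X = BioactivityMatrix(
            values=np.ones((4, 3)), target_ids=Z.target_ids, compound_ids=Z.compound_ids
        )
        table = build_code_word_table(Z, X, InformerSet(compound_ids=["C0", "C2"]))
        assert table.L_A == 1 and len(table.members[0]) == 4

    def test_all_distinct_one_word_per_target(self):
        Z = binary([[0, 0], [0, 1], [1, 0], [1, 1]])
        X = BioactivityMatrix(
            values=np.eye(4, 2), target_ids=Z.target_ids, compound_ids=Z.compound_ids
        )
        table = build_code_word_table(Z, X, InformerSet(compound_ids=["C0", "C1"]))
        assert table.L_A == 4


class TestAsymmetricDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 1, 0], [1, 0, 0], 0.5),
            ([1, 0, 1], [1, 0, 1], 0.0),
            ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),
            ([0, 0, 0], [0, 0, 0], 0.0),  # identical inactivity
        ],
    )
    def test_hand_counts(self, a, b, expected):
        assert asymmetric_binary_distance(np.array(a), np.array(b)) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            asymmetric_binary_distance(np.array([1]), np.array([1, 0]))


class TestObjective:
    def test_homogeneous_blocks_give_minus_lambda_L(self):
        Z = binary([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]])
        A = InformerSet(compound_ids=["C0", "C1"])
        # two words (00, 11); separate blocks; identical rows within block
        val = cs_objective(Z, A, [0, 1], lam=5.0)
        assert val == pytest.approx(-10.0)

    def test_singleton_blocks_no_pairs(self):
        Z = binary([[0, 0, 1], [0, 1, 0], [1, 0, 0]])
        A = InformerSet(compound_ids=["C0", "C1"])
        table_words = 3
        val = cs_objective(Z, A, list(range(table_words)), lam=2.0)
        assert val == pytest.approx(-2.0 * table_words)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = int(rng.integers(2, 9))
            n = int(rng.integers(3, 9))
            Z = binary(rng.integers(0, 2, size=(m, n)))
            n_A = int(rng.integers(1, min(n, 4)))
            cols = sorted(rng.choice(n, size=n_A, replace=False).tolist())
            A = InformerSet(compound_ids=[Z.compound_ids[j] for j in cols])
            L_A = len({tuple(r) for r in Z.values[:, cols]})
            blocks = rng.integers(0, 2, size=L_A).tolist()
            lam = float(rng.uniform(0, 10))
            assert cs_objective(Z, A, blocks, lam) == pytest.approx(
                brute_force_objective(Z.values, cols, blocks, lam)
            )


class TestSampling:
    def test_determinism_and_block_compaction(self):
        rng = np.random.default_rng(5)
        Z = binary(np.random.default_rng(1).integers(0, 2, size=(6, 8)))
        a1, b1 = sample_candidate(Z, 3, 4, np.random.default_rng(5))
        a2, b2 = sample_candidate(Z, 3, 4, np.random.default_rng(5))
        assert a1.compound_ids == a2.compound_ids and b1 == b2
        assert sorted(set(b1)) == list(range(len(set(b1))))

    def test_K1_single_block(self):
        Z = binary(np.random.default_rng(2).integers(0, 2, size=(5, 6)))
        _, blocks = sample_candidate(Z, 2, 1, np.random.default_rng(0))
        assert set(blocks) == {0}

    def test_full_library_informer_set(self):
        Z = binary(np.random.default_rng(3).integers(0, 2, size=(4, 5)))
        A, _ = sample_candidate(Z, 5, 2, np.random.default_rng(0))
        assert sorted(A.compound_ids) == Z.compound_ids


class TestMonteCarloScores:
    def test_deterministic_given_seed(self):
        Z = binary(np.random.default_rng(4).integers(0, 2, size=(6, 8)))
        r1, i1 = cs_informer_scores(Z, n_A=2, K_set=(2,), lam=5.0, B=200, seed=9)
        r2, i2 = cs_informer_scores(Z, n_A=2, K_set=(2,), lam=5.0, B=200, seed=9)
        assert i1.compound_ids == i2.compound_ids
        assert r1.scores == r2.scores

    def test_exchangeable_compounds_score_together(self):
        # two identical columns must have scores within 3 MC standard errors
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 2, size=(6, 6))
        rows[:, 5] = rows[:, 4]
        Z = binary(rows)
        record, _ = cs_informer_scores(Z, n_A=2, K_set=(2,), lam=5.0, B=4000, seed=1)
        vals = [record.scores[c] for c in ("C4", "C5")]
        se = np.hypot(record.score_se["C4"], record.score_se["C5"])
        assert abs(vals[0] - vals[1]) <= 3 * se

    def test_monte_carlo_reaches_exhaustive_optimum_small_space(self):
        rng = np.random.default_rng(12)
        Z = binary(rng.integers(0, 2, size=(5, 6)))
        target = exhaustive_best(Z, n_A=2, K=2, lam=5.0)
        record, _ = cs_informer_scores(Z, n_A=2, K_set=(2,), lam=5.0, B=3000, seed=3)
        assert record.best_objective == pytest.approx(target)


class TestRanking:
    def test_assign_word_zero_distance_and_tie_rule(self):
        table_words = np.array([[0, 0], [1, 1], [1, 0]], dtype=np.int8)
        from ibrank.coding import CodeWordTable

        table = CodeWordTable(
            words=table_words,
            members=[["T0"], ["T1"], ["T2"]],
            centroids=np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 0.0]]),
            informer_ids=["C0", "C1"],
        )
        assert assign_code_word(np.array([10.0, 10.0]), table) == 1
        # midway between words 0 and 1: lowest index wins
        assert assign_code_word(np.array([5.0, 5.0]), table) == 0

    def test_activity_rates_match_hand_count(self):
        Z = binary(
            [
                [1, 0, 1, 1, 0],
                [1, 0, 1, 0, 1],
                [1, 0, 0, 1, 1],
                [0, 1, 0, 0, 0],
            ]
        )
        X = BioactivityMatrix(
            values=Z.values.astype(float) * 50,
            target_ids=Z.target_ids,
            compound_ids=Z.compound_ids,
        )
        A = InformerSet(compound_ids=["C0", "C1"])
        table = build_code_word_table(Z, X, A)
        # word 0 = pattern (1, 0) with members T0, T1, T2
        rr, ids, scores = activity_rate_ranking(Z, A, 0, table)
        assert rr.n_star == 3
        assert rr.rates == {"C2": 2, "C3": 2, "C4": 2}

    def test_single_matched_target_rates_equal_row(self):
        Z = binary([[1, 0, 1, 0], [0, 1, 0, 1]])
        X = BioactivityMatrix(
            values=Z.values * 10.0,
            target_ids=Z.target_ids,
            compound_ids=Z.compound_ids,
        )
        A = InformerSet(compound_ids=["C0"])
        table = build_code_word_table(Z, X, A)
        rr, ids, _ = activity_rate_ranking(Z, A, 0, table)
        assert rr.rates == {"C1": 0, "C2": 1, "C3": 0}
        assert ids[0] == "C2"

    def test_ranking_invariant_to_compound_permutation(self):
        rng = np.random.default_rng(6)
        rows = rng.integers(0, 2, size=(6, 7))
        Z = binary(rows)
        X = BioactivityMatrix(
            values=rows * 30.0, target_ids=Z.target_ids, compound_ids=Z.compound_ids
        )
        A = InformerSet(compound_ids=["C1", "C4"])
        table = build_code_word_table(Z, X, A)
        _, ids, _ = activity_rate_ranking(Z, A, 0, table)

        perm = rng.permutation(7)
        Zp = BinaryActivityMatrix(
            values=rows[:, perm],
            thresholds=Z.thresholds,
            target_ids=Z.target_ids,
            compound_ids=[Z.compound_ids[j] for j in perm],
        )
        Xp = BioactivityMatrix(
            values=rows[:, perm] * 30.0,
            target_ids=Z.target_ids,
            compound_ids=[Z.compound_ids[j] for j in perm],
        )
        tablep = build_code_word_table(Zp, Xp, A)
        _, idsp, _ = activity_rate_ranking(Zp, A, 0, tablep)
        assert ids == idsp


class TestFdr:
    def test_all_full_rate_zero_fdr(self):
        from ibrank.coding import ActivityRateRanking

        rr = ActivityRateRanking(rates={"a": 4, "b": 4}, n_star=4, word_index=0)
        assert estimate_fdr(rr, 4) == 0.0

    def test_half_rate_single_selection(self):
        from ibrank.coding import ActivityRateRanking

        rr = ActivityRateRanking(rates={"a": 2, "b": 0}, n_star=4, word_index=0)
        assert estimate_fdr(rr, 1) == 0.5

    def test_mixed_rates_match_formula(self):
        from ibrank.coding import ActivityRateRanking

        rates = {"a": 5, "b": 3, "c": 2, "d": 0}
        rr = ActivityRateRanking(rates=rates, n_star=5, word_index=0)
        kappa = 2
        sel = [v for v in rates.values() if v >= kappa]
        expected = 1 - sum(v / 5 for v in sel) / len(sel)
        assert estimate_fdr(rr, kappa) == pytest.approx(expected)
        # kappa=2 selects {5,3,2}: FDR = 1 - 2/3 <= 0.35 already
        assert choose_kappa(rr, fdr_max=0.35) == 2
        assert choose_kappa(rr, fdr_max=0.25) == 3


class TestSelectorEndToEnd:
    def test_informer_set_size_and_determinism(self, planted):
        sel = CodingSelector(n_informers=8, K_set=(2, 3, 4), B=300, seed=5)
        sel.fit(planted["X"])
        sel2 = CodingSelector(n_informers=8, K_set=(2, 3, 4), B=300, seed=5)
        sel2.fit(planted["X"])
        assert len(sel.informers_) == 8
        assert sel.informers_.compound_ids == sel2.informers_.compound_ids
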