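"""Coding Selection (CS).

CS works on the binarized activity matrix.  The distinct binary patterns
of the targets across a candidate informer set A are *code words*; a
partition pi of the code words induces a clustering of targets, and the
pair (A, pi) is scored by how heterogeneous the clusters are on the
non-informer compounds (asymmetric binary distance summed over
within-cluster target pairs) minus a reward lambda * L_A for code-word
diversity.  The combinatorial search over (A, pi) is Monte Carlo: many
random candidates are drawn, and each compound is scored marginally by
the average objective of the candidates containing it (Eq-style
stabilization); the informer set collects the lowest-scoring compounds.

At ranking time the new target's informer readouts are matched to the
nearest code-word centroid (mean raw informer activities of the member
targets), and non-informers are ranked by their activity rates among the
matched targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .base import InformerStrategy, RankingResult
from .matrix import (
    BinaryActivityMatrix,
    BioactivityMatrix,
    InformerSet,
    binarize_matrix,
)

__all__ = [
    "CodeWordTable",
    "build_code_word_table",
    "asymmetric_binary_distance",
    "pairwise_asymmetric_distance",
    "cs_objective",
    "sample_candidate",
    "cs_informer_scores",
    "assign_code_word",
    "activity_rate_ranking",
    "estimate_fdr",
    "choose_kappa",
    "CSScoreRecord",
    "ActivityRateRanking",
    "CodingSelector",
]


@dataclass
class CodeWordTable:
    """Distinct informer-column binary patterns with members and centroids.

    Words are ordered by first occurrence among the targets.  The
    centroid of a word is the mean *raw* informer-activity row of its
    member targets, used to place a new target's intermediate data.
    """

    words: np.ndarray  # (L_A, n_A) of 0/1
    members: list[list[str]]
    centroids: np.ndarray  # (L_A, n_A) real
    informer_ids: list[str]

    @property
    def L_A(self) -> int:
        return self.words.shape[0]


def build_code_word_table(
    Z: BinaryActivityMatrix, X: BioactivityMatrix, informers: InformerSet
) -> CodeWordTable:
    """Group targets by identical binary pattern on the informer columns."""
    cols = Z.compound_indices(informers.compound_ids)
    sub = Z.values[:, cols]
    raw = X.values[:, X.compound_indices(informers.compound_ids)]
    index: dict[bytes, int] = {}
    members: list[list[str]] = []
    words: list[np.ndarray] = []
    for i, row in enumerate(sub):
        key = row.tobytes()
        if key not in index:
            index[key] = len(words)
            words.append(row.copy())
            members.append([])
        members[index[key]].append(Z.target_ids[i])
    word_arr = np.array(words, dtype=np.int8)
    centroids = np.empty((len(words), len(cols)))
    tpos = {t: i for i, t in enumerate(Z.target_ids)}
    for l, mem in enumerate(members):
        centroids[l] = raw[[tpos[t] for t in mem]].mean(axis=0)
    return CodeWordTable(
        words=word_arr,
        members=members,
        centroids=centroids,
        informer_ids=list(informers.compound_ids),
    )


def asymmetric_binary_distance(z1: np.ndarray, z2: np.ndarray) -> float:
    """1 - |intersection| / |union| over active positions.

    Among compounds active on either target, the fraction not active on
    both.  Two all-zero vectors are identically inactive and get
    distance 0 (the 0/0 case of the formula).
    """
    z1 = np.asarray(z1)
    z2 = np.asarray(z2)
    if z1.shape != z2.shape:
        raise ValueError("vectors must have equal length")
    inter = int(np.sum((z1 == 1) & (z2 == 1)))
    union = int(np.sum((z1 == 1) | (z2 == 1)))
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def pairwise_asymmetric_distance(Zvals: np.ndarray) -> np.ndarray:
    """(m, m) asymmetric binary distance matrix over rows of a 0/1 array."""
    Zf = Zvals.astype(float)
    inter = Zf @ Zf.T
    s = Zf.sum(axis=1)
    union = s[:, None] + s[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    return d


def _induced_blocks(
    Z: BinaryActivityMatrix, informer_cols: np.ndarray, word_blocks: Sequence[int]
) -> tuple[np.ndarray, int]:
    """Target block labels induced by a code-word partition."""
    sub = Z.values[:, informer_cols]
    index: dict[bytes, int] = {}
    for row in sub:
        key = row.tobytes()
        if key not in index:
            index[key] = len(index)
    labels = np.array([word_blocks[index[row.tobytes()]] for row in sub], dtype=int)
    return labels, len(index)


def cs_objective(
    Z: BinaryActivityMatrix,
    informers: InformerSet,
    word_blocks: Sequence[int],
    lam: float = 5.0,
) -> float:
    """Code-word objective: within-cluster pair distances minus lambda*L_A.

    ``word_blocks[l]`` assigns code word l (first-occurrence order) to a
    partition block.  The inner sum runs over unordered within-block
    target pairs of the asymmetric binary distance restricted to
    non-informer columns.
    """
    cols = Z.compound_indices(informers.compound_ids)
    labels, L_A = _induced_blocks(Z, cols, word_blocks)
    if len(word_blocks) != L_A:
        raise ValueError(f"partition covers {len(word_blocks)} words, table has {L_A}")
    mask = np.ones(Z.n, dtype=bool)
    mask[cols] = False
    d = pairwise_asymmetric_distance(Z.values[:, mask])
    total = 0.0
    for k in set(labels.tolist()):
        idx = np.where(labels == k)[0]
        if len(idx) > 1:
            block = d[np.ix_(idx, idx)]
            total += float(np.triu(block, k=1).sum())
    return total - lam * L_A


def sample_candidate(
    Z: BinaryActivityMatrix, n_A: int, K: int, rng: np.random.Generator
) -> tuple[InformerSet, list[int]]:
    """Draw a uniform random informer set and code-word partition.

    Each code word is assigned independently and uniformly to one of
    min(K, L_A) blocks; empty blocks are dropped and indices compacted.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    cols = rng.choice(Z.n, size=n_A, replace=False)
    cols.sort()
    informers = InformerSet(
        compound_ids=[Z.compound_ids[j] for j in cols], method="cs-sample"
    )
    sub = Z.values[:, cols]
    L_A = len({row.tobytes() for row in sub})
    k_eff = min(K, L_A)
    raw = rng.integers(0, k_eff, size=L_A)
    # compact empty blocks
    remap: dict[int, int] = {}
    blocks = []
    for b in raw:
        if int(b) not in remap:
            remap[int(b)] = len(remap)
        blocks.append(remap[int(b)])
    return informers, blocks


@dataclass
class CSScoreRecord:
    """Marginal Monte-Carlo compound scores and the best sampled candidate."""

    scores: dict[str, float]
    B: int
    K_set: tuple[int, ...]
    lam: float
    best_objective: float = float("inf")
    best_informers: InformerSet | None = None
    best_blocks: list[int] = field(default_factory=list)
    n_sampled: dict[str, int] = field(default_factory=dict)
    score_se: dict[str, float] = field(default_factory=dict)


def cs_informer_scores(
    Z: BinaryActivityMatrix,
    n_A: int,
    K_set: Sequence[int] = tuple(range(2, 41)),
    lam: float = 5.0,
    B: int = 100_000,
    seed: int = 0,
) -> tuple[CSScoreRecord, InformerSet]:
    """Monte-Carlo marginal scores f_j and the resulting informer set.

    For each K in ``K_set``, B candidates (A, pi) are drawn; compound j
    accrues (1/B) * objective for every candidate containing it, summed
    over K.  The informer set takes the n_A lowest-scoring compounds
    (ties by compound ID).  Compounds never sampled score +inf and are
    never selected; if fewer than n_A compounds were ever sampled the
    search errs, advising a larger B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not K_set:
        raise ValueError("K_set must be non-empty")
    rng = np.random.default_rng(seed)

    # Decomposition: the pair distance on A-complement columns is
    # computed from whole-matrix and informer-column intersections, so a
    # trial costs O(m^2 n_A) instead of O(m^2 n).
    Zf = Z.values.astype(float)
    inter_all = Zf @ Zf.T
    s_all = Zf.sum(axis=1)

    totals = np.zeros(Z.n)
    counts = np.zeros(Z.n, dtype=int)
    se2 = np.zeros(Z.n)  # variance of the per-K trial means, summed over K
    best = (np.inf, None, None)
    for K in K_set:
        k_sum = np.zeros(Z.n)
        k_sq = np.zeros(Z.n)
        for _ in range(B):
            cols = rng.choice(Z.n, size=n_A, replace=False)
            cols.sort()
            sub = Z.values[:, cols]
            index: dict[bytes, int] = {}
            word_of = np.empty(Z.m, dtype=int)
            for i, row in enumerate(sub):
                key = row.tobytes()
                if key not in index:
                    index[key] = len(index)
                word_of[i] = index[key]
            L_A = len(index)
            k_eff = min(K, L_A)
            word_blocks = rng.integers(0, k_eff, size=L_A)
            labels = word_blocks[word_of]

            subf = sub.astype(float)
            inter_c = inter_all - subf @ subf.T
            s_c = s_all - subf.sum(axis=1)
            union_c = s_c[:, None] + s_c[None, :] - inter_c
            obj = -lam * L_A
            for k in np.unique(labels):
                idx = np.where(labels == k)[0]
                if len(idx) > 1:
                    iu = np.triu_indices(len(idx), k=1)
                    un = union_c[np.ix_(idx, idx)][iu]
                    it = inter_c[np.ix_(idx, idx)][iu]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        dd = 1.0 - it / un
                    dd[un == 0] = 0.0
                    obj += float(dd.sum())

            k_sum[cols] += obj
            k_sq[cols] += obj * obj
            counts[cols] += 1
            if obj < best[0]:
                # compact blocks for reporting
                remap: dict[int, int] = {}
                blocks = []
                for b in word_blocks:
                    if int(b) not in remap:
                        remap[int(b)] = len(remap)
                    blocks.append(remap[int(b)])
                best = (obj, [Z.compound_ids[j] for j in cols], blocks)
        totals += k_sum / B
        se2 += np.maximum(k_sq / B - (k_sum / B) ** 2, 0.0) / B

    scores = np.where(counts > 0, totals, np.inf)
    n_finite = int((counts > 0).sum())
    if n_finite < n_A:
        raise RuntimeError(
            f"only {n_finite} compounds were ever sampled (< n_A={n_A}); "
            "increase the number of Monte-Carlo trials B"
        )
    order = sorted(range(Z.n), key=lambda j: (scores[j], Z.compound_ids[j]))
    chosen = [Z.compound_ids[j] for j in order[:n_A]]
    record = CSScoreRecord(
        scores={Z.compound_ids[j]: float(scores[j]) for j in range(Z.n)},
        B=B,
        K_set=tuple(K_set),
        lam=lam,
        best_objective=best[0],
        best_informers=InformerSet(compound_ids=best[1], method="cs-best-sample")
        if best[1]
        else None,
        best_blocks=best[2] or [],
        n_sampled={Z.compound_ids[j]: int(counts[j]) for j in range(Z.n)},
        score_se={Z.compound_ids[j]: float(np.sqrt(se2[j])) for j in range(Z.n)},
    )
    informers = InformerSet(
        compound_ids=chosen,
        method="cs",
        diagnostics={"B": B, "lambda": lam, "K_set": tuple(K_set)},
    )
    return record, informers


def assign_code_word(assay_values: np.ndarray, table: CodeWordTable) -> int:
    """Index of the code word whose centroid is nearest in Euclidean distance.

    Ties go to the lowest word index (first-occurrence order).
    """
    x = np.asarray(assay_values, dtype=float)
    d = np.linalg.norm(table.centroids - x[None, :], axis=1)
    return int(np.argmin(d))  # argmin takes the first (lowest) index on ties


@dataclass
class ActivityRateRanking:
    """Non-informer activity counts among code-word-matched targets."""

    rates: dict[str, int]
    n_star: int
    word_index: int
    kappa: float | None = None
    fdr_estimate: float | None = None


def activity_rate_ranking(
    Z: BinaryActivityMatrix,
    informers: InformerSet,
    word_index: int,
    table: CodeWordTable,
) -> tuple[ActivityRateRanking, list[str], np.ndarray]:
    """Rank non-informers by activity count among the matched targets.

    Ties break by descending whole-matrix column activity mean, then by
    compound ID.
    """
    members = table.members[word_index]
    tpos = {t: i for i, t in enumerate(Z.target_ids)}
    rows = [tpos[t] for t in members]
    informer_cols = set(Z.compound_indices(informers.compound_ids).tolist())
    counts = Z.values[rows].sum(axis=0)
    col_mean = Z.values.mean(axis=0)
    entries = [
        (j, Z.compound_ids[j])
        for j in range(Z.n)
        if j not in informer_cols
    ]
    entries.sort(key=lambda e: (-counts[e[0]], -col_mean[e[0]], e[1]))
    ids = [c for _, c in entries]
    scores = np.array([counts[j] for j, _ in entries], dtype=float)
    rates = {c: int(counts[j]) for j, c in entries}
    return (
        ActivityRateRanking(rates=rates, n_star=len(members), word_index=word_index),
        ids,
        scores,
    )


def estimate_fdr(ranking: ActivityRateRanking, kappa: float) -> float:
    """Crude FDR estimate for the selection {j : a_j >= kappa}.

    Treats a_j / n* as the Bernoulli success probability of activity on
    the new target.  Returns NaN when nothing is selected at kappa.
    """
    if ranking.n_star < 1:
        raise ValueError("need at least one matched target")
    rates = np.array(list(ranking.rates.values()), dtype=float)
    sel = rates >= kappa
    if not sel.any():
        return float("nan")
    return float(1.0 - (rates[sel] / ranking.n_star).sum() / sel.sum())


def choose_kappa(ranking: ActivityRateRanking, fdr_max: float = 0.1) -> float | None:
    """Smallest kappa whose crude FDR estimate is at most ``fdr_max``."""
    for kappa in sorted(set(ranking.rates.values())):
        if kappa == 0:
            continue
        est = estimate_fdr(ranking, kappa)
        if np.isfinite(est) and est <= fdr_max:
            return float(kappa)
    return None


class CodingSelector(InformerStrategy):
    """CS strategy as a scikit-learn style estimator.

    Parameters
    ----------
    n_informers : informer set size (default 16).
    K_set : cluster counts entertained by the Monte-Carlo search
        (default 2..40).
    lam : code-word-count weight in the objective (default 5).
    B : Monte-Carlo trials per K (default 100_000; production analyses
        use 10^6 or more, tests far fewer).
    seed : RNG seed for the candidate draws.
    """

    method = "cs"

    def __init__(
        self,
        n_informers: int = 16,
        K_set: tuple[int, ...] = tuple(range(2, 41)),
        lam: float = 5.0,
        B: int = 100_000,
        seed: int = 0,
    ):
        self.n_informers = n_informers
        self.K_set = K_set
        self.lam = lam
        self.B = B
        self.seed = seed

    def _fit(self, X: BioactivityMatrix) -> InformerSet:
        self.Z_ = binarize_matrix(X)
        self.score_record_, informers = cs_informer_scores(
            self.Z_,
            n_A=self.n_informers,
            K_set=self.K_set,
            lam=self.lam,
            B=self.B,
            seed=self.seed,
        )
        self.table_ = build_code_word_table(self.Z_, X, informers)
        return informers

    def _rank(self, values: np.ndarray) -> RankingResult:
        word = assign_code_word(values, self.table_)
        self.rate_ranking_, ids, scores = activity_rate_ranking(
            self.Z_, self.informers_, word, self.table_
        )
        self.rate_ranking_.kappa = choose_kappa(self.rate_ranking_)
        if self.rate_ranking_.kappa is not None:
            self.rate_ranking_.fdr_estimate = estimate_fdr(
                self.rate_ranking_, self.rate_ranking_.kappa
            )
        return self._result(ids, scores, values)
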