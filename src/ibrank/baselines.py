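"""Chemometric (BC) and frequent-hitter (BF) baseline strategies.

BC picks informers by chemical diversity: average-linkage agglomerative
clustering of the library on Morgan-fingerprint Jaccard distances, one
medoid per cluster.  BF picks the most promiscuous compounds — those
active on the most matrix targets.  Both rank the non-informers by
chemical proximity to the assayed informers with one of three hit
expansions: simple (distance to nearest active informer), loop
(round-robin over active informers by activity), or weighted (inner
product of Jaccard similarities with the normalized informer activity
vector).

Fingerprints and scaffolds sit behind a provider interface: supply a
precomputed bit matrix (no chemistry needed) or SMILES for RDKit Morgan
fingerprints (radius 2, 1024 bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .base import InformerStrategy, RankingResult, rank_descending
from .matrix import (
    BinaryActivityMatrix,
    BioactivityMatrix,
    InformerSet,
    binarize_matrix,
)

__all__ = [
    "FingerprintMatrix",
    "compute_fingerprints",
    "jaccard_distance_matrix",
    "bc_informers",
    "bf_informers",
    "infer_informer_labels",
    "simple_expansion",
    "loop_expansion",
    "weighted_expansion",
    "ChemometricBaseline",
    "FrequentHitterBaseline",
]


@dataclass
class FingerprintMatrix:
    """Binary fingerprint bits per compound, rows aligned to compound IDs."""

    bits: np.ndarray
    compound_ids: list[str]
    provider: str = "supplied"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.compound_ids):
            raise ValueError("one fingerprint row per compound required")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")

    def reindex(self, compound_ids) -> "FingerprintMatrix":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        try:
            rows = [pos[str(c)] for c in compound_ids]
        except KeyError as exc:
            raise KeyError(f"no fingerprint for compound {exc.args[0]!r}") from None
        return FingerprintMatrix(
            bits=self.bits[rows],
            compound_ids=[str(c) for c in compound_ids],
            provider=self.provider,
        )


def compute_fingerprints(
    smiles: list[str],
    compound_ids: list[str] | None = None,
    radius: int = 2,
    n_bits: int = 1024,
) -> tuple[FingerprintMatrix, list[int]]:
    """Morgan (circular) fingerprints from SMILES via RDKit.

    Unparseable SMILES are excluded with a warning; their indices are
    returned alongside the fingerprint matrix.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    if compound_ids is None:
        compound_ids = [f"C{i}" for i in range(len(smiles))]
    rows, ids, failed = [], [], []
    for i, (smi, cid) in enumerate(zip(smiles, compound_ids)):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            failed.append(i)
            continue
        fp = gen.GetFingerprintAsNumPy(mol)
        rows.append(np.asarray(fp, dtype=np.int8))
        ids.append(str(cid))
    if failed:
        warnings.warn(
            f"{len(failed)} unparseable SMILES excluded", UserWarning, stacklevel=2
        )
    return FingerprintMatrix(
        bits=np.array(rows, dtype=np.int8), compound_ids=ids, provider="computed"
    ), failed


def jaccard_distance_matrix(fp: FingerprintMatrix) -> np.ndarray:
    """Pairwise Jaccard (Tanimoto) distances; all-zero pairs get 0."""
    bits = fp.bits.astype(float)
    inter = bits @ bits.T
    s = bits.sum(axis=1)
    union = s[:, None] + s[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def bc_informers(
    distance: np.ndarray, compound_ids: list[str], n_A: int
) -> InformerSet:
    """Cluster medoids from average-linkage clustering at n_A clusters."""
    n = len(compound_ids)
    if n_A > n:
        raise ValueError("n_A cannot exceed the library size")
    if n_A == n:
        labels = np.arange(n)
    else:
        model = AgglomerativeClustering(
            n_clusters=n_A, metric="precomputed", linkage="average"
        ).fit(distance)
        labels = model.labels_
    medoids = []
    for k in range(n_A):
        idx = np.where(labels == k)[0]
        within = distance[np.ix_(idx, idx)].sum(axis=1)
        best = min(
            range(len(idx)),
            key=lambda i: (within[i], compound_ids[idx[i]]),
        )
        medoids.append(compound_ids[idx[best]])
    medoids.sort()
    return InformerSet(compound_ids=medoids, method="bc")


def bf_informers(Z: BinaryActivityMatrix, n_A: int) -> InformerSet:
    """The n_A most broadly active (frequent hitter) compounds."""
    if n_A > Z.n:
        raise ValueError("n_A cannot exceed the library size")
    counts = Z.values.sum(axis=0)
    if counts.sum() == 0:
        warnings.warn(
            "no active entries in the binary matrix; informers are the "
            "lexicographically first compounds",
            UserWarning,
            stacklevel=2,
        )
    order = sorted(range(Z.n), key=lambda j: (-counts[j], Z.compound_ids[j]))
    return InformerSet(
        compound_ids=[Z.compound_ids[j] for j in order[:n_A]],
        method="bf",
        diagnostics={"hit_counts": {Z.compound_ids[j]: int(counts[j]) for j in order[:n_A]}},
    )


def infer_informer_labels(
    assay_values: np.ndarray,
    X: BioactivityMatrix,
    thresholds: np.ndarray,
    informers: InformerSet,
) -> tuple[np.ndarray, float]:
    """Active/inactive calls for the informers on the new target.

    The activity threshold of a new target is unknown before a full
    screen, so its quantile level is inferred from the matrix: for each
    training target, locate its own mean+2SD threshold as a quantile
    level within that target's informer readouts; the median level over
    targets (kappa-hat) is then applied to the new target's informer
    readouts.  Being rank-based, the labels are invariant to monotone
    rescaling of the assay values.
    """
    cols = X.compound_indices(informers.compound_ids)
    sub = X.values[:, cols]
    levels = (sub < thresholds[:, None]).mean(axis=1)
    kappa_hat = float(np.median(levels))
    cutoff = float(np.quantile(np.asarray(assay_values, dtype=float), kappa_hat))
    labels = (np.asarray(assay_values, dtype=float) >= cutoff).astype(int)
    return labels, kappa_hat


def _active_centers(
    informer_ids: list[str], labels: np.ndarray, assay_values: np.ndarray
) -> list[int]:
    """Indices of active informers; falls back to the single most active."""
    active = [i for i, lab in enumerate(labels) if lab]
    if not active:
        best = int(
            min(
                range(len(informer_ids)),
                key=lambda i: (-assay_values[i], informer_ids[i]),
            )
        )
        active = [best]
    return active


def simple_expansion(
    distance: np.ndarray,
    compound_ids: list[str],
    informer_ids: list[str],
    labels: np.ndarray,
    assay_values: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    """Rank non-informers by distance to the nearest active informer."""
    pos = {c: i for i, c in enumerate(compound_ids)}
    centers = _active_centers(informer_ids, labels, assay_values)
    center_pos = [pos[informer_ids[i]] for i in centers]
    non = [c for c in compound_ids if c not in set(informer_ids)]
    scores = np.array([distance[pos[c], center_pos].min() for c in non])
    return rank_descending(non, scores, ascending=True)


def loop_expansion(
    distance: np.ndarray,
    compound_ids: list[str],
    informer_ids: list[str],
    labels: np.ndarray,
    assay_values: np.ndarray,
) -> tuple[list[str], np.ndarray]:
    """Round-robin over active informers, most active first.

    Each visit ranks the nearest not-yet-ranked non-informer to the
    current informer; the loop continues until all non-informers are
    ranked.  Scores are the assigned rank positions (1 = best).
    """
    pos = {c: i for i, c in enumerate(compound_ids)}
    centers = _active_centers(informer_ids, labels, assay_values)
    centers.sort(key=lambda i: (-assay_values[i], informer_ids[i]))
    center_pos = [pos[informer_ids[i]] for i in centers]
    remaining = sorted(c for c in compound_ids if c not in set(informer_ids))
    ordered: list[str] = []
    while remaining:
        for cp in center_pos:
            if not remaining:
                break
            nearest = min(remaining, key=lambda c: (distance[pos[c], cp], c))
            ordered.append(nearest)
            remaining.remove(nearest)
    scores = np.arange(1, len(ordered) + 1, dtype=float)
    return ordered, scores


def weighted_expansion(
    distance: np.ndarray,
    compound_ids: list[str],
    informer_ids: list[str],
    assay_values: np.ndarray,
    ascending: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Activity-weighted similarity ranking.

    Each non-informer's score is the inner product of its Jaccard
    similarities to the informers with the informer activity vector
    min-max normalized to [0, 1] (constant activities map to 0.5).  High
    scores rank first by default; ``ascending=True`` preserves the
    literal low-first reading.
    """
    pos = {c: i for i, c in enumerate(compound_ids)}
    x = np.asarray(assay_values, dtype=float)
    lo, hi = x.min(), x.max()
    xnorm = np.full_like(x, 0.5) if hi == lo else (x - lo) / (hi - lo)
    center_pos = [pos[c] for c in informer_ids]
    non = [c for c in compound_ids if c not in set(informer_ids)]
    sims = 1.0 - distance[np.ix_([pos[c] for c in non], center_pos)]
    scores = sims @ xnorm
    return rank_descending(non, scores, ascending=ascending)


class _ExpansionBaseline(InformerStrategy):
    """Shared ranking logic for the BC/BF baselines."""

    def __init__(
        self,
        n_informers: int = 16,
        expansion: str = "weighted",
        fingerprints: FingerprintMatrix | None = None,
        smiles: list[str] | None = None,
        ascending: bool = False,
        seed: int = 0,
    ):
        self.n_informers = n_informers
        self.expansion = expansion
        self.fingerprints = fingerprints
        self.smiles = smiles
        self.ascending = ascending
        self.seed = seed

    def _fingerprints_for(self, X: BioactivityMatrix) -> FingerprintMatrix:
        if self.fingerprints is not None:
            return self.fingerprints.reindex(X.compound_ids)
        if self.smiles is not None:
            fp, failed = compute_fingerprints(self.smiles, X.compound_ids)
            if failed:
                raise ValueError(
                    f"fingerprints unavailable for {len(failed)} compounds"
                )
            return fp
        raise ValueError("baseline strategies need fingerprints or SMILES")

    def _prepare(self, X: BioactivityMatrix) -> None:
        if self.expansion not in ("simple", "loop", "weighted"):
            raise ValueError(f"unknown expansion {self.expansion!r}")
        self.fp_ = self._fingerprints_for(X)
        self.distance_ = jaccard_distance_matrix(self.fp_)
        self.Z_ = binarize_matrix(X)

    def _rank(self, values: np.ndarray) -> RankingResult:
        X = self.train_matrix_
        labels, kappa_hat = infer_informer_labels(
            values, X, self.Z_.thresholds, self.informers_
        )
        self.informer_labels_ = labels
        self.kappa_hat_ = kappa_hat
        ids = list(X.compound_ids)
        inf_ids = list(self.informers_.compound_ids)
        if self.expansion == "simple":
            ranked, scores = simple_expansion(
                self.distance_, ids, inf_ids, labels, values
            )
        elif self.expansion == "loop":
            ranked, scores = loop_expansion(
                self.distance_, ids, inf_ids, labels, values
            )
        else:
            ranked, scores = weighted_expansion(
                self.distance_, ids, inf_ids, values, ascending=self.ascending
            )
        return self._result(ranked, scores, values)


class ChemometricBaseline(_ExpansionBaseline):
    """BC: diversity-selected informers, chemical-similarity ranking."""

    @property
    def method(self) -> str:  # type: ignore[override]
        return f"bc_{self.expansion[0]}"

    def _fit(self, X: BioactivityMatrix) -> InformerSet:
        self._prepare(X)
        return bc_informers(self.distance_, list(X.compound_ids), self.n_informers)


class FrequentHitterBaseline(_ExpansionBaseline):
    """BF: most broadly active informers, chemical-similarity ranking."""

    @property
    def method(self) -> str:  # type: ignore[override]
        return f"bf_{self.expansion[0]}"

    def _fit(self, X: BioactivityMatrix) -> InformerSet:
        self._prepare(X)
        return bf_informers(self.Z_, self.n_informers)
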