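"""Virtual-screening and classification metrics with informer bookkeeping.

Because informer compounds are the first ones assayed, active informers
are rewarded as true positives (placed ahead of every ranked
non-informer) while inactive informers are simply removed from the
library before any percentage cutoff is computed — they never count as
false positives.  All metrics therefore operate on an
:class:`EvaluationSet` built from a strategy's ranking plus the
experimental labels.

Metrics: ROCAUC, enrichment factor in the top fraction (EF10), its
normalization NEF10 (0.5 = random, 1.0 = perfect), the fraction of
active Bemis-Murcko generic scaffolds retrieved (FASR10), and F1/MCC at
a fixed predicted-active fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import f1_score, matthews_corrcoef

from .base import RankingResult

__all__ = [
    "EvaluationSet",
    "build_evaluation_set",
    "rocauc",
    "rocauc_from_scores",
    "ef_at_fraction",
    "nef10",
    "fasr10",
    "f1_mcc_at_fraction",
    "degenerate_scores",
    "generic_scaffold_ids",
    "compute_all_metrics",
    "top_fraction_cutoff",
]

#: returned where a metric is undefined (e.g. single-class labels)
SENTINEL = float("nan")


def top_fraction_cutoff(n_library: int, fraction: float) -> int:
    """Library-size cutoff for a top-``fraction`` selection.

    Rounds to the nearest integer (half away from zero), minimum 1: a
    366-compound library at 10% gives 37 compounds, at 5.5% gives 20; a
    415-compound library at 5.5% gives 23.
    """
    return max(1, int(np.floor(n_library * fraction + 0.5)))


@dataclass
class EvaluationSet:
    """Ordered compound list after informer bookkeeping.

    Active informers come first (descending experimental activity),
    then the ranked non-informers; inactive informers are absent.  The
    effective library size for percentage cutoffs is ``len(compound_ids)``.
    """

    compound_ids: list[str]
    labels: np.ndarray
    scaffold_ids: np.ndarray | None = None
    n_informers_active: int = 0
    n_informers_total: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.compound_ids):
            raise ValueError("one label per compound required")
        if self.scaffold_ids is not None:
            self.scaffold_ids = np.asarray(self.scaffold_ids)
            if self.scaffold_ids.shape[0] != len(self.compound_ids):
                raise ValueError("one scaffold ID per compound required")

    @property
    def n_library(self) -> int:
        return len(self.compound_ids)


def build_evaluation_set(
    ranking: RankingResult,
    labels: Mapping[str, int],
    scaffolds: Mapping[str, int] | None = None,
) -> EvaluationSet:
    """Apply the informer bookkeeping to a strategy's ranking.

    ``labels`` must cover every compound (informers included).  Active
    informers are prepended in descending experimental activity (ties by
    compound ID); inactive informers are dropped.
    """
    missing = [c for c in ranking.compound_ids if str(c) not in labels]
    missing += [c for c in ranking.informer_ids if str(c) not in labels]
    if missing:
        raise ValueError(f"labels missing for compounds: {sorted(set(missing))[:5]}")

    active_informers = [c for c in ranking.informer_ids if labels[str(c)]]
    active_informers.sort(key=lambda c: (-ranking.informer_activities[c], c))
    ordered = active_informers + list(ranking.compound_ids)
    lab = np.array([int(labels[str(c)]) for c in ordered], dtype=int)
    scaf = None
    if scaffolds is not None:
        try:
            scaf = np.array([scaffolds[str(c)] for c in ordered])
        except KeyError as exc:
            raise ValueError(f"scaffold ID missing for compound {exc.args[0]!r}") from None
    return EvaluationSet(
        compound_ids=ordered,
        labels=lab,
        scaffold_ids=scaf,
        n_informers_active=len(active_informers),
        n_informers_total=len(ranking.informer_ids),
    )


def rocauc_from_scores(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based ROC AUC with half credit for score ties.

    Equals the normalized Mann-Whitney U statistic.  Returns the
    sentinel (NaN) when only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return SENTINEL
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rocauc(evalset: EvaluationSet) -> float:
    """ROC AUC of the evaluation-set ordering (best compound first)."""
    n = evalset.n_library
    scores = -np.arange(n, dtype=float)  # descending with position
    return rocauc_from_scores(evalset.labels, scores)


def ef_at_fraction(evalset: EvaluationSet, fraction: float = 0.10) -> float:
    """Enrichment factor: active rate in the top fraction over the base rate."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = evalset.n_library
    n_act = int(evalset.labels.sum())
    if n_act == 0:
        return SENTINEL
    cut = top_fraction_cutoff(n, fraction)
    hits = int(evalset.labels[:cut].sum())
    return float((hits / cut) / (n_act / n))


def _ef_max(evalset: EvaluationSet, fraction: float) -> float:
    n = evalset.n_library
    n_act = int(evalset.labels.sum())
    cut = top_fraction_cutoff(n, fraction)
    best_hits = min(cut, n_act)
    return float((best_hits / cut) / (n_act / n))


def nef10(evalset: EvaluationSet, fraction: float = 0.10) -> float:
    """Normalized EF10: (1 + (EF10 - 1)/(EF10max - 1)) / 2.

    0.5 corresponds to random ranking (EF10 = 1) and 1.0 to a perfect
    ranking (EF10 at its theoretical maximum for this class balance).
    """
    ef = ef_at_fraction(evalset, fraction)
    if np.isnan(ef):
        return SENTINEL
    ef_max = _ef_max(evalset, fraction)
    if ef_max <= 1.0:
        return SENTINEL  # every compound active: no enrichment possible
    return float((1.0 + (ef - 1.0) / (ef_max - 1.0)) / 2.0)


def fasr10(evalset: EvaluationSet, fraction: float = 0.10) -> float:
    """Fraction of active scaffolds retrieved in the top fraction.

    A scaffold counts as retrieved only when an experimentally *active*
    member sits in the top fraction; inactive members of an active
    scaffold do not count.
    """
    if evalset.scaffold_ids is None:
        raise ValueError("FASR requires scaffold IDs")
    active = evalset.labels == 1
    if not active.any():
        return SENTINEL
    all_active_scaffolds = set(evalset.scaffold_ids[active].tolist())
    cut = top_fraction_cutoff(evalset.n_library, fraction)
    top_active = active[:cut]
    top_scaffolds = set(evalset.scaffold_ids[:cut][top_active].tolist())
    return float(len(top_scaffolds) / len(all_active_scaffolds))


def f1_mcc_at_fraction(
    evalset: EvaluationSet, active_fraction: float = 0.055
) -> tuple[float, float]:
    """F1 and MCC after calling the top ``active_fraction`` predicted active.

    The cutoff uses the same nearest-integer rounding as the enrichment
    metrics; MCC is 0 whenever a confusion-table marginal is zero.
    """
    if not 0.0 < active_fraction < 1.0:
        raise ValueError("active_fraction must be in (0, 1)")
    cut = top_fraction_cutoff(evalset.n_library, active_fraction)
    pred = np.zeros(evalset.n_library, dtype=int)
    pred[:cut] = 1
    f1 = float(f1_score(evalset.labels, pred, zero_division=0))
    mcc = float(matthews_corrcoef(evalset.labels, pred))
    return f1, mcc


def degenerate_scores(
    labels: Mapping[str, int] | None = None,
    active_fraction: float = 0.055,
    seed: int = 0,
) -> dict[str, float]:
    """Random-ranking scores assigned when a strategy cannot rank.

    ROCAUC and NEF10 are 0.5 and FASR10 is 0.0 by convention; F1/MCC are
    computed on a reproducible random-order ranking of the labels.
    """
    out = {"rocauc": 0.5, "nef10": 0.5, "fasr10": 0.0, "degenerate": 1.0}
    if labels is not None:
        ids = sorted(str(c) for c in labels)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        evalset = EvaluationSet(
            compound_ids=[ids[i] for i in order],
            labels=np.array([labels[ids[i]] for i in order], dtype=int),
        )
        f1, mcc = f1_mcc_at_fraction(evalset, active_fraction)
        out["f1"], out["mcc"] = f1, mcc
    else:
        out["f1"], out["mcc"] = SENTINEL, SENTINEL
    return out


def generic_scaffold_ids(smiles: Sequence[str]) -> tuple[list[int], list[int]]:
    """Integer IDs of generic Bemis-Murcko scaffolds computed from SMILES.

    The generic scaffold strips side chains, sets every atom to aliphatic
    carbon and every bond to single, so chemotype equivalence ignores
    decoration and heteroatoms.  Acyclic molecules (empty scaffold) share
    the reserved ID 0.  Returns (ids, failed_indices); unparseable SMILES
    get ID -1 and are listed in ``failed_indices``.

    Requires RDKit.  Supplying precomputed integer scaffold columns
    bypasses chemistry entirely (see the compound metadata interface).
    """
    from rdkit import Chem  # deferred: chemistry is optional
    from rdkit.Chem.Scaffolds import MurckoScaffold

    table: dict[str, int] = {"": 0}
    ids: list[int] = []
    failed: list[int] = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            ids.append(-1)
            failed.append(i)
            continue
        scaf = MurckoScaffold.GetScaffoldForMol(mol)
        try:
            generic = MurckoScaffold.MakeScaffoldGeneric(scaf)
            key = Chem.MolToSmiles(generic)
        except Exception:
            key = Chem.MolToSmiles(scaf)
        if key not in table:
            table[key] = len(table)
        ids.append(table[key])
    return ids, failed


def compute_all_metrics(
    evalset: EvaluationSet, active_fraction: float = 0.055
) -> dict[str, float]:
    """All headline metrics for one (target, method) evaluation."""
    out = {
        "rocauc": rocauc(evalset),
        "nef10": nef10(evalset),
        "degenerate": 0.0,
    }
    if evalset.scaffold_ids is not None:
        out["fasr10"] = fasr10(evalset)
    f1, mcc = f1_mcc_at_fraction(evalset, active_fraction)
    out["f1"], out["mcc"] = f1, mcc
    out["n_informers_active"] = float(evalset.n_informers_active)
    return out
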