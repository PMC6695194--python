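"""Common strategy contract shared by every informer-based ranking method.

A strategy is a scikit-learn style estimator: ``fit`` consumes only the
training bioactivity matrix (never the new target) and stores the chosen
informer set in ``informers_``; ``rank`` consumes the intermediate assay
data measured on those informers for a new target and returns a total
order over the non-informer compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import BioactivityMatrix, InformerSet

__all__ = ["RankingResult", "InformerStrategy", "validate_intermediate_data"]


def validate_intermediate_data(
    assays: Mapping[str, float], informers: InformerSet
) -> np.ndarray:
    """Check assay keys equal the informer set; return values in informer order."""
    keys = {str(k) for k in assays}
    expected = set(informers.compound_ids)
    missing = expected - keys
    if missing:
        raise ValueError(f"missing assay readouts for informers: {sorted(missing)}")
    extra = keys - expected
    if extra:
        raise ValueError(f"assay readouts for non-informer compounds: {sorted(extra)}")
    vals = np.array([float(assays[c]) for c in informers.compound_ids])
    if not np.all(np.isfinite(vals)):
        raise ValueError("informer assay readouts must be finite")
    return vals


@dataclass
class RankingResult:
    """Scored, ordered non-informer compounds plus informer bookkeeping.

    ``compound_ids`` holds the non-informers from best to worst.  The
    informer compounds never appear in the ranking; their experimental
    activities (and, once labels are available, active calls) ride along
    for the metric bookkeeping that prepends active informers and drops
    inactive ones.
    """

    compound_ids: list[str]
    scores: np.ndarray
    informer_ids: list[str]
    informer_activities: dict[str, float]
    method: str = ""
    informer_active: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.compound_ids) != self.scores.shape[0]:
            raise ValueError("one score per ranked compound required")
        if set(self.compound_ids) & set(self.informer_ids):
            raise ValueError("informers may not appear among ranked non-informers")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("ranked compounds must be unique")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.compound_ids) + 1),
                "compound_id": self.compound_ids,
                "score": self.scores,
                "is_informer": 0,
            }
        )
        inf = pd.DataFrame(
            {
                "rank": 0,
                "compound_id": self.informer_ids,
                "score": [self.informer_activities[c] for c in self.informer_ids],
                "is_informer": 1,
            }
        )
        out = pd.concat([inf, frame], ignore_index=True)
        if self.informer_active is not None:
            out["informer_active"] = [
                self.informer_active.get(c, "") if flag else ""
                for c, flag in zip(out["compound_id"], out["is_informer"])
            ]
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_descending(
    compound_ids: list[str], scores: np.ndarray, ascending: bool = False
) -> tuple[list[str], np.ndarray]:
    """Order compounds by score with lexical compound-ID tie-breaking."""
    scores = np.asarray(scores, dtype=float)
    key = scores if ascending else -scores
    order = sorted(range(len(compound_ids)), key=lambda i: (key[i], compound_ids[i]))
    return [compound_ids[i] for i in order], scores[order]


class InformerStrategy(BaseEstimator):
    """Base class for informer selection + compound ranking strategies.

    Subclasses implement ``_fit(X)`` (returning an :class:`InformerSet`)
    and ``_rank(assay_values)``.  Estimator parameters follow sklearn
    conventions so strategies compose with ``clone`` and grid search.
    """

    method: str = ""

    def fit(self, X: BioactivityMatrix, y=None) -> "InformerStrategy":
        if not isinstance(X, BioactivityMatrix):
            raise TypeError("X must be a BioactivityMatrix")
        n_A = int(getattr(self, "n_informers"))
        if n_A < 1:
            raise ValueError("n_informers must be >= 1")
        if n_A >= X.n:
            raise ValueError("n_informers must be smaller than the library size")
        self.train_matrix_ = X
        self.informers_ = self._fit(X)
        return self

    def rank(self, assays: Mapping[str, float]) -> RankingResult:
        if not hasattr(self, "informers_"):
            raise ValueError("strategy is not fitted; call fit(X) first")
        values = validate_intermediate_data(assays, self.informers_)
        return self._rank(values)

    # subclass hooks -------------------------------------------------------
    def _fit(self, X: BioactivityMatrix) -> InformerSet:  # pragma: no cover
        raise NotImplementedError

    def _rank(self, values: np.ndarray) -> RankingResult:  # pragma: no cover
        raise NotImplementedError

    def _result(self, compound_ids, scores, values) -> RankingResult:
        return RankingResult(
            compound_ids=list(compound_ids),
            scores=np.asarray(scores, dtype=float),
            informer_ids=list(self.informers_.compound_ids),
            informer_activities={
                c: float(v) for c, v in zip(self.informers_.compound_ids, values)
            },
            method=self.method,
        )
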