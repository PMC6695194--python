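"""Evaluation drivers: leave-one-target-out, prospective screens, and
cross-method statistics.

The LOTO driver removes each target in turn, lets every strategy pick
informers from the reduced matrix alone (the left-out row is never seen
at selection time), reveals the left-out target's readouts on the chosen
informers, ranks the non-informers and scores the ranking against the
target's own mean+2SD activity calls.  Method comparisons use paired
two-sided Wilcoxon signed-rank tests with a Sidak correction for the
number of baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

from . import metrics as _metrics
from .base import InformerStrategy
from .matrix import BioactivityMatrix, binarize_row, remove_target

__all__ = [
    "LotoResult",
    "run_loto",
    "run_prospective",
    "compare_methods",
    "sidak_alpha",
    "stratify_by_hit_rate",
]


@dataclass
class LotoResult:
    """Per (target, method) metric records from a LOTO run."""

    records: pd.DataFrame
    informer_sets: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def metric_matrix(self, metric: str) -> pd.DataFrame:
        """targets x methods table of one metric."""
        return self.records.pivot(index="target_id", columns="method", values=metric)


def _evaluate_one(
    strategy: InformerStrategy,
    X_train: BioactivityMatrix,
    assays_full: Mapping[str, float],
    scaffolds: Mapping[str, int] | None,
) -> tuple[dict[str, float], list[str], "_metrics.EvaluationSet"]:
    """Fit on the training matrix, rank from informer readouts, score."""
    strategy.fit(X_train)
    informers = strategy.informers_
    revealed = {c: float(assays_full[c]) for c in informers.compound_ids}
    ranking = strategy.rank(revealed)

    full_vec = np.array([assays_full[c] for c in X_train.compound_ids], dtype=float)
    label_vec, _thr = binarize_row(full_vec)
    labels = {c: int(z) for c, z in zip(X_train.compound_ids, label_vec)}
    ranking.informer_active = {c: labels[c] for c in informers.compound_ids}
    evalset = _metrics.build_evaluation_set(ranking, labels, scaffolds)
    record = _metrics.compute_all_metrics(evalset)
    return record, list(informers.compound_ids), evalset


def run_loto(
    X: BioactivityMatrix,
    methods: Mapping[str, InformerStrategy],
    seed: int = 0,
    scaffolds: Mapping[str, int] | None = None,
    targets: list[str] | None = None,
) -> LotoResult:
    """Leave-one-target-out evaluation of every method.

    ``methods`` maps a tag to an unfitted strategy prototype; each
    (target, method) run gets a cloned strategy seeded from a child
    stream, so the whole run is reproducible from ``seed``.  A method
    failure on a target yields the degenerate random-ranking scores and
    the run continues.  ``targets`` restricts the evaluation to a subset
    of rows (all rows by default).
    """
    rng = np.random.default_rng(seed)
    targets = list(targets) if targets is not None else list(X.target_ids)
    rows = []
    result = LotoResult(records=pd.DataFrame())
    for target_id in targets:
        i = X.target_index(target_id)
        X_red = remove_target(X, target_id)
        assays_full = {c: float(X.values[i, j]) for j, c in enumerate(X.compound_ids)}
        for tag, proto in methods.items():
            strat = clone(proto)
            if hasattr(strat, "seed"):
                strat.set_params(seed=int(rng.integers(2**31)))
            try:
                record, informers, _ = _evaluate_one(
                    strat, X_red, assays_full, scaffolds
                )
                result.informer_sets[(target_id, tag)] = informers
            except Exception as exc:  # noqa: BLE001 - driver must continue
                full_vec = np.array(
                    [assays_full[c] for c in X.compound_ids], dtype=float
                )
                label_vec, _ = binarize_row(full_vec)
                labels = {c: int(z) for c, z in zip(X.compound_ids, label_vec)}
                record = _metrics.degenerate_scores(labels)
                result.failures.append((target_id, tag, repr(exc)))
            rows.append({"target_id": target_id, "method": tag, **record})
    result.records = pd.DataFrame(rows)
    return result


def run_prospective(
    X_train: BioactivityMatrix,
    assays_full: Mapping[str, float],
    methods: Mapping[str, InformerStrategy],
    seed: int = 0,
    scaffolds: Mapping[str, int] | None = None,
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Prospective screen of a genuinely new target.

    ``assays_full`` must cover every training compound (the full panel
    is assayed for evaluation; only informer readouts are revealed to
    the strategies).  Reports, per method, the usual metrics plus the
    retrieval counts: active informers, actives in the top fraction and
    unique active scaffolds in the top fraction.
    """
    missing = [c for c in X_train.compound_ids if c not in assays_full]
    if missing:
        raise ValueError(f"assays missing for {len(missing)} compounds")
    rng = np.random.default_rng(seed)
    rows = []
    for tag, proto in methods.items():
        strat = clone(proto)
        if hasattr(strat, "seed"):
            strat.set_params(seed=int(rng.integers(2**31)))
        record, informers, evalset = _evaluate_one(
            strat, X_train, assays_full, scaffolds
        )
        cut = _metrics.top_fraction_cutoff(evalset.n_library, fraction)
        top = evalset.labels[:cut]
        record["n_active_top"] = int(top.sum())
        if evalset.scaffold_ids is not None:
            active_top = evalset.scaffold_ids[:cut][top == 1]
            record["n_active_scaffolds_top"] = len(set(active_top.tolist()))
        rows.append({"method": tag, **record})
    return pd.DataFrame(rows)


def sidak_alpha(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance level under a Sidak correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / n_tests)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original treatment); the
    exact null distribution is used for up to 25 non-zero pairs without
    ties, otherwise a normal approximation with continuity correction.
    All-zero differences yield p = 1.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 and np.unique(np.abs(d)).size == d.size else "approx"
    res = stats.wilcoxon(
        d, alternative="two-sided", zero_method="wilcox", method=method, correction=True
    )
    return float(res.pvalue)


def compare_methods(
    result: LotoResult,
    metric: str,
    methods: list[str],
    baselines: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise method-vs-baseline Wilcoxon tests on per-target metrics.

    The per-test threshold is Sidak-adjusted for the number of baselines.
    Rows flag all-zero-difference pairs (p reported as 1).
    """
    table = result.metric_matrix(metric)
    adj = sidak_alpha(len(baselines), alpha)
    rows = []
    for m in methods:
        for b in baselines:
            pair = table[[m, b]].dropna()
            if len(pair) < 6:
                raise ValueError(
                    f"need >= 6 paired observations for {m} vs {b}, got {len(pair)}"
                )
            x, y = pair[m].to_numpy(), pair[b].to_numpy()
            all_zero = bool(np.all(x == y))
            p = wilcoxon_signed_rank(x, y)
            rows.append(
                {
                    "method": m,
                    "baseline": b,
                    "metric": metric,
                    "p_value": p,
                    "adjusted_alpha": adj,
                    "significant": bool(p < adj),
                    "all_differences_zero": all_zero,
                    "method_median": float(np.median(x)),
                    "baseline_median": float(np.median(y)),
                    "n_pairs": len(pair),
                }
            )
    return pd.DataFrame(rows)


def stratify_by_hit_rate(
    result: LotoResult,
    hit_rates: Mapping[str, float],
    metric: str,
    n_bins: int = 4,
) -> dict:
    """Per-hit-rate-bin summaries plus a target+method effect decomposition.

    Targets are ranked by active fraction (ties by target ID) and cut
    into ``n_bins`` equal-size bins.  An additive two-factor linear
    model (target effect + method effect) is fitted to the per-target
    metric and simultaneous Tukey intervals are reported for method
    effect differences.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    table = result.metric_matrix(metric).dropna()
    targets = sorted(table.index, key=lambda t: (hit_rates[t], t))
    n_t = len(targets)
    if n_t < 2 * n_bins:
        warnings.warn("few targets per bin; merging into fewer bins", UserWarning)
        n_bins = max(2, n_t // 2)
    edges = np.linspace(0, n_t, n_bins + 1).astype(int)
    bins = {}
    for b in range(n_bins):
        bins.update({t: b for t in targets[edges[b] : edges[b + 1]]})

    long = table.loc[targets].reset_index().melt(
        id_vars="target_id", var_name="method", value_name="value"
    )
    long["bin"] = long["target_id"].map(bins)
    per_bin = (
        long.groupby(["bin", "method"])["value"]
        .agg(["mean", "median", "std", "count"])
        .reset_index()
    )

    import statsmodels.formula.api as smf

    fit = smf.ols("value ~ C(target_id) + C(method)", data=long).fit()
    method_names = sorted(long["method"].unique())
    ref = method_names[0]
    effects = {ref: 0.0}
    for m in method_names[1:]:
        effects[m] = float(fit.params.get(f"C(method)[T.{m}]", 0.0))

    # Tukey simultaneous intervals on pairwise method-effect differences
    k = len(method_names)
    df_resid = fit.df_resid
    sigma2 = fit.mse_resid
    n_per = long.groupby("method")["value"].count().min()
    q = stats.studentized_range.ppf(0.95, k, df_resid)
    half_width = q / np.sqrt(2.0) * np.sqrt(2.0 * sigma2 / n_per)
    comparisons = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = effects[method_names[b]] - effects[method_names[a]]
            comparisons.append(
                {
                    "method_a": method_names[a],
                    "method_b": method_names[b],
                    "effect_difference": diff,
                    "ci_lower": diff - half_width,
                    "ci_upper": diff + half_width,
                }
            )
    return {
        "per_bin": per_bin,
        "bins": bins,
        "method_effects": effects,
        "tukey": pd.DataFrame(comparisons),
        "model": fit,
    }
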