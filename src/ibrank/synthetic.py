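"""Synthetic chemogenomic matrices with planted informer structure.

The generator emulates the statistical features the ranking strategies
rely on in a kinase percent-inhibition panel:

* targets fall into K latent clusters;
* a small set of *informative* compounds is strongly active exactly on
  the targets of its own cluster, so those columns predict the cluster
  label;
* every target shares a common background set of active compounds plus
  a few idiosyncratic ones, producing the heavy class imbalance seen in
  real panels (active fractions of a few percent after the mean+2SD
  call);
* all other readouts are low-level Gaussian noise, truncated to a
  plausible percent-inhibition range.

Synthetic fingerprints and scaffold IDs are generated so the chemometric
baselines have chemistry-free inputs: compounds in a scaffold group
share a core bit pattern, and group membership is correlated with
activity status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import FingerprintMatrix
from .matrix import BinaryActivityMatrix, BioactivityMatrix, binarize_matrix

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_matrix",
    "generate_fingerprints_and_scaffolds",
    "generate_new_target",
]

ACTIVE_SCALE = 80.0  # percent-inhibition level of a planted active readout
TRUNC_LO, TRUNC_HI = -20.0, 120.0  # plausible assay readout range


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic matrix."""

    m: int = 60
    n: int = 80
    K: int = 3
    n_informative: int = 6
    cluster_sep: float = 80.0
    noise_sd: float = 4.0
    active_fraction_range: tuple[float, float] = (0.03, 0.10)
    n_bits: int = 256
    n_scaffolds: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.K <= self.m:
            raise ValueError("need 2 <= K <= m")
        if self.n_informative > self.n:
            raise ValueError("n_informative cannot exceed n")
        lo, hi = self.active_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("active fractions must satisfy 0 < lo <= hi < 1")
        # the informative and background actives must fit inside the range
        if int(np.floor(lo * self.n)) < 1:
            raise ValueError("active_fraction_range too small for this n")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    cluster_labels: dict[str, int]
    informative_compounds: list[str]
    cluster_profiles: np.ndarray  # (K, n) noiseless mean profiles
    background_active: list[str]
    target_ids: list[str] = field(default_factory=list)
    compound_ids: list[str] = field(default_factory=list)


def _ids(prefix: str, k: int) -> list[str]:
    width = len(str(k - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(k)]


def generate_matrix(spec: SyntheticSpec) -> tuple[BioactivityMatrix, SyntheticTruth]:
    """Draw one planted-structure bioactivity matrix.

    Targets are assigned to K balanced clusters.  Informative compound j
    is "on" (mean ``cluster_sep``) exactly for the targets of its
    assigned cluster.  A shared background active set of size
    floor(lo * n) is on for every target; each target additionally gets
    idiosyncratic actives drawn so its total active fraction stays
    within ``active_fraction_range``.  Gaussian noise with SD
    ``noise_sd`` is added everywhere, then readouts are truncated to a
    percent-inhibition-like range.
    """
    rng = np.random.default_rng(spec.seed)
    target_ids = _ids("T", spec.m)
    compound_ids = _ids("C", spec.n)

    labels = np.arange(spec.m) % spec.K
    rng.shuffle(labels)
    # every cluster must be non-empty under any shuffle of the balanced fill
    informative = sorted(rng.choice(spec.n, size=spec.n_informative, replace=False))
    inf_cluster = {j: k % spec.K for k, j in enumerate(informative)}

    lo, hi = spec.active_fraction_range
    per_cluster_informative = int(np.ceil(spec.n_informative / spec.K))
    n_background = max(1, int(np.floor(lo * spec.n)) - per_cluster_informative)
    non_informative = [j for j in range(spec.n) if j not in informative]
    background = sorted(
        rng.choice(non_informative, size=n_background, replace=False)
    )

    profiles = np.zeros((spec.K, spec.n))
    for j in informative:
        profiles[inf_cluster[j], j] = spec.cluster_sep
    profiles[:, background] = ACTIVE_SCALE

    values = profiles[labels] + rng.normal(0.0, spec.noise_sd, size=(spec.m, spec.n))

    # idiosyncratic actives: top the active fraction up within the range
    free = [j for j in non_informative if j not in background]
    for i in range(spec.m):
        n_on = n_background + sum(1 for j in informative if inf_cluster[j] == labels[i])
        if n_on > int(np.floor(hi * spec.n)):
            raise RuntimeError(
                f"active_fraction_range infeasible: target {target_ids[i]} has "
                f"{n_on} planted actives but hi allows {int(np.floor(hi * spec.n))}"
            )
        lo_extra = max(0, int(np.ceil(lo * spec.n)) - n_on)
        hi_extra = max(lo_extra, int(np.floor(hi * spec.n)) - n_on)
        n_extra = int(rng.integers(lo_extra, hi_extra + 1))
        n_extra = min(n_extra, len(free))
        if n_extra > 0:
            extra = rng.choice(free, size=n_extra, replace=False)
            values[i, extra] = ACTIVE_SCALE + rng.normal(
                0.0, spec.noise_sd, size=n_extra
            )

    values = np.clip(values, TRUNC_LO, TRUNC_HI)
    X = BioactivityMatrix(
        values=values, target_ids=target_ids, compound_ids=compound_ids
    )
    truth = SyntheticTruth(
        cluster_labels={t: int(l) for t, l in zip(target_ids, labels)},
        informative_compounds=[compound_ids[j] for j in informative],
        cluster_profiles=profiles,
        background_active=[compound_ids[j] for j in background],
        target_ids=target_ids,
        compound_ids=compound_ids,
    )
    _check_active_fractions(X, spec)
    return X, truth


def _check_active_fractions(X: BioactivityMatrix, spec: SyntheticSpec) -> None:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = binarize_matrix(X)
    frac = Z.active_fraction()
    lo, hi = spec.active_fraction_range
    # the mean+2SD call drifts outside the planted range only when noise
    # overwhelms the separation; surface that as a hard error
    if frac.min() < lo - 1.0 / X.n or frac.max() > hi + 1e-12:
        raise RuntimeError(
            f"planted active fractions infeasible under noise_sd={spec.noise_sd}: "
            f"observed [{frac.min():.3f}, {frac.max():.3f}] vs requested [{lo}, {hi}]"
        )


def generate_fingerprints_and_scaffolds(
    spec: SyntheticSpec, truth: SyntheticTruth
) -> tuple[FingerprintMatrix, dict[str, int]]:
    """Synthetic fingerprint bits and scaffold IDs correlated with activity.

    Compounds are partitioned into ``n_scaffolds`` groups; informative
    and background-active compounds are concentrated in the low-index
    groups so chemical similarity carries activity signal.  As in real
    chemotypes, those groups also hold inactive members: the remaining
    compounds are spread over *all* groups, so similarity to an active
    is suggestive but never conclusive.  Each group has a random core
    bit pattern; compounds flip a small fraction of bits around it.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n
    ids = truth.compound_ids
    special = [c for c in ids if c in set(truth.informative_compounds)]
    active = [c for c in ids if c in set(truth.background_active)]
    rest = [c for c in ids if c not in set(special) | set(active)]

    n_active_groups = max(1, spec.n_scaffolds // 4)
    scaffold: dict[str, int] = {}
    for i, c in enumerate(special + active):
        scaffold[c] = i % n_active_groups
    for i, c in enumerate(rest):
        scaffold[c] = i % spec.n_scaffolds

    cores = rng.random((spec.n_scaffolds, spec.n_bits)) < 0.10
    bit_noise = 0.01
    bits = np.empty((n, spec.n_bits), dtype=np.int8)
    for i, c in enumerate(ids):
        flips = rng.random(spec.n_bits) < bit_noise
        bits[i] = np.where(flips, ~cores[scaffold[c]], cores[scaffold[c]])
    # guarantee at least one set bit per compound
    empty = bits.sum(axis=1) == 0
    bits[empty, 0] = 1
    fp = FingerprintMatrix(bits=bits, compound_ids=list(ids), provider="synthetic")
    return fp, scaffold


def generate_new_target(
    truth: SyntheticTruth, cluster: int, noise_sd: float, seed: int = 0
) -> dict[str, float]:
    """Full activity vector for a fresh target drawn from one cluster.

    Returns a compound -> readout map covering the whole library so any
    informer subset can be 'assayed' and the remainder evaluated.
    """
    K = truth.cluster_profiles.shape[0]
    if not 0 <= cluster < K:
        raise ValueError(f"cluster must be in 0..{K - 1}")
    rng = np.random.default_rng(seed)
    vec = truth.cluster_profiles[cluster] + rng.normal(
        0.0, noise_sd, size=truth.cluster_profiles.shape[1]
    )
    vec = np.clip(vec, TRUNC_LO, TRUNC_HI)
    return {c: float(v) for c, v in zip(truth.compound_ids, vec)}
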