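"""Shared fixtures: toy matrices and planted-structure synthetic data."""

import warnings

import numpy as np
import pytest

from ibrank.matrix import BioactivityMatrix
from ibrank.synthetic import (
    SyntheticSpec,
    generate_fingerprints_and_scaffolds,
    generate_matrix,
)


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    """Silence the expected constant-row/column warnings in bulk fixtures."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="constant ")
        yield


@pytest.fixture
def toy_matrix() -> BioactivityMatrix:
    """4 targets x 5 compounds with hand-checkable values."""
    values = np.array(
        [
            [0.0, 10.0, 2.0, 3.0, 1.0],
            [5.0, 5.0, 80.0, 0.0, 2.0],
            [1.0, 0.0, 0.0, 90.0, 3.0],
            [2.0, 1.0, 1.0, 0.0, 70.0],
        ]
    )
    return BioactivityMatrix(
        values=values,
        target_ids=["T1", "T2", "T3", "T4"],
        compound_ids=["C1", "C2", "C3", "C4", "C5"],
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted-structure study: matrix, truth, fingerprints, scaffolds."""
    spec = SyntheticSpec(seed=7)
    X, truth = generate_matrix(spec)
    fp, scaffolds = generate_fingerprints_and_scaffolds(spec, truth)
    return {"spec": spec, "X": X, "truth": truth, "fp": fp, "scaffolds": scaffolds}


@pytest.fixture(scope="session")
def crisp_small():
    """Low-noise 3-cluster matrix without idiosyncratic actives (m=60, n=50)."""
    spec = SyntheticSpec(
        m=60,
        n=50,
        K=3,
        n_informative=5,
        cluster_sep=80.0,
        noise_sd=2.0,
        active_fraction_range=(3.0 / 50, 3.9 / 50),
        seed=11,
    )
    X, truth = generate_matrix(spec)
    return {"spec": spec, "X": X, "truth": truth}
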