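import numpy as np
import pytest

from connrep import Cohort, ConnectomeScan, SyntheticConfig, generate_cohort


def random_weight_matrix(rng: np.random.Generator, n: int, density: float = 0.6,
                         max_weight: float = 1.0) -> np.ndarray:
    """Random symmetric non-negative weight matrix with zero diagonal."""
    W = rng.random((n, n)) * max_weight
    keep = rng.random((n, n)) < density
    W = np.where(keep, W, 0.0)
    W = np.triu(W, k=1)
    return W + W.T


def make_cohort(values: np.ndarray) -> Cohort:
    """Cohort from an (n_subjects, n_sessions, n, n) array of matrices."""
    S, R = values.shape[:2]
    scans = {}
    for s in range(S):
        for r in range(R):
            sub, ses = f"{s + 1:02d}", str(r + 1)
            scans[(sub, ses)] = ConnectomeScan(sub, ses, values[s, r])
    return Cohort(scans=scans)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A fast 12-node, 6-subject synthetic cohort for unit tests."""
    return generate_cohort(
        SyntheticConfig(n_nodes=12, n_subjects=6, n_sessions=2, seed=42)
    )


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """One full-size (78-node, 30-subject) default cohort, shared per session."""
    return generate_cohort(SyntheticConfig(seed=7))
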