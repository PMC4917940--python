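import numpy as np
import pytest

from multide import CountMatrix, SimConfig, run_de, simulate_rank1


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """2 genes x 4 samples, two conditions of two samples each."""
    return CountMatrix(
        counts=np.array([[5, 7, 20, 22], [3, 4, 2, 1]]),
        gene_ids=["gA", "gB"],
        sample_ids=["s1", "s2", "s3", "s4"],
        conditions=[1, 1, 2, 2],
    )


def _matched_cm(counts, D, n):
    G = counts.shape[0]
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(G)],
        sample_ids=[f"c{d}_s{i}" for d in range(1, D + 1) for i in range(1, n + 1)],
        conditions=np.repeat(np.arange(1, D + 1), n),
        subjects=np.tile(np.arange(1, n + 1), D),
    )


@pytest.fixture
def matched_cm_factory():
    """Build a matched CountMatrix from a (G, D*n) array (condition-major)."""
    return _matched_cm


@pytest.fixture(scope="session")
def default_matched_run():
    """One full-scale matched D=3 replicate with its pipeline result.

    Session-scoped because several tests reuse the same simulated dataset
    for different read-only checks.
    """
    cm, truth = simulate_rank1(SimConfig(D=3, design="matched", G=10_000, seed=7))
    res = run_de(cm, method="median")
    return cm, truth, res
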