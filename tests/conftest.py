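import numpy as np
import pytest

from hypermda.io import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from hypermda.synthetic import SynthConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Planted 20x15 benchmark used by the slower end-to-end tests."""
    return simulate_dataset(
        SynthConfig(nm=20, nd=15, rank=3, density=0.08, noise=0.02, rng_seed=0)
    )


@pytest.fixture(scope="session")
def medium_dataset():
    """Planted 60x40 benchmark at the documented default scale."""
    return simulate_dataset(SynthConfig(rng_seed=0))


@pytest.fixture
def chain_dag():
    """r -> a -> b: T(b) = {b, a, r}."""
    return DiseaseDAG(["r", "a", "b"], [("r", "a"), ("a", "b")])


@pytest.fixture
def diamond_dag():
    """r -> {a, b} -> c."""
    return DiseaseDAG(
        ["r", "a", "b", "c"],
        [("r", "a"), ("r", "b"), ("a", "c"), ("b", "c")],
    )


def random_similarity(n, rng, ids=None):
    vals = rng.uniform(0, 1, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(vals, ids or [f"e{i}" for i in range(n)])


def random_association(nm, nd, rng, density=0.3):
    vals = (rng.random((nm, nd)) < density).astype(float)
    return AssociationMatrix(
        vals, [f"m{i}" for i in range(nm)], [f"d{j}" for j in range(nd)]
    )
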