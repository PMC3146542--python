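import numpy as np
import pytest

from disfree import (
    EnergyBackendParams,
    FreeEnergyParams,
    InteractionMatrix,
    SyntheticSpec,
    generate_ensemble,
)


def zero_matrix(n: int) -> InteractionMatrix:
    return InteractionMatrix(n=n, e_attr=np.zeros((n, n)), e_rep=np.zeros((n, n)))


def attr_matrix(n: int, pairs: dict[tuple[int, int], float]) -> InteractionMatrix:
    """Attractive matrix from 1-based pair -> energy (<= 0) entries."""
    e = np.zeros((n, n))
    for (i, j), v in pairs.items():
        assert v <= 0 and abs(i - j) > 1
        e[i - 1, j - 1] = e[j - 1, i - 1] = v
    return InteractionMatrix(n=n, e_attr=e, e_rep=np.zeros((n, n)))


def random_attr_matrix(n: int, rng: np.random.Generator,
                       scale: float = 2.0) -> InteractionMatrix:
    """Random attractive matrix (no repulsion) for search property tests."""
    raw = -scale * rng.random((n, n))
    raw = np.triu(raw, k=2)
    e = raw + raw.T
    return InteractionMatrix(n=n, e_attr=e, e_rep=np.zeros((n, n)))


@pytest.fixture(scope="session")
def default_params() -> FreeEnergyParams:
    return FreeEnergyParams()


@pytest.fixture(scope="session")
def default_backend() -> EnergyBackendParams:
    return EnergyBackendParams()


@pytest.fixture(scope="session")
def tail_ensemble():
    """Small ensemble with planted 6/4-residue tails and its ground truth."""
    spec = SyntheticSpec(n_core=30, n_tail_n=6, n_tail_c=4, n_models=5, seed=11)
    return generate_ensemble(spec)


@pytest.fixture(scope="session")
def loop_ensemble():
    """Ensemble with one planted 8-residue internal loop."""
    spec = SyntheticSpec(n_core=36, loops=((18, 8),), n_models=6, seed=23)
    return generate_ensemble(spec)
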