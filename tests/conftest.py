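import numpy as np
import pytest

from chiflip.msm import CompositeStateSpace
from chiflip.synthetic import JumpProcessSpec


def random_reversible_generator(space: CompositeStateSpace, rng: np.random.Generator,
                                low: float = 0.01, high: float = 0.1) -> np.ndarray:
    """Random detailed-balance generator on the single-flip mask.

    Built from symmetric conductances s_ij and stationary weights pi:
    q_ij = s_ij / pi_i, so pi_i q_ij = pi_j q_ji exactly.
    """
    k = space.size
    mask = space.single_flip_mask()
    pi = rng.dirichlet(np.full(k, 5.0))
    s = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if mask[i, j]:
                s[i, j] = s[j, i] = rng.uniform(low, high)
    q = s / pi[:, None]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def random_masked_generator(space: CompositeStateSpace, rng: np.random.Generator,
                            low: float = 1e-3, high: float = 5.0) -> np.ndarray:
    """Random (generally non-reversible) generator on the single-flip mask,
    with rates drawn log-uniformly in [low, high] per ns."""
    mask = space.single_flip_mask()
    q = np.zeros(mask.shape)
    q[mask] = np.exp(rng.uniform(np.log(low), np.log(high), mask.sum()))
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@pytest.fixture
def two_state_spec() -> JumpProcessSpec:
    """Symmetric two-state process, both exit rates 1/ns."""
    return JumpProcessSpec(("A", "B"), np.array([[-1.0, 1.0], [1.0, -1.0]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
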