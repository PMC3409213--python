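import numpy as np
import pytest

from mcgsm import DeadLeavesConfig, MCGSMParams, dead_leaves


def random_spd(dim: int, rng: np.random.Generator) -> np.ndarray:
    Q = rng.standard_normal((dim, dim))
    return Q @ Q.T + dim * np.eye(dim)


def random_mcgsm(m: int, d: int, C: int, S: int, rng: np.random.Generator) -> MCGSMParams:
    """A random valid MCGSM in canonical gauge."""
    K = np.stack([random_spd(m, rng) for _ in range(C)])
    Sigma = np.stack([random_spd(d, rng) for _ in range(C)])
    A = 0.5 * rng.standard_normal((C, d, m))
    la = rng.standard_normal((C, S))
    alphas = np.exp(la - la.mean(axis=1, keepdims=True))
    return MCGSMParams(K=K, alphas=alphas, A=A, Sigma=Sigma)


@pytest.fixture(scope="session")
def dead_leaves_corpus():
    """32 seeded dead-leaves images of 128x128, shared across tests."""
    return [
        dead_leaves(DeadLeavesConfig(size=(128, 128), seed=1000 + i)) for i in range(32)
    ]
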