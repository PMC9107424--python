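import numpy as np
import pytest

from reggnn.geometry import matrix_exp


def random_spd(d: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """Random SPD matrix: exponential of a random symmetric matrix."""
    S = rng.standard_normal((d, d))
    S = scale * (S + S.T) / 2.0
    return matrix_exp(S)


def random_symmetric(d: int, rng: np.random.Generator, zero_diag: bool = False) -> np.ndarray:
    S = rng.standard_normal((d, d))
    S = (S + S.T) / 2.0
    if zero_diag:
        np.fill_diagonal(S, 0.0)
    return S


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
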