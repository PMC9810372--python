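import numpy as np
import pytest

import connwave as cw
from connwave.normalize import NormalizedConnectome


def nc_from_matrix(W: np.ndarray, frequency_hz: float = 10.0) -> NormalizedConnectome:
    """Wrap an explicit signed coupling matrix as a NormalizedConnectome.

    The base connectome gets |W| as weights and unit lengths on links, so
    the |w^(f)| <= w invariant holds by construction.
    """
    W = np.asarray(W, dtype=float)
    absW = np.abs(W)
    lengths = np.where(absW > 0, 1.0, 0.0)
    base = cw.Connectome(absW, lengths)
    return NormalizedConnectome(
        base=base,
        frequency_hz=frequency_hz,
        velocity_mps=5.0,
        delays=np.zeros_like(W),
        wave_weights=W,
    )


def triangle_nc() -> NormalizedConnectome:
    """3-node signed triangle: w12=1, w13=-1, w23=1."""
    W = np.array(
        [
            [0.0, 1.0, -1.0],
            [1.0, 0.0, 1.0],
            [-1.0, 0.0, 0.0],
        ]
    )
    W[2, 1] = 1.0  # symmetrize explicitly
    W = np.triu(W, 1) + np.triu(W, 1).T
    return nc_from_matrix(W)


@pytest.fixture
def triangle():
    return triangle_nc()


@pytest.fixture
def small_connectome():
    return cw.generate_synthetic_connectome(10, density=0.6, seed=42)


@pytest.fixture
def medium_connectome():
    return cw.generate_synthetic_connectome(30, density=0.3, seed=7)
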