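import numpy as np
import pytest

from muc3 import (
    DEFAULT_FMLP,
    DEFAULT_LTB4,
    DeviceGeometry,
    solve_channel_diffusion,
)


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def fields(geometry):
    """Solved gradient fields for both attractants over a 5-h experiment."""
    return {
        "fmlp": solve_channel_diffusion(DEFAULT_FMLP, geometry, t_end=300),
        "ltb4": solve_channel_diffusion(DEFAULT_LTB4, geometry, t_end=300),
    }


def analytic_series_profile(x, t_s, D, c0, L, n_terms=400):
    """Fourier-series solution of 1-D diffusion with c(0)=c0, c(L)=0, c(x,0)=0."""
    x = np.asarray(x, dtype=float)
    c = c0 * (1.0 - x / L)
    for n in range(1, n_terms + 1):
        c -= (
            (2.0 * c0 / np.pi)
            * (1.0 / n)
            * np.sin(n * np.pi * x / L)
            * np.exp(-(n**2) * np.pi**2 * D * t_s / L**2)
        )
    return c
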