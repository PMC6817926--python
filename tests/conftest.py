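import numpy as np
import pytest

from wavepred.model import ScaledParams


@pytest.fixture
def pulse_params() -> ScaledParams:
    """Parameters of the reference solitary-pulse evaluation (k1=3, k2=0.5)."""
    return ScaledParams(k1=3.0, k2=0.5)


@pytest.fixture
def generic_params() -> ScaledParams:
    """Parameters off the alpha1 = -beta1 slice (all gg branches generic)."""
    return ScaledParams(k1=4.0, k2=0.5)


@pytest.fixture
def xi_grid() -> np.ndarray:
    return np.linspace(-4.0, 4.0, 801)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def nderiv4(f, x, h=3e-4):
    """Fourth-order central difference (truncation ~h**4, roundoff ~eps/h)."""
    return (-f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)) / (12 * h)


def moderate_points(f, lo=-20.0, hi=20.0, n=8000, fmax=5.0, h=3e-4, count=30):
    """Sample points of a generator's validity domain away from its poles.

    Keeps locations where the function and the whole difference stencil stay
    moderate, so the numeric derivative is trustworthy; returns up to
    ``count`` of them, spread over the domain.
    """
    xi = np.linspace(lo, hi, n)
    ok = np.ones(n, dtype=bool)
    for s in (-2 * h, -h, 0.0, h, 2 * h):
        Fs = np.asarray(f(xi + s))
        ok &= np.isfinite(Fs) & (np.abs(Fs) < (fmax if s == 0.0 else 2 * fmax))
    xi = xi[ok]
    if len(xi) == 0:
        return xi
    idx = np.unique(np.linspace(0, len(xi) - 1, min(count, len(xi))).astype(int))
    return xi[idx]
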