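"""Travelling-wave reduction xi = X - c*T and residual operators.

With ``U(X, T) = u1(xi)`` and ``V(X, T) = v1(xi)`` the dimensionless system
reduces to

    -c u1' = u1 - u1**2 - u1 v1 - u1 v1**2                      (prey)
    -c v1' = v1'' - k1 k2 v1 - k1 v1**2 + k1 u1 v1 + k1 u1 v1**2  (predator)

and their sum gives the single combined scalar ODE that the expansion
methods annihilate.  Residuals here follow the "move everything to one
side" convention, with signs fixed so that the combined residual is
pointwise the exact sum of the two system residuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import sympy as sp

from .model import ScaledParams

__all__ = [
    "WaveFrame",
    "ProfilePair",
    "ClosedFormProfile",
    "residual_system",
    "residual_combined",
    "residual_report",
]

XI = sp.Symbol("xi", real=True)


@dataclass(frozen=True)
class WaveFrame:
    """A co-moving frame: wave speed c and an ordered grid of xi samples."""

    c: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", g)
        if g.ndim != 1 or g.size < 2 or not np.all(np.diff(g) > 0):
            raise ValueError("grid must be 1-D and strictly increasing")
        if not np.isfinite(self.c):
            raise ValueError("wave speed must be finite")


class ProfilePair:
    """Prey/predator profiles (u1, v1) on the wave coordinate.

    Profiles are callables of xi.  Analytic derivatives can be supplied
    (closed-form solutions do); otherwise second-order finite differences of
    the callables are used, with step sizes ``fd_step`` (first derivative)
    and ``fd_step2`` (second derivative).
    """

    def __init__(
        self,
        u1: Callable,
        v1: Callable,
        du1: Callable | None = None,
        dv1: Callable | None = None,
        d2v1: Callable | None = None,
        fd_step: float = 1e-6,
        fd_step2: float = 1e-4,
    ) -> None:
        self.u1 = u1
        self.v1 = v1
        self.du1 = du1
        self.dv1 = dv1
        self.d2v1 = d2v1
        self.fd_step = float(fd_step)
        self.fd_step2 = float(fd_step2)

    def _d1(self, f: Callable, xi: np.ndarray) -> np.ndarray:
        h = self.fd_step
        return (np.asarray(f(xi + h), dtype=float) - np.asarray(f(xi - h), dtype=float)) / (2.0 * h)

    def _d2(self, f: Callable, xi: np.ndarray) -> np.ndarray:
        h = self.fd_step2
        return (
            np.asarray(f(xi + h), dtype=float)
            - 2.0 * np.asarray(f(xi), dtype=float)
            + np.asarray(f(xi - h), dtype=float)
        ) / (h * h)

    def eval(self, xi: np.ndarray):
        """Return (u, du, v, dv, d2v) arrays on the given points."""
        xi = np.asarray(xi, dtype=float)
        u = np.asarray(self.u1(xi), dtype=float)
        v = np.asarray(self.v1(xi), dtype=float)
        du = np.asarray(self.du1(xi), dtype=float) if self.du1 else self._d1(self.u1, xi)
        dv = np.asarray(self.dv1(xi), dtype=float) if self.dv1 else self._d1(self.v1, xi)
        d2v = np.asarray(self.d2v1(xi), dtype=float) if self.d2v1 else self._d2(self.v1, xi)
        return u, du, v, dv, d2v


def _sanitize(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    return np.where(np.isfinite(arr), arr, np.nan)


def residual_system(pp: ProfilePair, frame: WaveFrame, p: ScaledParams):
    """Pointwise residuals of the prey and predator travelling-wave ODEs.

    r_a = c u1' + u1 - u1**2 - u1 v1 - u1 v1**2
    r_b = c v1' + v1'' - k1 k2 v1 - k1 v1**2 + k1 u1 v1 + k1 u1 v1**2

    Non-finite profile values propagate as NaN entries (reported, not raised).
    """
    with np.errstate(all="ignore"):
        u, du, v, dv, d2v = pp.eval(frame.grid)
        c = frame.c
        ra = c * du + u - u * u - u * v - u * v * v
        rb = c * dv + d2v - p.k1 * p.k2 * v - p.k1 * v * v + p.k1 * u * v + p.k1 * u * v * v
    return _sanitize(ra), _sanitize(rb)


def residual_combined(pp: ProfilePair, frame: WaveFrame, p: ScaledParams) -> np.ndarray:
    """Pointwise residual of the combined scalar ODE (the sum of the two above)."""
    with np.errstate(all="ignore"):
        u, du, v, dv, d2v = pp.eval(frame.grid)
        c, k1 = frame.c, p.k1
        r = (
            c * (du + dv)
            + d2v
            - k1 * p.k2 * v
            - k1 * v * v
            + u
            - u * u
            - (1.0 - k1) * u * v
            - (1.0 - k1) * u * v * v
        )
    return _sanitize(r)


def residual_report(pp: ProfilePair, frame: WaveFrame, p: ScaledParams):
    """Residual table and summary.

    Returns ``(DataFrame[xi, r_a, r_b, r_combined], summary dict)``; the
    summary carries NaN-masked max norms and the masked-point count.
    """
    ra, rb = residual_system(pp, frame, p)
    rc = residual_combined(pp, frame, p)
    df = pd.DataFrame({"xi": frame.grid, "r_a": ra, "r_b": rb, "r_combined": rc})
    masked = int(np.sum(~np.isfinite(rc)))
    summary = {
        "max_abs_r_a": float(np.nanmax(np.abs(ra))) if np.any(np.isfinite(ra)) else float("nan"),
        "max_abs_r_b": float(np.nanmax(np.abs(rb))) if np.any(np.isfinite(rb)) else float("nan"),
        "max_abs_r_combined": float(np.nanmax(np.abs(rc))) if np.any(np.isfinite(rc)) else float("nan"),
        "masked_points": masked,
        "n_points": int(frame.grid.size),
    }
    return df, summary


@dataclass
class ClosedFormProfile:
    """A travelling-wave solution (u1, v1) = (alpha1*F, beta1*F) with symbolic F.

    Derivatives are taken analytically from the sympy expression, so the
    residual operators see the exact closed form.  ``c`` may have been a free
    parameter of the family; the value recorded here is the one the profile
    travels with.
    """

    F_expr: sp.Expr
    alpha1: float
    beta1: float
    c: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        F = self.F_expr
        mods = ["numpy"]
        self._F = _nanwrap(sp.lambdify(XI, F, mods))
        self._dF = _nanwrap(sp.lambdify(XI, sp.diff(F, XI), mods))
        self._d2F = _nanwrap(sp.lambdify(XI, sp.diff(F, XI, 2), mods))

    def u1(self, xi):
        return self.alpha1 * self._F(xi)

    def v1(self, xi):
        return self.beta1 * self._F(xi)

    def profile_pair(self) -> ProfilePair:
        a, b = self.alpha1, self.beta1
        return ProfilePair(
            u1=lambda x: a * self._F(x),
            v1=lambda x: b * self._F(x),
            du1=lambda x: a * self._dF(x),
            dv1=lambda x: b * self._dF(x),
            d2v1=lambda x: b * self._d2F(x),
        )

    def evaluate(self, x, t):
        """U(x, t), V(x, t) on broadcast arrays of space and time."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        xi = x - self.c * t
        F = self._F(xi)
        return self.alpha1 * F, self.beta1 * F


def _nanwrap(f: Callable) -> Callable:
    def g(x):
        x = np.asarray(x, dtype=float)
        with np.errstate(all="ignore"):
            y = np.asarray(f(x), dtype=float)
        y = np.broadcast_to(y, x.shape).copy() if y.shape != x.shape else y
        return np.where(np.isfinite(y), y, np.nan)

    return g
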