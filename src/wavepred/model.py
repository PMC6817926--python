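"""Diffusive predator-prey model with a two-predators-one-prey interaction term.

The dimensional model tracks a prey density ``u`` and a predator density
``v``.  Beyond the classical logistic growth, linear predation and predator
mortality, it carries an ``u v**2`` term: during the mating period male and
female predators feed together on the same prey, which boosts predator
recruitment and accelerates prey decay.  Prey do not diffuse (``D1 = 0``);
predators move towards the prey with diffusivity ``D2``.

After rescaling, the dimensionless system in prey ``U`` and predator ``V`` is

    U_t = U - U**2 - U*V - U*V**2
    V_t = V_XX - k1*k2*V - k1*V**2 + k1*U*V + k1*U*V**2

with two dimensionless composites: ``k1`` measures the strength of the
pair-predation interaction relative to intraspecific prey competition, and
``k2`` is the scaled predator mortality.  The regime ``k1 > 1`` (pair
predation dominating competition, ``a4 > a2**2/a1``) is the biologically
admitted one; both exact-solution families below degenerate at ``k1 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

__all__ = [
    "DimensionalParams",
    "ScaledParams",
    "Equilibrium",
    "DegenerateParameterError",
    "kinetics",
    "equilibria",
    "nondimensionalize",
    "require_solvable",
]


class DegenerateParameterError(ValueError):
    """Raised by solver operations when ``k1 == 1`` (both families divide by k1 - 1)."""


@dataclass(frozen=True)
class DimensionalParams:
    """Positive rate constants of the dimensional model.

    a1: prey growth rate; a2: prey decay from intraspecific competition;
    a3: decay from single-predator predation; a4: decay from the
    two-predators-one-prey interaction; a5: predator mortality;
    a6: predator intraspecific competition.  D1, D2: diffusivities
    (the model assumes D1 = 0: only the predator diffuses).
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    D1: float = 0.0
    D2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "a5", "a6"):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate constant {name} must be positive, got {getattr(self, name)!r}")
        if self.D1 < 0:
            raise ValueError("D1 must be nonnegative")
        if not self.D2 > 0:
            raise ValueError("D2 must be positive")


@dataclass(frozen=True)
class ScaledParams:
    """Dimensionless parameters (k1, k2) of the rescaled system."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError("k1 must be positive")
        if not self.k2 > 0:
            raise ValueError("k2 must be positive")

    @property
    def solvable(self) -> bool:
        """Both exact-solution families require k1 != 1."""
        return self.k1 != 1.0

    @property
    def biologically_admissible(self) -> bool:
        """k1 > 1 encodes a4 > a2**2/a1, the regime admitted on biological grounds."""
        return self.k1 > 1.0


def require_solvable(p: ScaledParams) -> None:
    if not p.solvable:
        raise DegenerateParameterError("degenerate: k1 = 1 (solution families divide by k1 - 1)")


@dataclass(frozen=True)
class Equilibrium:
    """A spatially homogeneous steady state of the kinetics.

    ``stability_tag`` is a contextual label only; no stability analysis is
    performed.  ``biological`` marks nonnegative-density states.
    """

    U_star: float
    V_star: float
    stability_tag: str = "not-assessed"
    biological: bool = True


def kinetics(U, V, p: ScaledParams):
    """Reaction terms of the dimensionless system (diffusion excluded).

    Returns ``(dU/dt, dV/dt)`` evaluated pointwise; accepts scalars or
    ndarrays.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    fU = U - U * U - U * V - U * V * V
    fV = p.k1 * (-p.k2 * V - V * V + U * V + U * V * V)
    if fU.ndim == 0:
        return float(fU), float(fV)
    return fU, fV


def _polish_cubic_root(v: float, k2: float, iters: int = 8) -> float:
    # Newton on V^3 + 2V^2 + V + (k2 - 1)
    for _ in range(iters):
        f = ((v + 2.0) * v + 1.0) * v + (k2 - 1.0)
        df = (3.0 * v + 4.0) * v + 1.0
        if df == 0.0:
            break
        step = f / df
        v -= step
        if abs(step) < 1e-15 * max(1.0, abs(v)):
            break
    return v


def equilibria(p: ScaledParams, tol: float = 1e-12) -> list[Equilibrium]:
    """All real homogeneous steady states, sorted by V*.

    Besides extinction ``(0, 0)`` and the prey-only state ``(1, 0)``,
    coexistence states satisfy ``U = (k2 + V)/(1 + V)`` together with
    ``1 - U - V - V**2 = 0``, i.e. ``V`` is a real root of the cubic
    ``V**3 + 2V**2 + V + (k2 - 1) = 0``.  Negative-density branches are
    returned with ``biological=False`` rather than suppressed.
    """
    found: list[Equilibrium] = [
        Equilibrium(0.0, 0.0, "extinction"),
        Equilibrium(1.0, 0.0, "prey-only"),
    ]
    roots = np.roots([1.0, 2.0, 1.0, p.k2 - 1.0])
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        v = _polish_cubic_root(float(r.real), p.k2)
        if abs(1.0 + v) < 1e-9:
            # U = (k2+V)/(1+V) undefined; occurs only at k2 = 1 where the
            # branch collapses into a double root with no paired prey level.
            continue
        u = (p.k2 + v) / (1.0 + v)
        if any(abs(u - e.U_star) < 1e-9 and abs(v - e.V_star) < 1e-9 for e in found):
            continue
        fU, fV = kinetics(u, v, p)
        if max(abs(fU), abs(fV)) > tol:
            continue
        bio = u >= -1e-12 and v >= -1e-12
        found.append(Equilibrium(u, v, "coexistence", biological=bio))
    found.sort(key=lambda e: (e.V_star, e.U_star))
    return found


def nondimensionalize(d: DimensionalParams) -> ScaledParams:
    """Map dimensional rates to (k1, k2).

    ``k1 = sqrt(a1*a4)/a2`` and ``k2 = a5/(a1*k1)``.  This makes
    ``a4 > a2**2/a1`` equivalent to ``k1 > 1`` exactly; callers should check
    ``ScaledParams.biologically_admissible`` (and ``solvable``) on the result.
    """
    k1 = sqrt(d.a1 * d.a4) / d.a2
    k2 = d.a5 / (d.a1 * k1)
    return ScaledParams(k1=k1, k2=k2)
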