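"""Generalized auxiliary-equation backend.

The generator obeys (F')**2 = h0 + h1*F + h2*F**2 + h3*F**3 + h4*F**4.  With
h0 = h1 = 0 the quartic admits a catalog of closed-form branches (sech,
csch, tanh, sech**2 and their trigonometric/rational degenerations); every
branch implemented here has been checked against the defining ODE.  Solving
the collected coefficient system of the predator-prey travelling-wave ODE
gives alpha1 = -beta1, h1 = 0, h2 = 1 + k1*k2, h3 = 4*k1*beta1/3,
h4 = (k1 - 1)*beta1**2/2 with h0 free; taking h0 = 0 and the
sech**2/(2*sqrt(h2*h4)*tanh - h3) branch yields a solitary pulse with
V = -U identically.  The wave speed c never enters the coefficients (it
multiplies alpha1 + beta1 = 0) and remains a free parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import sqrt

import numpy as np
import sympy as sp

from . import expansion as ex
from .model import ScaledParams, require_solvable
from .travelling_wave import XI, ClosedFormProfile

__all__ = [
    "AuxCoefficients",
    "AuxSolution",
    "BranchPreconditionError",
    "ComplexCoefficientError",
    "BRANCHES",
    "aux_F",
    "aux_F_expr",
    "derive_aux_coefficients",
    "build_aux_solution",
]


class BranchPreconditionError(ValueError):
    """A catalog branch was requested outside its validity domain."""


class ComplexCoefficientError(ValueError):
    """Coefficients would need complex radicals (k1 < 1 makes h4 negative)."""


@dataclass(frozen=True)
class AuxCoefficients:
    """Quartic coefficients h0..h4 with the cached discriminant delta1."""

    h0: float = 0.0
    h1: float = 0.0
    h2: float = 0.0
    h3: float = 0.0
    h4: float = 0.0

    def __post_init__(self) -> None:
        if self.h2 == 0.0 and self.h3 == 0.0 and self.h4 == 0.0:
            raise ValueError("at least one of h2..h4 must be nonzero")

    @property
    def delta1(self) -> float:
        return self.h3 * self.h3 - 4.0 * self.h2 * self.h4


def _chk(name: str, cond: bool) -> None:
    if not cond:
        raise BranchPreconditionError(f"branch precondition violated: requires {name}")


# Catalog of closed-form branches of the quartic auxiliary ODE.  Each entry:
# (preconditions checker, symbolic expression builder).  Branch ids group as
# I (h0=h1=0), II (additionally h3=0), III (additionally h4=0).
def _pre_I(h: AuxCoefficients) -> None:
    _chk("h0 = 0", h.h0 == 0.0)
    _chk("h1 = 0", h.h1 == 0.0)


def _expr_I_sech(h):
    r = sp.sqrt(sp.Float(h.h2))
    return 2 * h.h2 * sp.sech(r * XI) / (sp.sqrt(sp.Float(h.delta1)) - h.h3 * sp.sech(r * XI))


def _expr_I_csch(h):
    r = sp.sqrt(sp.Float(h.h2))
    return 2 * h.h2 * sp.csch(r * XI) / (sp.sqrt(sp.Float(-h.delta1)) - h.h3 * sp.csch(r * XI))


def _expr_I_tanh(h, sign):
    r = sp.sqrt(sp.Float(h.h2)) / 2
    return -(sp.Float(h.h2) / h.h3) * (1 + sign * sp.tanh(r * XI))


def _expr_I_sech2(h):
    r = sp.sqrt(sp.Float(h.h2)) / 2
    return h.h2 * sp.sech(r * XI) ** 2 / (2 * sp.sqrt(sp.Float(h.h2 * h.h4)) * sp.tanh(r * XI) - h.h3)


def _expr_I_sec2(h):
    r = sp.sqrt(sp.Float(-h.h2)) / 2
    return h.h2 * sp.sec(r * XI) ** 2 / (-2 * sp.sqrt(sp.Float(-h.h2 * h.h4)) * sp.tan(r * XI) - h.h3)


BRANCHES: dict[str, dict] = {
    "I.sech": {
        "pre": lambda h: (_pre_I(h), _chk("h2 > 0", h.h2 > 0), _chk("delta1 > 0", h.delta1 > 0)),
        "expr": _expr_I_sech,
    },
    "I.csch": {
        "pre": lambda h: (_pre_I(h), _chk("h2 > 0", h.h2 > 0), _chk("delta1 < 0", h.delta1 < 0)),
        "expr": _expr_I_csch,
    },
    "I.tanh+": {
        "pre": lambda h: (_pre_I(h), _chk("h2 > 0", h.h2 > 0), _chk("delta1 = 0", h.delta1 == 0),
                          _chk("h3 != 0", h.h3 != 0)),
        "expr": lambda h: _expr_I_tanh(h, +1),
    },
    "I.tanh-": {
        "pre": lambda h: (_pre_I(h), _chk("h2 > 0", h.h2 > 0), _chk("delta1 = 0", h.delta1 == 0),
                          _chk("h3 != 0", h.h3 != 0)),
        "expr": lambda h: _expr_I_tanh(h, -1),
    },
    "I.sech2": {
        "pre": lambda h: (_pre_I(h), _chk("h2 > 0", h.h2 > 0), _chk("h2*h4 >= 0", h.h2 * h.h4 >= 0)),
        "expr": _expr_I_sech2,
    },
    "I.sec2": {
        "pre": lambda h: (_pre_I(h), _chk("h2 < 0", h.h2 < 0), _chk("h2*h4 <= 0", h.h2 * h.h4 <= 0)),
        "expr": _expr_I_sec2,
    },
    "II.sech": {
        "pre": lambda h: (_pre_I(h), _chk("h3 = 0", h.h3 == 0.0), _chk("h2 > 0", h.h2 > 0),
                          _chk("h4 < 0", h.h4 < 0)),
        "expr": lambda h: sp.sqrt(sp.Float(-h.h2 / h.h4)) * sp.sech(sp.sqrt(sp.Float(h.h2)) * XI),
    },
    "II.sec": {
        "pre": lambda h: (_pre_I(h), _chk("h3 = 0", h.h3 == 0.0), _chk("h2 < 0", h.h2 < 0),
                          _chk("h4 > 0", h.h4 > 0)),
        "expr": lambda h: sp.sqrt(sp.Float(-h.h2 / h.h4)) * sp.sec(sp.sqrt(sp.Float(-h.h2)) * XI),
    },
    "II.rational": {
        "pre": lambda h: (_pre_I(h), _chk("h3 = 0", h.h3 == 0.0), _chk("h2 = 0", h.h2 == 0.0),
                          _chk("h4 > 0", h.h4 > 0)),
        "expr": lambda h: 1 / (sp.sqrt(sp.Float(h.h4)) * XI),
    },
    "III.sech2": {
        "pre": lambda h: (_pre_I(h), _chk("h4 = 0", h.h4 == 0.0), _chk("h2 > 0", h.h2 > 0),
                          _chk("h3 != 0", h.h3 != 0)),
        "expr": lambda h: -(sp.Float(h.h2) / h.h3) * sp.sech(sp.sqrt(sp.Float(h.h2)) / 2 * XI) ** 2,
    },
    "III.sec2": {
        "pre": lambda h: (_pre_I(h), _chk("h4 = 0", h.h4 == 0.0), _chk("h2 < 0", h.h2 < 0),
                          _chk("h3 != 0", h.h3 != 0)),
        "expr": lambda h: -(sp.Float(h.h2) / h.h3) * sp.sec(sp.sqrt(sp.Float(-h.h2)) / 2 * XI) ** 2,
    },
    # The rational degeneration of the h4 = 0 case: 4/(h3*xi**2) solves the
    # defining ODE (the 1/(h3*xi**2) form sometimes quoted does not).
    "III.rational": {
        "pre": lambda h: (_pre_I(h), _chk("h4 = 0", h.h4 == 0.0), _chk("h2 = 0", h.h2 == 0.0),
                          _chk("h3 != 0", h.h3 != 0)),
        "expr": lambda h: 4 / (sp.Float(h.h3) * XI**2),
    },
}


def aux_F_expr(h: AuxCoefficients, branch_id: str) -> sp.Expr:
    """Symbolic generator for a catalog branch (preconditions enforced)."""
    if branch_id not in BRANCHES:
        raise KeyError(f"unknown branch {branch_id!r}; known: {sorted(BRANCHES)}")
    BRANCHES[branch_id]["pre"](h)
    return BRANCHES[branch_id]["expr"](h)


def aux_F(xi, h: AuxCoefficients, branch_id: str):
    """Numeric evaluation of a catalog branch; denominator zeros return NaN."""
    expr = aux_F_expr(h, branch_id)
    f = sp.lambdify(XI, expr, "numpy")
    xi = np.asarray(xi, dtype=float)
    with np.errstate(all="ignore"):
        y = np.asarray(f(xi), dtype=float)
    y = np.broadcast_to(y, xi.shape).copy() if y.shape != xi.shape else y
    y = np.where(np.isfinite(y), y, np.nan)
    return float(y) if y.ndim == 0 else y


@dataclass
class AuxSolution:
    """The auxiliary-method family at numeric (k1, k2, beta1): coefficients only.

    ``h0`` stays free in the derivation; the pulse evaluator assumes h0 = 0.
    ``catalog_branch`` records which catalog entry generates the closed-form
    pulse (identified by inspection of the printed solution, not claimed
    beyond that).
    """

    params: ScaledParams
    beta1: float
    alpha1: float
    coeffs: AuxCoefficients
    catalog_branch: str = "I.sech2"
    notes: list = field(default_factory=list)


def derive_aux_coefficients(p: ScaledParams, beta1_val: float, h0: float = 0.0) -> AuxSolution:
    """Solve the collected quartic system at numeric parameters.

    Yields alpha1 = -beta1, h1 = 0, h2 = 1 + k1*k2, h3 = 4*k1*beta1/3,
    h4 = (k1-1)*beta1**2/2 (computed from the symbolic family, not
    hard-coded).
    """
    require_solvable(p)
    if beta1_val == 0:
        raise ValueError("beta1 must be nonzero")
    fam = ex.quartic_family()
    vals = {ex.beta1: beta1_val, ex.k1: p.k1, ex.k2: p.k2}
    num = {str(s): float(e.subs(vals)) for s, e in fam.assignments.items()}
    coeffs = AuxCoefficients(h0=h0, h1=num["h1"], h2=num["h2"], h3=num["h3"], h4=num["h4"])
    notes = []
    if p.k1 < 1:
        notes.append("k1 < 1 gives h4 < 0: the pulse branch needs a complex radical")
    return AuxSolution(params=p, beta1=beta1_val, alpha1=num["alpha1"], coeffs=coeffs, notes=notes)


def build_aux_solution(sol: AuxSolution, c: float) -> ClosedFormProfile:
    """Solitary-pulse evaluator U(x,t) = alpha1*F(x - c t), V = -U.

    Requires h0 = 0 and real sqrt(h2*h4) (k1 > 1).  Metadata records whether
    the denominator 2*sqrt(h2*h4)*tanh - h3 can vanish on the real line: it
    cannot when \\|h3\\| > 2*sqrt(h2*h4).
    """
    h = sol.coeffs
    if h.h0 != 0.0:
        raise ValueError("pulse evaluator requires h0 = 0 (h0 != 0 families are not built)")
    if h.h2 <= 0:
        raise BranchPreconditionError("branch precondition violated: requires h2 = 1 + k1*k2 > 0")
    if h.h4 < 0:
        warnings.warn("h4 < 0 (k1 < 1): sqrt(h2*h4) is complex; refusing to build", stacklevel=2)
        raise ComplexCoefficientError("h4 < 0 (k1 < 1) makes sqrt(h2*h4) complex")
    F = aux_F_expr(h, sol.catalog_branch)
    s = 2.0 * sqrt(h.h2 * h.h4)
    den_range = (-s - h.h3, s - h.h3)  # denominator range as tanh sweeps (-1, 1)
    meta = {
        "method": "aux",
        "catalog_branch": sol.catalog_branch,
        "k1": sol.params.k1,
        "k2": sol.params.k2,
        "beta1": sol.beta1,
        "alpha1": sol.alpha1,
        "h": [h.h0, h.h1, h.h2, h.h3, h.h4],
        "delta1": h.delta1,
        "c": float(c),
        "c_free": True,
        "denominator_range": den_range,
        "pole_free": abs(h.h3) > s,
        "notes": list(sol.notes),
    }
    return ClosedFormProfile(F_expr=F, alpha1=sol.alpha1, beta1=sol.beta1, c=float(c), meta=meta)
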