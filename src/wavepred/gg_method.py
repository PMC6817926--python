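"""(G'/G)-expansion backend.

The generator F = G'/G obeys F' = -F**2 - lambda*F - mu, with G solving
G'' + lambda*G' + mu*G = 0.  The sign of the discriminant
Delta = lambda**2 - 4*mu selects the hyperbolic (kink-bearing),
trigonometric or rational branch of F.  Solving the collected coefficient
system yields two families: Case I fixes (mu, lambda, c) in terms of the
free amplitude beta1 and the model parameters, while Case II has mu = 0 with
lambda and c from the remaining quadratic conditions.  On the slice
k1 = 2/beta1**2 + 1 the amplitudes satisfy alpha1 = -beta1, the wave speed
drops out of the system entirely and must be supplied by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import atanh, isfinite, sqrt

import numpy as np
import sympy as sp

from . import expansion as ex
from .model import ScaledParams, require_solvable
from .travelling_wave import XI, ClosedFormProfile

__all__ = [
    "GGAuxiliary",
    "GGSolution",
    "InvalidConstantsError",
    "gg_F",
    "gg_F_expr",
    "derive_gg_cases",
    "derive_gg_families",
    "derive_fig2_slice",
    "build_gg_solution",
    "SLICE_TOL",
]

SLICE_TOL = 1e-10


class InvalidConstantsError(ValueError):
    """Both integration constants of the generator are zero."""


@dataclass(frozen=True)
class GGAuxiliary:
    """Generator parameters (lambda, mu) and integration constants (A1, A2)."""

    lam: float
    mu: float
    A1: float = 0.0
    A2: float = 1.0

    def __post_init__(self) -> None:
        if self.A1 == 0.0 and self.A2 == 0.0:
            raise InvalidConstantsError("integration constants (A1, A2) must not both vanish")

    @property
    def discriminant(self) -> float:
        return self.lam * self.lam - 4.0 * self.mu


def gg_F(xi, aux: GGAuxiliary):
    """The generator F(xi) on its three discriminant branches.

    Hyperbolic branch evaluated through tanh for overflow safety; poles
    (zeros of the denominator) return NaN.
    """
    xi = np.asarray(xi, dtype=float)
    d = aux.discriminant
    A1, A2 = aux.A1, aux.A2
    with np.errstate(all="ignore"):
        if d > 0:
            s = sqrt(d) / 2.0
            tau = np.tanh(s * xi)
            F = s * (A1 + A2 * tau) / (A1 * tau + A2) - aux.lam / 2.0
        elif d < 0:
            w = sqrt(-d) / 2.0
            sn, cn = np.sin(w * xi), np.cos(w * xi)
            F = w * (A1 * cn - A2 * sn) / (A1 * sn + A2 * cn) - aux.lam / 2.0
        else:
            F = A2 / (A1 + A2 * xi) - aux.lam / 2.0
    F = np.where(np.isfinite(F), F, np.nan)
    return float(F) if F.ndim == 0 else F


def gg_F_expr(aux: GGAuxiliary, xi: sp.Symbol = XI) -> sp.Expr:
    """Symbolic form of the generator (for exact derivatives in residuals)."""
    d = aux.discriminant
    A1, A2 = sp.Float(aux.A1), sp.Float(aux.A2)
    L = sp.Float(aux.lam)
    if d > 0:
        s = sp.sqrt(sp.Float(d)) / 2
        num = A1 * sp.cosh(s * xi) + A2 * sp.sinh(s * xi)
        den = A1 * sp.sinh(s * xi) + A2 * sp.cosh(s * xi)
        return s * num / den - L / 2
    if d < 0:
        w = sp.sqrt(sp.Float(-d)) / 2
        num = A1 * sp.cos(w * xi) - A2 * sp.sin(w * xi)
        den = A1 * sp.sin(w * xi) + A2 * sp.cos(w * xi)
        return w * num / den - L / 2
    return A2 / (A1 + A2 * xi) - L / 2


@dataclass
class GGSolution:
    """A numerically bound (G'/G) family at given (k1, k2, beta1).

    ``c`` is None when the wave speed is a free parameter (the
    alpha1 + beta1 = 0 slice, where c cancels from the system).
    ``validity_ok`` is False when a validity condition of the symbolic family
    is violated at these parameters (e.g. the Case I wave-speed pole).
    """

    case: str
    params: ScaledParams
    beta1: float
    alpha1: float
    lam: float
    mu: float
    c: float | None
    validity_ok: bool = True
    notes: list = field(default_factory=list)

    @property
    def discriminant(self) -> float:
        return self.lam * self.lam - 4.0 * self.mu


def _on_slice(p: ScaledParams, beta1_val: float) -> bool:
    return abs(beta1_val**2 * (p.k1 - 1.0) - 2.0) < SLICE_TOL


@lru_cache(maxsize=None)
def _slice_exprs():
    """Symbolic Case II on the alpha1 = -beta1 slice: solve the system with
    mu = 0 under k1 = 2/beta1**2 + 1 (c drops out)."""
    sys = ex.gg_system()
    k1_slice = 2 / ex.beta1**2 + 1
    eqs = [sp.expand(e.subs({ex.mu: 0, ex.k1: k1_slice})) for e in sys.equations]
    a1 = sp.solve(sp.cancel(eqs[0] / ex.beta1), ex.alpha1)[0]
    lam_v = sp.solve(eqs[1].subs(ex.alpha1, a1), ex.lam)[0]
    k2_v = sp.solve(eqs[2].subs({ex.alpha1: a1, ex.lam: lam_v}), ex.k2)[0]
    return {
        "alpha1": sp.simplify(a1),
        "lam": sp.simplify(lam_v),
        "k1": sp.simplify(k1_slice),
        "k2": sp.simplify(k2_v),
    }


def derive_fig2_slice(beta1_val: float | None = None) -> dict:
    """Case II slice relations, symbolic (beta1 free) or numeric at beta1.

    Returns alpha1 = -beta1, lambda = 2*(beta1**2+2)/(3*beta1),
    k1 = 2/beta1**2 + 1 and the matching k2, derived by solving the
    coefficient system rather than transcribed.
    """
    exprs = _slice_exprs()
    if beta1_val is None:
        return dict(exprs)
    return {k: float(v.subs(ex.beta1, beta1_val)) for k, v in exprs.items()}


def derive_gg_families(p: ScaledParams, beta1_val: float) -> list[GGSolution]:
    """All nontrivial (G'/G) families bound at numeric (k1, k2, beta1)."""
    require_solvable(p)
    if beta1_val == 0:
        raise ValueError("beta1 must be nonzero")
    vals = {ex.beta1: beta1_val, ex.k1: p.k1, ex.k2: p.k2}
    out: list[GGSolution] = []
    slice_mode = _on_slice(p, beta1_val)
    for fam in ex.gg_families():
        if fam.trivial:
            continue
        a1 = float(fam.assignments[ex.alpha1].subs(vals))
        if fam.case_label == "gg Case I":
            mu_v = float(fam.assignments[ex.mu].subs(vals))
            lam_v = float(fam.assignments[ex.lam].subs(vals))
            if slice_mode:
                out.append(
                    GGSolution(
                        "I", p, beta1_val, a1, lam_v, mu_v, None, validity_ok=False,
                        notes=["beta1**2*(k1-1) = 2: Case I wave speed pole; family flagged invalid"],
                    )
                )
            else:
                c_v = float(fam.assignments[ex.c].subs(vals))
                out.append(GGSolution("I", p, beta1_val, a1, lam_v, mu_v, c_v))
        else:
            if slice_mode:
                continue  # generic Case II branches are 0/0 here; slice handled below
            lam_e = fam.assignments[ex.lam].subs(vals)
            if not lam_e.is_real:
                out.append(
                    GGSolution(
                        fam.case_label.replace("gg Case ", ""), p, beta1_val, a1,
                        float("nan"), 0.0, None, validity_ok=False,
                        notes=["lambda branch is complex at these parameters"],
                    )
                )
                continue
            lam_v = float(lam_e)
            c_v = float(fam.assignments[ex.c].subs(vals))
            out.append(GGSolution(fam.case_label.replace("gg Case ", ""), p, beta1_val, a1, lam_v, 0.0, c_v))
    if slice_mode:
        s = derive_fig2_slice(beta1_val)
        out.append(
            GGSolution(
                "II-slice", p, beta1_val, s["alpha1"], s["lam"], 0.0, None,
                notes=["alpha1 + beta1 = 0: wave speed cancels from the system and is a free parameter"],
            )
        )
    return out


def derive_gg_cases(p: ScaledParams, beta1_val: float) -> tuple[GGSolution, GGSolution]:
    """(Case I, Case II) at numeric parameters.

    Case II is the slice solution when beta1**2*(k1-1) = 2, else the first
    real mu = 0 branch.
    """
    fams = derive_gg_families(p, beta1_val)
    case_I = next(f for f in fams if f.case == "I")
    case_II = next(f for f in fams if f.case.startswith("II") and (f.validity_ok or f.c is None))
    return case_I, case_II


def build_gg_solution(
    sol: GGSolution,
    A1: float = 0.0,
    A2: float = 1.0,
    c_if_free: float | None = None,
) -> ClosedFormProfile:
    """Evaluator U = alpha1*F(x - c t), V = beta1*F(x - c t).

    Defaults A1 = 0, A2 = 1 give the bounded tanh-type kink on the
    hyperbolic branch (A1 = 1, A2 = 0 is the coth-type branch with a pole at
    xi = 0).  When the family leaves c free, ``c_if_free`` must be supplied.
    """
    if sol.c is None and c_if_free is None:
        raise ValueError("wave speed is a free parameter for this family; pass c_if_free")
    c_val = sol.c if sol.c is not None else float(c_if_free)
    aux = GGAuxiliary(lam=sol.lam, mu=sol.mu, A1=A1, A2=A2)
    meta = {
        "method": "gg",
        "case": sol.case,
        "k1": sol.params.k1,
        "k2": sol.params.k2,
        "beta1": sol.beta1,
        "alpha1": sol.alpha1,
        "lam": sol.lam,
        "mu": sol.mu,
        "A1": A1,
        "A2": A2,
        "c": c_val,
        "c_free": sol.c is None,
        "discriminant": aux.discriminant,
        "branch": "hyperbolic" if aux.discriminant > 0 else ("trigonometric" if aux.discriminant < 0 else "rational"),
        "paper_branch": aux.discriminant > 0,
        "notes": list(sol.notes),
    }
    if aux.discriminant > 0:
        s = sqrt(aux.discriminant) / 2.0
        meta["plateaus_F"] = [-sol.lam / 2.0 - s, -sol.lam / 2.0 + s]
        # pole of the hyperbolic branch: A1*tanh(s xi) + A2 = 0
        if A1 != 0 and abs(A2 / A1) < 1.0:
            meta["pole_xi"] = atanh(-A2 / A1) / s
    return ClosedFormProfile(F_expr=gg_F_expr(aux), alpha1=sol.alpha1, beta1=sol.beta1, c=c_val, meta=meta)
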