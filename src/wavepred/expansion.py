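"""Generic function-expansion engine for the combined travelling-wave ODE.

The pipeline mirrors the standard expansion recipe: pick polynomial ansaetze
``u1 = sum(alpha_i F**i)``, ``v1 = sum(beta_i F**i)`` in a generator function
F(xi); fix the degrees by homogeneous balance; substitute into the combined
ODE, rewriting F' and F'' through the auxiliary rule the generator obeys;
collect coefficients of each power of F (and of any irreducible bare F'
term); and solve the resulting nonlinear algebraic system symbolically, with
beta1 kept as a free parameter.

Two auxiliary rules are supported:

* ``gg``      -- F' = -F**2 - lambda*F - mu (the (G'/G) generator), for which
                 F'' = (-2F - lambda) * F' rewrites polynomially;
* ``quartic`` -- (F')**2 = h0 + h1 F + h2 F**2 + h3 F**3 + h4 F**4 (the
                 generalized auxiliary equation), for which F'' = h1/2 +
                 h2 F + (3/2) h3 F**2 + 2 h4 F**3 while a bare F' cannot be
                 rewritten and its coefficient must vanish on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import sympy as sp

__all__ = [
    "F",
    "FP",
    "alpha1",
    "beta1",
    "lam",
    "mu",
    "c",
    "k1",
    "k2",
    "h0",
    "h1",
    "h2",
    "h3",
    "h4",
    "AuxiliaryRule",
    "GG_RULE",
    "QUARTIC_RULE",
    "PolynomialAnsatz",
    "paper_ansatz",
    "AlgebraicSystem",
    "SolutionFamily",
    "NoBalanceError",
    "InternalConsistencyError",
    "UnsolvedSystemError",
    "homogeneous_balance",
    "substitute_and_collect",
    "solve_system",
    "gg_system",
    "quartic_system",
    "gg_families",
    "quartic_family",
    "prove_zero",
]

# Canonical symbols.  beta1 is the free amplitude of the predator ansatz;
# k1, k2 are the dimensionless model parameters; c the wave speed.
F = sp.Symbol("F")
FP = sp.Symbol("Fprime")
_FPP = sp.Symbol("Fsecond")
alpha1, beta1 = sp.symbols("alpha1 beta1", real=True)
lam, mu = sp.symbols("lambda mu", real=True)
c = sp.Symbol("c", real=True)
k1, k2 = sp.symbols("k1 k2", positive=True)
h0, h1, h2, h3, h4 = sp.symbols("h0:5", real=True)


class NoBalanceError(ValueError):
    """No positive-integer degree pair balances nonlinearity against dispersion."""


class InternalConsistencyError(RuntimeError):
    """Leftover non-polynomial structure after rewriting through the auxiliary rule."""


class UnsolvedSystemError(RuntimeError):
    """The symbolic solver returned no branch for a collected system."""


@dataclass(frozen=True)
class AuxiliaryRule:
    """An auxiliary ODE for the generator F, with polynomial rewrite rules.

    ``second_deriv_gain`` is the polynomial degree gained by differentiating
    twice (2 for both rules here); it drives the homogeneous balance.
    """

    kind: str  # "gg" | "quartic"
    second_deriv_gain: int = 2

    def fprime(self) -> sp.Expr | None:
        """F' as a polynomial in F, or None when only (F')**2 rewrites."""
        if self.kind == "gg":
            return -(F**2) - lam * F - mu
        return None

    def fprime_squared(self) -> sp.Expr:
        if self.kind == "gg":
            fp = self.fprime()
            return sp.expand(fp * fp)
        return h0 + h1 * F + h2 * F**2 + h3 * F**3 + h4 * F**4

    def fsecond(self) -> sp.Expr:
        """F'' as a polynomial in F."""
        if self.kind == "gg":
            fp = self.fprime()
            return sp.expand(sp.diff(fp, F) * fp)
        return sp.expand(sp.diff(self.fprime_squared(), F) / 2)

    @property
    def symbols(self) -> tuple[sp.Symbol, ...]:
        return (lam, mu) if self.kind == "gg" else (h0, h1, h2, h3, h4)


GG_RULE = AuxiliaryRule("gg")
QUARTIC_RULE = AuxiliaryRule("quartic")


@dataclass(frozen=True)
class PolynomialAnsatz:
    """Polynomial ansatz degrees and coefficients (constant terms first)."""

    n: int
    m: int
    alpha: tuple
    beta: tuple

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("ansatz degrees must be >= 1")
        if len(self.alpha) != self.n + 1 or len(self.beta) != self.m + 1:
            raise ValueError("coefficient counts must match degrees")

    def u1(self) -> sp.Expr:
        return sum(a * F**i for i, a in enumerate(self.alpha))

    def v1(self) -> sp.Expr:
        return sum(b * F**i for i, b in enumerate(self.beta))


def paper_ansatz() -> PolynomialAnsatz:
    """The degree-(1, 1) ansatz u1 = alpha1*F, v1 = beta1*F (constants zero)."""
    return PolynomialAnsatz(1, 1, (sp.Integer(0), alpha1), (sp.Integer(0), beta1))


@dataclass
class AlgebraicSystem:
    """Collected coefficient equations, each required to vanish.

    ``monomials`` pairs each equation with the monomial in (F, F') it
    multiplies, so the collected polynomial can be reconstructed exactly.
    """

    equations: list
    monomials: list
    unknowns: list
    parameters: list
    rule_kind: str

    def reconstruct(self) -> sp.Expr:
        return sp.expand(sum(e * m for e, m in zip(self.equations, self.monomials)))

    def pretty(self) -> str:
        lines = []
        for e, m in zip(self.equations, self.monomials):
            lines.append(f"[coeff of {sp.sstr(m)}]  {sp.sstr(sp.expand(e))} = 0")
        return "\n".join(lines)


@dataclass
class SolutionFamily:
    """A closed-form branch of a collected system.

    ``assignments`` maps solved symbols to expressions in the free
    parameters; ``validity`` lists the conditions under which the branch is
    defined (inequations such as k1 != 1).  Trivial branches (zero
    amplitudes) are tagged rather than dropped.
    """

    case_label: str
    assignments: dict
    validity: list
    provenance: str
    trivial: bool = False

    def back_substitute(self, system: AlgebraicSystem) -> list:
        """Residuals of the source equations under this family (should all be 0)."""
        return [prove_zero(sp.expand(eq.subs(self.assignments))) for eq in system.equations]

    def subs_numeric(self, values: dict) -> dict:
        """Evaluate the assignments at numeric free-parameter values."""
        out = {}
        for sym, expr in self.assignments.items():
            e = sp.simplify(sp.sympify(expr).subs(values))
            out[str(sym)] = complex(e) if e.is_number and not e.is_real else (float(e) if e.is_number else e)
        return out

    def as_strings(self) -> dict:
        return {
            "case": self.case_label,
            "assignments": {str(k): sp.sstr(v) for k, v in self.assignments.items()},
            "validity": [sp.sstr(v) if isinstance(v, sp.Basic) else str(v) for v in self.validity],
            "provenance": self.provenance,
            "trivial": self.trivial,
        }


def prove_zero(expr: sp.Expr) -> sp.Expr:
    """Simplification ladder used when an expression must be shown to vanish."""
    e = sp.expand(expr)
    if e == 0:
        return e
    e = sp.cancel(sp.together(e))
    if e == 0:
        return e
    e = sp.radsimp(e)
    if e == 0:
        return e
    return sp.simplify(e)


def homogeneous_balance(rule: AuxiliaryRule, n_eq_m: bool = True) -> tuple[int, int]:
    """Degrees (n, m) balancing u1*v1**2 (degree n + 2m) against v1'' (degree m + gain).

    The quadratic terms u1**2 versus u1*v1 force n = m; the remaining balance
    n + 2m = m + gain then gives 2n = gain.
    """
    g = rule.second_deriv_gain
    if not n_eq_m:
        raise NoBalanceError("only the n = m balance is consistent with the quadratic terms")
    if g <= 0 or g % 2 != 0:
        raise NoBalanceError(f"no positive-integer balance: 2n = {g} has no integer solution")
    n = g // 2
    return n, n


def combined_ode_in_F(ansatz: PolynomialAnsatz) -> sp.Expr:
    """The combined ODE with derivatives left as the abstract symbols F', F''."""
    u1, v1 = ansatz.u1(), ansatz.v1()
    du = sp.diff(u1, F) * FP
    dv = sp.diff(v1, F) * FP
    d2v = sp.diff(v1, F, 2) * FP**2 + sp.diff(v1, F) * _FPP
    return sp.expand(
        c * (du + dv)
        + d2v
        - k1 * k2 * v1
        - k1 * v1**2
        + u1
        - u1**2
        - (1 - k1) * u1 * v1
        - (1 - k1) * u1 * v1**2
    )


def substitute_and_collect(ansatz: PolynomialAnsatz, rule: AuxiliaryRule) -> AlgebraicSystem:
    """Substitute the ansatz into the combined ODE, rewrite derivatives, collect.

    Returns one equation per monomial in (F, F'); for the quartic rule a bare
    F' survives (only its square rewrites) and its coefficient is the first
    equation.  Equations are ordered: bare-F' coefficients first, then
    descending powers of F.
    """
    expr = combined_ode_in_F(ansatz).subs(_FPP, rule.fsecond())
    expr = sp.expand(expr)
    # rewrite powers of F'
    fp_poly = sp.Poly(expr, FP)
    q = rule.fprime_squared()
    rewritten = sp.Integer(0)
    for (deg,), coeff in fp_poly.terms():
        if rule.kind == "gg":
            rewritten += coeff * rule.fprime() ** deg
        else:
            even, odd = divmod(deg, 2)
            rewritten += coeff * q**even * (FP if odd else 1)
    expr = sp.expand(rewritten)

    poly = sp.Poly(expr, F, FP)
    eqs_fp: dict[int, sp.Expr] = {}
    eqs_f: dict[int, sp.Expr] = {}
    for (df, dfp), coeff in poly.terms():
        if dfp > 1:
            raise InternalConsistencyError("unreduced (F')**2 term survived the rewrite")
        if dfp == 1:
            if df != 0:
                raise InternalConsistencyError("mixed F*F' monomial cannot be collected")
            eqs_fp[df] = eqs_fp.get(df, 0) + coeff
        else:
            eqs_f[df] = eqs_f.get(df, 0) + coeff
    equations, monomials = [], []
    for d in sorted(eqs_fp, reverse=True):
        equations.append(sp.expand(eqs_fp[d]))
        monomials.append(F**d * FP)
    for d in sorted(eqs_f, reverse=True):
        equations.append(sp.expand(eqs_f[d]))
        monomials.append(F**d)
    unknowns = [alpha1, *rule.symbols, c] if rule.kind == "gg" else [alpha1, h1, h2, h3, h4]
    params = [beta1, k1, k2] if rule.kind == "gg" else [beta1, k1, k2, c, h0]
    return AlgebraicSystem(equations, monomials, unknowns, params, rule.kind)


@lru_cache(maxsize=None)
def gg_system() -> AlgebraicSystem:
    """The four coefficient equations of the (G'/G) derivation."""
    return substitute_and_collect(paper_ansatz(), GG_RULE)


@lru_cache(maxsize=None)
def quartic_system() -> AlgebraicSystem:
    """The five coefficient equations of the generalized auxiliary-equation derivation."""
    return substitute_and_collect(paper_ansatz(), QUARTIC_RULE)


def _coeff_of(system: AlgebraicSystem, monomial: sp.Expr) -> sp.Expr:
    for e, m in zip(system.equations, system.monomials):
        if m == monomial:
            return e
    raise KeyError(f"system has no {monomial} coefficient")


def _solve_gg(system: AlgebraicSystem) -> list[SolutionFamily]:
    e3 = _coeff_of(system, F**3)
    e2 = _coeff_of(system, F**2)
    e1 = _coeff_of(system, F**1)
    base_validity = [sp.Ne(k1, 1), sp.Ne(beta1, 0)]
    # cubic coefficient: beta1*(alpha1*beta1*(k1-1) + 2) = 0; nontrivial branch
    a1_sol = sp.solve(sp.cancel(e3 / beta1), alpha1)
    if not a1_sol:
        raise UnsolvedSystemError(f"cubic coefficient unsolvable:\n{system.pretty()}")
    a1_sol = sp.simplify(a1_sol[0])
    families: list[SolutionFamily] = []

    # Case I: the F**0 equation -mu*(c*(alpha1+beta1) - lambda*beta1) = 0 is
    # satisfied by constraining c; mu, lambda follow from the linear F, F**2
    # coefficients.
    c_I = sp.simplify(lam * beta1 / (a1_sol + beta1))
    lam_I = sp.solve(e2.subs({alpha1: a1_sol, c: c_I}), lam)
    if not lam_I:
        raise UnsolvedSystemError("Case I lambda equation unsolvable")
    lam_I = sp.simplify(lam_I[0])
    mu_I = sp.solve(e1.subs({alpha1: a1_sol, c: c_I, lam: lam_I}), mu)
    if not mu_I:
        raise UnsolvedSystemError("Case I mu equation unsolvable")
    mu_I = sp.simplify(mu_I[0])
    families.append(
        SolutionFamily(
            case_label="gg Case I",
            assignments={alpha1: a1_sol, lam: lam_I, mu: mu_I, c: sp.simplify(c_I.subs(lam, lam_I))},
            validity=base_validity + [sp.Ne(beta1**2 * (k1 - 1), 2)],
            provenance="gg rule; F**0 equation satisfied via c*(alpha1+beta1) = lambda*beta1",
        )
    )

    # Case II: mu = 0; c from the F**2 coefficient (linear in c), lambda from
    # the remaining quadratic -> two sign branches.
    c_II = sp.solve(e2.subs(alpha1, a1_sol), c)
    if not c_II:
        raise UnsolvedSystemError("Case II c equation unsolvable")
    c_II = sp.simplify(c_II[0])
    lam_eq = sp.numer(sp.together(e1.subs({alpha1: a1_sol, mu: 0, c: c_II})))
    lam_roots = sorted(sp.solve(lam_eq, lam), key=sp.default_sort_key)
    if not lam_roots:
        raise UnsolvedSystemError("Case II lambda quadratic unsolvable")
    for i, lr in enumerate(lam_roots):
        lr = sp.simplify(lr)
        families.append(
            SolutionFamily(
                case_label=f"gg Case II ({'ab'[i]})" if len(lam_roots) > 1 else "gg Case II",
                assignments={alpha1: a1_sol, lam: lr, mu: sp.Integer(0), c: sp.simplify(c_II.subs(lam, lr))},
                validity=base_validity + [sp.Ne(a1_sol + beta1, 0)],
                provenance="gg rule; F**0 equation satisfied by mu = 0",
            )
        )
    families.append(
        SolutionFamily(
            case_label="gg trivial",
            assignments={alpha1: sp.Integer(0), beta1: sp.Integer(0)},
            validity=[],
            provenance="gg rule; zero-amplitude branch",
            trivial=True,
        )
    )
    return families


def _solve_quartic(system: AlgebraicSystem) -> list[SolutionFamily]:
    e_fp = _coeff_of(system, FP)
    subs: dict = {}
    a1_sol = sp.solve(e_fp, alpha1)  # c*(alpha1 + beta1) = 0 with c != 0
    if not a1_sol:
        raise UnsolvedSystemError("bare-F' coefficient unsolvable")
    subs[alpha1] = sp.simplify(a1_sol[0])
    for mono, sym in ((F**0, h1), (F**1, h2), (F**2, h3), (F**3, h4)):
        eq = _coeff_of(system, mono).subs(subs)
        sol = sp.solve(eq, sym)
        if not sol:
            raise UnsolvedSystemError(f"coefficient of {mono} unsolvable for {sym}")
        subs[sym] = sp.simplify(sol[0])
    fam = SolutionFamily(
        case_label="quartic",
        assignments=subs,
        validity=[sp.Ne(k1, 1), sp.Ne(beta1, 0), sp.Ne(c, 0)],
        provenance="quartic rule; bare F' coefficient forces alpha1 = -beta1 (c != 0); h0 free",
    )
    triv = SolutionFamily(
        case_label="quartic trivial",
        assignments={alpha1: sp.Integer(0), beta1: sp.Integer(0)},
        validity=[],
        provenance="quartic rule; zero-amplitude branch",
        trivial=True,
    )
    return [fam, triv]


def solve_system(system: AlgebraicSystem) -> list[SolutionFamily]:
    """All solution branches of a collected system, beta1 kept free.

    Ordering is deterministic: gg Case I, gg Case II branches (sorted), then
    trivial branches last.  Every returned nontrivial family annihilates the
    source system on back-substitution (asserted in the test-suite).
    """
    if system.rule_kind == "gg":
        return _solve_gg(system)
    if system.rule_kind == "quartic":
        return _solve_quartic(system)
    raise ValueError(f"unknown rule kind {system.rule_kind!r}")


@lru_cache(maxsize=None)
def gg_families() -> tuple[SolutionFamily, ...]:
    return tuple(solve_system(gg_system()))


@lru_cache(maxsize=None)
def quartic_family() -> SolutionFamily:
    return solve_system(quartic_system())[0]
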