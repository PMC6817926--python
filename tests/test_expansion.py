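import numpy as np
import pytest
import sympy as sp

from wavepred import expansion as ex
from wavepred.expansion import (
    F,
    FP,
    GG_RULE,
    QUARTIC_RULE,
    AuxiliaryRule,
    NoBalanceError,
    alpha1,
    beta1,
    c,
    h1,
    h2,
    h3,
    h4,
    homogeneous_balance,
    k1,
    k2,
    lam,
    mu,
    paper_ansatz,
    substitute_and_collect,
)


def equivalent(e1, e2) -> bool:
    """Equal up to a nonzero constant factor (coefficient equations are
    only defined up to scaling)."""
    q = sp.simplify(sp.cancel(e1 / e2))
    return q.is_number and q != 0


class TestHomogeneousBalance:
    @pytest.mark.parametrize("rule", [GG_RULE, QUARTIC_RULE])
    def test_both_rules_balance_at_degree_one(self, rule):
        assert homogeneous_balance(rule) == (1, 1)

    def test_synthetic_rule_without_integer_balance_errors(self):
        odd = AuxiliaryRule("gg", second_deriv_gain=1)  # F'' gains one degree only
        with pytest.raises(NoBalanceError):
            homogeneous_balance(odd)

    @pytest.mark.parametrize("rule", [GG_RULE, QUARTIC_RULE])
    def test_balance_degrees_close_the_collected_system(self, rule):
        """At the balanced degrees the collected polynomial has no monomial
        beyond F**3 (cubic nonlinearity meets second derivative)."""
        sys = substitute_and_collect(paper_ansatz(), rule)
        max_deg = max(sp.Poly(m, F).degree() for m in sys.monomials)
        assert max_deg == 3


class TestCollectedSystems:
    def test_gg_cubic_coefficient_matches_reference_relation(self):
        sys = ex.gg_system()
        e3 = sys.equations[sys.monomials.index(F**3)]
        assert equivalent(e3, beta1 * (alpha1 * beta1 * (k1 - 1) + 2))

    def test_gg_constant_coefficient_structure(self):
        sys = ex.gg_system()
        e0 = sys.equations[sys.monomials.index(F**0)]
        assert sp.expand(e0 - (-mu * (c * (alpha1 + beta1) - lam * beta1))) == 0

    def test_quartic_first_equation_is_bare_derivative_coefficient(self):
        sys = ex.quartic_system()
        assert sys.monomials[0] == FP
        assert sp.expand(sys.equations[0] - c * (alpha1 + beta1)) == 0

    def test_quartic_constant_coefficient_forces_h1(self):
        sys = ex.quartic_system()
        e0 = sys.equations[sys.monomials.index(F**0)]
        assert equivalent(e0, beta1 * h1)

    @pytest.mark.parametrize("rule", [GG_RULE, QUARTIC_RULE])
    def test_collection_matches_direct_substitution_numerically(self, rule, rng):
        """Evaluation oracle: the collected polynomial, summed back over its
        monomials, equals direct substitution of the ansatz into the combined
        ODE at random numeric values of every symbol."""
        sys = substitute_and_collect(paper_ansatz(), rule)
        direct = ex.combined_ode_in_F(paper_ansatz())
        # rewrite the abstract F'' the same way the collector did, and give
        # F' a numeric value consistent with the rule
        for _ in range(20):
            vals = {
                F: rng.uniform(-1.5, 1.5),
                alpha1: rng.uniform(-2, 2),
                beta1: rng.uniform(0.2, 2),
                c: rng.uniform(-2, 2),
                k1: rng.uniform(1.2, 5),
                k2: rng.uniform(0.1, 2),
            }
            if rule.kind == "gg":
                vals[lam] = rng.uniform(-2, 2)
                vals[mu] = rng.uniform(-2, 2)
                fp_val = float(rule.fprime().subs(vals))
            else:
                vals[F] = rng.uniform(0.1, 1.5)  # keep the quartic positive so F' is real
                for s in rule.symbols:
                    vals[s] = rng.uniform(0.1, 2)
                fp_val = float(sp.sqrt(rule.fprime_squared().subs(vals)))
            vals[FP] = fp_val
            lhs = float(sys.reconstruct().subs(vals))
            rhs = float(direct.subs(ex._FPP, rule.fsecond()).subs(vals))
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestSolveSystem:
    def test_gg_returns_two_case_families_plus_sign_branches(self):
        fams = [f for f in ex.gg_families() if not f.trivial]
        labels = [f.case_label for f in fams]
        assert labels[0] == "gg Case I"
        assert all(l.startswith("gg Case II") for l in labels[1:])
        assert len(fams) == 3  # Case I + the two sign branches of Case II

    def test_gg_case_I_closed_forms(self):
        fI = ex.gg_families()[0]
        a = fI.assignments
        assert sp.simplify(a[alpha1] + 2 / (beta1 * (k1 - 1))) == 0
        assert sp.simplify(a[mu] - (k1 * k2 / 2 + 1 / (beta1**2 * (k1 - 1)))) == 0
        assert sp.simplify(a[lam] - (1 / beta1 + k1 * beta1 / 2 + 2 / (beta1**3 * (k1 - 1) ** 2))) == 0
        assert sp.simplify(a[c] - a[lam] * beta1**2 * (k1 - 1) / (beta1**2 * (k1 - 1) - 2)) == 0

    def test_gg_case_I_speed_constraint_holds_symbolically(self):
        fI = ex.gg_families()[0]
        a = fI.assignments
        assert sp.simplify(a[c] * (a[alpha1] + beta1) - a[lam] * beta1) == 0

    def test_gg_case_II_has_mu_zero(self):
        for f in ex.gg_families():
            if f.case_label.startswith("gg Case II"):
                assert f.assignments[mu] == 0

    def test_all_nontrivial_gg_families_annihilate_source_system(self):
        sys = ex.gg_system()
        for f in ex.gg_families():
            if f.trivial:
                continue
            assert all(r == 0 for r in f.back_substitute(sys))

    def test_quartic_family_closed_forms(self):
        fam = ex.quartic_family()
        a = fam.assignments
        assert sp.simplify(a[alpha1] + beta1) == 0
        assert a[h1] == 0
        assert sp.simplify(a[h2] - (1 + k1 * k2)) == 0
        assert sp.simplify(a[h3] - 4 * k1 * beta1 / 3) == 0
        assert sp.simplify(a[h4] - (k1 - 1) * beta1**2 / 2) == 0

    def test_quartic_family_annihilates_source_system(self):
        fam = ex.quartic_family()
        assert all(r == 0 for r in fam.back_substitute(ex.quartic_system()))

    def test_trivial_branches_tagged(self):
        assert any(f.trivial for f in ex.gg_families())
        assert any(f.trivial for f in ex.solve_system(ex.quartic_system()))

    def test_family_ordering_is_deterministic(self):
        labels1 = [f.case_label for f in ex.solve_system(ex.gg_system())]
        labels2 = [f.case_label for f in ex.solve_system(ex.gg_system())]
        assert labels1 == labels2
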