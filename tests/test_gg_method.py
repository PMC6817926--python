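import numpy as np
import pytest
import sympy as sp

from wavepred import expansion as ex
from wavepred.gg_method import (
    GGAuxiliary,
    InvalidConstantsError,
    build_gg_solution,
    derive_fig2_slice,
    derive_gg_cases,
    derive_gg_families,
    gg_F,
)
from wavepred.model import DegenerateParameterError, ScaledParams
from wavepred.travelling_wave import WaveFrame, residual_combined


from conftest import moderate_points, nderiv4


class TestGenerator:
    def test_pure_tanh_special_case(self):
        aux = GGAuxiliary(lam=0.0, mu=-1.0, A1=0.0, A2=1.0)
        xi = np.linspace(-3, 3, 101)
        assert np.allclose(gg_F(xi, aux), np.tanh(xi), atol=1e-12)

    def test_rational_branch_with_A2_zero_is_constant(self):
        aux = GGAuxiliary(lam=2.0, mu=1.0, A1=1.0, A2=0.0)
        assert gg_F(0.7, aux) == pytest.approx(-1.0)

    def test_zero_constants_rejected(self):
        with pytest.raises(InvalidConstantsError):
            GGAuxiliary(lam=1.0, mu=0.0, A1=0.0, A2=0.0)

    def test_defining_ode_on_all_branches(self, rng):
        """F' + F**2 + lambda*F + mu = 0 numerically, every discriminant sign."""
        for _ in range(30):
            lam = rng.uniform(-2, 2)
            kind = rng.integers(3)
            if kind == 0:
                mu = (lam**2 - rng.uniform(0.5, 4.0)) / 4  # Delta > 0
            elif kind == 1:
                mu = (lam**2 + rng.uniform(0.5, 4.0)) / 4  # Delta < 0
            else:
                mu = lam**2 / 4  # Delta = 0
            aux = GGAuxiliary(lam=lam, mu=mu, A1=rng.uniform(-1, 1), A2=rng.uniform(0.5, 1.5))
            f = lambda x: gg_F(x, aux)
            xi = moderate_points(f)  # validity domain with poles masked
            assert len(xi) >= 20
            F = f(xi)
            res = nderiv4(f, xi) + F**2 + aux.lam * F + aux.mu
            scale = 1.0 + F**2  # local size of the equation terms
            assert np.max(np.abs(res) / scale) < 1e-9

    def test_pole_returns_nan(self):
        aux = GGAuxiliary(lam=0.0, mu=-1.0, A1=1.0, A2=0.0)  # coth: pole at 0
        assert np.isnan(gg_F(0.0, aux))


class TestCaseDerivation:
    def test_degenerate_k1_rejected(self):
        with pytest.raises(DegenerateParameterError):
            derive_gg_cases(ScaledParams(1.0, 0.5), 1.0)

    def test_case_II_reports_mu_zero(self, generic_params):
        _, cII = derive_gg_cases(generic_params, 1.0)
        assert cII.mu == 0.0

    def test_amplitude_relation_holds_for_all_families(self, generic_params):
        for f in derive_gg_families(generic_params, 1.3):
            assert f.alpha1 * f.beta1 * (generic_params.k1 - 1) + 2 == pytest.approx(0.0, abs=1e-12)

    def test_case_I_pole_on_slice_flagged_invalid(self):
        p = ScaledParams(3.0, 0.5)  # beta1 = 1 puts beta1**2*(k1-1) = 2
        cI, cII = derive_gg_cases(p, 1.0)
        assert not cI.validity_ok
        assert cI.c is None
        assert cII.case == "II-slice" and cII.c is None

    def test_fig2_slice_symbolic_identities(self):
        """Solving the system with mu = 0 under k1 = 2/beta1**2 + 1 must give
        alpha1 = -beta1, lambda = 2(beta1**2+2)/(3 beta1) and
        k2 = (4 beta1**4 + 7 beta1**2 + 16)/(9 beta1**2 + 18)."""
        s = derive_fig2_slice()
        b = ex.beta1
        assert sp.simplify(s["alpha1"] + b) == 0
        assert sp.simplify(s["lam"] - 2 * (b**2 + 2) / (3 * b)) == 0
        assert sp.simplify(s["k2"] - (4 * b**4 + 7 * b**2 + 16) / (9 * b**2 + 18)) == 0

    def test_fig2_slice_numeric_values(self):
        s = derive_fig2_slice(0.5)
        assert s["alpha1"] == pytest.approx(-0.5)
        assert s["lam"] == pytest.approx(3.0)
        assert s["k1"] == pytest.approx(9.0)
        assert s["k2"] == pytest.approx(8 / 9)


class TestBuiltSolutions:
    def test_predator_prey_ratio_is_constant(self, generic_params):
        cI, _ = derive_gg_cases(generic_params, 1.0)
        prof = build_gg_solution(cI)
        x = np.linspace(-3, 3, 50)
        U, V = prof.evaluate(x, 0.5)
        m = np.isfinite(U) & (np.abs(U) > 1e-12)
        assert np.allclose(V[m] / U[m], prof.beta1 / prof.alpha1)

    def test_slice_kink_annihilates_combined_ode(self, xi_grid):
        s = derive_fig2_slice(0.5)
        p = ScaledParams(s["k1"], s["k2"])
        _, cII = derive_gg_cases(p, 0.5)
        prof = build_gg_solution(cII, A1=0.0, A2=1.0, c_if_free=1.0)
        r = residual_combined(prof.profile_pair(), WaveFrame(1.0, xi_grid), p)
        assert np.nanmax(np.abs(r)) <= 1e-8

    def test_all_generic_families_annihilate_combined_ode(self, generic_params, xi_grid):
        for f in derive_gg_families(generic_params, 1.0):
            prof = build_gg_solution(f)
            r = residual_combined(prof.profile_pair(), WaveFrame(prof.c, xi_grid), generic_params)
            assert np.nanmax(np.abs(r)) <= 1e-8

    def test_free_speed_requires_explicit_c(self):
        p = ScaledParams(3.0, 0.5)
        _, cII = derive_gg_cases(p, 1.0)
        with pytest.raises(ValueError, match="free"):
            build_gg_solution(cII)
        prof = build_gg_solution(cII, c_if_free=2.0)
        assert prof.meta["c_free"] and prof.c == 2.0

    def test_plateaus_are_fixed_points_of_the_generator_ode(self, generic_params):
        cI, _ = derive_gg_cases(generic_params, 1.0)
        prof = build_gg_solution(cI)
        for plateau in prof.meta["plateaus_F"]:
            assert plateau**2 + cI.lam * plateau + cI.mu == pytest.approx(0.0, abs=1e-9)

    def test_hyperbolic_kink_is_monotone_between_plateaus(self, generic_params):
        """With A1*A2 >= 0 and Delta > 0 the generator is a monotone kink."""
        cI, _ = derive_gg_cases(generic_params, 1.0)
        aux = GGAuxiliary(lam=cI.lam, mu=cI.mu, A1=0.0, A2=1.0)
        xi = np.linspace(-10, 10, 2001)
        F = gg_F(xi, aux)
        dF = np.diff(F)
        assert np.all(dF >= 0) or np.all(dF <= 0)
        lo, hi = sorted(prof_plateaus := build_gg_solution(cI).meta["plateaus_F"])
        assert lo - 1e-9 <= F.min() and F.max() <= hi + 1e-9

    def test_coth_branch_pole_recorded_in_metadata(self, generic_params):
        cI, _ = derive_gg_cases(generic_params, 1.0)
        prof = build_gg_solution(cI, A1=1.0, A2=0.0)
        assert prof.meta["pole_xi"] == pytest.approx(0.0)
        assert np.isnan(prof.evaluate(np.array([prof.meta["pole_xi"]]), 0.0)[0][0])
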