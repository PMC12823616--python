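"""Riemann-Liouville / Caputo operators against Gamma-ratio closed forms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import erfcx, gamma

from fracsir.fractional import (FractionalOrder, build_operator,
                                caputo_derivative, mittag_leffler, rl_integral)
from fracsir.wavelets import HybridBasis, build_basis, make_filter, project


class TestRLIntegral:
    def test_constant_closed_form(self):
        # I^a 1 = t^a / Gamma(a+1)
        assert rl_integral(lambda t: np.ones_like(t), 0.5, 1.0).item() == \
            pytest.approx(1.0 / gamma(1.5), abs=1e-9)

    def test_alpha_one_is_ordinary_integral(self):
        assert rl_integral(lambda t: t, 1.0, 2.0).item() == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("p", [1, 2, 3])
    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7, 0.9])
    def test_power_law(self, p, alpha):
        # I^a t^p = Gamma(p+1)/Gamma(p+1+a) t^{p+a}
        t = np.array([0.5, 1.0, 4.0, 10.0])
        got = rl_integral(lambda s: s**p, alpha, t, n_panels=512)
        want = gamma(p + 1) / gamma(p + 1 + alpha) * t ** (p + alpha)
        assert np.max(np.abs(got - want) / want) < 1e-5

    def test_quadrature_refinement_reduces_error(self):
        t = np.array([1.0])
        want = gamma(3.0) / gamma(3.5) * 1.0
        errs = [abs(rl_integral(lambda s: s**2, 0.5, t, n_panels=n).item() - want)
                for n in (64, 128)]
        assert errs[0] / errs[1] >= 3.0

    def test_semigroup_property(self):
        # I^a I^b = I^{a+b} on a smooth function
        t = np.array([0.5, 1.5, 3.0])
        inner = lambda s: rl_integral(lambda u: np.sin(u), 0.4, s, n_panels=512)
        got = rl_integral(inner, 0.3, t, n_panels=512)
        want = rl_integral(lambda u: np.sin(u), 0.7, t, n_panels=2048)
        assert np.max(np.abs(got - want)) < 1e-5

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            rl_integral(lambda t: t, 0.0, 1.0)


class TestCaputo:
    def test_constant_annihilated(self):
        got = caputo_derivative(lambda t: 7.7 * np.ones_like(t), 0.6,
                                np.array([0.1, 1.0, 5.0]),
                                fprime=lambda t: np.zeros_like(t))
        assert np.max(np.abs(got)) == 0.0

    @pytest.mark.parametrize("p", [1, 2, 3])
    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7, 0.9])
    def test_power_law(self, p, alpha):
        # D^a t^p = Gamma(p+1)/Gamma(p+1-a) t^{p-a}
        t = np.array([0.5, 1.0, 4.0, 10.0])
        got = caputo_derivative(lambda s: s**p, alpha, t,
                                fprime=lambda s: p * s ** (p - 1), n_panels=512)
        want = gamma(p + 1) / gamma(p + 1 - alpha) * t ** (p - alpha)
        assert np.max(np.abs(got - want) / want) < 1e-5

    def test_classical_limit(self):
        got = caputo_derivative(lambda t: t * t, 1.0, 3.0, fprime=lambda t: 2 * t)
        assert got.item() == pytest.approx(6.0, abs=1e-12)

    def test_numeric_derivative_fallback(self):
        got = caputo_derivative(lambda t: t * t, 0.5, 1.0)
        assert got.item() == pytest.approx(2.0 / gamma(2.5), rel=1e-4)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            caputo_derivative(lambda t: t, 1.5, 1.0)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3),
           alpha=st.sampled_from([0.4, 0.8]))
    def test_linearity(self, a, b, alpha):
        t = np.array([0.5, 2.0])
        f = lambda s: np.sin(s)
        g = lambda s: s**2
        fp = lambda s: np.cos(s)
        gp = lambda s: 2 * s
        lhs = caputo_derivative(lambda s: a * f(s) + b * g(s), alpha, t,
                                fprime=lambda s: a * fp(s) + b * gp(s))
        rhs = (a * caputo_derivative(f, alpha, t, fprime=fp)
               + b * caputo_derivative(g, alpha, t, fprime=gp))
        assert np.max(np.abs(lhs - rhs)) < 1e-10 * max(1.0, abs(a), abs(b))


class TestMittagLeffler:
    def test_exponential_case(self):
        z = np.linspace(-20, 20, 9)
        assert np.max(np.abs(mittag_leffler(1.0, z) - np.exp(z))) < 1e-10

    def test_cosine_case(self):
        assert mittag_leffler(2.0, -4.0) == pytest.approx(np.cos(2.0), abs=1e-12)

    def test_half_order_against_erfcx(self):
        # E_{1/2}(-x) = exp(x^2) erfc(x), an independent scipy closed form
        for x in (0.2, 3.0, 7.0, 20.0):
            assert mittag_leffler(0.5, -x) == pytest.approx(erfcx(x), rel=1e-9)

    def test_at_zero_and_range(self):
        assert mittag_leffler(0.3, 0.0) == 1.0
        with pytest.raises(ValueError):
            mittag_leffler(0.5, -60.0)
        with pytest.raises(ValueError):
            mittag_leffler(0.0, 1.0)

    def test_series_integral_seam_is_continuous(self):
        lo = mittag_leffler(0.7, -4.999999)
        hi = mittag_leffler(0.7, -5.000001)
        assert abs(lo - hi) < 1e-6

    def test_second_parameter_recursion(self):
        # E_{a,a+1}(z) = (E_a(z) - 1)/z
        for z in (-0.5, -8.0):
            want = (mittag_leffler(0.6, z) - 1.0) / z
            assert mittag_leffler(0.6, z, beta=1.6) == pytest.approx(want, rel=1e-8)


@pytest.fixture(scope="module")
def setup():
    basis = HybridBasis(build_basis(make_filter(4), 1.0, 4))
    nodes = (np.arange(basis.n_b) + 0.5) / basis.n_b
    return basis, nodes


class TestCollocationOperator:
    def test_node_at_zero_rejected(self, setup):
        basis, _ = setup
        with pytest.raises(ValueError, match="midpoint"):
            build_operator(basis, 0.5, np.array([0.0, 0.5]))

    def test_caputo_annihilates_constants(self, setup):
        basis, nodes = setup
        op = build_operator(basis, 0.6, nodes)
        c = project(basis, lambda t: np.ones_like(t))
        assert np.max(np.abs(op.D_alpha @ c)) < 1e-6

    def test_classical_derivative_of_t(self, setup):
        basis, nodes = setup
        op = build_operator(basis, 1.0, nodes)
        c = project(basis, lambda t: t)
        assert np.max(np.abs(op.D_alpha @ c - 1.0)) < 1e-4

    def test_integral_of_constant_gives_power_law(self, setup):
        basis, nodes = setup
        op = build_operator(basis, 0.5, nodes)
        c = project(basis, lambda t: np.ones_like(t))
        want = nodes**0.5 / gamma(1.5)
        assert np.max(np.abs(op.P_alpha @ c - want)) < 1e-6

    def test_integral_inverts_derivative(self, setup):
        # I^a D^a f = f - f(0) for f = t^2 (represented in the span up to
        # the hybrid basis approximation error)
        basis, nodes = setup
        alpha = 0.5
        op = build_operator(basis, alpha, nodes)
        dvals = 2.0 / gamma(2.5) * nodes**1.5
        c = np.linalg.lstsq(basis.evaluate(nodes), dvals, rcond=None)[0]
        got = op.P_alpha @ c
        # dominated by the basis representation error of the t^{3/2} cusp
        assert np.max(np.abs(got - nodes**2)) < 5e-3

    def test_galerkin_cross_check(self, setup):
        # physical-space action and the Galerkin matrix must agree on
        # smooth span members: <D^a f, u_i> via quadrature of D_alpha rows
        basis, nodes = setup
        op = build_operator(basis, 1.0, nodes)
        c = project(basis, lambda t: t)
        g = op.gram_D_alpha @ c  # inner products of f' = 1 with basis
        want = project(basis, lambda t: np.ones_like(t))  # <1, u_i> = coeffs of 1
        # orthonormal wavelet rows agree to quadrature precision; the trend
        # ramp has wavelet-scale oscillations that the midpoint rule resolves
        # only coarsely
        assert np.max(np.abs(g[1:] - want[1:])) < 1e-6
        assert abs(g[0] - want[0]) < 0.05

    def test_fractional_order_validation(self):
        with pytest.raises(ValueError):
            FractionalOrder(0.0)
        with pytest.raises(ValueError):
            FractionalOrder(1.2)
        assert FractionalOrder(1.0).is_classical
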