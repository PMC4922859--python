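"""Characteristic polynomial, Routh-Hurwitz and the dispersion relation."""

import numpy as np
import pytest

from rdscreen import (
    RDSystem,
    char_poly_coeffs,
    dispersion,
    is_turing_unstable,
    routh_hurwitz_stable,
)

RNG = np.random.default_rng(20240917)
D_CRIT = 4 + 2 * np.sqrt(3)  # two-node instability threshold for [[1,-1],[3,-2]]


class TestCharPoly:
    def test_diagonal_matrix(self):
        cp = char_poly_coeffs(np.diag([-1.0, -2.0, -3.0]))
        assert np.allclose(cp.coeffs, (6.0, 11.0, 6.0))

    def test_two_node_with_diffusion(self, ai_jacobian):
        cp = char_poly_coeffs(ai_jacobian, np.array([1.0, 10.0]), q2=1.0)
        assert np.allclose(cp.coeffs, (12.0, 3.0))

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            char_poly_coeffs(np.ones((2, 3)))

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_polynomial_interpolation_oracle(self, n):
        """Coefficients agree with a polynomial fit of det(lambda I - M)
        sampled at N+1 points, for 25 random matrices per size."""
        for _ in range(25):
            M = RNG.normal(size=(n, n))
            cp = char_poly_coeffs(M)
            xs = np.linspace(-2, 2, n + 1)
            ys = [np.linalg.det(x * np.eye(n) - M) for x in xs]
            fit = np.polyfit(xs, ys, n)
            fit /= fit[0]
            assert np.allclose(cp.coeffs, fit[1:], atol=1e-8 * max(1, np.abs(fit).max()))

    def test_roots_at_q0_are_eigenvalues(self):
        M = RNG.normal(size=(4, 4))
        cp = char_poly_coeffs(M)
        got = np.sort_complex(cp.roots())
        want = np.sort_complex(np.linalg.eigvals(M))
        assert np.allclose(got, want, atol=1e-8)


class TestRouthHurwitz:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [
            ((6.0, 11.0, 6.0), True),    # roots -1, -2, -3
            ((1.0, 1.0, 2.0), False),    # a1*a2 < a3
            ((1.75, 3.5, 2.75), True),   # the capacitor fixture Jacobian
        ],
    )
    def test_examples(self, coeffs, expected):
        assert routh_hurwitz_stable(coeffs) is expected

    def test_unsupported_degree(self):
        with pytest.raises(ValueError, match="degree"):
            routh_hurwitz_stable((1.0,) * 6)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_agrees_with_numeric_eigenvalues(self, n):
        """1,000 random matrices per size, skipping near-marginal spectra."""
        rng = np.random.default_rng(100 + n)
        checked = 0
        for _ in range(1000):
            M = rng.normal(size=(n, n))
            abscissa = np.linalg.eigvals(M).real.max()
            if abs(abscissa) <= 1e-7:
                continue
            cp = char_poly_coeffs(M)
            assert routh_hurwitz_stable(cp) == (abscissa < 0)
            checked += 1
        assert checked > 900

    def test_degree_five_routh_array(self):
        rng = np.random.default_rng(55)
        for _ in range(200):
            M = rng.normal(size=(5, 5)) - 0.5 * np.eye(5)
            abscissa = np.linalg.eigvals(M).real.max()
            if abs(abscissa) <= 1e-7:
                continue
            assert routh_hurwitz_stable(char_poly_coeffs(M)) == (abscissa < 0)


class TestDispersion:
    def test_pure_decay_is_monotone(self):
        disp = dispersion(np.diag([-1.0, -1.0]), np.array([1.0, 1.0]))
        assert np.all(np.diff(disp.max_re_lambda) <= 1e-12)
        assert disp.q_star == 0.0

    def test_two_node_positive_maximum_at_finite_q(self, ai_jacobian):
        disp = dispersion(ai_jacobian, np.array([1.0, 10.0]))
        assert disp.max_growth > 0
        assert 0 < disp.q_star < np.inf

    def test_limit_at_infinity_is_immobile_block_abscissa(self, capacitor_system):
        disp = dispersion(capacitor_system.J, capacitor_system.D)
        assert disp.limit_at_infinity == pytest.approx(0.25)
        assert np.isinf(disp.q_star)

    def test_q0_value_equals_jacobian_abscissa(self):
        M = RNG.normal(size=(3, 3))
        disp = dispersion(M, np.array([1.0, 0.5, 0.0]))
        assert disp.max_re_lambda[0] == pytest.approx(np.linalg.eigvals(M).real.max(), abs=1e-9)

    def test_tail_approaches_limit(self):
        J = np.array([[-1.0, 0.5, 0.2], [0.1, -2.0, 0.3], [0.4, -0.2, -0.7]])
        disp = dispersion(J, np.array([1.0, 1.0, 0.0]), q2_max=1e6)
        assert disp.max_re_lambda[-1] == pytest.approx(disp.limit_at_infinity, abs=1e-3)


class TestTuringDecision:
    def test_two_node_unstable_with_large_ratio(self, ai_jacobian):
        rep = is_turing_unstable(RDSystem(ai_jacobian, np.array([1.0, 10.0])))
        assert rep.stable_at_q0 and rep.turing_unstable
        assert not rep.oscillatory

    def test_two_node_stable_at_equal_diffusivity(self, ai_jacobian):
        rep = is_turing_unstable(RDSystem(ai_jacobian, np.array([1.0, 1.0])))
        assert rep.stable_at_q0 and not rep.turing_unstable

    def test_threshold_matches_closed_form(self, ai_jacobian):
        below = is_turing_unstable(RDSystem(ai_jacobian, np.array([1.0, D_CRIT - 0.05])))
        above = is_turing_unstable(RDSystem(ai_jacobian, np.array([1.0, D_CRIT + 0.05])))
        assert not below.turing_unstable
        assert above.turing_unstable

    def test_capacitor_unstable_at_high_q(self, capacitor_system):
        rep = is_turing_unstable(capacitor_system)
        assert rep.turing_unstable
        assert np.isinf(rep.q_star)
        # the catalog convention filters these out
        strictly = is_turing_unstable(capacitor_system, require_wavelength_selection=True)
        assert not strictly.turing_unstable

    def test_not_turing_when_unstable_without_diffusion(self):
        J = np.array([[0.5, 0.1], [0.1, 0.3]])  # positive trace: unstable at q=0
        rep = is_turing_unstable(RDSystem(J, np.array([1.0, 5.0])))
        assert not rep.stable_at_q0 and not rep.turing_unstable

    def test_scaling_invariance(self, ai_jacobian):
        """(sJ, sD) scales the dispersion by s and keeps the decision."""
        D = np.array([1.0, 10.0])
        base = dispersion(ai_jacobian, D)
        for s in (0.1, 3.0):
            scaled = dispersion(s * ai_jacobian, s * D)
            assert scaled.max_growth == pytest.approx(s * base.max_growth, rel=1e-4)
            assert (
                is_turing_unstable(RDSystem(s * ai_jacobian, s * D)).turing_unstable
                == is_turing_unstable(RDSystem(ai_jacobian, D)).turing_unstable
            )

    def test_equal_diffusion_is_shifted_spectrum(self):
        """With D = d*1 the dispersion is exactly max Re eig(J) - d q^2."""
        J = RNG.normal(size=(3, 3)) - np.eye(3)
        d = 0.7
        disp = dispersion(J, np.full(3, d))
        expected = np.linalg.eigvals(J).real.max() - d * disp.q2_grid
        assert np.allclose(disp.max_re_lambda, expected, atol=1e-8)

    def test_rdsystem_validates_against_topology(self, activator_inhibitor):
        with pytest.raises(ValueError, match="contradicts"):
            RDSystem(np.array([[-0.3, -0.4], [0.4, -0.4]]), np.array([1.0, 1.0]),
                     topology=activator_inhibitor)
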