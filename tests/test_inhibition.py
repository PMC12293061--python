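"""Lateral-inhibition lattice: Hill responses, steady states, pitchfork,
and the Fourier-mode factorization of the uniform-state Jacobian."""

import numpy as np
import pytest
from scipy.optimize import brentq

from axodyn.dynsys import finite_difference_jacobian, integrate
from axodyn.inhibition import (
    InhibitionParams,
    block_eigenvalues,
    control_parameter_m,
    dense_jacobian,
    extract_mode_blocks,
    hill_f,
    hill_g,
    hill_f_prime,
    hill_g_prime,
    homogeneous_steady_state,
    inhibition_field,
    inhibition_rhs,
    mode_block,
    neighbor_mean,
    pitchfork_branches,
    pitchfork_normal_form_rhs,
    sort_spectrum,
    uniform_mode_growth_rate,
    uniform_state_stability,
)


class TestHillFunctions:
    def test_anchor_values_and_limits(self):
        assert hill_f(0.0, 1.0) == 0.0
        assert hill_f(1.0, 1.0) == 0.5
        assert hill_f(1e9, 1.0) == pytest.approx(1.0)
        assert hill_g(0.0, 1.0) == 1.0
        assert hill_g(1.0, 1.0) == 0.5
        assert hill_g(1e9, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotonicity_and_derivative_signs(self):
        x = np.linspace(0.0, 10.0, 200)
        assert np.all(np.diff(hill_f(x, 0.7)) > 0)
        assert np.all(np.diff(hill_g(x, 0.7)) < 0)
        assert np.all(hill_f_prime(x[1:], 0.7) > 0)
        assert np.all(hill_g_prime(x[1:], 0.7) < 0)

    def test_derivatives_match_finite_differences(self):
        for x in (0.3, 1.0, 2.7):
            h = 1e-6
            assert hill_f_prime(x, 1.3) == pytest.approx(
                (hill_f(x + h, 1.3) - hill_f(x - h, 1.3)) / (2 * h), rel=1e-6
            )
            assert hill_g_prime(x, 1.3) == pytest.approx(
                (hill_g(x + h, 1.3) - hill_g(x - h, 1.3)) / (2 * h), rel=1e-6
            )


class TestNeighborMean:
    def test_interior_and_wrap(self):
        assert neighbor_mean([1.0, 2.0, 3.0], 1) == 2.0
        assert neighbor_mean([1.0, 2.0, 3.0], 0, "periodic") == 2.5
        assert neighbor_mean([1.0, 2.0, 3.0], 0, "reflecting") == 1.5

    def test_uniform_profile_is_fixed_by_averaging(self):
        S = np.full(6, 0.8)
        for i in range(6):
            for boundary in ("periodic", "reflecting"):
                assert neighbor_mean(S, i, boundary) == pytest.approx(0.8)


class TestLatticeRhs:
    def test_uniform_steady_state_has_zero_derivative(self):
        params = InhibitionParams(n_cones=6)
        i0, s0 = homogeneous_steady_state(params)
        dI, dS = inhibition_rhs(
            (np.full(6, i0), np.full(6, s0)), np.zeros(6), params
        )
        assert np.max(np.abs(dI)) < 1e-11
        assert np.max(np.abs(dS)) < 1e-11

    def test_readings_coincide_without_coupling(self):
        state = (np.array([0.2, 0.4, 0.1]), np.array([0.5, 0.3, 0.9]))
        a = inhibition_rhs(state, np.zeros(3), InhibitionParams(n_cones=3, gamma=0.0))
        b = inhibition_rhs(
            state,
            np.zeros(3),
            InhibitionParams(n_cones=3, gamma=0.0, coupling_reading="decay_scaled"),
        )
        assert np.allclose(a, b)

    def test_high_force_shuts_off_emission(self):
        params = InhibitionParams(n_cones=3, gamma=1.0)
        state = (np.zeros(3), np.array([0.5, 0.3, 0.9]))
        _, dS = inhibition_rhs(state, np.full(3, 1e3), params)
        assert np.allclose(dS, -state[1])

    def test_zero_state_emission_rate(self):
        params = InhibitionParams(n_cones=3, nu=1.0, gamma=0.5)
        F = np.full(3, 2.0)
        dI, dS = inhibition_rhs((np.zeros(3), np.zeros(3)), F, params)
        assert np.allclose(dI, 0.0)
        assert np.allclose(dS, np.exp(-0.5 * 2.0))

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(4)
        params = InhibitionParams(n_cones=5, gamma=0.3)
        field = inhibition_field(np.full(5, 1.0), params)
        for _ in range(20):
            y0 = rng.uniform(0.0, 2.0, size=10)
            sol = integrate(field, y0, (0.0, 30.0), t_eval=np.linspace(0, 30, 31))
            assert sol.states.min() > -1e-9

    def test_relaxes_to_high_S_low_I_steady_state(self):
        # pattern period matching the growth-cone size (a ~ 1)
        rng = np.random.default_rng(8)
        params = InhibitionParams(a=1.0, n_cones=10)
        field = inhibition_field(np.zeros(10), params)
        y0 = rng.uniform(0.0, 1.0, size=20)
        sol = integrate(field, y0, (0.0, 80.0), t_eval=[80.0])
        final = sol.states[-1]
        assert np.max(np.abs(field(0.0, final))) < 1e-8
        assert final[10:].mean() > final[:10].mean()  # S above I


class TestHomogeneousSteadyState:
    def test_matches_bisection_oracle(self):
        params = InhibitionParams(a=1.0, nu=1.0, gamma=0.0)
        i0, s0 = homogeneous_steady_state(params)
        s_ref = brentq(
            lambda s: s - hill_g(hill_f(s, 1.0), 1.0), 0.0, 1.0, xtol=1e-14
        )
        assert s0 == pytest.approx(s_ref, abs=1e-10)
        assert i0 == pytest.approx(hill_f(s_ref, 1.0), abs=1e-10)
        assert abs(s0 - hill_g(i0, 1.0)) < 1e-11

    def test_emission_vanishes_at_large_coupled_force(self):
        params = InhibitionParams(gamma=1.0)
        i0, s0 = homogeneous_steady_state(params, force=60.0)
        assert s0 == pytest.approx(0.0, abs=1e-20)
        assert i0 == pytest.approx(0.0, abs=1e-20)

    def test_steady_emission_decreases_with_force(self):
        params = InhibitionParams(gamma=0.5)
        s_values = [homogeneous_steady_state(params, f)[1] for f in np.linspace(0, 5, 11)]
        assert np.all(np.diff(s_values) < 0)


class TestControlParameter:
    def test_matches_finite_difference_slopes(self):
        params = InhibitionParams(a=1.0, nu=1.0, gamma=0.0)
        i0, s0 = homogeneous_steady_state(params)
        h = 1e-6
        fp = (hill_f(s0 + h, 1.0) - hill_f(s0 - h, 1.0)) / (2 * h)
        gp = (hill_g(i0 + h, 1.0) - hill_g(i0 - h, 1.0)) / (2 * h)
        assert control_parameter_m(params) == pytest.approx(-fp * gp, rel=1e-6)

    def test_nonnegative_and_suppressed_by_force(self):
        free = control_parameter_m(InhibitionParams(gamma=0.0), force=2.0)
        coupled = control_parameter_m(InhibitionParams(gamma=0.8), force=2.0)
        assert free >= 0.0 and coupled >= 0.0
        assert coupled < free
        assert control_parameter_m(InhibitionParams(gamma=1.0), force=80.0) == (
            pytest.approx(0.0, abs=1e-20)
        )

    def test_monotone_nonincreasing_in_force(self):
        params = InhibitionParams(gamma=0.4)
        m_values = [control_parameter_m(params, f) for f in np.linspace(0.0, 6.0, 13)]
        assert np.all(np.diff(m_values) <= 1e-15)

    def test_printed_convention_available(self):
        params = InhibitionParams()
        assert control_parameter_m(params, argument_convention="printed") >= 0.0


class TestPitchfork:
    @pytest.mark.parametrize(
        "m, expected",
        [(-2.0, [0.0]), (-1.0, [0.0]), (0.0, [-1.0, 0.0, 1.0]), (3.0, [-2.0, 0.0, 2.0])],
    )
    def test_branch_values(self, m, expected):
        assert pitchfork_branches(m) == pytest.approx(expected)

    def test_uniform_branch_changes_stability_at_minus_one(self):
        assert uniform_mode_growth_rate(-1.0) == 0.0
        assert uniform_mode_growth_rate(-1.0 - 1e-9) < 0
        assert uniform_mode_growth_rate(-1.0 + 1e-9) > 0

    def test_branches_are_normal_form_equilibria(self):
        for m in (-0.5, 0.0, 2.0):
            for y in pitchfork_branches(m):
                assert pitchfork_normal_form_rhs(y, m) == pytest.approx(0.0, abs=1e-12)


class TestUniformStateSpectrum:
    @pytest.mark.parametrize("n", [4, 10])
    def test_dense_spectrum_equals_mode_blocks(self, n):
        params = InhibitionParams(n_cones=n, gamma=0.3)
        dense = uniform_state_stability(params, force=1.0)
        blocks = sort_spectrum(
            np.concatenate(
                [block_eigenvalues(mode_block(params, 1.0, q)) for q in range(n)]
            )
        )
        assert np.max(np.abs(dense - blocks)) < 1e-10

    def test_extracted_blocks_match_analytic_blocks(self):
        params = InhibitionParams(n_cones=6, gamma=0.2)
        extracted = extract_mode_blocks(params, force=0.5)
        analytic = np.stack([mode_block(params, 0.5, q) for q in range(6)])
        assert np.max(np.abs(extracted - analytic)) < 1e-12

    def test_lapack_dense_eigenvalues_near_block_values(self):
        # raw LAPACK solve on the dense matrix, defect-aware tolerance
        params = InhibitionParams(n_cones=4)
        lapack = np.linalg.eigvals(dense_jacobian(params))
        blocks = np.concatenate(
            [block_eigenvalues(mode_block(params, 0.0, q)) for q in range(4)]
        )
        for e in lapack:
            assert np.min(np.abs(blocks - e)) < 1e-6

    def test_decoupled_limit_spectrum_collapses_to_minus_one(self):
        params = InhibitionParams(n_cones=6, gamma=1.0)
        eigs = uniform_state_stability(params, force=80.0)
        assert np.allclose(eigs, -1.0, atol=1e-6)

    def test_dense_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(15)
        params = InhibitionParams(
            a=rng.uniform(0.5, 2.0), nu=rng.uniform(0.5, 2.0), gamma=0.4, n_cones=4
        )
        force = 1.3
        i0, s0 = homogeneous_steady_state(params, force)
        field = inhibition_field(np.full(4, force), params)
        y_star = np.concatenate([np.full(4, i0), np.full(4, s0)])
        fd = finite_difference_jacobian(lambda y: field(0.0, y), y_star)
        assert np.allclose(fd, dense_jacobian(params, force), atol=1e-7)
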