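"""Forward simulators: reduced model, oracle, comparison models, oscillator."""

import numpy as np
import pytest
from scipy.optimize import brentq

from rootgrav import (
    GrowthProfile,
    OrganGeometry,
    Sensitivities,
    gravity_crossings,
    lagrangian_oracle,
    oscillator_quantities,
    overshoots_gravity,
    reconstruct_shape_history,
    residual_arcsin_form,
    small_angle_solution,
    solve_ac_model,
    solve_ace_exponential,
    solve_root_model,
    tip_angle_from_solution,
)


class TestRootModel:
    def test_straight_organ_is_steady_state(self):
        sol = solve_root_model(1.0, 1.0, 0.0, tau_max=10)
        assert np.max(np.abs(sol.k)) < 1e-12
        assert np.max(np.abs(sol.K)) < 1e-12

    @pytest.mark.parametrize("gamma", [0.0, 1.0, 5.0, 10.0])
    def test_tip_always_reaches_gravity(self, gamma):
        """Long-time alignment with the stimulus for any proprioception."""
        sol = solve_root_model(1.0, gamma, -np.pi / 2, tau_max=60)
        assert abs(sol.theta_tip[-1] - np.pi / 2) < 0.01

    def test_long_time_limit_cohort_scale(self):
        sol = solve_root_model(1.0, 1.6, -np.pi / 2, tau_max=20)
        assert abs(sol.theta_tip[-1] - np.pi / 2) < 0.01

    def test_initial_slope_by_richardson(self):
        """k'(0) = -eta sin(theta0_tilde) emerges from the augmented system."""
        sol = solve_root_model(1.0, 1.0, -np.pi / 2, tau_max=1)
        slopes = []
        for h in (1e-3, 5e-4, 2.5e-4):
            _, k = sol.interp([h])
            slopes.append(k[0] / h)
        # Richardson extrapolation toward h -> 0
        extrap = 2 * slopes[2] - slopes[1]
        assert extrap == pytest.approx(1.0, abs=1e-4)
        assert abs(slopes[2] - 1.0) < abs(slopes[0] - 1.0)

    def test_tip_angle_identity_pointwise(self):
        sol = solve_root_model(1.3, 0.7, -0.8, tau_max=10)
        assert np.max(
            np.abs(sol.theta_tip - (sol.params.theta0 + sol.K + sol.k))
        ) < 1e-8

    def test_rescaling_invariance(self, cohort_geometry):
        """Dimensional trajectories depend on (eta, gamma, theta0) and eps0*t only."""
        sol = solve_root_model(1.1, 1.6, -np.pi / 2, tau_max=6)
        t = np.linspace(0, 10, 50)
        a = tip_angle_from_solution(sol, 0.0, 0.2, t)
        b = tip_angle_from_solution(sol, 0.0, 0.4, t / 2)
        np.testing.assert_allclose(a.theta_tip, b.theta_tip, atol=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            solve_root_model(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            solve_root_model(1.0, -0.5, 0.0)
        with pytest.raises(ValueError):
            solve_root_model(np.nan, 1.0, 0.0)

    def test_time_outside_solved_range(self):
        sol = solve_root_model(1.0, 1.0, -0.3, tau_max=2)
        with pytest.raises(ValueError, match="outside"):
            tip_angle_from_solution(sol, 0.0, 1.0, [0.0, 3.0])


class TestArcsinFormResidual:
    def test_residual_small_on_generic_solution(self):
        sol = solve_root_model(1.0, 2.0, -0.3)
        res = residual_arcsin_form(sol)
        assert np.max(np.abs(res)) < 1e-4

    def test_zero_solution_zero_residual(self):
        sol = solve_root_model(1.0, 1.0, 0.0)
        res = residual_arcsin_form(sol)
        assert np.max(np.abs(res.compressed())) < 1e-12

    def test_horizontal_tilt_masks_degenerate_start(self):
        # denominator sqrt(eta^2 - (k'+gamma k)^2) vanishes at tau=0
        sol = solve_root_model(1.0, 1.0, -np.pi / 2)
        res = residual_arcsin_form(sol)
        assert res.mask[0]


class TestShapeReconstruction:
    def test_straight_organ_grows_linearly(self, cohort_geometry):
        sol = solve_root_model(1.1, 1.6, 0.0, tau_max=4)
        eps0 = cohort_geometry.growth_rate_eps0
        t3 = 3.0 / eps0  # tau = 3
        kymo, lines = reconstruct_shape_history(sol, cohort_geometry, [0.0, t3])
        assert kymo.length_per_time[-1] == pytest.approx(4 * 0.6, rel=1e-12)
        assert np.max(np.abs(kymo.kappa.compressed())) < 1e-12
        # theta0_tilde = 0 means the organ points along the stimulus: the
        # centerline is a straight vertical segment of length L
        assert lines[-1].coords_xy[-1][1] == pytest.approx(2.4, rel=1e-9)
        assert abs(lines[-1].coords_xy[-1][0]) < 1e-9

    def test_cohort_scale_length_after_10h(self, cohort_geometry):
        sol = solve_root_model(1.1, 1.6, -np.pi / 2, tau_max=3)
        kymo, _ = reconstruct_shape_history(sol, cohort_geometry, [0.0, 10.0])
        assert kymo.length_per_time[-1] == pytest.approx(1.90, abs=0.005)

    def test_mature_zone_frozen_in_time(self, cohort_geometry):
        sol = solve_root_model(1.1, 1.6, -np.pi / 2, tau_max=5.3)
        t_grid = np.linspace(0.0, 24.0, 25)
        kymo, _ = reconstruct_shape_history(sol, cohort_geometry, t_grid)
        lgz = cohort_geometry.growth_zone_Lgz
        mask = np.ma.getmaskarray(kymo.kappa)
        for j, s in enumerate(kymo.s_grid):
            mature = (s < kymo.length_per_time - lgz) & ~mask[:, j]
            vals = kymo.kappa[mature, j]
            if vals.size > 1:
                assert np.ptp(vals) < 1e-9

    def test_curvature_continuous_at_zone_boundary(self, cohort_geometry):
        sol = solve_root_model(1.1, 1.6, -np.pi / 2, tau_max=4)
        kymo, _ = reconstruct_shape_history(
            sol, cohort_geometry, [12.0], ds=0.002
        )
        row = kymo.kappa[0].compressed()
        # no jump anywhere: max cell-to-cell difference bounded by the
        # curvature gradient scale, far below the curvature magnitude
        assert np.max(np.abs(np.diff(row))) < 0.1 * np.max(np.abs(row))


class TestACModel:
    def test_gamma_zero_aligns_with_gravity(self):
        sol = solve_ac_model(1.0, 0.0, -np.pi / 2, tau_max=30)
        assert abs(sol.theta_tip[-1] - np.pi / 2) < 1e-6

    def test_steady_state_preserved(self):
        sol = solve_ac_model(1.0, 1.0, 0.0)
        assert np.max(np.abs(sol.k)) < 1e-12

    def test_stalls_at_fixed_point_short_of_gravity(self):
        """For eta = gamma = 1, horizontal tilt: k* solves cos(k) = k."""
        sol = solve_ac_model(1.0, 1.0, -np.pi / 2, tau_max=40)
        kstar = brentq(lambda k: np.cos(k) - k, 0.0, 1.0)
        assert kstar == pytest.approx(0.739085, abs=1e-6)
        assert sol.k[-1] == pytest.approx(kstar, abs=1e-6)
        # tip stalls short of vertical
        assert sol.theta_tip[-1] < np.pi / 2 - 0.5


class TestExponentialACE:
    def test_steady_state_preserved(self):
        sol = solve_ace_exponential(1.0, 1.0, 0.0, tau_max=5)
        assert np.max(np.abs(sol.k)) < 1e-10

    @pytest.mark.parametrize("gamma", [0.0, 1.0, 5.0])
    def test_tip_crosses_gravity_for_every_gamma(self, gamma):
        sol = solve_ace_exponential(1.0, gamma, -np.pi / 2, tau_max=10)
        phi = sol.theta_tip - np.pi / 2
        assert np.any(phi > 0)

    def test_sustained_oscillation_at_moderate_gamma(self):
        sol = solve_ace_exponential(1.0, 1.0, -np.pi / 2, tau_max=10)
        phi = sol.theta_tip - np.pi / 2
        late = np.abs(phi[sol.tau_grid > 9.0])
        assert np.max(late) > 0.01  # still swinging at the end

    def test_apical_variant_collapses_to_scalar_relaxation(self):
        """With apical sensing the whole-organ model settles onto the stimulus."""
        sol = solve_ace_exponential(1.0, 0.0, -np.pi / 2, tau_max=8, sensing="apical")
        phi = sol.theta_tip - np.pi / 2
        assert np.max(np.abs(phi[sol.tau_grid > 7.0])) < 0.01


class TestLagrangianOracle:
    def test_straight_stays_straight(self, cohort_geometry):
        sens = Sensitivities(gamma=1.0, eta=1.0, theta0=np.pi / 2)
        traj, kymo = lagrangian_oracle(
            cohort_geometry, sens, t_max=5.0, n_material_points=80
        )
        assert np.max(np.abs(traj.theta_tip - np.pi / 2)) < 1e-12
        assert np.max(np.abs(kymo.kappa.compressed())) < 1e-12

    def test_matches_reduced_model(self, cohort_geometry):
        """The material-point PDE reproduces the reduced ODE solution."""
        eps0 = cohort_geometry.growth_rate_eps0
        sens = Sensitivities(gamma=2.0, eta=1.0, theta0=0.0)
        traj, _ = lagrangian_oracle(
            cohort_geometry, sens, t_max=6.0 / eps0, n_material_points=400
        )
        sol = solve_root_model(1.0, 2.0, -np.pi / 2, tau_max=6.01)
        ref = tip_angle_from_solution(sol, 0.0, eps0, traj.times_t)
        assert np.max(np.abs(traj.theta_tip - ref.theta_tip)) < 0.01

    def test_error_decreases_with_resolution(self, cohort_geometry):
        eps0 = cohort_geometry.growth_rate_eps0
        sens = Sensitivities(gamma=1.0, eta=1.0, theta0=0.0)
        devs = []
        for n in (100, 400):
            traj, _ = lagrangian_oracle(
                cohort_geometry, sens, t_max=4.0 / eps0, n_material_points=n
            )
            sol = solve_root_model(1.0, 1.0, -np.pi / 2, tau_max=4.01)
            ref = tip_angle_from_solution(sol, 0.0, eps0, traj.times_t)
            devs.append(np.max(np.abs(traj.theta_tip - ref.theta_tip)))
        assert devs[1] <= devs[0]

    def test_triangular_profile_negligible_effect(self, cohort_geometry):
        """A triangular growth-rate profile barely changes the tip trajectory."""
        eps0 = cohort_geometry.growth_rate_eps0
        sens = Sensitivities(gamma=1.6, eta=1.1, theta0=0.0)
        uni, _ = lagrangian_oracle(
            cohort_geometry, sens, t_max=5.0 / eps0, n_material_points=200
        )
        tri, _ = lagrangian_oracle(
            cohort_geometry,
            sens,
            growth_profile=GrowthProfile.triangular(),
            t_max=5.0 / eps0,
            n_material_points=200,
        )
        assert np.max(np.abs(uni.theta_tip - tri.theta_tip)) < 0.05

    def test_rejects_too_few_points(self, cohort_geometry):
        sens = Sensitivities(gamma=1.0, eta=1.0, theta0=0.0)
        with pytest.raises(ValueError, match="50"):
            lagrangian_oracle(cohort_geometry, sens, n_material_points=10)

    def test_custom_profile_must_normalize(self):
        with pytest.raises(ValueError, match="integrate to 1"):
            GrowthProfile.custom(lambda x: 2.0 * np.ones_like(x))


class TestOscillator:
    def test_reference_values(self):
        q = oscillator_quantities(1.0, 1.0)
        assert q.omega0 == 1.0
        assert q.gamma_crit == pytest.approx(1.0)
        assert q.Q == pytest.approx(0.5)
        assert q.regime == "critically_damped"

    def test_cohort_mean_parameters_are_overdamped(self):
        q = oscillator_quantities(1.1, 1.6)
        assert q.Q == pytest.approx(np.sqrt(1.1) / 2.7, rel=1e-12)
        assert q.Q == pytest.approx(0.389, abs=2e-3)
        assert q.gamma_crit == pytest.approx(2 * np.sqrt(1.1) - 1.1, rel=1e-12)
        assert q.regime == "overdamped"

    @pytest.mark.parametrize("gamma,label", [(0.5, "under"), (2.0, "over")])
    def test_small_angle_limit_matches_nonlinear(self, gamma, label):
        """|theta0_tilde| = 0.05: closed form tracks the nonlinear solution."""
        theta0_tilde = -0.05
        sol = solve_root_model(1.0, gamma, theta0_tilde, tau_max=10)
        lin = small_angle_solution(
            1.0, gamma, 0.0, -1.0 * np.sin(theta0_tilde), sol.tau_grid
        )
        assert np.max(np.abs(sol.k - lin)) < 1e-3

    def test_underdamped_closed_form(self):
        # eta=1, gamma=0.5: omega_d = sqrt(1 - 0.5625)
        tau = np.linspace(0, 10, 200)
        wd = np.sqrt(1 - 0.75**2)
        expected = (0.05 / wd) * np.exp(-0.75 * tau) * np.sin(wd * tau)
        got = small_angle_solution(1.0, 0.5, 0.0, 0.05, tau)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_zero_initial_data_stays_zero(self):
        tau = np.linspace(0, 5, 50)
        assert np.all(small_angle_solution(1.0, 1.0, 0.0, 0.0, tau) == 0.0)

    def test_critical_branch_single_extremum(self):
        tau = np.linspace(0, 20, 4000)
        k = small_angle_solution(1.0, 1.0, 0.0, 0.05, tau)
        sign_changes = np.sum(np.diff(np.sign(np.diff(k))) != 0)
        assert sign_changes <= 1


class TestOvershootClassification:
    @pytest.mark.parametrize("eta", [0.5, 1.0, 2.0])
    def test_boundary_at_critical_proprioception(self, eta):
        gc = 2 * np.sqrt(eta) - eta
        assert overshoots_gravity(eta, gc / 2)
        assert not overshoots_gravity(eta, 2 * gc)
        assert not overshoots_gravity(eta, gc)
        assert overshoots_gravity(eta, 0.0)

    def test_single_nonreturning_crossing_above_critical_for_large_eta(self):
        """For eta > 1 the tilt-from-rest start crosses the stimulus once even
        when overdamped; only the returning (oscillatory) overshoot marks the
        underdamped regime."""
        eta = 2.0
        gc = 2 * np.sqrt(eta) - eta
        assert gravity_crossings(eta, gc + 0.05) == 1
        assert gravity_crossings(eta, 1.2) == 0
        assert gravity_crossings(eta, gc - 0.05) == 2
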