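"""Two-layer residual-stress boundary-value problem."""

from dataclasses import replace

import numpy as np
import pytest

import coromech as cm
from coromech.kinematics import KinematicState
from coromech.twolayer import (
    LayerSpec,
    WallSolveError,
    calibrate_geometry,
    coronary_layer_templates,
    deformed_map,
    interface_metrics,
    local_state,
    planar_active_counterpart,
    solve_wall,
    stress_difference,
    uniform_stress_thickness,
)

PC = cm.PassiveConstants(6.29, 3.05, 4.56, 4.75, 5.59, 5.25, 2.15)


@pytest.fixture(scope="module")
def calibrated():
    """Coronary templates calibrated to the physiological scenario:
    80 mmHg, lam_z 1.3, loaded thickness 0.22 mm, IM half of the wall."""
    im0, ad0 = coronary_layer_templates()
    im, ad = calibrate_geometry(0.22, 0.5, 80.0, 1.3, [im0, ad0], activation="active")
    return im, ad


@pytest.fixture(scope="module")
def profile_active(calibrated):
    return solve_wall(list(calibrated), 80.0, 1.3, "active")


@pytest.fixture(scope="module")
def profile_passive(calibrated):
    return solve_wall(list(calibrated), 80.0, 1.3, "passive")


class TestKinematicsOfMap:
    def test_identity_without_residual_strain(self):
        R = np.linspace(2.0, 2.4, 5)
        r = deformed_map(R, 2.0, 2.0, lam_z=1.0, k=1.0)
        assert np.allclose(r, R, atol=1e-14)

    def test_layer_volume_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            R_in = rng.uniform(1.0, 3.0)
            R = np.linspace(R_in, R_in + rng.uniform(0.1, 1.0), 7)
            r_in, lam_z, k = rng.uniform(0.5, 2.5), rng.uniform(1.0, 1.6), rng.uniform(1.0, 3.0)
            r = deformed_map(R, R_in, r_in, lam_z, k)
            assert np.allclose(k * lam_z * (r**2 - r_in**2), R**2 - R_in**2, atol=1e-12)

    def test_inner_surface_anchored(self):
        assert deformed_map(1.8, 1.8, 1.2, lam_z=1.3, k=2.0) == pytest.approx(1.2)

    def test_local_state_stretches(self):
        s = local_state(r=1.1, R=1.0, k=1.2, lam_z=1.3)
        assert s.lam_theta == pytest.approx(1.32)
        assert s.lam_r == pytest.approx(1 / (1.32 * 1.3))
        assert s.volume_ratio == pytest.approx(1.0, abs=1e-12)


class TestStressDifference:
    layer = LayerSpec(R_in=2.0, R_out=2.3, opening_angle=0.9, passive=PC,
                      active=cm.published_constants("two_layer"))

    def test_reference_state_passive_difference_vanishes(self):
        s = KinematicState.from_biaxial(1.0, 1.0)
        assert stress_difference(s, replace(self.layer, active=None)) == pytest.approx(0.0)

    def test_matches_isochoric_finite_difference(self):
        """Oracle: D_theta = lam_theta * d/dlam_theta of the total energy
        along the incompressible path at fixed lam_z."""
        from coromech.constitutive import active_energy, passive_energy

        lam_z, h = 1.3, 1e-6
        for lam_t in (1.15, 1.3, 1.45):
            def W(lt):
                s = KinematicState.from_biaxial(lt, lam_z)
                return passive_energy(s, self.layer.passive) + active_energy(s, self.layer.active)

            fd = lam_t * (W(lam_t + h) - W(lam_t - h)) / (2 * h)
            s = KinematicState.from_biaxial(lam_t, lam_z)
            D = stress_difference(s, self.layer, activation="active")
            assert D == pytest.approx(fd, rel=1e-6)

    def test_active_term_off_when_passive(self):
        s = KinematicState.from_biaxial(1.35, 1.3)
        D_pas = stress_difference(s, self.layer, activation="passive")
        D_act = stress_difference(s, self.layer, activation="active")
        assert D_act != pytest.approx(D_pas)
        assert stress_difference(s, replace(self.layer, active=None), "active") == pytest.approx(
            D_pas
        )


class TestSolveWall:
    def test_stress_free_configuration_is_a_solution(self):
        layers = [LayerSpec(R_in=2.0, R_out=2.1, opening_angle=0.0, passive=PC),
                  LayerSpec(R_in=2.1, R_out=2.2, opening_angle=0.0, passive=PC)]
        prof = solve_wall(layers, 0.0, 1.0, "passive")
        assert np.abs(prof.sigma_theta).max() < 1e-10
        assert np.abs(prof.sigma_r).max() < 1e-10
        assert np.allclose(prof.lam_theta, 1.0, atol=1e-12)

    def test_boundary_conditions(self, profile_active):
        P = 80.0 * 0.1333224
        assert profile_active.sigma_r[0] == pytest.approx(-P, abs=1e-6)
        assert abs(profile_active.sigma_r[-1]) < 1e-6

    def test_equilibrium_residual_on_refined_grid(self, calibrated):
        prof = solve_wall(list(calibrated), 80.0, 1.3, "active", n_grid=800)
        ii = prof.interface_index
        for sl in (slice(0, ii), slice(ii, None)):
            r, sr, st = prof.r[sl], prof.sigma_r[sl], prof.sigma_theta[sl]
            dsr = np.gradient(sr, r)
            resid = dsr - (st - sr) / r
            assert np.abs(resid[2:-2]).max() < 1e-4

    def test_radial_stress_continuous_circumferential_discontinuous(self, profile_active):
        ii = profile_active.interface_index
        assert profile_active.sigma_r[ii] == pytest.approx(profile_active.sigma_r[ii - 1],
                                                           abs=1e-6)
        jump = abs(profile_active.sigma_theta[ii] - profile_active.sigma_theta[ii - 1])
        assert jump > 1.0  # kPa: a genuine discontinuity

    def test_grid_convergence_of_interface_stress(self, calibrated):
        p1 = solve_wall(list(calibrated), 80.0, 1.3, "active", n_grid=200)
        p2 = solve_wall(list(calibrated), 80.0, 1.3, "active", n_grid=400)
        s1 = p1.sigma_theta[p1.interface_index - 1]
        s2 = p2.sigma_theta[p2.interface_index - 1]
        assert abs(s1 / s2 - 1) < 1e-3

    def test_thin_wall_laplace_limit(self):
        layers = [LayerSpec(R_in=2.0, R_out=2.02, opening_angle=0.0, passive=PC),
                  LayerSpec(R_in=2.02, R_out=2.04, opening_angle=0.0, passive=PC)]
        prof = solve_wall(layers, 80.0, 1.3, "passive")
        laplace = 80.0 * 0.1333224 * prof.r_i / prof.thickness
        assert prof.mean_sigma_theta() == pytest.approx(laplace, rel=0.02)

    def test_radial_stress_magnitude_decreases_outward(self, profile_active):
        d = np.diff(profile_active.sigma_r)
        ii = profile_active.interface_index
        inside = np.r_[d[: ii - 1], d[ii:]]  # skip the interface duplicate
        assert np.all(inside > 0)

    def test_no_solution_reported_with_diagnostics(self):
        layers = [LayerSpec(R_in=2.0, R_out=2.1, opening_angle=0.0, passive=PC),
                  LayerSpec(R_in=2.1, R_out=2.2, opening_angle=0.0, passive=PC)]
        with pytest.raises(WallSolveError, match="residual"):
            solve_wall(layers, 80.0, 1.3, "passive", r_i_bracket=(0.01, 0.02))


class TestScenarios:
    def test_calibration_meets_targets(self, profile_active):
        h = profile_active.thickness
        h_im = profile_active.r[profile_active.interface_index - 1] - profile_active.r_i
        assert h == pytest.approx(0.22, rel=5e-3)
        assert h_im / h == pytest.approx(0.5, rel=5e-3)

    def test_activation_lowers_im_circumferential_stress(self, profile_active, profile_passive):
        ii = profile_active.interface_index
        mean_act = profile_active.sigma_theta[:ii].mean()
        mean_pas = profile_passive.sigma_theta[:ii].mean()
        assert mean_act < mean_pas
        # while the radial stress changes comparatively little (in kPa)
        d_sr = abs(profile_active.sigma_r[ii - 1] - profile_passive.sigma_r[ii - 1])
        assert d_sr < 0.1 * (mean_pas - mean_act) + 1.0

    def test_pressure_overload_raises_radial_to_circumferential_ratio(self, profile_active):
        im0, ad0 = coronary_layer_templates()
        im, ad = calibrate_geometry(0.44, 0.5, 160.0, 1.3, [im0, ad0], activation="active")
        over = solve_wall([im, ad], 160.0, 1.3, "active")
        r_base = abs(profile_active.sigma_r[0]) / profile_active.sigma_theta[0]
        r_over = abs(over.sigma_r[0]) / over.sigma_theta[0]
        assert r_over > r_base

    def test_interface_metrics_identity_and_hand_value(self, profile_active, profile_passive):
        m0 = interface_metrics(profile_active, profile_active)
        assert m0 == {"sigma_theta": 0.0, "sigma_r": 0.0}
        m = interface_metrics(profile_active, profile_passive)
        ii = profile_active.interface_index - 1
        expected = abs(
            (profile_active.sigma_theta[ii] - profile_passive.sigma_theta[ii])
            / profile_active.sigma_theta[ii]
        )
        assert m["sigma_theta"] == pytest.approx(expected, rel=1e-12)

    def test_planar_and_triaxial_active_runs_differ(self, calibrated):
        im, ad = calibrated
        p3 = solve_wall([im, ad], 80.0, 1.3, "active")
        ac2d = planar_active_counterpart(im.active)
        assert ac2d.is_planar
        p2 = solve_wall([replace(im, active=ac2d), ad], 80.0, 1.3, "active")
        m = interface_metrics(p3, p2)
        assert m["sigma_theta"] > 0 and m["sigma_r"] > 0

    def test_uniform_stress_thickness_scaling(self, profile_active):
        im0, ad0 = coronary_layer_templates()
        series = uniform_stress_thickness([80.0, 160.0], profile_active, [im0, ad0],
                                          activation="active")
        assert series[0][1] == pytest.approx(0.22, rel=5e-3)  # baseline identity
        # doubling the pressure roughly doubles the thickness
        assert series[1][1] == pytest.approx(0.44, rel=0.05)
        # defining property: averaged circumferential stress is conserved
        im, ad = calibrate_geometry(series[1][1], 0.5, 160.0, 1.3, [im0, ad0],
                                    activation="active")
        prof = solve_wall([im, ad], 160.0, 1.3, "active")
        assert prof.mean_sigma_theta() == pytest.approx(
            profile_active.mean_sigma_theta(), rel=0.01
        )
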