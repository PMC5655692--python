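"""Objectives, local/global optimizers, R^2, and the estimator API."""

import numpy as np
import pytest
from sklearn.base import clone

import coromech as cm
from coromech.experimental import StressPoint, point_arrays
from coromech.fitting import (
    ACTIVE_BOUNDS,
    PASSIVE_BOUNDS,
    ActiveStressRegressor,
    FitConfig,
    PassiveStressRegressor,
    fit_active,
    fit_passive,
    ga_fit,
    lm_warm_start,
    passive_objective,
    r_squared,
    total_objective,
    _batch_objective_passive,
)
from coromech.meanwall import theoretical_pk_stresses


def toy_points(truth, state="passive", n=3):
    """A tiny hand-checkable point set: theory stresses with an offset."""
    pts = []
    for i, lam_t in enumerate(np.linspace(1.2, 1.4, n)):
        r_i, r_o = 1.5, 1.72
        active = truth.active if state == "total" else None
        Tt, Tz, Tr = theoretical_pk_stresses(lam_t, 1.3, r_i, r_o, truth.passive, active)
        pts.append(StressPoint(lam_theta=lam_t, lam_z=1.3, r_i=r_i, r_o=r_o,
                               T_theta=Tt + 1.0, T_z=Tz - 2.0, T_r=Tr + 0.5,
                               state=state))
    return pts


class TestObjectives:
    def test_zero_at_truth_on_noiseless_data(self, truth, points_split):
        assert passive_objective(truth.passive, points_split["passive"]) < 1e-10
        assert total_objective(truth.active, truth.passive, points_split["total"]) < 1e-10

    def test_matches_independent_sum_of_squares(self, truth):
        # offsets of (1, -2, 0.5) kPa on 3 points: sum = 3*(1+4+0.25)
        pts = toy_points(truth)
        assert passive_objective(truth.passive, pts) == pytest.approx(3 * 5.25, rel=1e-9)
        pts_t = toy_points(truth, "total")
        assert total_objective(truth.active, truth.passive, pts_t) == pytest.approx(
            3 * 5.25, rel=1e-9
        )

    def test_zero_active_scale_reduces_to_passive_residual(self, truth, points_split):
        tiny = cm.ActiveConstants(C2=1e-12, b1=0.5, b2=1.0, b3=4.0, b_prime=5.0)
        pts = points_split["total"]
        lam_t, lam_z, r_i, r_o, T = point_arrays(pts)
        Tt, Tz, Tr = theoretical_pk_stresses(lam_t, lam_z, r_i, r_o, truth.passive)
        expected = float(((Tt - T[:, 0]) ** 2 + (Tz - T[:, 1]) ** 2 + (Tr - T[:, 2]) ** 2).sum())
        assert total_objective(tiny, truth.passive, pts) == pytest.approx(expected, rel=1e-9)

    def test_empty_and_mixed_state_points_rejected(self, truth, points_split):
        with pytest.raises(ValueError, match="empty"):
            passive_objective(truth.passive, [])
        with pytest.raises(ValueError, match="not passive"):
            passive_objective(truth.passive, points_split["total"])

    def test_diverged_energy_penalized_not_nan(self, truth, points_split):
        huge = cm.PassiveConstants(C1=50.0, a1=50, a2=50, a3=50, a4=50, a5=50, a6=50)
        val = passive_objective(huge, points_split["passive"])
        assert np.isfinite(val) and val >= 1e10


class TestRSquared:
    def test_perfect_and_mean_predictions(self):
        obs = np.column_stack([np.arange(5.0), np.arange(5.0) * 2, -np.arange(5.0)])
        assert all(v == 1.0 for v in r_squared(obs, obs).values())
        mean_pred = np.tile(obs.mean(axis=0), (5, 1))
        assert all(v == pytest.approx(0.0) for v in r_squared(mean_pred, obs).values())

    def test_three_point_hand_example(self):
        obs = np.array([[1.0, 0, 0], [2.0, 0.5, 0], [3.0, 1.0, 0]])
        pred = np.array([[1.1, 0, 0], [2.0, 0.5, 0], [2.9, 1.0, 0]])
        obs[:, 2] = [1, 2, 4]
        pred[:, 2] = [1, 2, 4]
        # component theta: SSres = 0.02, SStot = 2 -> R2 = 0.99
        assert r_squared(pred, obs)["T_theta"] == pytest.approx(0.99)

    def test_zero_variance_rejected(self):
        obs = np.ones((4, 3))
        with pytest.raises(ValueError, match="zero variance"):
            r_squared(obs, obs)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            r_squared(np.ones((1, 3)), np.ones((1, 3)))


class TestLocalOptimizer:
    def test_stays_at_truth_on_noiseless_data(self, truth, points_split):
        from coromech.fitting import _passive_residual_fn

        arrays = point_arrays(points_split["passive"])
        res = _passive_residual_fn(arrays)
        x, warn = lm_warm_start(res, truth.passive.as_array(), PASSIVE_BOUNDS)
        assert warn is None
        assert np.allclose(x, truth.passive.as_array(), rtol=1e-6)

    def test_recovers_from_perturbed_start(self, truth, points_split):
        from coromech.fitting import _passive_residual_fn

        arrays = point_arrays(points_split["passive"])
        res = _passive_residual_fn(arrays)
        x, _ = lm_warm_start(res, truth.passive.as_array() * 1.1, PASSIVE_BOUNDS)
        pred = np.stack(
            theoretical_pk_stresses(arrays[0], arrays[1], arrays[2], arrays[3],
                                    cm.PassiveConstants.from_array(x)), axis=1)
        rms = np.sqrt(np.mean((pred - arrays[4]) ** 2)) / np.sqrt(np.mean(arrays[4] ** 2))
        assert rms < 0.005

    def test_infeasible_start_rejected(self, truth, points_split):
        from coromech.fitting import _passive_residual_fn

        res = _passive_residual_fn(point_arrays(points_split["passive"]))
        with pytest.raises(ValueError, match="bounds"):
            lm_warm_start(res, np.full(7, 100.0), PASSIVE_BOUNDS)


class TestGeneticAlgorithm:
    def _sphere(self, p):
        return ((p - 0.3) ** 2).sum(axis=1)

    def test_deterministic_for_fixed_seed(self):
        cfg = FitConfig(population_size=30, generations=40, seed=5)
        bounds = [(-1.0, 1.0)] * 4
        r1 = ga_fit(self._sphere, cfg, bounds)
        r2 = ga_fit(self._sphere, cfg, bounds)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]
        assert np.array_equal(r1[2], r2[2])

    def test_elitism_keeps_injected_optimum(self):
        cfg = FitConfig(population_size=30, generations=25, seed=1)
        bounds = [(-1.0, 1.0)] * 4
        x_opt = np.full(4, 0.3)
        x, f, _ = ga_fit(self._sphere, cfg, bounds, x_warm=x_opt)
        assert f <= self._sphere(x_opt[None, :])[0] + 1e-15

    def test_trace_non_increasing(self):
        cfg = FitConfig(population_size=30, generations=50, seed=2)
        _, _, trace = ga_fit(self._sphere, cfg, [(-2.0, 2.0)] * 3)
        assert np.all(np.diff(trace) <= 0)

    def test_all_infeasible_initialization_fails_loudly(self):
        cfg = FitConfig(population_size=20, generations=5, seed=0)
        with pytest.raises(RuntimeError, match="feasible"):
            ga_fit(self._sphere, cfg, [(0.0, 1.0)] * 2,
                   constraint_fn=lambda p: np.ones(len(p)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(population_size=5)
        with pytest.raises(ValueError):
            FitConfig(crossover_prob=1.5)
        with pytest.raises(ValueError):
            FitConfig(constraint_mode="convex")


class TestSequentialProtocol:
    def test_noiseless_recovery_machine_precision(self, truth, points_split):
        cfg = FitConfig(seed=0)
        res_p = fit_passive(points_split["passive"], cfg)
        assert res_p.objective < 1e-10
        assert np.allclose(res_p.constants.as_array(), truth.passive.as_array(), rtol=1e-5)
        assert all(v > 0.999999 for v in res_p.r2.values())
        res_a = fit_active(points_split["total"], res_p.constants, cfg)
        assert res_a.objective < 1e-10
        assert np.allclose(res_a.constants.as_array(), truth.active.as_array(), rtol=1e-4)

    def test_constraint_mode_enforced_on_returned_constants(self, truth, points_split):
        cfg = FitConfig(seed=3, generations=60, population_size=40, constraint_mode="strict")
        res = fit_passive(points_split["passive"], cfg)
        assert cm.convexity_check(res.constants, "strict").passed

    def test_reported_seed_matches_config(self, truth, points_split):
        cfg = FitConfig(seed=11, generations=20, population_size=20)
        assert fit_passive(points_split["passive"], cfg).seed == 11

    def test_joint_refinement_never_degrades_the_fit(self, truth, points_split):
        from coromech.fitting import fit_sequential

        cfg = FitConfig(seed=0, generations=30, population_size=30)
        rp, ra = fit_sequential(points_split["passive"], points_split["total"], cfg)
        rpj, raj = fit_sequential(points_split["passive"], points_split["total"], cfg,
                                  joint_refine=True)
        assert rpj.objective + raj.objective <= rp.objective + ra.objective + 1e-12


class TestEstimators:
    def _Xy(self, points):
        lam_t, lam_z, r_i, r_o, T = point_arrays(points)
        return np.column_stack([lam_t, lam_z, r_i, r_o]), T

    def test_passive_estimator_fit_predict(self, truth, points_split):
        X, y = self._Xy(points_split["passive"])
        est = PassiveStressRegressor(seed=0)
        est.fit(X, y)
        assert np.allclose(est.predict(X), y, atol=1e-6)
        assert est.score(X, y) > 0.999999
        r2 = est.score_components(X, y)
        assert set(r2) == {"T_theta", "T_z", "T_r"}

    def test_sequential_estimators_compose(self, truth, points_split):
        Xp, yp = self._Xy(points_split["passive"])
        passive = PassiveStressRegressor(seed=0).fit(Xp, yp)
        Xt, yt = self._Xy(points_split["total"])
        active = ActiveStressRegressor(passive_constants=passive.constants_, seed=0)
        active.fit(Xt, yt)
        assert np.allclose(active.predict(Xt), yt, atol=1e-6)

    def test_sklearn_protocol(self, truth, points_split):
        est = PassiveStressRegressor(generations=10, population_size=20, seed=4)
        params = est.get_params()
        assert params["generations"] == 10
        cloned = clone(est)
        assert cloned.get_params() == params
        X, y = self._Xy(points_split["passive"])
        with pytest.raises(Exception):
            est.predict(X)  # not fitted yet
        est.set_params(generations=5).fit(X, y)
        assert hasattr(est, "constants_")

    def test_input_validation(self, truth, points_split):
        X, y = self._Xy(points_split["passive"])
        est = PassiveStressRegressor(generations=5, population_size=20)
        with pytest.raises(ValueError):
            est.fit(X[:, :3], y)
        with pytest.raises(ValueError):
            est.fit(X, y[:, :2])
        with pytest.raises(ValueError):
            ActiveStressRegressor().fit(X, y)  # missing passive constants
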