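"""Estimation of passive and active material constants.

The constants are found by minimizing the summed squared differences
between theoretical and experimental 1st PK stresses in all three normal
directions, sequentially: first the seven passive constants against the
Ca2+-free (passive) points, then the five active constants against the
K+-constricted (total) points with the passive set held fixed.

Two optimizers cooperate.  A bounded Levenberg-Marquardt-type local least
squares (scipy's trust-region reflective) provides a deterministic warm
start; a real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation with a linearly decaying scale, elitism)
then searches globally, its population seeded around the warm start.
Constraints — positivity of all constants and, optionally, a convexity
condition on the Fung quadratic form — are handled by rejection-resampling
at initialization and a static penalty during evolution.

The module exposes both the operation-level functions and two
scikit-learn style estimators, :class:`PassiveStressRegressor` and
:class:`ActiveStressRegressor`, whose ``X`` rows are
``(lam_theta, lam_z, r_i, r_o)`` loading states and whose ``y`` rows are
``(T_theta, T_z, T_r)`` stress triples in kPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .constitutive import ActiveConstants, PassiveConstants, convexity_check
from .experimental import StressPoint, point_arrays
from .meanwall import passive_pk_batch, total_pk_batch

__all__ = [
    "FitConfig",
    "FitResult",
    "passive_objective",
    "total_objective",
    "lm_warm_start",
    "ga_fit",
    "r_squared",
    "PassiveStressRegressor",
    "ActiveStressRegressor",
    "fit_passive",
    "fit_active",
]

#: Default parameter bounds; cover the published constant ranges with margin.
PASSIVE_BOUNDS: Tuple[Tuple[float, float], ...] = tuple([(1e-4, 50.0)] * 7)
ACTIVE_BOUNDS: Tuple[Tuple[float, float], ...] = (
    (1e-3, 200.0),  # C2
    (1e-3, 20.0),   # b1
    (1e-3, 20.0),   # b2
    (1e-3, 20.0),   # b3
    (1e-3, 20.0),   # b_prime
)

_PENALTY = 1e9        # static penalty weight per unit constraint violation
_DIVERGED = 1e12      # objective value substituted for diverged energies

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Genetic-algorithm and constraint configuration.

    The search space is box-bounded; ``constraint_mode`` adds a convexity
    constraint on the Fung quadratic form: ``'strict'`` (positive-definite),
    ``'printed'`` (the printed inequality of the source literature) or
    ``'none'`` (positivity only — the default, because published constant
    sets are inconsistent with both convexity inequalities).
    """

    population_size: int = 120
    generations: int = 300
    crossover_prob: float = 0.8
    mutation_scale: float = 0.1     # initial Gaussian sd, fraction of bound width
    mutation_scale_final: float = 0.01
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0
    bounds: Optional[Tuple[Tuple[float, float], ...]] = None
    constraint_mode: str = "none"

    def __post_init__(self):
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.constraint_mode not in ("none", "strict", "printed"):
            raise ValueError("constraint_mode must be 'none', 'strict' or 'printed'")
        if self.bounds is not None and any(lo >= hi for lo, hi in self.bounds):
            raise ValueError("bounds must satisfy low < high")


@dataclass
class FitResult:
    """Outcome of a fit: the constants, the objective (kPa^2), per-component
    R^2 (keys 'T_theta', 'T_z', 'T_r'), the best-ever objective trace per
    generation, and the seed that produced it."""

    constants: object
    objective: float
    r2: dict
    trace: np.ndarray
    seed: int
    warning: Optional[str] = None

    def __post_init__(self):
        if self.objective < 0:
            raise ValueError("objective must be non-negative")


# -- objectives ---------------------------------------------------------------


def _check_points(points: Sequence[StressPoint], state: str):
    points = list(points)
    if not points:
        raise ValueError("empty point list")
    bad = [i for i, p in enumerate(points) if p.state != state]
    if bad:
        raise ValueError(f"points at indices {bad} are not {state}-state")
    return points


def _batch_objective_passive(params2d, arrays):
    lam_t, lam_z, r_i, r_o, T = arrays
    with np.errstate(over="ignore", invalid="ignore"):
        Tt, Tz, Tr = passive_pk_batch(params2d, lam_t, lam_z, r_i, r_o)
        obj = ((Tt - T[:, 0]) ** 2 + (Tz - T[:, 1]) ** 2 + (Tr - T[:, 2]) ** 2).sum(axis=1)
    return np.where(np.isfinite(obj), obj, _DIVERGED)


def _batch_objective_total(params2d, passive_vec, arrays, planar=False):
    lam_t, lam_z, r_i, r_o, T = arrays
    with np.errstate(over="ignore", invalid="ignore"):
        Tt, Tz, Tr = total_pk_batch(params2d, passive_vec, lam_t, lam_z, r_i, r_o, planar=planar)
        obj = ((Tt - T[:, 0]) ** 2 + (Tz - T[:, 1]) ** 2 + (Tr - T[:, 2]) ** 2).sum(axis=1)
    return np.where(np.isfinite(obj), obj, _DIVERGED)


def passive_objective(pc: PassiveConstants, points: Sequence[StressPoint]) -> float:
    """Summed squared theory-experiment differences of the passive 1st PK
    stresses over all points and all three directions (kPa^2)."""
    points = _check_points(points, "passive")
    arrays = point_arrays(points)
    return float(_batch_objective_passive(pc.as_array()[None, :], arrays)[0])


def total_objective(
    ac: ActiveConstants, pc_fixed: PassiveConstants, points: Sequence[StressPoint]
) -> float:
    """Summed squared differences between theoretical total (passive +
    active) and experimental total 1st PK stresses (kPa^2)."""
    points = _check_points(points, "total")
    arrays = point_arrays(points)
    if ac.is_planar:
        vec = np.array([ac.C2, ac.b1, ac.b2, np.nan, ac.b_prime])
    else:
        vec = ac.as_array()
    return float(
        _batch_objective_total(vec[None, :], pc_fixed.as_array(), arrays, planar=ac.is_planar)[0]
    )


def r_squared(theory: np.ndarray, experiment: np.ndarray) -> dict:
    """Coefficient of determination per stress component.

    Both arrays have shape (n, 3) ordered (T_theta, T_z, T_r); R^2 is
    1 - SSres/SStot with SStot about the experimental mean.
    """
    theory = np.asarray(theory, dtype=float)
    experiment = np.asarray(experiment, dtype=float)
    if experiment.shape[0] < 2:
        raise ValueError("need at least 2 points for R^2")
    out = {}
    for j, name in enumerate(("T_theta", "T_z", "T_r")):
        obs, pred = experiment[:, j], theory[:, j]
        sstot = float(((obs - obs.mean()) ** 2).sum())
        if sstot == 0.0:
            raise ValueError(f"zero variance in experimental {name}: R^2 undefined")
        out[name] = 1.0 - float(((pred - obs) ** 2).sum()) / sstot
    return out


# -- constraint handling ------------------------------------------------------


def _convexity_violation(params2d: np.ndarray, mode: str) -> np.ndarray:
    """Non-negative violation measure of the configured convexity mode for a
    (m, 7) passive parameter batch (zero where satisfied)."""
    a1, a2, a3, a4, a5, a6 = (params2d[:, k] for k in range(1, 7))
    if mode == "strict":
        m1 = a1
        m2 = a1 * a2 - a4**2
        m3 = (a1 * (a2 * a3 - a5**2) - a4 * (a4 * a3 - a5 * a6) + a6 * (a4 * a5 - a2 * a6))
        return np.maximum(0, -m1) + np.maximum(0, -m2) + np.maximum(0, -m3)
    if mode == "printed":
        crit = a4**2 + a5**2 + a6**2 - a1 * a2 - a2 * a3 - a1 * a3
        return np.maximum(0, -crit)
    return np.zeros(len(params2d))


# -- local optimizer ----------------------------------------------------------


def lm_warm_start(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
    max_nfev: int = 2000,
):
    """Bounded local least squares from ``x0`` (deterministic).

    Returns ``(x, warning)`` where ``warning`` is None on convergence and a
    message when the iteration limit was hit (the best iterate is still
    returned).  Raises if ``x0`` violates the bounds.
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError(f"x0={x0} outside bounds")
    sol = least_squares(
        residual_fn, x0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=max_nfev,
    )
    warning = None if sol.status != 0 else "local least squares hit the iteration limit"
    return sol.x, warning


# -- genetic algorithm --------------------------------------------------------


def ga_fit(
    batch_objective: Callable[[np.ndarray], np.ndarray],
    config: FitConfig,
    bounds: Sequence[Tuple[float, float]],
    x_warm: Optional[np.ndarray] = None,
    constraint_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Tuple[np.ndarray, float, np.ndarray]:
    """Minimize a batched objective with a real-coded genetic algorithm.

    Parameters
    ----------
    batch_objective : callable
        Maps an (m, k) parameter matrix to an (m,) objective vector.
    config : FitConfig
    bounds : sequence of (low, high)
    x_warm : array, optional
        Warm-start individual; the population is initialized around it
        (Gaussian jitter) plus uniformly random individuals, all feasible
        by rejection-resampling.
    constraint_fn : callable, optional
        Maps (m, k) parameters to an (m,) non-negative violation measure;
        violations incur a static penalty of 1e9 per unit during evolution
        and are rejected at initialization.

    Returns
    -------
    (x_best, f_best, trace) where ``trace[g]`` is the best-ever objective
    after generation g (non-increasing).  Bit-reproducible for a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    k = len(bounds)
    npop = config.population_size

    def feasible_mask(pop):
        ok = np.all((pop >= lo) & (pop <= hi), axis=1)
        if constraint_fn is not None:
            ok &= constraint_fn(pop) <= 0
        return ok

    # --- initialization: jitter around the warm start + uniform explorers,
    #     rejection-resampled to feasibility
    pop = np.empty((npop, k))
    n_warm = npop // 2 if x_warm is not None else 0
    if n_warm:
        width = (hi - lo) * 0.05
        pop[:n_warm] = np.clip(x_warm + width * rng.standard_normal((n_warm, k)), lo, hi)
        pop[0] = np.clip(x_warm, lo, hi)
    pop[n_warm:] = rng.uniform(lo, hi, (npop - n_warm, k))
    for _ in range(200):
        bad = ~feasible_mask(pop)
        if not bad.any():
            break
        pop[bad] = rng.uniform(lo, hi, (int(bad.sum()), k))
    else:
        viol = constraint_fn(pop) if constraint_fn is not None else None
        raise RuntimeError(
            "could not initialize a feasible population; constraint violations: "
            f"{viol}"
        )

    def fitness(p):
        f = batch_objective(p)
        if constraint_fn is not None:
            f = f + _PENALTY * constraint_fn(p)
        return f

    fit = fitness(pop)
    best_i = int(np.argmin(fit))
    x_best, f_best = pop[best_i].copy(), float(fit[best_i])
    trace = np.empty(config.generations)

    for g in range(config.generations):
        # tournament selection
        idx = rng.integers(0, npop, (npop, config.tournament_size))
        winners = idx[np.arange(npop), np.argmin(fit[idx], axis=1)]
        parents = pop[winners]

        # blend crossover on consecutive pairs
        children = parents.copy()
        do_cx = rng.random(npop // 2) < config.crossover_prob
        alpha = rng.random((npop // 2, k))
        p1, p2 = parents[0::2], parents[1::2]
        c1 = alpha * p1 + (1 - alpha) * p2
        c2 = alpha * p2 + (1 - alpha) * p1
        children[0::2] = np.where(do_cx[:, None], c1, p1)
        children[1::2] = np.where(do_cx[:, None], c2, p2)

        # Gaussian mutation, scale decaying linearly over generations
        frac = g / max(config.generations - 1, 1)
        scale = (config.mutation_scale * (1 - frac) + config.mutation_scale_final * frac)
        mutate = rng.random((npop, k)) < 0.5
        children = children + mutate * (scale * (hi - lo)) * rng.standard_normal((npop, k))
        children = np.clip(children, lo, hi)

        # elitism: best-so-far individuals survive unchanged
        order = np.argsort(fit)
        children[: config.elitism] = pop[order[: config.elitism]]

        pop = children
        fit = fitness(pop)
        i = int(np.argmin(fit))
        if fit[i] < f_best:
            x_best, f_best = pop[i].copy(), float(fit[i])
        trace[g] = f_best
        if log.isEnabledFor(logging.DEBUG) and (g % 25 == 0 or g == config.generations - 1):
            log.debug("generation %d: best %.6g, median %.6g", g, f_best,
                      float(np.median(fit)))

    return x_best, f_best, trace


# -- high-level sequential protocol -------------------------------------------


def _passive_constraint_fn(mode):
    if mode == "none":
        return None
    return lambda p: _convexity_violation(p, mode)


def fit_passive(points: Sequence[StressPoint], config: FitConfig,
                x0: Optional[np.ndarray] = None) -> FitResult:
    """Fit the seven passive constants to passive-state stress points."""
    points = _check_points(points, "passive")
    arrays = point_arrays(points)
    bounds = config.bounds or PASSIVE_BOUNDS
    batch = lambda p: _batch_objective_passive(p, arrays)

    if x0 is None:
        x0 = np.array([np.sqrt(lo * hi) for lo, hi in bounds])  # geometric mid
    residual = _passive_residual_fn(arrays)
    x_warm, warning = lm_warm_start(residual, x0, bounds)
    x_best, f_best, trace = ga_fit(
        batch, config, bounds, x_warm=x_warm,
        constraint_fn=_passive_constraint_fn(config.constraint_mode),
    )
    # polish the GA winner locally (keeps the objective monotone)
    x_pol, _ = lm_warm_start(residual, x_best, bounds)
    if batch(x_pol[None, :])[0] <= f_best and _feasible(x_pol, config):
        x_best = x_pol
        f_best = float(batch(x_pol[None, :])[0])
    pc = PassiveConstants.from_array(x_best)
    Tt, Tz, Tr = passive_pk_batch(x_best[None, :], *arrays[:4])
    r2 = r_squared(np.stack([Tt[0], Tz[0], Tr[0]], axis=1), arrays[4])
    return FitResult(constants=pc, objective=f_best, r2=r2,
                     trace=trace, seed=config.seed, warning=warning)


def fit_active(points: Sequence[StressPoint], pc_fixed: PassiveConstants,
               config: FitConfig, x0: Optional[np.ndarray] = None) -> FitResult:
    """Fit the five active constants to total-state points, passive fixed."""
    points = _check_points(points, "total")
    arrays = point_arrays(points)
    bounds = config.bounds or ACTIVE_BOUNDS
    pvec = pc_fixed.as_array()
    batch = lambda p: _batch_objective_total(p, pvec, arrays)

    if x0 is None:
        x0 = np.array([np.sqrt(lo * hi) for lo, hi in bounds])
    residual = _total_residual_fn(arrays, pvec)
    x_warm, warning = lm_warm_start(residual, x0, bounds)
    x_best, f_best, trace = ga_fit(batch, config, bounds, x_warm=x_warm)
    x_pol, _ = lm_warm_start(residual, x_best, bounds)
    if batch(x_pol[None, :])[0] <= f_best:
        x_best = x_pol
        f_best = float(batch(x_pol[None, :])[0])
    ac = ActiveConstants.from_array(x_best)
    Tt, Tz, Tr = total_pk_batch(x_best[None, :], pvec, *arrays[:4])
    r2 = r_squared(np.stack([Tt[0], Tz[0], Tr[0]], axis=1), arrays[4])
    return FitResult(constants=ac, objective=f_best, r2=r2,
                     trace=trace, seed=config.seed, warning=warning)


def _feasible(x, config):
    if config.constraint_mode == "none":
        return True
    return _convexity_violation(x[None, :], config.constraint_mode)[0] <= 0


def _passive_residual_fn(arrays):
    lam_t, lam_z, r_i, r_o, T = arrays

    def residual(x):
        with np.errstate(over="ignore", invalid="ignore"):
            Tt, Tz, Tr = passive_pk_batch(x[None, :], lam_t, lam_z, r_i, r_o)
            r = np.concatenate([Tt[0] - T[:, 0], Tz[0] - T[:, 1], Tr[0] - T[:, 2]])
        return np.where(np.isfinite(r), r, 1e6)

    return residual


def _total_residual_fn(arrays, pvec):
    lam_t, lam_z, r_i, r_o, T = arrays

    def residual(x):
        with np.errstate(over="ignore", invalid="ignore"):
            Tt, Tz, Tr = total_pk_batch(x[None, :], pvec, lam_t, lam_z, r_i, r_o)
            r = np.concatenate([Tt[0] - T[:, 0], Tz[0] - T[:, 1], Tr[0] - T[:, 2]])
        return np.where(np.isfinite(r), r, 1e6)

    return residual


def fit_sequential(
    passive_points: Sequence[StressPoint],
    total_points: Sequence[StressPoint],
    config: FitConfig,
    joint_refine: bool = False,
) -> Tuple[FitResult, FitResult]:
    """Full sequential protocol: passive constants first, then active with
    the passive set fixed.

    ``joint_refine=True`` follows with one bounded local least-squares pass
    over all twelve constants against both point sets simultaneously (off
    by default; the sequential solution is already exact on self-consistent
    data and the joint pass couples the stages).
    """
    res_p = fit_passive(passive_points, config)
    res_a = fit_active(total_points, res_p.constants, config)
    if not joint_refine:
        return res_p, res_a

    arr_p = point_arrays(_check_points(passive_points, "passive"))
    arr_t = point_arrays(_check_points(total_points, "total"))
    bounds = tuple(PASSIVE_BOUNDS) + tuple(ACTIVE_BOUNDS)

    def residual(x):
        with np.errstate(over="ignore", invalid="ignore"):
            Tt, Tz, Tr = passive_pk_batch(x[None, :7], *arr_p[:4])
            rp = np.concatenate([Tt[0] - arr_p[4][:, 0], Tz[0] - arr_p[4][:, 1],
                                 Tr[0] - arr_p[4][:, 2]])
            Tt, Tz, Tr = total_pk_batch(x[None, 7:], x[:7], *arr_t[:4])
            rt = np.concatenate([Tt[0] - arr_t[4][:, 0], Tz[0] - arr_t[4][:, 1],
                                 Tr[0] - arr_t[4][:, 2]])
        r = np.concatenate([rp, rt])
        return np.where(np.isfinite(r), r, 1e6)

    x0 = np.concatenate([res_p.constants.as_array(), res_a.constants.as_array()])
    x, _ = lm_warm_start(residual, x0, bounds)
    obj_p = float(_batch_objective_passive(x[None, :7], arr_p)[0])
    obj_t = float(_batch_objective_total(x[None, 7:], x[:7], arr_t)[0])
    if obj_p + obj_t <= res_p.objective + res_a.objective:
        pc = PassiveConstants.from_array(x[:7])
        ac = ActiveConstants.from_array(x[7:])
        Tt, Tz, Tr = passive_pk_batch(x[None, :7], *arr_p[:4])
        r2p = r_squared(np.stack([Tt[0], Tz[0], Tr[0]], 1), arr_p[4])
        Tt, Tz, Tr = total_pk_batch(x[None, 7:], x[:7], *arr_t[:4])
        r2t = r_squared(np.stack([Tt[0], Tz[0], Tr[0]], 1), arr_t[4])
        res_p = FitResult(constants=pc, objective=obj_p, r2=r2p,
                          trace=res_p.trace, seed=config.seed)
        res_a = FitResult(constants=ac, objective=obj_t, r2=r2t,
                          trace=res_a.trace, seed=config.seed)
    return res_p, res_a


# -- scikit-learn estimators --------------------------------------------------


class _StressRegressorBase(BaseEstimator, RegressorMixin):
    """Shared plumbing: X rows are (lam_theta, lam_z, r_i, r_o), y rows are
    (T_theta, T_z, T_r) in kPa."""

    def _validate(self, X, y=None):
        X = check_array(X, ensure_min_features=4)
        if X.shape[1] != 4:
            raise ValueError("X must have 4 columns: lam_theta, lam_z, r_i, r_o")
        if np.any(X[:, :2] <= 0):
            raise ValueError("stretch ratios must be positive")
        if y is not None:
            y = check_array(y, ensure_2d=True)
            if y.shape != (X.shape[0], 3):
                raise ValueError("y must have shape (n_samples, 3)")
            return X, y
        return X

    def _config(self):
        return FitConfig(
            population_size=self.population_size, generations=self.generations,
            crossover_prob=self.crossover_prob, mutation_scale=self.mutation_scale,
            tournament_size=self.tournament_size, seed=self.seed,
            constraint_mode=self.constraint_mode,
        )

    def score_components(self, X, y):
        """Per-component R^2 dict (keys 'T_theta', 'T_z', 'T_r')."""
        check_is_fitted(self)
        X, y = self._validate(X, y)
        return r_squared(self.predict(X), y)


class PassiveStressRegressor(_StressRegressorBase):
    """Fit Fung passive constants to mean-wall stress data.

    Parameters mirror :class:`FitConfig`.  After ``fit``, the estimated
    constants are in ``constants_`` and the per-component training R^2 in
    ``r2_``.
    """

    def __init__(self, population_size=120, generations=300, crossover_prob=0.8,
                 mutation_scale=0.1, tournament_size=3, seed=0, constraint_mode="none"):
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_scale = mutation_scale
        self.tournament_size = tournament_size
        self.seed = seed
        self.constraint_mode = constraint_mode

    def fit(self, X, y):
        X, y = self._validate(X, y)
        points = [
            StressPoint(lam_theta=r[0], lam_z=r[1], r_i=r[2], r_o=r[3],
                        T_theta=t[0], T_z=t[1], T_r=t[2], state="passive")
            for r, t in zip(X, y)
        ]
        res = fit_passive(points, self._config())
        self.constants_ = res.constants
        self.objective_ = res.objective
        self.r2_ = res.r2
        self.trace_ = res.trace
        self.n_features_in_ = 4
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = self._validate(X)
        Tt, Tz, Tr = passive_pk_batch(
            self.constants_.as_array()[None, :], X[:, 0], X[:, 1], X[:, 2], X[:, 3]
        )
        return np.stack([Tt[0], Tz[0], Tr[0]], axis=1)


class ActiveStressRegressor(_StressRegressorBase):
    """Fit active constants to total-state stress data with the passive
    constants held fixed (``passive_constants`` is required)."""

    def __init__(self, passive_constants=None, population_size=120, generations=300,
                 crossover_prob=0.8, mutation_scale=0.1, tournament_size=3, seed=0,
                 constraint_mode="none"):
        self.passive_constants = passive_constants
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_scale = mutation_scale
        self.tournament_size = tournament_size
        self.seed = seed
        self.constraint_mode = constraint_mode

    def fit(self, X, y):
        if self.passive_constants is None:
            raise ValueError("passive_constants must be set before fitting the active stage")
        X, y = self._validate(X, y)
        points = [
            StressPoint(lam_theta=r[0], lam_z=r[1], r_i=r[2], r_o=r[3],
                        T_theta=t[0], T_z=t[1], T_r=t[2], state="total")
            for r, t in zip(X, y)
        ]
        res = fit_active(points, self.passive_constants, self._config())
        self.constants_ = res.constants
        self.objective_ = res.objective
        self.r2_ = res.r2
        self.trace_ = res.trace
        self.n_features_in_ = 4
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = self._validate(X)
        Tt, Tz, Tr = total_pk_batch(
            self.constants_.as_array()[None, :],
            self.passive_constants.as_array(),
            X[:, 0], X[:, 1], X[:, 2], X[:, 3],
        )
        return np.stack([Tt[0], Tz[0], Tr[0]], axis=1)
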