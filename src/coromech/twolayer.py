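"""Two-layer thick-wall cylinder with layer-specific residual strain.

The wall is modelled as two concentric incompressible layers — intima-media
(IM), which carries the smooth-muscle active stress, and a passive
adventitia — each with its own stress-free (cut-open) configuration
characterized by inner/outer radii and an opening angle Phi.  With
k = pi/(pi - Phi), a material point at stress-free radius R maps to the
deformed radius

    r(R) = sqrt(r_in^2 + (R^2 - R_in^2) / (k * lam_z)),

(per-layer incompressibility), with local stretches lam_theta = k*r/R and
lam_r = 1/(lam_theta*lam_z).  Phi = 0 means no residual strain.  The two
layers have independent stress-free states; the deformed configuration is
continuous (the adventitia's map is anchored at the IM's deformed outer
radius), which makes the stretches — and hence the circumferential stress —
discontinuous at the interface while the radial traction stays continuous.

Radial equilibrium of the axisymmetric wall,

    d sigma_r / dr = (sigma_theta - sigma_r) / r,    sigma_r(r_i) = -P,
    sigma_r(r_o) = 0,

is solved by shooting on the deformed inner radius r_i: for a trial r_i the
equilibrium integral is a pure quadrature (the stress difference depends
only on the kinematics), and the outer-boundary residual sigma_r(r_o) is
driven to zero by bracketing root-finding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, least_squares

from .constitutive import ActiveConstants, PassiveConstants
from .kinematics import KinematicState
from .units import mmhg_to_kpa

__all__ = [
    "LayerSpec",
    "TransmuralProfile",
    "deformed_map",
    "local_state",
    "stress_difference",
    "solve_wall",
    "calibrate_geometry",
    "interface_metrics",
    "uniform_stress_thickness",
    "coronary_layer_templates",
    "planar_active_counterpart",
]


class WallSolveError(RuntimeError):
    """The shooting bracket contains no sign change (no equilibrium found)."""


@dataclass(frozen=True)
class LayerSpec:
    """One wall layer: stress-free geometry plus material constants.

    R_in, R_out : stress-free inner/outer radii (mm); opening_angle : Phi in
    radians, 0 <= Phi < pi; ``active`` is present only for the IM layer.
    """

    R_in: float
    R_out: float
    opening_angle: float
    passive: PassiveConstants
    active: Optional[ActiveConstants] = None

    def __post_init__(self):
        if not (0 < self.R_in < self.R_out):
            raise ValueError("need 0 < R_in < R_out")
        if not (0 <= self.opening_angle < np.pi):
            raise ValueError("opening angle must be in [0, pi)")

    @property
    def k(self) -> float:
        """Residual-strain factor k = pi/(pi - Phi)."""
        return np.pi / (np.pi - self.opening_angle)


@dataclass
class TransmuralProfile:
    """Radial profiles across the deformed two-layer wall.

    Arrays are ordered from the inner to the outer boundary; ``layer`` holds
    'IM' or 'adventitia' per point and ``interface_index`` the first index
    of the adventitia.  ``x_norm`` is the normalized wall coordinate
    (r - r_i)/(r_o - r_i).
    """

    r: np.ndarray
    x_norm: np.ndarray
    sigma_theta: np.ndarray
    sigma_r: np.ndarray
    lam_theta: np.ndarray
    lam_r: np.ndarray
    layer: np.ndarray
    interface_index: int
    P_mmHg: float
    lam_z: float
    activation: str

    def __post_init__(self):
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("deformed radii must be strictly increasing")

    @property
    def r_i(self) -> float:
        return float(self.r[0])

    @property
    def r_o(self) -> float:
        return float(self.r[-1])

    @property
    def thickness(self) -> float:
        return self.r_o - self.r_i

    def mean_sigma_theta(self) -> float:
        """Thickness-averaged circumferential Cauchy stress (kPa)."""
        return float(np.trapezoid(self.sigma_theta, self.r) / self.thickness)


def deformed_map(R, R_in, r_in_layer, lam_z, k):
    """Deformed radius of a material point at stress-free radius R.

    ``r_in_layer`` is the deformed radius of the layer's stress-free inner
    surface ``R_in``: r = sqrt(r_in^2 + (R^2 - R_in^2)/(k lam_z)), which
    conserves the layer's wall volume exactly.  Raises on a negative
    radicand (infeasible deformation).
    """
    R = np.asarray(R, dtype=float)
    arg = r_in_layer**2 + (R**2 - R_in**2) / (k * lam_z)
    if np.any(arg <= 0):
        raise ValueError("infeasible deformation: negative radicand in radial map")
    return np.sqrt(arg)


def local_state(r, R, k, lam_z) -> KinematicState:
    """Local incompressible kinematic state: lam_theta = k r / R."""
    lam_theta = k * np.asarray(r, dtype=float) / np.asarray(R, dtype=float)
    return KinematicState.from_biaxial(lam_theta, lam_z)


def stress_difference(state: KinematicState, layer: LayerSpec, activation: str = "passive"):
    """Cauchy stress differences (sigma_theta - sigma_r, sigma_z - sigma_r).

    The passive part is lam_i^2 dW/dE_i differences (the Lagrange
    multiplier cancels); the active part lam_i dW_active/dlam_i differences
    is added when the layer has an active law and ``activation='active'``.
    Returns the circumferential difference (the quantity equilibrium
    needs); use :func:`_stress_differences` for both.
    """
    return _stress_differences(state, layer, activation)[0]


def _stress_differences(state: KinematicState, layer: LayerSpec, activation: str):
    from .constitutive import _passive_dW_dE, first_pk_active

    dWt, dWz, dWr = _passive_dW_dE(state, layer.passive)
    D_theta = state.lam_theta**2 * dWt - state.lam_r**2 * dWr
    D_z = state.lam_z**2 * dWz - state.lam_r**2 * dWr
    if activation == "active" and layer.active is not None:
        Ta = first_pk_active(state, layer.active)
        D_theta = D_theta + state.lam_theta * Ta.T_theta - state.lam_r * Ta.T_r
        D_z = D_z + state.lam_z * Ta.T_z - state.lam_r * Ta.T_r
    return D_theta, D_z


def _layer_profiles(layers, r_i, lam_z, n_grid):
    """Kinematics and stress differences on per-layer grids for trial r_i."""
    r_all, lam_t_all, lam_r_all, D_all, labels = [], [], [], [], []
    r_anchor = r_i
    for name, layer in zip(("IM", "adventitia"), layers):
        R = np.linspace(layer.R_in, layer.R_out, n_grid)
        r = deformed_map(R, layer.R_in, r_anchor, lam_z, layer.k)
        lam_t = layer.k * r / R
        state = KinematicState.from_biaxial(lam_t, lam_z)
        activation = "active" if layer.active is not None else "passive"
        # activation decided by caller via layer.active presence
        D, _ = _stress_differences(state, layer, activation)
        r_all.append(r)
        lam_t_all.append(lam_t)
        lam_r_all.append(1.0 / (lam_t * lam_z))
        D_all.append(D)
        labels.append(np.full(n_grid, name, dtype=object))
        r_anchor = r[-1]
    return r_all, lam_t_all, lam_r_all, D_all, labels


def _outer_sigma_r(layers, r_i, lam_z, P_kpa, n_grid):
    r_all, _, _, D_all, _ = _layer_profiles(layers, r_i, lam_z, n_grid)
    sigma = -P_kpa
    for r, D in zip(r_all, D_all):
        sigma = sigma + np.trapezoid(D / r, r)
    return sigma


def solve_wall(
    layers: Sequence[LayerSpec],
    P_mmHg: float,
    lam_z: float,
    activation: str = "passive",
    n_grid: int = 200,
    r_i_bracket: Tuple[float, float] = None,
) -> TransmuralProfile:
    """Solve the two-layer wall at pressure P (mmHg) and axial stretch lam_z.

    ``layers`` is the (IM, adventitia) pair, inner first.
    ``activation='passive'`` switches the IM active law off even if
    present.  Shooting on the deformed inner radius until the outer surface
    is traction-free; tolerance 1e-6 kPa on sigma_r(r_o) (achieved via a
    relative 1e-12 root on r_i).
    """
    if len(layers) != 2:
        raise ValueError("expected exactly two layers (IM, adventitia)")
    if activation not in ("passive", "active"):
        raise ValueError("activation must be 'passive' or 'active'")
    work = list(layers)
    if activation == "passive":
        work = [replace(L, active=None) for L in work]
    P_kpa = float(mmhg_to_kpa(P_mmHg))

    # bracket the shooting variable: r_i between near-collapse and the
    # stress-free inner radius scaled well beyond physiological distension
    if r_i_bracket is None:
        R_in = work[0].R_in
        r_i_bracket = (0.05 * R_in, 2.5 * R_in / work[0].k)
    lo, hi = r_i_bracket
    grid = np.linspace(lo, hi, 80)
    with np.errstate(over="ignore"):
        vals = []
        for g in grid:
            try:
                vals.append(_outer_sigma_r(work, g, lam_z, P_kpa, max(n_grid // 4, 25)))
            except (ValueError, FloatingPointError, OverflowError):
                vals.append(np.nan)
        vals = np.array(vals)
    ok = np.isfinite(vals)
    sign = np.sign(vals)
    cross = [
        i for i in range(len(grid) - 1)
        if ok[i] and ok[i + 1] and sign[i] * sign[i + 1] < 0
    ]
    if not cross:
        rng_txt = (
            f"[{np.nanmin(vals):.3g}, {np.nanmax(vals):.3g}] kPa"
            if ok.any() else "all evaluations infeasible"
        )
        raise WallSolveError(
            f"no sign change of the outer-boundary residual for r_i in "
            f"({lo:.3g}, {hi:.3g}) at P={P_mmHg} mmHg, lam_z={lam_z}; "
            f"residual range {rng_txt}"
        )
    i = cross[-1]
    r_i = brentq(
        lambda x: _outer_sigma_r(work, x, lam_z, P_kpa, n_grid),
        grid[i], grid[i + 1], xtol=1e-13, rtol=1e-14,
    )

    # assemble the full profile at the solved inner radius
    r_all, lt_all, lr_all, D_all, labels = _layer_profiles(work, r_i, lam_z, n_grid)
    sigma_r_parts = []
    sigma0 = -P_kpa
    for r, D in zip(r_all, D_all):
        s = sigma0 + cumulative_trapezoid(D / r, r, initial=0.0)
        sigma_r_parts.append(s)
        sigma0 = s[-1]
    r = np.concatenate(r_all)
    sigma_r = np.concatenate(sigma_r_parts)
    D = np.concatenate(D_all)
    # drop the duplicated interface radius? both sides kept: the interface is
    # a genuine discontinuity of sigma_theta, represented by two points at
    # (numerically) the same radius -- nudge for strict monotonicity
    eps = 1e-12 * r[-1]
    r[n_grid] = r[n_grid] + eps
    profile = TransmuralProfile(
        r=r,
        x_norm=(r - r[0]) / (r[-1] - r[0]),
        sigma_theta=sigma_r + D,
        sigma_r=sigma_r,
        lam_theta=np.concatenate(lt_all),
        lam_r=np.concatenate(lr_all),
        layer=np.concatenate(labels),
        interface_index=n_grid,
        P_mmHg=float(P_mmHg),
        lam_z=float(lam_z),
        activation=activation,
    )
    return profile


def calibrate_geometry(
    target_loaded_thickness: float,
    target_im_fraction: float,
    P_mmHg: float,
    lam_z: float,
    layers_template: Sequence[LayerSpec],
    activation: str = "passive",
    tol: float = 5e-3,
    n_grid: int = 120,
) -> Tuple[LayerSpec, LayerSpec]:
    """Rescale the stress-free layer thicknesses so the solved loaded wall
    matches a target thickness and IM thickness fraction within ``tol``
    (relative).

    The stress-free inner radius of the IM layer is kept from the template;
    the two stress-free thicknesses are the free variables.
    """
    im0, ad0 = layers_template

    def build(log_t):
        t_im, t_ad = np.exp(log_t)
        im = replace(im0, R_out=im0.R_in + t_im)
        ad = replace(ad0, R_in=ad0.R_in, R_out=ad0.R_in + t_ad)
        return im, ad

    def residual(log_t):
        im, ad = build(log_t)
        try:
            prof = solve_wall([im, ad], P_mmHg, lam_z, activation, n_grid=n_grid)
        except WallSolveError:
            return np.array([10.0, 10.0])
        h = prof.thickness
        h_im = prof.r[prof.interface_index - 1] - prof.r_i
        return np.array(
            [h / target_loaded_thickness - 1.0, (h_im / h) / target_im_fraction - 1.0]
        )

    x0 = np.log([im0.R_out - im0.R_in, ad0.R_out - ad0.R_in])
    sol = least_squares(residual, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12, diff_step=1e-6)
    res = residual(sol.x)
    if np.max(np.abs(res)) > tol:
        raise RuntimeError(
            f"geometry calibration did not converge: relative residuals {res}"
        )
    return build(sol.x)


def coronary_layer_templates() -> Tuple[LayerSpec, LayerSpec]:
    """Default (IM, adventitia) stress-free templates for a porcine right
    coronary artery.

    The layer-specific stress-free geometry of the original preparations is
    not published, so the defaults are synthetic, chosen to reproduce the
    printed loaded-state picture once calibrated: at 80 mmHg and axial
    stretch 1.3 (loaded thickness 0.22 mm, IM half of it) the IM layer
    carries most of the circumferential load at lam_theta ~ 1.3-1.4 while
    the adventitia stays near-slack (lam_theta ~ 1.1), and the IM opening
    angle exceeds the adventitia's.  Constants: IM passive = IM-table mean,
    adventitia passive = whole-wall-table mean (surrogate — no
    adventitia-specific table is published), IM active = the joint fit of
    all six IM layers.  Layer thicknesses are placeholders for
    :func:`calibrate_geometry`.
    """
    from .synthetic import published_constants, subject_table

    def _mean(table):
        sub = subject_table(table, "passive")
        cols = ["C1", "a1", "a2", "a3", "a4", "a5", "a6"]
        return PassiveConstants(*[float(np.round(sub[c].mean(), 2)) for c in cols])

    im = LayerSpec(R_in=2.1, R_out=2.3, opening_angle=1.6,
                   passive=_mean("IM"), active=published_constants("two_layer"))
    ad = LayerSpec(R_in=1.85, R_out=2.02, opening_angle=0.8, passive=_mean("wall"))
    return im, ad


def planar_active_counterpart(
    ac: ActiveConstants,
    b1: float = 0.12,
    b2: float = 0.18,
    lam_z: float = 1.3,
    lam_theta_range: Tuple[float, float] = (1.1, 1.5),
) -> ActiveConstants:
    """Planar (2D) active law calibrated against a 3D law.

    The earlier biaxial active model has no radial term; its published
    width constants are b1 = 0.12, b2 = 0.18, but its stress scale and
    offset are not printed.  They are determined here the way the original
    models were built — by fitting the same circumferential response: C2
    and b' are least-squares matched to the 3D law's circumferential
    active 1st PK stress over the physiological stretch sweep at the
    reference axial stretch.
    """
    from scipy.optimize import least_squares as _ls

    lam = np.linspace(*lam_theta_range, 41)
    lam_r = 1.0 / (lam * lam_z)
    Qp3 = lam / ac.b1 + lam_z / ac.b2 - ac.b_prime
    if not ac.is_planar:
        Qp3 = Qp3 + lam_r / ac.b3
    T3 = 2.0 * ac.C2 / np.sqrt(np.pi) * np.exp(-Qp3**2) / ac.b1

    def resid(x):
        C2, bp = x
        Qp = lam / b1 + lam_z / b2 - bp
        return 2.0 * C2 / np.sqrt(np.pi) * np.exp(-Qp**2) / b1 - T3

    sol = _ls(resid, x0=[ac.C2 * b1 / ac.b1, 1.3 / b1 + lam_z / b2],
              bounds=([1e-3, 1.0], [1e3, 100.0]))
    return ActiveConstants(C2=float(sol.x[0]), b1=b1, b2=b2, b3=None,
                           b_prime=float(sol.x[1]))


def interface_metrics(profile_a: TransmuralProfile, profile_b: TransmuralProfile) -> dict:
    """Relative stress differences between two solutions at the interface
    (media side): |d sigma_theta / sigma_theta| and |d sigma_r / sigma_r|,
    normalized by profile_a (e.g. the 3D-active solution)."""
    ia, ib = profile_a.interface_index - 1, profile_b.interface_index - 1
    out = {}
    for key, xa, xb in (
        ("sigma_theta", profile_a.sigma_theta[ia], profile_b.sigma_theta[ib]),
        ("sigma_r", profile_a.sigma_r[ia], profile_b.sigma_r[ib]),
    ):
        if xa == 0:
            raise ZeroDivisionError(f"reference {key} is zero at the interface")
        out[key] = abs((xa - xb) / xa)
    return out


def uniform_stress_thickness(
    P_series_mmHg: Sequence[float],
    baseline: TransmuralProfile,
    layers_template: Sequence[LayerSpec],
    activation: str = "passive",
    im_fraction: Optional[float] = None,
    tol: float = 5e-3,
    n_grid: int = 120,
) -> List[Tuple[float, float]]:
    """Loaded wall thickness per pressure under the uniform circumferential
    stress hypothesis.

    For each pressure, the loaded thickness is adjusted (via geometry
    calibration at a fixed IM fraction) until the thickness-averaged
    circumferential Cauchy stress matches the baseline profile's average
    within ``tol``.  Returns [(P_mmHg, thickness_mm), ...].
    """
    target = baseline.mean_sigma_theta()
    h0 = baseline.thickness
    if im_fraction is None:
        im_fraction = (
            baseline.r[baseline.interface_index - 1] - baseline.r_i
        ) / baseline.thickness
    out = []
    for P in P_series_mmHg:
        def mismatch(h):
            layers = calibrate_geometry(
                h, im_fraction, P, baseline.lam_z, layers_template,
                activation=activation, tol=tol, n_grid=n_grid,
            )
            prof = solve_wall(layers, P, baseline.lam_z, activation, n_grid=n_grid)
            return prof.mean_sigma_theta() / target - 1.0

        # bracket around Laplace scaling of the baseline thickness
        h_guess = h0 * P / baseline.P_mmHg
        lo, hi = 0.4 * h_guess, 2.5 * h_guess
        f_lo, f_hi = mismatch(lo), mismatch(hi)
        if f_lo * f_hi > 0:
            raise WallSolveError(
                f"could not bracket the uniform-stress thickness at P={P} mmHg "
                f"(residuals {f_lo:.3g}, {f_hi:.3g})"
            )
        h = brentq(mismatch, lo, hi, xtol=1e-6, rtol=1e-6)
        out.append((float(P), float(h)))
    return out
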