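"""Theoretical mean-wall stresses of the loaded vessel.

For an incompressible wall the strain energy determines only the normal
stress *differences*

    sigma_theta - sigma_r = lam_theta^2 dW/dEt - lam_r^2 dW/dEr + (active)
    sigma_z     - sigma_r = lam_z^2     dW/dEz - lam_r^2 dW/dEr + (active)

the absolute level being fixed by the reaction pressure.  In the
homogenized (mean-wall) analysis of an inflation-extension test the
reaction is evaluated from the mean radial equilibrium of the loaded
thick-walled cylinder: with inner pressure P and a traction-free outer
surface, the thickness-averaged stresses satisfy

    <sigma_theta> = P r_i / h        and       <sigma_r> = -P r_i/(r_i+r_o),

hence  <sigma_r> = -<sigma_theta> * h / (r_i + r_o).  Imposing this ratio
on the theoretical differences closes the system:

    sigma_theta = D_theta * (r_i + r_o) / (2 r_o),     sigma_r = sigma_theta - D_theta,
    sigma_z     = D_z + sigma_r,

where D_i are the energy-derived differences above.  Division by the
stretches converts to 1st Piola-Kirchhoff stresses, the quantities the
experimental reduction produces.  This closure makes the theoretical
triple exactly consistent with the pressure-diameter-force reduction: a
dataset generated from a constant set is fitted by that same set with
zero residual.

The module also provides parameter-batched evaluators used by the genetic
algorithm, which scores whole populations in single numpy calls.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import erf  # noqa: F401  (re-exported convention partner)

from .constitutive import ActiveConstants, PassiveConstants

__all__ = [
    "theoretical_pk_stresses",
    "passive_pk_batch",
    "total_pk_batch",
]


def _passive_differences(lam_theta, lam_z, params):
    """Cauchy stress differences (D_theta, D_z) for a batch of passive params.

    ``params`` has shape (m, 7) = [C1, a1..a6]; stretches have shape (n,).
    Returns arrays of shape (m, n).  Overflowing exponents are clipped to a
    large finite value (the caller penalizes, never sees nan).
    """
    lam_theta = np.atleast_1d(np.asarray(lam_theta, dtype=float))
    lam_z = np.atleast_1d(np.asarray(lam_z, dtype=float))
    lam_r = 1.0 / (lam_theta * lam_z)
    Et = 0.5 * (lam_theta**2 - 1.0)
    Ez = 0.5 * (lam_z**2 - 1.0)
    Er = 0.5 * (lam_r**2 - 1.0)

    params = np.atleast_2d(np.asarray(params, dtype=float))
    C1 = params[:, [0]]
    a1, a2, a3, a4, a5, a6 = (params[:, [k]] for k in range(1, 7))

    Q = (
        a1 * Et**2 + a2 * Ez**2 + a3 * Er**2
        + 2.0 * (a4 * Et * Ez + a5 * Ez * Er + a6 * Er * Et)
    )
    CeQ = C1 * np.exp(np.minimum(Q, 700.0))
    dWt = CeQ * (a1 * Et + a4 * Ez + a6 * Er)
    dWz = CeQ * (a2 * Ez + a4 * Et + a5 * Er)
    dWr = CeQ * (a3 * Er + a5 * Ez + a6 * Et)
    D_theta = lam_theta**2 * dWt - lam_r**2 * dWr
    D_z = lam_z**2 * dWz - lam_r**2 * dWr
    return D_theta, D_z


def _active_differences(lam_theta, lam_z, params, planar=False):
    """Active contributions to (D_theta, D_z) for a batch of active params.

    ``params``: (m, 5) = [C2, b1, b2, b3, b_prime]; for ``planar=True`` the
    b3 column is ignored and the radial active stress is zero.
    """
    lam_theta = np.atleast_1d(np.asarray(lam_theta, dtype=float))
    lam_z = np.atleast_1d(np.asarray(lam_z, dtype=float))
    lam_r = 1.0 / (lam_theta * lam_z)

    params = np.atleast_2d(np.asarray(params, dtype=float))
    C2, b1, b2, b3, bp = (params[:, [k]] for k in range(5))
    Qp = lam_theta / b1 + lam_z / b2 - bp
    if not planar:
        Qp = Qp + lam_r / b3
    g = 2.0 * C2 / np.sqrt(np.pi) * np.exp(-(Qp**2))
    T_r = 0.0 if planar else g / b3
    D_theta = lam_theta * g / b1 - lam_r * T_r
    D_z = lam_z * g / b2 - lam_r * T_r
    return D_theta, D_z


def _close(D_theta, D_z, lam_theta, lam_z, r_i, r_o):
    """Fix the reaction pressure by the mean radial equilibrium and return
    the 1st PK triple (T_theta, T_z, T_r)."""
    lam_r = 1.0 / (lam_theta * lam_z)
    sigma_theta = D_theta * (r_i + r_o) / (2.0 * r_o)
    sigma_r = sigma_theta - D_theta
    sigma_z = D_z + sigma_r
    return sigma_theta / lam_theta, sigma_z / lam_z, sigma_r / lam_r


def passive_pk_batch(params, lam_theta, lam_z, r_i, r_o):
    """Mean-wall passive 1st PK triples for (m, 7) parameter batches.

    Returns three arrays of shape (m, n).
    """
    Dt, Dz = _passive_differences(lam_theta, lam_z, params)
    return _close(Dt, Dz, np.atleast_1d(lam_theta), np.atleast_1d(lam_z), r_i, r_o)


def total_pk_batch(active_params, passive_params, lam_theta, lam_z, r_i, r_o, planar=False):
    """Mean-wall total (passive + active) 1st PK triples.

    ``active_params`` is an (m, 5) batch; ``passive_params`` a single
    7-vector held fixed (the sequential fitting protocol).
    """
    Dt_p, Dz_p = _passive_differences(lam_theta, lam_z, np.atleast_2d(passive_params))
    Dt_a, Dz_a = _active_differences(lam_theta, lam_z, active_params, planar=planar)
    return _close(
        Dt_p + Dt_a, Dz_p + Dz_a, np.atleast_1d(lam_theta), np.atleast_1d(lam_z), r_i, r_o
    )


def theoretical_pk_stresses(
    lam_theta,
    lam_z,
    r_i,
    r_o,
    passive: PassiveConstants,
    active: Optional[ActiveConstants] = None,
):
    """Theoretical mean-wall 1st PK stress triple at one or more states.

    Parameters
    ----------
    lam_theta, lam_z : float or array
        Mid-wall circumferential and axial stretch ratios.
    r_i, r_o : float or array
        Loaded inner and outer radii (mm), needed to evaluate the reaction
        pressure of the closure.
    passive : PassiveConstants
    active : ActiveConstants, optional
        When given, the total (passive + active) stresses are returned;
        otherwise the passive stresses.

    Returns
    -------
    (T_theta, T_z, T_r) : arrays broadcast to the input shape, in kPa.
    """
    if active is None:
        Tt, Tz, Tr = passive_pk_batch(passive.as_array(), lam_theta, lam_z, r_i, r_o)
    else:
        if active.is_planar:
            ap = np.array([active.C2, active.b1, active.b2, np.nan, active.b_prime])
        else:
            ap = active.as_array()
        Tt, Tz, Tr = total_pk_batch(
            ap, passive.as_array(), lam_theta, lam_z, r_i, r_o, planar=active.is_planar
        )
    scalar = np.ndim(lam_theta) == 0 and np.ndim(lam_z) == 0
    return tuple(float(x[0, 0]) if scalar else x[0] for x in (Tt, Tz, Tr))
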