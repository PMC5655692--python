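"""Passive and active strain-energy functions of the arterial wall.

Passive behaviour follows the Fung exponential pseudo-strain-energy

    W_passive = (C1/2) * (exp(Q) - 1),
    Q = a1*Et^2 + a2*Ez^2 + a3*Er^2 + 2*a4*Et*Ez + 2*a5*Ez*Er + 2*a6*Er*Et,

with Green strains E_i in the circumferential (theta), axial (z) and radial
(r) directions.  Smooth-muscle activation (maximal K+-induced constriction)
is described by an error-function energy

    W_active = C2 * (erf(Q') - 1),
    Q' = lam_theta/b1 + lam_z/b2 + lam_r/b3 - b',

which saturates at 0 for large Q' and equals -2*C2 in the slack limit.  The
constants b1-b3 set the width of the active length-tension curve along each
direction; b' sets its position.  b4-b6 of the general form enter only
through b' = b4/b1 + b5/b2 + b6/b3 and are not individually identifiable,
so only b' is stored.

First Piola-Kirchhoff (1st PK) stresses are the direct partial derivatives
of the energies with the three strains treated as independent arguments:

    T_i,passive = lam_i * dW_passive/dE_i
    T_i,active  = dW_active/dlam_i = (2*C2 / (b_i*sqrt(pi))) * exp(-Q'^2)

For incompressible normal loading the Cauchy stress is sigma_i = lam_i*T_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erfc

from .kinematics import KinematicState

__all__ = [
    "PassiveConstants",
    "ActiveConstants",
    "StressTriple",
    "DivergedEnergyError",
    "passive_energy",
    "active_energy",
    "first_pk_passive",
    "first_pk_active",
    "cauchy_normal",
    "convexity_check",
    "ConvexityReport",
]

#: exp(Q) overflows float64 near Q ~ 709; above this the energy is treated
#: as diverged so optimizers see a clean exception, not inf/nan.
_Q_OVERFLOW = 700.0


class DivergedEnergyError(FloatingPointError):
    """The Fung exponent exceeded the overflow guard (Q > 700)."""


@dataclass(frozen=True)
class PassiveConstants:
    """Constants of the Fung exponential: stress scale C1 (kPa) and the
    dimensionless quadratic-form coefficients a1-a6 (all positive)."""

    C1: float
    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float

    def __post_init__(self):
        for name in ("C1", "a1", "a2", "a3", "a4", "a5", "a6"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def a(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4, self.a5, self.a6])

    def as_array(self) -> np.ndarray:
        return np.array([self.C1, self.a1, self.a2, self.a3, self.a4, self.a5, self.a6])

    @classmethod
    def from_array(cls, x) -> "PassiveConstants":
        return cls(*np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ActiveConstants:
    """Constants of the active error-function energy.

    C2 is the stress-like scale (kPa); b1, b2, b3 the stretch-scale widths;
    b_prime the offset.  ``b3=None`` selects the planar (2D) variant used by
    earlier biaxial work, in which the radial term lam_r/b3 is absent and
    the active radial stress is identically zero.
    """

    C2: float
    b1: float
    b2: float
    b3: Optional[float]
    b_prime: float

    def __post_init__(self):
        for name in ("C2", "b1", "b2", "b_prime"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.b3 is not None and self.b3 <= 0:
            raise ValueError(f"b3 must be positive or None, got {self.b3}")

    @property
    def is_planar(self) -> bool:
        return self.b3 is None

    def as_array(self) -> np.ndarray:
        if self.is_planar:
            raise ValueError("planar (2D) active constants have no b3 component")
        return np.array([self.C2, self.b1, self.b2, self.b3, self.b_prime])

    @classmethod
    def from_array(cls, x) -> "ActiveConstants":
        x = np.asarray(x, dtype=float)
        return cls(C2=x[0], b1=x[1], b2=x[2], b3=x[3], b_prime=x[4])


@dataclass(frozen=True)
class StressTriple:
    """Signed normal stresses (kPa) in the theta, z, r directions."""

    T_theta: float
    T_z: float
    T_r: float

    def as_array(self) -> np.ndarray:
        return np.array([self.T_theta, self.T_z, self.T_r])


# -- energies -----------------------------------------------------------------


def _fung_exponent(E_theta, E_z, E_r, a):
    a1, a2, a3, a4, a5, a6 = a
    return (
        a1 * E_theta**2
        + a2 * E_z**2
        + a3 * E_r**2
        + 2.0 * a4 * E_theta * E_z
        + 2.0 * a5 * E_z * E_r
        + 2.0 * a6 * E_r * E_theta
    )


def passive_energy(state: KinematicState, pc: PassiveConstants):
    """Fung passive energy density W = (C1/2)(e^Q - 1), in kPa."""
    Q = _fung_exponent(state.E_theta, state.E_z, state.E_r, pc.a)
    if np.any(Q > _Q_OVERFLOW):
        raise DivergedEnergyError(f"Fung exponent Q={np.max(Q):.3g} exceeds overflow guard")
    return 0.5 * pc.C1 * (np.exp(Q) - 1.0)


def _active_Q(state: KinematicState, ac: ActiveConstants):
    Qp = state.lam_theta / ac.b1 + state.lam_z / ac.b2 - ac.b_prime
    if not ac.is_planar:
        Qp = Qp + state.lam_r / ac.b3
    return Qp


def active_energy(state: KinematicState, ac: ActiveConstants):
    """Active energy density W = C2*(erf(Q') - 1), in kPa; always in (-2*C2, 0].

    Evaluated as -C2*erfc(Q') to stay accurate in the saturated tail,
    where erf(Q') - 1 underflows by cancellation.
    """
    return -ac.C2 * erfc(_active_Q(state, ac))


# -- first Piola-Kirchhoff stresses -------------------------------------------


def _passive_dW_dE(state: KinematicState, pc: PassiveConstants):
    """Partials of W_passive w.r.t. the three Green strains (independent args)."""
    Et, Ez, Er = state.E_theta, state.E_z, state.E_r
    Q = _fung_exponent(Et, Ez, Er, pc.a)
    if np.any(Q > _Q_OVERFLOW):
        raise DivergedEnergyError(f"Fung exponent Q={np.max(Q):.3g} exceeds overflow guard")
    CeQ = pc.C1 * np.exp(Q)
    dWt = CeQ * (pc.a1 * Et + pc.a4 * Ez + pc.a6 * Er)
    dWz = CeQ * (pc.a2 * Ez + pc.a4 * Et + pc.a5 * Er)
    dWr = CeQ * (pc.a3 * Er + pc.a5 * Ez + pc.a6 * Et)
    return dWt, dWz, dWr


def first_pk_passive(state: KinematicState, pc: PassiveConstants) -> StressTriple:
    """Passive 1st PK stresses T_i = lam_i * dW/dE_i."""
    dWt, dWz, dWr = _passive_dW_dE(state, pc)
    return StressTriple(state.lam_theta * dWt, state.lam_z * dWz, state.lam_r * dWr)


def first_pk_active(state: KinematicState, ac: ActiveConstants) -> StressTriple:
    """Active 1st PK stresses T_i = dW_active/dlam_i.

    Each component is (2*C2/(b_i*sqrt(pi))) * exp(-Q'^2) > 0; the maximum
    attainable value of component i is 2*C2/(b_i*sqrt(pi)), reached iff
    Q' = 0.  The radial component is zero for the planar variant.
    """
    g = 2.0 * ac.C2 / np.sqrt(np.pi) * np.exp(-_active_Q(state, ac) ** 2)
    T_r = np.zeros_like(g) if ac.is_planar else g / ac.b3
    return StressTriple(g / ac.b1, g / ac.b2, T_r)


def cauchy_normal(state: KinematicState, T: StressTriple) -> StressTriple:
    """Cauchy stresses sigma_i = lam_i * T_i (incompressible, J = 1)."""
    return StressTriple(
        state.lam_theta * T.T_theta, state.lam_z * T.T_z, state.lam_r * T.T_r
    )


# -- convexity ----------------------------------------------------------------


@dataclass(frozen=True)
class ConvexityReport:
    """Outcome of :func:`convexity_check` with the underlying diagnostics."""

    mode: str
    passed: bool
    minors: tuple  # leading principal minors of the quadratic-form matrix
    printed_criterion: float  # a4^2 + a5^2 + a6^2 - a1*a2 - a2*a3 - a1*a3


def convexity_check(pc: PassiveConstants, mode: str = "strict") -> ConvexityReport:
    """Check the convexity of the Fung quadratic form Q.

    ``mode='strict'`` requires all three leading principal minors of the
    symmetric matrix [[a1,a4,a6],[a4,a2,a5],[a6,a5,a3]] to be positive
    (true positive-definiteness of Q, hence a convex energy).

    ``mode='printed'`` evaluates the inequality as printed in the source
    literature for this constitutive family,
    ``a4^2 + a5^2 + a6^2 - a1*a2 - a2*a3 - a1*a3 > 0``, which is the
    reverse of a positive-definiteness surrogate.  Published constant sets
    satisfy one, the other, or neither; both modes are therefore reported
    and neither is silently enforced on packaged fixtures.
    """
    if mode not in ("strict", "printed"):
        raise ValueError(f"mode must be 'strict' or 'printed', got {mode!r}")
    a1, a2, a3, a4, a5, a6 = pc.a
    M = np.array([[a1, a4, a6], [a4, a2, a5], [a6, a5, a3]])
    minors = (
        float(M[0, 0]),
        float(np.linalg.det(M[:2, :2])),
        float(np.linalg.det(M)),
    )
    printed = float(a4**2 + a5**2 + a6**2 - a1 * a2 - a2 * a3 - a1 * a3)
    passed = all(m > 0 for m in minors) if mode == "strict" else printed > 0
    return ConvexityReport(mode=mode, passed=passed, minors=minors, printed_criterion=printed)
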