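"""Finite-deformation kinematics of the inflated, axially stretched vessel.

The deformation of a cylindrical segment under inflation-extension is
described by the three principal stretch ratios (circumferential
``lam_theta``, axial ``lam_z``, radial ``lam_r``) and the corresponding
Green strains ``E_i = (lam_i**2 - 1) / 2``.  The wall is treated as
incompressible, so ``lam_r = 1 / (lam_theta * lam_z)``.

Reference configurations
------------------------
* zero-stress state: the radially cut, opened ring; reference for the
  circumferential length ``l0`` (measured at mid-wall).
* no-load state: the intact ring at zero pressure; reference for the wall
  cross-sectional area ``A0``.  The axial length at no-load is taken equal
  to that at zero stress, so ``lam_z`` is referenced to either.

All functions broadcast over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KinematicState",
    "LoadedGeometry",
    "green_strain",
    "stretch_from_strain",
    "radial_stretch",
    "loaded_inner_radius",
    "midwall_circ_stretch",
]


class InfeasibleGeometryError(ValueError):
    """Measured geometry is inconsistent (e.g. wall volume exceeds the tube)."""


def green_strain(lam):
    """Green strain ``E = (lam**2 - 1) / 2`` of a principal stretch ratio.

    Parameters
    ----------
    lam : float or array
        Stretch ratio; must be positive.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch ratio must be positive")
    return 0.5 * (lam * lam - 1.0)


def stretch_from_strain(E):
    """Inverse of :func:`green_strain`: ``lam = sqrt(2E + 1)`` for ``E > -1/2``."""
    E = np.asarray(E, dtype=float)
    if np.any(2.0 * E + 1.0 <= 0):
        raise ValueError("Green strain must exceed -1/2")
    return np.sqrt(2.0 * E + 1.0)


def radial_stretch(lam_theta, lam_z):
    """Radial stretch from incompressibility, ``lam_r = 1/(lam_theta*lam_z)``."""
    lam_theta = np.asarray(lam_theta, dtype=float)
    lam_z = np.asarray(lam_z, dtype=float)
    if np.any(lam_theta <= 0) or np.any(lam_z <= 0):
        raise ValueError("stretch ratios must be positive")
    return 1.0 / (lam_theta * lam_z)


def loaded_inner_radius(r_o, A0, lam_z):
    """Loaded inner radius from wall-volume conservation.

    ``r_i = sqrt(r_o**2 - A0 / (pi * lam_z))`` so that the deformed wall
    cross-section times the axial stretch equals the no-load wall area A0.

    Raises
    ------
    InfeasibleGeometryError
        If the radicand is non-positive, i.e. the stated no-load wall area
        cannot fit inside the measured outer radius.
    """
    r_o = np.asarray(r_o, dtype=float)
    arg = r_o * r_o - A0 / (np.pi * lam_z)
    if np.any(arg <= 0):
        raise InfeasibleGeometryError(
            f"r_o^2 - A0/(pi*lam_z) = {arg} <= 0: no-load wall area "
            f"A0={A0} mm^2 is inconsistent with outer radius r_o={r_o} mm "
            f"at lam_z={lam_z}"
        )
    return np.sqrt(arg)


def midwall_circ_stretch(r_i, r_o, l0):
    """Mid-wall circumferential stretch ``lam_theta = pi*(r_i + r_o)/l0``.

    The loaded circumference is evaluated at the mid-wall radius
    ``(r_i + r_o)/2`` and referenced to the zero-stress circumferential
    length ``l0``.
    """
    return np.pi * (np.asarray(r_i, dtype=float) + r_o) / l0


@dataclass(frozen=True)
class KinematicState:
    """Triplet of principal stretches with their Green strains.

    Use :meth:`from_biaxial` to construct an incompressible state from the
    two measured stretches.  The direct constructor accepts three
    independent stretches (used by finite-difference checks where the
    strains are varied one at a time).
    """

    lam_theta: float
    lam_z: float
    lam_r: float
    E_theta: float = field(init=False)
    E_z: float = field(init=False)
    E_r: float = field(init=False)

    def __post_init__(self):
        for name in ("lam_theta", "lam_z", "lam_r"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        object.__setattr__(self, "E_theta", green_strain(self.lam_theta))
        object.__setattr__(self, "E_z", green_strain(self.lam_z))
        object.__setattr__(self, "E_r", green_strain(self.lam_r))

    @classmethod
    def from_biaxial(cls, lam_theta, lam_z) -> "KinematicState":
        """Incompressible state from circumferential and axial stretches."""
        return cls(lam_theta, lam_z, radial_stretch(lam_theta, lam_z))

    @property
    def volume_ratio(self):
        """``lam_theta * lam_z * lam_r`` (1 for an incompressible state)."""
        return self.lam_theta * self.lam_z * self.lam_r


@dataclass(frozen=True)
class LoadedGeometry:
    """Loaded cross-section of the vessel together with its references.

    Attributes
    ----------
    r_o, r_i : float
        Loaded outer and inner radii (mm).
    A0 : float
        No-load wall cross-sectional area (mm^2).
    l0 : float
        Zero-stress mid-wall circumferential length (mm).
    """

    r_o: float
    r_i: float
    A0: float
    l0: float

    def __post_init__(self):
        if not (self.r_o > self.r_i > 0):
            raise ValueError(f"need r_o > r_i > 0, got r_o={self.r_o}, r_i={self.r_i}")
        if self.A0 <= 0 or self.l0 <= 0:
            raise ValueError("A0 and l0 must be positive")

    @property
    def h(self) -> float:
        """Loaded wall thickness ``r_o - r_i`` (mm)."""
        return self.r_o - self.r_i

    @classmethod
    def from_outer(cls, r_o, A0, l0, lam_z) -> "LoadedGeometry":
        """Build from the measured outer radius via wall-volume conservation."""
        r_i = loaded_inner_radius(r_o, A0, lam_z)
        return cls(r_o=float(r_o), r_i=float(r_i), A0=A0, l0=l0)
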