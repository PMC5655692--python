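"""Sensitivity of the active stress components to the width constants b1-b3.

Each active 1st PK component is T_i = (2 C2 / (b_i sqrt(pi))) exp(-Q'^2),
so over a circumferential-stretch sweep at fixed axial stretch:

* rescaling b3 changes the peak magnitude of the radial component
  (proportional to 1/b3) and shifts the stretch at which every component
  peaks (through Q'), while the peak magnitude of the circumferential and
  axial components is unchanged;
* rescaling b1 or b2 moves the location of the peaks without changing the
  radial peak magnitude.

These closed-form properties hold whenever Q' crosses zero inside the
sweep, i.e. whenever the activation window is inside the sampled stretch
range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .constitutive import ActiveConstants, first_pk_active
from .kinematics import KinematicState

__all__ = [
    "SensitivitySpec",
    "SensitivityCurve",
    "sensitivity_curves",
    "active_component_sweep",
    "stress_ordering_holds",
]

_COMPONENTS = ("T_theta", "T_z", "T_r")
_PARAMS = ("b1", "b2", "b3")


@dataclass(frozen=True)
class SensitivitySpec:
    """One sensitivity sweep: vary one width constant by multipliers and
    trace an active stress component against circumferential stretch."""

    base: ActiveConstants
    parameter: str                      # 'b1' | 'b2' | 'b3'
    component: str = "T_theta"          # which active stress to trace
    multipliers: Tuple[float, ...] = (0.5, 1.0, 2.0)
    lam_theta_range: Tuple[float, float] = (1.05, 1.95)
    lam_theta_step: float = 0.005
    lam_z: float = 1.3

    def __post_init__(self):
        if self.parameter not in _PARAMS:
            raise ValueError(f"parameter must be one of {_PARAMS}")
        if self.component not in _COMPONENTS:
            raise ValueError(f"component must be one of {_COMPONENTS}")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be positive")
        lo, hi = self.lam_theta_range
        if not (1.0 < lo < hi < 2.0):
            raise ValueError("sweep must lie within (1, 2)")


@dataclass(frozen=True)
class SensitivityCurve:
    multiplier: float
    lam_theta: np.ndarray
    value: np.ndarray       # active stress component along the sweep (kPa)
    peak_value: float
    peak_lam_theta: float


def active_component_sweep(ac: ActiveConstants, lam_theta: np.ndarray, lam_z: float):
    """All three active 1st PK components over a stretch sweep, as a dict."""
    state = KinematicState.from_biaxial(np.asarray(lam_theta, dtype=float), lam_z)
    T = first_pk_active(state, ac)
    return {"T_theta": np.asarray(T.T_theta), "T_z": np.asarray(T.T_z), "T_r": np.asarray(T.T_r)}


def sensitivity_curves(spec: SensitivitySpec) -> List[SensitivityCurve]:
    """Family of component-vs-stretch curves, one per multiplier, with the
    peak value and its stretch location."""
    lo, hi = spec.lam_theta_range
    lam_theta = np.arange(lo, hi + 0.5 * spec.lam_theta_step, spec.lam_theta_step)
    curves = []
    for m in spec.multipliers:
        ac = replace(spec.base, **{spec.parameter: getattr(spec.base, spec.parameter) * m})
        vals = active_component_sweep(ac, lam_theta, spec.lam_z)[spec.component]
        i = int(np.argmax(vals))
        curves.append(
            SensitivityCurve(
                multiplier=m, lam_theta=lam_theta, value=vals,
                peak_value=float(vals[i]), peak_lam_theta=float(lam_theta[i]),
            )
        )
    return curves


def stress_ordering_holds(
    passive, active=None,
    lam_theta_range: Tuple[float, float] = (1.15, 1.6),
    lam_z: float = 1.3,
    n: int = 90,
) -> bool:
    """Whether T_theta > T_z > |T_r| pointwise over a stretch sweep.

    Evaluates the constitutive (direct-partial) 1st PK stresses — passive
    alone, or total when ``active`` is given — and checks the directional
    ordering of the three normal components reported for these vessels.
    """
    from .constitutive import first_pk_passive

    lam_theta = np.linspace(*lam_theta_range, n)
    state = KinematicState.from_biaxial(lam_theta, lam_z)
    T = first_pk_passive(state, passive)
    Tt, Tz, Tr = np.asarray(T.T_theta), np.asarray(T.T_z), np.asarray(T.T_r)
    if active is not None:
        Ta = first_pk_active(state, active)
        Tt, Tz, Tr = Tt + Ta.T_theta, Tz + Ta.T_z, Tr + Ta.T_r
    return bool(np.all(Tt > Tz) and np.all(Tz > np.abs(Tr)))
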