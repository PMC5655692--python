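"""Reduction of inflation-extension records to mean-wall 1st PK stresses.

One record of the protocol is a (pressure, outer diameter, axial force)
triple measured at a fixed axial stretch and activation state.  With the
reference geometry (no-load wall area A0, zero-stress circumferential
length l0) each record reduces to an experimental stress triple:

    T_theta = P r_i / (lam_theta h)
    T_z     = (1/lam_z) [ F / (pi (r_o^2 - r_i^2)) + P r_i^2 / (h (r_o + r_i)) ]
    T_r     = -r_i P / ((r_o + r_i) lam_r)

where r_i follows from wall-volume conservation, h = r_o - r_i, and
lam_theta is the mid-wall circumferential stretch.  F is the externally
measured transducer force (no buoyancy or cannula corrections).  Pressures
arrive in mmHg and are converted to kPa before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .kinematics import LoadedGeometry, midwall_circ_stretch, radial_stretch
from .units import mmhg_to_kpa

__all__ = [
    "PdfRecord",
    "StressPoint",
    "ReferenceGeometry",
    "reduce_record",
    "reduce_dataset",
    "read_measurements_csv",
    "write_measurements_csv",
    "write_stress_csv",
]

ACTIVATION_STATES = ("passive", "total")

#: column order of the measurement CSV dialect
MEASUREMENT_COLUMNS = ["subject_id", "layer", "state", "lam_z", "P_mmHg", "d_o_mm", "F_mN"]


@dataclass(frozen=True)
class ReferenceGeometry:
    """Reference geometry of one vessel: no-load wall area A0 (mm^2) and
    zero-stress mid-wall circumferential length l0 (mm)."""

    A0: float
    l0: float

    def __post_init__(self):
        if self.A0 <= 0 or self.l0 <= 0:
            raise ValueError("A0 and l0 must be positive")


@dataclass(frozen=True)
class PdfRecord:
    """One pressure-diameter-force observation.

    P : transmural pressure (mmHg); d_o : loaded outer diameter (mm);
    F : axial force (mN); lam_z : axial stretch; state : 'passive' for the
    Ca2+-free vessel or 'total' for maximal K+ constriction.
    """

    P: float
    d_o: float
    F: float
    lam_z: float
    state: str

    def __post_init__(self):
        if self.P < 0:
            raise ValueError(f"pressure must be non-negative, got {self.P}")
        if self.d_o <= 0:
            raise ValueError(f"outer diameter must be positive, got {self.d_o}")
        if self.lam_z <= 0:
            raise ValueError(f"axial stretch must be positive, got {self.lam_z}")
        if self.state not in ACTIVATION_STATES:
            raise ValueError(f"state must be one of {ACTIVATION_STATES}, got {self.state!r}")


@dataclass(frozen=True)
class StressPoint:
    """Reduced experimental stresses at one loading state.

    Carries the kinematics (lam_theta, lam_z) and the loaded radii needed
    by the theory side of the fit, the 1st PK stress triple in kPa, and the
    activation state.
    """

    lam_theta: float
    lam_z: float
    r_i: float
    r_o: float
    T_theta: float
    T_z: float
    T_r: float
    state: str
    P: float = np.nan  # original pressure in mmHg, for reporting

    def __post_init__(self):
        if self.lam_theta <= 0:
            raise ValueError("lam_theta must be positive")


def reduce_record(rec: PdfRecord, geom: ReferenceGeometry) -> StressPoint:
    """Reduce one record to an experimental mean-wall stress triple."""
    r_o = rec.d_o / 2.0
    loaded = LoadedGeometry.from_outer(r_o, geom.A0, geom.l0, rec.lam_z)
    r_i, h = loaded.r_i, loaded.h
    lam_theta = float(midwall_circ_stretch(r_i, r_o, geom.l0))
    lam_r = float(radial_stretch(lam_theta, rec.lam_z))
    P = float(mmhg_to_kpa(rec.P))

    T_theta = P * r_i / (lam_theta * h)
    T_z = (1.0 / rec.lam_z) * (
        rec.F / (np.pi * (r_o**2 - r_i**2)) + P * r_i**2 / (h * (r_o + r_i))
    )
    T_r = -r_i * P / ((r_o + r_i) * lam_r)
    return StressPoint(
        lam_theta=lam_theta,
        lam_z=rec.lam_z,
        r_i=r_i,
        r_o=r_o,
        T_theta=float(T_theta),
        T_z=float(T_z),
        T_r=float(T_r),
        state=rec.state,
        P=rec.P,
    )


def reduce_dataset(records: Sequence[PdfRecord], geom: ReferenceGeometry) -> List[StressPoint]:
    """Reduce a full dataset, preserving input order.

    Passive and total records stay distinguishable via ``StressPoint.state``;
    use :func:`points_by_state` to split.  Raises on an empty input and
    annotates failures with the offending row index.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    points = []
    for i, rec in enumerate(records):
        if not isinstance(rec, PdfRecord):
            raise TypeError(f"row {i}: expected PdfRecord, got {type(rec).__name__}")
        try:
            points.append(reduce_record(rec, geom))
        except (ValueError, ArithmeticError) as exc:
            raise type(exc)(f"row {i}: {exc}") from exc
    return points


def points_by_state(points: Iterable[StressPoint]) -> dict:
    """Split stress points into {'passive': [...], 'total': [...]}."""
    out = {s: [] for s in ACTIVATION_STATES}
    for p in points:
        out[p.state].append(p)
    return out


def point_arrays(points: Sequence[StressPoint]):
    """Stack a point list into (lam_theta, lam_z, r_i, r_o, T) arrays,
    with T of shape (n, 3)."""
    lam_theta = np.array([p.lam_theta for p in points])
    lam_z = np.array([p.lam_z for p in points])
    r_i = np.array([p.r_i for p in points])
    r_o = np.array([p.r_o for p in points])
    T = np.array([[p.T_theta, p.T_z, p.T_r] for p in points])
    return lam_theta, lam_z, r_i, r_o, T


# -- CSV dialect --------------------------------------------------------------


def read_measurements_csv(path) -> pd.DataFrame:
    """Read a measurement CSV (comma-separated, header row, UTF-8).

    Required columns: subject_id, layer, state, lam_z, P_mmHg, d_o_mm, F_mN.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["state"].isin(ACTIVATION_STATES)
    if bad.any():
        raise ValueError(f"{path}: invalid activation state at rows {list(df.index[bad])}")
    return df


def records_from_frame(df: pd.DataFrame) -> List[PdfRecord]:
    return [
        PdfRecord(
            P=float(r.P_mmHg), d_o=float(r.d_o_mm), F=float(r.F_mN),
            lam_z=float(r.lam_z), state=str(r.state),
        )
        for r in df.itertuples(index=False)
    ]


def write_measurements_csv(path, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=[c for c in MEASUREMENT_COLUMNS if c in df.columns]
              if all(c in df.columns for c in MEASUREMENT_COLUMNS) else None)


def write_stress_csv(path, points: Sequence[StressPoint], meta: dict | None = None) -> None:
    """Write reduced stresses as CSV with the standard columns."""
    rows = [
        dict(
            state=p.state, lam_z=p.lam_z, P_mmHg=p.P, lam_theta=p.lam_theta,
            r_i_mm=p.r_i, r_o_mm=p.r_o,
            T_theta_kPa=p.T_theta, T_z_kPa=p.T_z, T_r_kPa=p.T_r,
        )
        for p in points
    ]
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
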