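"""Protocol-faithful synthetic inflation-extension data and packaged fixtures.

The generator emulates the measurement protocol behind the constitutive
fits: transmural pressures from 20 to 200 mmHg in steps of 20, axial
stretches 1.3 and 1.5, a passive (Ca2+-free) and a maximally constricted
(60 mM K+) state, with the change of outer diameter and axial force
recorded at each point.  Given ground-truth material constants and a
reference geometry, each record is produced by solving the mean-wall
equilibrium for the loaded outer radius (the circumferential theoretical
stress must carry the pressure) and inverting the axial-stress formula for
the transducer force, so that reducing the record returns the theoretical
stress triple exactly.  Measurement noise is applied multiplicatively to
diameter and force — the quantities an experimenter actually measures —
never to derived stresses.

The module also packages the published material-constant tables (subject
rows, Mean and SD rows at printed precision) and reproduces their summary
statistics from the subject rows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constitutive import ActiveConstants, PassiveConstants
from .experimental import PdfRecord, ReferenceGeometry
from .meanwall import theoretical_pk_stresses

__all__ = [
    "ProtocolSpec",
    "GroundTruth",
    "forward_record",
    "generate_dataset",
    "generate_frame",
    "theoretical_stress_points",
    "published_constants",
    "column_stats",
    "printed_summary",
    "subject_table",
    "default_ground_truth",
]


class InfeasibleProtocolError(RuntimeError):
    """No equilibrium stretch exists in the admissible bracket for a record."""


@dataclass(frozen=True)
class ProtocolSpec:
    """The inflation-extension protocol to emulate.

    Defaults are the measurement protocol of the source experiments:
    pressures 20..200 mmHg by 20, axial stretches {1.3, 1.5}, both
    activation states, noiseless.  ``noise_cv`` is the relative standard
    deviation of the multiplicative Gaussian noise applied independently
    to diameter and force.
    """

    pressures: Tuple[float, ...] = tuple(range(20, 201, 20))
    axial_stretches: Tuple[float, ...] = (1.3, 1.5)
    states: Tuple[str, ...] = ("passive", "total")
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.pressures, dtype=float)
        if len(p) == 0 or np.any(p <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be positive and strictly ascending")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth constants plus reference geometry for data generation."""

    passive: PassiveConstants
    active: Optional[ActiveConstants]
    geometry: ReferenceGeometry


#: Admissible mid-wall circumferential stretch bracket for the equilibrium
#: root.  Where several equilibria exist (the soft toe of the exponential
#: admits a spurious low-stretch crossing), the largest root — the stable
#: distension branch — is selected.
DEFAULT_BRACKET = (1.01, 2.5)


def _equilibrium_lam_theta(truth: GroundTruth, P_mmHg, lam_z, state, bracket):
    from .units import mmhg_to_kpa

    P = float(mmhg_to_kpa(P_mmHg))
    A0, l0 = truth.geometry.A0, truth.geometry.l0
    active = truth.active if state == "total" else None
    if state == "total" and truth.active is None:
        raise ValueError("ground truth has no active constants but state='total'")

    def geometry_at(lam_theta):
        s = lam_theta * l0 / np.pi  # r_i + r_o
        h = A0 / (np.pi * lam_z * s)
        return 0.5 * (s - h), 0.5 * (s + h), h

    def resid(lam_theta):
        r_i, r_o, h = geometry_at(lam_theta)
        if r_i <= 0:
            return -np.inf
        T_theta = theoretical_pk_stresses(lam_theta, lam_z, r_i, r_o, truth.passive, active)[0]
        return T_theta - P * r_i / (lam_theta * h)

    grid = np.linspace(bracket[0], bracket[1], 160)
    with np.errstate(over="ignore"):
        vals = np.array([resid(g) for g in grid])
    sign_change = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if len(sign_change) == 0:
        raise InfeasibleProtocolError(
            f"no equilibrium stretch in ({bracket[0]}, {bracket[1]}) for "
            f"P={P_mmHg} mmHg, lam_z={lam_z}, state={state}"
        )
    i = sign_change[-1]
    lam_theta = brentq(resid, grid[i], grid[i + 1], xtol=1e-13, rtol=1e-15)
    return lam_theta, geometry_at(lam_theta)


def forward_record(
    truth: GroundTruth, P_mmHg: float, lam_z: float, state: str,
    bracket: Tuple[float, float] = DEFAULT_BRACKET,
) -> PdfRecord:
    """Generate one noiseless record consistent with the reduction formulas.

    Solves the mean-wall equilibrium for the loaded outer radius (the
    theoretical circumferential stress equals ``P r_i/(lam_theta h)``) and
    inverts the axial formula for the transducer force, so that
    ``reduce_record(forward_record(...))`` returns the theoretical stress
    triple to machine precision.
    """
    from .units import mmhg_to_kpa

    lam_theta, (r_i, r_o, h) = _equilibrium_lam_theta(truth, P_mmHg, lam_z, state, bracket)
    P = float(mmhg_to_kpa(P_mmHg))
    active = truth.active if state == "total" else None
    _, T_z, _ = theoretical_pk_stresses(lam_theta, lam_z, r_i, r_o, truth.passive, active)
    F = np.pi * (r_o**2 - r_i**2) * (lam_z * T_z - P * r_i**2 / (h * (r_o + r_i)))
    return PdfRecord(P=float(P_mmHg), d_o=2.0 * r_o, F=float(F), lam_z=float(lam_z), state=state)


def generate_dataset(truth: GroundTruth, protocol: ProtocolSpec) -> List[PdfRecord]:
    """One record per (pressure, axial stretch, state) of the protocol.

    Multiplicative Gaussian noise with CV ``protocol.noise_cv`` is applied
    independently to the diameter and force of each record; the draw is
    reproducible from ``protocol.seed``.
    """
    rng = np.random.default_rng(protocol.seed)
    records = []
    for state in protocol.states:
        for lam_z in protocol.axial_stretches:
            for P in protocol.pressures:
                rec = forward_record(truth, P, lam_z, state)
                if protocol.noise_cv > 0:
                    f_d, f_F = 1.0 + protocol.noise_cv * rng.standard_normal(2)
                    rec = replace(rec, d_o=rec.d_o * f_d, F=rec.F * f_F)
                records.append(rec)
    return records


def generate_frame(
    truth: GroundTruth, protocol: ProtocolSpec, subject_id="synthetic", layer="IM"
) -> pd.DataFrame:
    """Dataset as a measurement-CSV DataFrame (see :mod:`coromech.experimental`)."""
    recs = generate_dataset(truth, protocol)
    return pd.DataFrame(
        dict(
            subject_id=subject_id, layer=layer,
            state=[r.state for r in recs], lam_z=[r.lam_z for r in recs],
            P_mmHg=[r.P for r in recs], d_o_mm=[r.d_o for r in recs],
            F_mN=[r.F for r in recs],
        )
    )


def theoretical_stress_points(
    truth: GroundTruth, protocol: ProtocolSpec
) -> list:
    """Noiseless reduced stress points for the protocol (generate + reduce)."""
    from .experimental import reduce_dataset

    return reduce_dataset(generate_dataset(truth, replace(protocol, noise_cv=0.0)),
                          truth.geometry)


# -- packaged fixtures --------------------------------------------------------


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("coromech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str)


def subject_table(table: str, kind: str) -> pd.DataFrame:
    """Numeric subject rows of a packaged table.

    Parameters
    ----------
    table : {'wall', 'IM'}
        Entire-vessel-wall or intima-media-layer table.
    kind : {'passive', 'active'}
    """
    name = {"passive": "passive_constants.csv", "active": "active_constants.csv"}[kind]
    df = _load_fixture(name)
    sub = df[(df["table"] == table) & (~df["subject"].isin(["Mean", "SD"]))].copy()
    if sub.empty:
        valid = sorted(df["table"].unique())
        raise KeyError(f"unknown table {table!r}; valid: {valid}")
    for c in sub.columns[2:]:
        sub[c] = sub[c].astype(float)
    return sub.reset_index(drop=True)


class SubjectConstants(NamedTuple):
    passive: PassiveConstants
    active: ActiveConstants


def published_constants(table: str, subject: Optional[str] = None):
    """Packaged published constants, verbatim.

    ``table='wall'`` or ``'IM'`` with a subject (e.g. ``'Heart 1'``)
    returns a :class:`SubjectConstants` pair.  ``table='two_layer'``
    returns the active constants fitted jointly to all six IM layers
    (C2=28.92, b1=0.43, b2=1.62, b3=4.38, b'=4.87) used in the two-layer
    wall model.  ``table='fig4'`` returns the active constants of the
    whole-wall joint fit (b1=0.35, b2=0.47, b3=1.89) used for sensitivity
    sweeps, and ``'fig4_2d'`` the planar-model widths (b1=0.12, b2=0.18);
    for these two the published source prints no C2 or offset, so the
    packaged C2 defaults to the whole-wall mean (12.8 kPa) and the offset
    centres the activation window on the sweep (documented package
    defaults, not published values).
    """
    act = _load_fixture("active_constants.csv")
    if table in ("two_layer", "fig4", "fig4_2d"):
        row = act[act["table"] == table].iloc[0]
        C2 = float(row["C2"]) if pd.notna(row["C2"]) else 12.8
        b3 = float(row["b3"]) if pd.notna(row["b3"]) else None
        if pd.notna(row["b_prime"]):
            b_prime = float(row["b_prime"])
        else:
            # centre the activation window at lam_theta=1.4, lam_z=1.3
            b_prime = 1.4 / float(row["b1"]) + 1.3 / float(row["b2"])
            if b3 is not None:
                b_prime += (1.0 / (1.4 * 1.3)) / b3
        return ActiveConstants(C2=C2, b1=float(row["b1"]), b2=float(row["b2"]),
                               b3=b3, b_prime=b_prime)
    if subject is None:
        raise KeyError("subject required for tables 'wall' and 'IM'")
    pas = _load_fixture("passive_constants.csv")
    prow = pas[(pas["table"] == table) & (pas["subject"] == subject)]
    arow = act[(act["table"] == table) & (act["subject"] == subject)]
    if prow.empty or arow.empty:
        valid = sorted(set(zip(pas["table"], pas["subject"])) | set(zip(act["table"], act["subject"])))
        raise KeyError(f"unknown (table, subject) = ({table!r}, {subject!r}); valid: {valid}")
    p, a = prow.iloc[0], arow.iloc[0]
    return SubjectConstants(
        passive=PassiveConstants(*(float(p[c]) for c in ["C1", "a1", "a2", "a3", "a4", "a5", "a6"])),
        active=ActiveConstants(C2=float(a["C2"]), b1=float(a["b1"]), b2=float(a["b2"]),
                               b3=float(a["b3"]), b_prime=float(a["b_prime"])),
    )


def _decimals(printed: str) -> int:
    return len(printed.split(".")[1]) if "." in printed else 0


def printed_summary(table: str, column: str, statistic: str) -> Tuple[float, int]:
    """Printed Mean/SD cell of a packaged table and its decimal precision."""
    if statistic not in ("mean", "sd"):
        raise ValueError("statistic must be 'mean' or 'sd'")
    key = {"mean": "Mean", "sd": "SD"}[statistic]
    for name in ("passive_constants.csv", "active_constants.csv"):
        df = _load_fixture(name)
        if column in df.columns:
            row = df[(df["table"] == table) & (df["subject"] == key)]
            if not row.empty and pd.notna(row.iloc[0][column]):
                s = str(row.iloc[0][column])
                return float(s), _decimals(s)
    raise KeyError(f"no printed {key} cell for ({table!r}, {column!r})")


def column_stats(table: str, column: str, statistic: str) -> float:
    """Mean or sample SD (n-1) of a table column over subjects, rounded to
    the printed precision of the corresponding summary cell."""
    for kind in ("passive", "active"):
        try:
            sub = subject_table(table, kind)
        except KeyError:
            continue
        if column in sub.columns:
            x = sub[column].to_numpy(dtype=float)
            val = float(np.mean(x)) if statistic == "mean" else float(np.std(x, ddof=1))
            _, dec = printed_summary(table, column, statistic)
            return float(np.round(val, dec))
    raise KeyError(f"unknown column {column!r} for table {table!r}")


#: Default reference geometry per preparation: the real vessels' A0 and l0
#: are not published, so these are plausible porcine-RCA values chosen once:
#: the dissected IM layer is thin-walled (loaded r_i ~ 2 mm, h ~ 0.09 mm);
#: the entire wall is thicker (h/r_i ~ 0.1), which also reproduces the
#: reported ~5:1 circumferential-to-radial 1st PK stress ratio.
DEFAULT_GEOMETRY = {
    "IM": ReferenceGeometry(A0=1.4, l0=8.4),
    "wall": ReferenceGeometry(A0=2.9, l0=7.2),
}


def default_ground_truth(table: str = "IM", subject: str = "Heart 1") -> GroundTruth:
    """Ground truth for synthetic subjects: published constants plus the
    package's default reference geometry for that preparation."""
    consts = published_constants(table, subject)
    return GroundTruth(passive=consts.passive, active=consts.active,
                       geometry=DEFAULT_GEOMETRY[table])
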