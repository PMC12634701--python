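"""Parametric sagittal spine geometry.

Synthesizes a patient-specific sagittal osteo-ligamentous spine model
(T1..S1 + pelvis) from standard radiographic parameters (PI, PT, TK, LL)
and measures those parameters back from any model or solved state.

Coordinate convention (fixed package-wide): x anterior-positive, z
cranial-positive, rotations theta counter-clockwise-positive in the x-z
plane, so positive theta tilts a vertebral axis posteriorly (extension)
and negative theta anteriorly (flexion).  Thoracic kyphosis TK (T4-T12
Cobb) is positive in kyphosis, lumbar lordosis LL (L1-S1 Cobb) positive
in lordosis.  Lengths in mm, angles in degrees at the API surface.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

# Ordered levels, cranial to caudal.
THORACIC = [f"T{i}" for i in range(1, 13)]
LUMBAR = [f"L{i}" for i in range(1, 6)]
LEVELS = THORACIC + LUMBAR + ["S1"]
JUNCTIONS = [f"{a}-{b}" for a, b in zip(LEVELS[:-1], LEVELS[1:])]

# Junctions spanned by the two Cobb measures (parallel-endplate bodies).
TK_JUNCTIONS = JUNCTIONS[JUNCTIONS.index("T4-T5"): JUNCTIONS.index("T11-T12") + 1]
LL_JUNCTIONS = JUNCTIONS[JUNCTIONS.index("L1-L2"):]

# Normative per-junction apportionment of the aggregate Cobb angles.
# Lumbar lordosis concentrates caudally; thoracic kyphosis is mildly
# apex-weighted (apex ~T7-T8).
LL_FRACTIONS = {"L1-L2": 0.12, "L2-L3": 0.16, "L3-L4": 0.20,
                "L4-L5": 0.26, "L5-S1": 0.26}
TK_FRACTIONS = {"T4-T5": 0.11, "T5-T6": 0.12, "T6-T7": 0.13, "T7-T8": 0.14,
                "T8-T9": 0.14, "T9-T10": 0.13, "T10-T11": 0.12, "T11-T12": 0.11}
# Upper-thoracic junctions above the TK span get a wedge proportional to TK.
UPPER_T_FRACTION = 0.04  # per junction, of TK
# Per-junction wedge beyond which the apportionment is declared unreachable.
MAX_JUNCTION_WEDGE = 25.0  # degrees

SACRO_PELVIC_LENGTH = 90.0  # mm, S1 endplate centre to femoral-head axis


class GeometryError(ValueError):
    """Raised when a requested geometry is invalid or unreachable."""


def _rot(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class SagittalProfile:
    """Radiographic sagittal parameters of one patient.

    PI = PT + SS must hold (SS may be omitted and is then derived).
    """

    PI: float
    PT: float
    TK: float
    LL: float
    SS: float | None = None
    lumbar_cobb_coronal: float = 0.0
    body_mass: float = 60.0  # kg

    def __post_init__(self):
        ss = self.PI - self.PT if self.SS is None else self.SS
        object.__setattr__(self, "SS", float(ss))
        if abs(self.PI - (self.PT + self.SS)) > 0.1:
            raise GeometryError(
                f"PI ({self.PI}) != PT + SS ({self.PT} + {self.SS}) beyond 0.1 deg")
        if not (20.0 <= self.PI <= 100.0):
            raise GeometryError(f"PI {self.PI} outside plausible range [20, 100] deg")
        if self.body_mass <= 0:
            raise GeometryError("body_mass must be positive")


@dataclass
class VertebraPose:
    level: str
    centroid: np.ndarray  # (2,) [x, z] mm
    orientation: float  # deg, endplates perpendicular to the body axis
    body_height: float  # mm

    def endplate(self, which: str) -> tuple[np.ndarray, float]:
        """Centre point and orientation of the superior/inferior endplate."""
        sign = +1.0 if which == "superior" else -1.0
        offset = _rot(self.orientation) @ np.array([0.0, sign * self.body_height / 2])
        return self.centroid + offset, self.orientation


@dataclass
class SpineModel:
    """Rigid vertebrae T1..S1 plus a pelvis pose, with junction metadata."""

    poses: dict[str, VertebraPose]  # keyed by level, ordered cranio-caudally
    pelvis_centroid: np.ndarray  # femoral-head axis position, mm
    pelvis_orientation: float  # deg; equals PT at build time
    disc_heights: dict[str, float]  # per junction, mm
    mass_fraction: dict[str, float]  # per level, of body mass
    junction_angles: dict[str, float]  # rest wedge, extension-positive, deg
    profile: SagittalProfile

    def validate(self) -> None:
        if list(self.poses) != LEVELS:
            raise GeometryError("model must contain T1..T12, L1..L5, S1 in order")
        z = [p.centroid[1] for p in self.poses.values()]
        if not all(a > b for a, b in zip(z[:-1], z[1:])):
            raise GeometryError("levels not strictly ordered cranio-caudally in z")
        if any(h <= 0 for h in self.disc_heights.values()):
            raise GeometryError("disc heights must be positive")
        if any(p.body_height <= 0 for p in self.poses.values()):
            raise GeometryError("body heights must be positive")
        if sum(self.mass_fraction.values()) > 1.0 + 1e-9:
            raise GeometryError("mass fractions exceed total body mass")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lv, "x_mm": p.centroid[0], "z_mm": p.centroid[1],
             "theta_deg": p.orientation, "body_height_mm": p.body_height}
            for lv, p in self.poses.items()
        ]
        rows.append({"level": "pelvis", "x_mm": self.pelvis_centroid[0],
                     "z_mm": self.pelvis_centroid[1],
                     "theta_deg": self.pelvis_orientation, "body_height_mm": np.nan})
        return pd.DataFrame(rows)


def load_anthropometry(path: str | None = None, scale: float = 1.0) -> pd.DataFrame:
    """Default (or user-supplied) per-level body/disc height and mass table."""
    if path is None:
        text = resources.files("spinerod.data").joinpath("anthropometry.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    df = pd.read_csv(_io.StringIO(text), comment="#").set_index("level")
    missing = [lv for lv in LEVELS if lv not in df.index]
    if missing:
        raise GeometryError(f"anthropometry table missing levels: {missing}")
    df = df.loc[LEVELS].copy()
    df[["body_height_mm", "disc_height_mm"]] *= scale
    return df


def apportion_junction_angles(profile: SagittalProfile) -> dict[str, float]:
    """Distribute TK and LL over junction wedges (extension-positive).

    Kyphosis flexes the upper body forward relative to the lower one, so a
    positive TK maps to negative wedges over T4-T12; positive LL maps to
    positive wedges over L1-S1.
    """
    ang = {j: 0.0 for j in JUNCTIONS}
    for j, f in TK_FRACTIONS.items():
        ang[j] = -profile.TK * f
    for j in ("T1-T2", "T2-T3", "T3-T4"):
        ang[j] = -profile.TK * UPPER_T_FRACTION
    for j, f in LL_FRACTIONS.items():
        ang[j] = profile.LL * f
    ang["T12-L1"] = 0.0
    bad = [j for j, a in ang.items() if abs(a) > MAX_JUNCTION_WEDGE]
    if bad:
        raise GeometryError(
            f"requested angles unreachable: per-junction wedge exceeds "
            f"{MAX_JUNCTION_WEDGE} deg at {bad[0]}..{bad[-1]}")
    return ang


def build_spine(profile: SagittalProfile,
                anthropometry: pd.DataFrame | None = None) -> SpineModel:
    """Synthesize a sagittal spine model realizing the requested profile.

    The pelvis is placed from PT, the S1 endplate from SS = PI - PT, and
    the aggregate Cobb angles are apportioned over junction wedges using
    normative per-level fractions, so measuring the returned model recovers
    the request exactly (up to floating point).
    """
    anthro = load_anthropometry() if anthropometry is None else anthropometry
    ang = apportion_junction_angles(profile)

    theta = {"S1": -profile.SS}
    for j in reversed(JUNCTIONS):  # walk caudal -> cranial
        upper, lower = j.split("-")
        theta[upper] = theta[lower] + ang[j]

    # Pelvis: femoral-head axis at origin; S1 superior endplate centre sits
    # SACRO_PELVIC_LENGTH away along a line tilted PT from vertical.
    fh = np.array([0.0, 0.0])
    e_s1 = fh + SACRO_PELVIC_LENGTH * np.array(
        [-math.sin(math.radians(profile.PT)), math.cos(math.radians(profile.PT))])

    poses: dict[str, VertebraPose] = {}
    h_s1 = float(anthro.loc["S1", "body_height_mm"])
    c = e_s1 - _rot(theta["S1"]) @ np.array([0.0, h_s1 / 2])
    poses["S1"] = VertebraPose("S1", c, theta["S1"], h_s1)

    disc_heights: dict[str, float] = {}
    for j in reversed(JUNCTIONS):
        upper, lower = j.split("-")
        h_u = float(anthro.loc[upper, "body_height_mm"])
        h_l = poses[lower].body_height
        d = float(anthro.loc[upper, "disc_height_mm"])
        disc_heights[j] = d
        mid = 0.5 * (theta[upper] + theta[lower])
        c = (poses[lower].centroid
             + _rot(theta[lower]) @ np.array([0.0, h_l / 2])
             + _rot(mid) @ np.array([0.0, d])
             + _rot(theta[upper]) @ np.array([0.0, h_u / 2]))
        poses[upper] = VertebraPose(upper, c, theta[upper], h_u)

    model = SpineModel(
        poses={lv: poses[lv] for lv in LEVELS},
        pelvis_centroid=fh,
        pelvis_orientation=profile.PT,
        disc_heights=disc_heights,
        mass_fraction={lv: float(anthro.loc[lv, "mass_fraction"]) for lv in LEVELS},
        junction_angles=ang,
        profile=profile,
    )
    model.validate()
    return model


def _s1_endplate(poses: Mapping[str, VertebraPose]) -> np.ndarray:
    p, _ = poses["S1"].endplate("superior")
    return p


def measure_profile(model: SpineModel,
                    poses: Mapping[str, VertebraPose] | None = None) -> SagittalProfile:
    """Measure radiographic parameters from a model (or solved poses).

    TK = Cobb between superior T4 and inferior T12 endplates (kyphosis
    positive); LL = Cobb between superior L1 and superior S1 (lordosis
    positive); PT from the vertical tilt of the femoral-head -> S1-endplate
    line; PI = PT + SS with SS the S1 endplate inclination (so PI is
    invariant under rigid motion of the whole model while PT is not).
    """
    poses = model.poses if poses is None else poses
    tk = poses["T12"].orientation - poses["T4"].orientation
    ll = poses["L1"].orientation - poses["S1"].orientation
    e_s1 = _s1_endplate(poses)
    v = e_s1 - model.pelvis_centroid
    pt = math.degrees(math.atan2(-v[0], v[1]))
    ss = -poses["S1"].orientation
    return SagittalProfile(
        PI=pt + ss, PT=pt, SS=ss, TK=tk, LL=ll,
        lumbar_cobb_coronal=model.profile.lumbar_cobb_coronal,
        body_mass=model.profile.body_mass,
    )


def pi_ll_mismatch(profile: SagittalProfile) -> float:
    """PI - LL sagittal mismatch in degrees."""
    return profile.PI - profile.LL


def target_pt(PI: float, rule: str = "lehuec") -> float:
    """Post-operative pelvic-tilt target for a given pelvic incidence.

    ``lehuec`` evaluates the affine regression PT = 0.44*PI - 11.4;
    ``schwab`` returns the 20 deg upper bound.
    """
    if rule == "lehuec":
        return 0.44 * PI - 11.4
    if rule == "schwab":
        return 20.0
    raise ValueError(f"unknown rule {rule!r}; expected 'lehuec' or 'schwab'")


def restack(model: SpineModel, junction_angles: Mapping[str, float]) -> SpineModel:
    """Rebuild poses from the (immobile) sacrum upward with new wedges.

    Used to realize a planned post-operative alignment: S1 and the pelvis
    stay put, and every junction wedge is replaced by the planned value
    (angles not listed keep the model's current wedge).
    """
    ang = dict(model.junction_angles)
    ang.update(junction_angles)
    theta = {"S1": model.poses["S1"].orientation}
    for j in reversed(JUNCTIONS):
        upper, lower = j.split("-")
        theta[upper] = theta[lower] + ang[j]
    poses = {"S1": model.poses["S1"]}
    for j in reversed(JUNCTIONS):
        upper, lower = j.split("-")
        h_u = model.poses[upper].body_height
        h_l = poses[lower].body_height
        d = model.disc_heights[j]
        mid = 0.5 * (theta[upper] + theta[lower])
        c = (poses[lower].centroid
             + _rot(theta[lower]) @ np.array([0.0, h_l / 2])
             + _rot(mid) @ np.array([0.0, d])
             + _rot(theta[upper]) @ np.array([0.0, h_u / 2]))
        poses[upper] = VertebraPose(upper, c, theta[upper], h_u)
    return replace(model, poses={lv: poses[lv] for lv in LEVELS},
                   junction_angles=ang)


def transform_poses(model: SpineModel, dx: float = 0.0, dz: float = 0.0,
                    dtheta: float = 0.0) -> SpineModel:
    """Rigidly move the whole model (useful for invariance checks)."""
    pivot = model.pelvis_centroid
    R = _rot(dtheta)
    new_poses = {}
    for lv, p in model.poses.items():
        c = pivot + R @ (p.centroid - pivot) + np.array([dx, dz])
        new_poses[lv] = VertebraPose(lv, c, p.orientation + dtheta, p.body_height)
    m = replace(model, poses=new_poses,
                pelvis_centroid=model.pelvis_centroid + np.array([dx, dz]),
                pelvis_orientation=model.pelvis_orientation + dtheta)
    return m
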