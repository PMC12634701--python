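"""Nonlinear functional-spinal-unit (FSU) constitutive laws.

Each junction between adjacent vertebrae is one generalized joint: a
smooth, odd, stiffening moment-rotation curve for sagittal rotation

    M(theta) = kappa * f * (k0 * theta + c * sinh(theta / theta_ref))   [N*m]

plus linear shear and axial springs for the in-plane translations.
``kappa`` is the rib-cage stiffening multiplier (thoracic junctions only)
and ``f`` the accumulated surgical flexion-stiffness factor.  Surgical
state modifiers cover facet release, pedicle-subtraction-osteotomy wedging
and fusion.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .geometry import JUNCTIONS

log = logging.getLogger(__name__)

#: Rotational stiffness used for a fused joint, N*m/deg.  Large enough that
#: physiologic moments (~tens of N*m) produce rotations far below 1e-6 deg.
FUSED_STIFFNESS = 1.0e8

#: Default physiologic rotation range; beyond it the law clamps (and warns).
PHYSIOLOGIC_RANGE = 15.0  # deg

VALID_STATES = ("intact", "facetectomized", "osteotomized", "fused")


class JointStateError(ValueError):
    """Invalid surgical state transition."""


@dataclass(frozen=True)
class JointLaw:
    junction: str
    k0: float          # N*m/deg neutral-zone tangent stiffness
    c: float           # N*m stiffening amplitude
    theta_ref: float   # deg stiffening scale
    kappa: float = 1.0  # rib-cage multiplier, >= 1, thoracic only
    shear_stiffness: float = 200.0   # N/mm
    axial_stiffness: float = 1500.0  # N/mm
    flexion_factor: float = 1.0      # accumulated surgical scaling, (0, 1]
    rest_angle: float = 0.0          # deg, zero-moment rotation offset
    state: str = "intact"
    physiologic_range: float = PHYSIOLOGIC_RANGE
    corridor: tuple[float, float] | None = None  # deg at 7.5 N*m flexion

    def __post_init__(self):
        if self.k0 <= 0 or self.theta_ref <= 0 or self.c < 0:
            raise ValueError(f"{self.junction}: invalid curve parameters")
        if self.kappa < 1.0:
            raise ValueError(f"{self.junction}: kappa must be >= 1")
        if not (0.0 < self.flexion_factor <= 1.0):
            raise ValueError(f"{self.junction}: flexion factor must be in (0, 1]")
        if self.state not in VALID_STATES:
            raise ValueError(f"{self.junction}: unknown state {self.state!r}")


@dataclass(frozen=True)
class JointStateModifier:
    kind: str  # facetectomy | pso_wedge | fusion
    flexion_stiffness_factor: float = 1.0
    wedge_angle: float = 0.0  # deg, PSO only

    def __post_init__(self):
        if self.kind == "facetectomy" and not (0.0 < self.flexion_stiffness_factor <= 1.0):
            raise ValueError("facetectomy factor must be in (0, 1]")
        if self.kind not in ("facetectomy", "pso_wedge", "fusion"):
            raise ValueError(f"unknown modifier kind {self.kind!r}")


def joint_moment(law: JointLaw, theta: float | np.ndarray) -> float | np.ndarray:
    """Sagittal moment (N*m) at rotation ``theta`` (deg) from rest.

    ``theta`` is measured from the joint's rest angle.  Rotations beyond
    the physiologic range are clamped with a logged warning (extrapolation
    signal); fused joints respond linearly-rigidly and are never clamped.
    """
    th = np.asarray(theta, dtype=float) - law.rest_angle
    if law.state == "fused":
        m = FUSED_STIFFNESS * th
        return float(m) if np.isscalar(theta) else m
    lim = law.physiologic_range
    if np.any(np.abs(th) > lim):
        log.warning("%s: rotation beyond physiologic range (+/-%g deg), clamped",
                    law.junction, lim)
        th = np.clip(th, -lim, lim)
    m = law.kappa * law.flexion_factor * (
        law.k0 * th + law.c * np.sinh(th / law.theta_ref))
    return float(m) if np.isscalar(theta) else m


def tangent_stiffness(law: JointLaw, theta: float) -> float:
    """dM/dtheta (N*m/deg), positive everywhere."""
    th = theta - law.rest_angle
    if law.state == "fused":
        return FUSED_STIFFNESS
    lim = law.physiologic_range
    if abs(th) > lim:
        th = math.copysign(lim, th)
    return law.kappa * law.flexion_factor * (
        law.k0 + (law.c / law.theta_ref) * math.cosh(th / law.theta_ref))


def apply_modifier(law: JointLaw, mod: JointStateModifier) -> JointLaw:
    """Return the law after one surgical act (input law unchanged)."""
    if mod.kind == "facetectomy":
        if law.state == "fused":
            raise JointStateError(f"cannot facetectomize fused joint {law.junction}")
        return replace(law,
                       flexion_factor=law.flexion_factor * mod.flexion_stiffness_factor,
                       state="facetectomized")
    if mod.kind == "pso_wedge":
        if law.state == "fused":
            raise JointStateError(f"cannot osteotomize fused joint {law.junction}")
        return replace(law, rest_angle=law.rest_angle + mod.wedge_angle,
                       state="osteotomized")
    # fusion
    return replace(law, state="fused")


def rotation_at_moment(law: JointLaw, moment: float) -> float:
    """Invert the moment-rotation curve (scalar Newton; curve is monotone)."""
    if law.state == "fused":
        return law.rest_angle + moment / FUSED_STIFFNESS
    th = 0.0
    for _ in range(100):
        r = joint_moment(law, th + law.rest_angle) - moment
        if abs(r) < 1e-10:
            break
        th -= r / tangent_stiffness(law, th + law.rest_angle)
        th = float(np.clip(th, -law.physiologic_range, law.physiologic_range))
    return th + law.rest_angle


def strain_energy(law: JointLaw, theta: float, n: int = 200) -> float:
    """Joint strain energy (N*m*deg) from rest to ``theta``, by quadrature."""
    t = np.linspace(law.rest_angle, theta, n)
    return float(np.trapezoid(joint_moment(law, t), t))


def default_joint_table(path: str | None = None) -> dict[str, JointLaw]:
    """The 17 default junction laws loaded from the shipped CSV table."""
    if path is None:
        text = resources.files("spinerod.data").joinpath("joint_table.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    df = pd.read_csv(_io.StringIO(text), comment="#").set_index("junction")
    missing = [j for j in JUNCTIONS if j not in df.index]
    if missing:
        raise ValueError(f"joint table missing junctions: {missing}")
    laws = {}
    for j in JUNCTIONS:
        r = df.loc[j]
        laws[j] = JointLaw(
            junction=j, k0=float(r.k0), c=float(r.c), theta_ref=float(r.theta_ref),
            kappa=float(r.kappa), shear_stiffness=float(r.shear),
            axial_stiffness=float(r.axial),
            corridor=(float(r.corridor_lo_deg), float(r.corridor_hi_deg)),
        )
    return laws
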