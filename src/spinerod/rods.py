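"""Spinal rod implants: diameter profiles, circular-section mechanics.

Covers the five compared rod designs (constant, stepped, and
Bezier-smoothed variable diameter), the titanium-alloy elastoplastic
multilinear material, fiber-discretized moment-curvature of the circular
section (with path-dependent plasticity), and the pedicle-screw coupling
description.  Units: mm, MPa, N, N*mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_N_FIBERS = 32
DEFAULT_TRANSITION_MM = 20.0


def section_area(d: float) -> float:
    """Area of a circular section, A = pi d^2 / 4 (mm^2)."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * d * d / 4.0


def section_inertia(d: float) -> float:
    """Second moment of a circular section, I = pi d^4 / 64 (mm^4)."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    return math.pi * d ** 4 / 64.0


@dataclass(frozen=True)
class RodMaterial:
    """Uniaxial elastoplastic multilinear law (isotropic hardening)."""

    E: float = 113_000.0   # MPa (Ti alloy)
    sigma_y: float = 950.0  # MPa
    sigma_u: float = 1180.0  # MPa
    eps_u: float = 0.10     # total strain at sigma_u

    def __post_init__(self):
        if not (0 < self.sigma_y < self.sigma_u):
            raise ValueError("require 0 < sigma_y < sigma_u")
        if self.eps_u <= self.sigma_u / self.E:
            raise ValueError("eps_u must exceed the elastic strain at sigma_u")

    @property
    def eps_p_u(self) -> float:
        """Plastic strain at the ultimate point."""
        return self.eps_u - self.sigma_u / self.E

    @property
    def hardening_modulus(self) -> float:
        return (self.sigma_u - self.sigma_y) / self.eps_p_u

    def stress_strain_points(self) -> list[tuple[float, float]]:
        """Monotone multilinear total-strain/stress point list."""
        return [(0.0, 0.0), (self.sigma_y / self.E, self.sigma_y),
                (self.eps_u, self.sigma_u)]

    def flow_stress(self, alpha: np.ndarray) -> np.ndarray:
        """Yield surface size at accumulated plastic strain ``alpha``."""
        return np.where(alpha < self.eps_p_u,
                        self.sigma_y + self.hardening_modulus * alpha,
                        self.sigma_u)


class FiberSection:
    """Circular section discretized into horizontal strips ("fibers").

    Strip areas and centroids are exact circle-segment integrals, so the
    fiber-summed elastic A and EI converge fast.  ``multiplicity`` models
    several identical parallel rods sharing one curvature (fiber stresses
    then equal the per-rod stresses).
    """

    def __init__(self, d: float, material: RodMaterial,
                 n_fibers: int = DEFAULT_N_FIBERS, multiplicity: int = 1):
        if d <= 0:
            raise ValueError("diameter must be positive")
        self.d = float(d)
        self.material = material
        self.n_fibers = int(n_fibers)
        r = d / 2.0
        edges = np.linspace(-r, r, n_fibers + 1)

        def G(y):  # integral of strip width 2*sqrt(r^2-y^2)
            y = np.clip(y, -r, r)
            return y * np.sqrt(np.maximum(r * r - y * y, 0.0)) + r * r * np.arcsin(y / r)

        def H(y):  # integral of 2*y*sqrt(r^2-y^2)
            y = np.clip(y, -r, r)
            return -(2.0 / 3.0) * np.maximum(r * r - y * y, 0.0) ** 1.5

        areas = G(edges[1:]) - G(edges[:-1])
        first = H(edges[1:]) - H(edges[:-1])
        self.y = first / areas  # strip centroids
        self.A_fib = areas * multiplicity

    @property
    def area(self) -> float:
        return float(self.A_fib.sum())

    @property
    def inertia(self) -> float:
        return float((self.A_fib * self.y ** 2).sum())

    def new_state(self) -> dict[str, np.ndarray]:
        z = np.zeros(self.n_fibers)
        return {"eps_p": z.copy(), "alpha": z.copy()}

    def response(self, eps0: float, kappa: float, state: dict[str, np.ndarray]
                 ) -> tuple[float, float, dict[str, np.ndarray]]:
        """Axial force N and moment M for a section strain state.

        ``eps0``: membrane strain; ``kappa``: curvature (1/mm).  Returns
        (N, M, trial_state); commit the trial state only after a converged
        load step (path dependence).
        """
        mat = self.material
        eps = eps0 + kappa * self.y
        sig_tr = mat.E * (eps - state["eps_p"])
        flow = mat.flow_stress(state["alpha"])
        f = np.abs(sig_tr) - flow
        yielding = f > 0.0
        # Return map for bilinear hardening followed by a flat branch.
        H1 = mat.hardening_modulus
        dalpha = np.where(yielding, f / (mat.E + H1), 0.0)
        over = yielding & (state["alpha"] + dalpha > mat.eps_p_u)
        if np.any(over):
            # Finish crossing the hardening knee on the flat branch.
            f_rem = f - (mat.eps_p_u - state["alpha"]) * (mat.E + H1)
            dalpha = np.where(over,
                              (mat.eps_p_u - state["alpha"]) + f_rem / mat.E,
                              dalpha)
        alpha = state["alpha"] + dalpha
        eps_p = state["eps_p"] + np.sign(sig_tr) * dalpha
        sigma = mat.E * (eps - eps_p)
        N = float((sigma * self.A_fib).sum())
        M = float((sigma * self.A_fib * self.y).sum())
        trial = {"eps_p": eps_p, "alpha": alpha,
                 "sigma": sigma, "ruptured": bool(np.any(alpha > mat.eps_p_u + 1e-12))}
        return N, M, trial

    def outer_stress(self, state: dict[str, np.ndarray]) -> float:
        """Largest fiber stress magnitude of the last evaluated state."""
        sigma = state.get("sigma")
        if sigma is None:
            return 0.0
        return float(np.max(np.abs(sigma)))


def moment_curvature(d: float, material: RodMaterial, curvature: float,
                     n_fibers: int = DEFAULT_N_FIBERS,
                     state: dict[str, np.ndarray] | None = None,
                     multiplicity: int = 1):
    """Bending moment (N*mm) of a circular section at a given curvature.

    Elastic branch slope is E*I; first yield at M_y = sigma_y*I/(d/2).
    Pass the returned state back in to follow unloading/reloading paths.
    """
    sec = FiberSection(d, material, n_fibers=n_fibers, multiplicity=multiplicity)
    st = sec.new_state() if state is None else state
    _, M, trial = sec.response(0.0, curvature, st)
    return M, trial


@dataclass(frozen=True)
class DiameterProfile:
    """Rod diameter d(s) along arc length.

    ``zones``: ordered (start_s, end_s, diameter) plateaus covering the rod.
    Stepped profiles jump at the zone boundary; Bezier profiles blend the
    plateaus with a C1 cubic (smoothstep) transition of width
    ``transition``.
    """

    kind: str  # constant | stepped | bezier
    zones: tuple[tuple[float, float, float], ...]
    transition: float = DEFAULT_TRANSITION_MM

    def __post_init__(self):
        if self.kind not in ("constant", "stepped", "bezier"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if any(d <= 0 for _, _, d in self.zones):
            raise ValueError("diameters must be positive")
        if self.kind == "constant" and len(self.zones) != 1:
            raise ValueError("constant profile takes exactly one zone")
        if self.kind == "stepped" and len(self.zones) != 2:
            raise ValueError("stepped profile takes exactly two zones")
        for (a, b, _), (c, d_, _) in zip(self.zones[:-1], self.zones[1:]):
            if not (a < b and abs(b - c) < 1e-9):
                raise ValueError("zones must be contiguous and ordered")

    @property
    def span(self) -> tuple[float, float]:
        return self.zones[0][0], self.zones[-1][1]

    def diameter_at(self, s: float | np.ndarray) -> float | np.ndarray:
        scalar = np.isscalar(s) or np.ndim(s) == 0
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        lo, hi = self.span
        if np.any(s_arr < lo - 1e-9) or np.any(s_arr > hi + 1e-9):
            raise ValueError(f"arc position outside rod span [{lo}, {hi}]")
        d = np.empty_like(s_arr)
        for a, b, dz in self.zones:
            mask = (s_arr >= a - 1e-9) & (s_arr <= b + 1e-9)
            d[mask] = dz
        if self.kind == "stepped":
            # left-continuous at the step: s == boundary keeps distal diameter
            a, b, dz = self.zones[0]
            d[np.asarray(s_arr <= b)] = dz
        if self.kind == "bezier":
            w = self.transition
            for (a, b, d0), (_, _, d1) in zip(self.zones[:-1], self.zones[1:]):
                s0, s1 = b - w / 2.0, b + w / 2.0
                mask = (s_arr > s0) & (s_arr < s1)
                if np.any(mask):
                    t = (s_arr[mask] - s0) / w
                    d[mask] = d0 + (d1 - d0) * (3 * t * t - 2 * t ** 3)
        return float(d[0]) if scalar else d


@dataclass(frozen=True)
class ScrewElement:
    """A locked polyaxial pedicle screw: rigid tie after locking."""

    level: str
    head_offset: tuple[float, float] = (-40.0, 0.0)  # mm, posterior of centroid
    connection: str = "locked_rigid"


@dataclass(frozen=True)
class RodScenario:
    """One rod design: named diameter plateaus per zone + material.

    ``zone_diameters`` are listed distal (sacral) to proximal; the zone
    boundaries are named by the disc junction where the section changes.
    """

    name: str
    kind: str  # constant | stepped | bezier
    zone_diameters: tuple[float, ...]
    zone_boundaries: tuple[str, ...] = ()  # junction names, len = n_zones - 1
    material: RodMaterial = field(default_factory=RodMaterial)
    transition: float = DEFAULT_TRANSITION_MM

    def __post_init__(self):
        if len(self.zone_boundaries) != len(self.zone_diameters) - 1:
            raise ValueError("need one boundary junction per zone change")

    def build_profile(self, boundary_s: Sequence[float],
                      span: tuple[float, float]) -> DiameterProfile:
        """Realize the profile over a concrete arc-length span."""
        lo, hi = span
        cuts = [lo, *boundary_s, hi]
        zones = tuple((cuts[i], cuts[i + 1], self.zone_diameters[i])
                      for i in range(len(self.zone_diameters)))
        return DiameterProfile(self.kind, zones, transition=self.transition)


def default_scenarios(material: RodMaterial | None = None) -> list[RodScenario]:
    """The five compared rod designs.

    Diameters run distal (S1) to proximal (T10); section-change boundaries
    sit at the named disc junctions.
    """
    mat = material or RodMaterial()
    return [
        RodScenario("constant-6.0", "constant", (6.0,), (), mat),
        RodScenario("stepped-6.0-5.0", "stepped", (6.0, 5.0), ("T11-T12",), mat),
        RodScenario("bezier-6.0-5.5-5.0", "bezier", (6.0, 5.5, 5.0),
                    ("L1-L2", "T11-T12"), mat),
        RodScenario("constant-5.5", "constant", (5.5,), (), mat),
        RodScenario("bezier-5.5-5.0-4.75", "bezier", (5.5, 5.0, 4.75),
                    ("L1-L2", "T11-T12"), mat),
    ]


def mean_flexural_rigidity(scenario: RodScenario, boundary_s: Sequence[float],
                           span: tuple[float, float], n: int = 2001) -> float:
    """Length-averaged EI (N*mm^2) of a scenario over a concrete span."""
    profile = scenario.build_profile(boundary_s, span)
    s = np.linspace(span[0], span[1], n)
    d = profile.diameter_at(s)
    EI = scenario.material.E * np.pi * np.asarray(d) ** 4 / 64.0
    return float(np.trapezoid(EI, s) / (span[1] - span[0]))
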