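"""Nonlinear static equilibrium of the instrumented spine.

Rigid vertebrae (3 DOF each: x, z, theta), nonlinear FSU joint elements,
co-rotational 2-node beam elements with fiber-plastic circular sections
for the rod, and stiff penalty ties for locked pedicle screws.  Newton's
method with incremental load stepping; follower gravity is re-oriented
along the deformed inter-vertebral tangents at the start of every step.

Internal units: N, mm, N*mm, radians.  The public joint law speaks
N*m/degrees and is converted here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import JUNCTIONS, LEVELS, SpineModel, VertebraPose
from .joints import JointLaw, joint_moment
from .rods import FiberSection, RodScenario

log = logging.getLogger(__name__)

G = 9.81  # N/kg

_S = np.array([[0.0, -1.0], [1.0, 0.0]])  # d/dtheta of a rotation matrix, left factor

# Penalty stiffness of a locked polyaxial screw head (rigid tie).
TIE_TRANSLATION_STIFFNESS = 1.0e5  # N/mm
TIE_ROTATION_STIFFNESS = 1.0e8  # N*mm/rad
TIE_MAX_RESIDUAL_GAP = 2.0  # mm

# Fused joints are capped at this stiffness inside the solver: rigid to
# well below measurement resolution, but without pushing residuals under
# the double-precision force floor.
SOLVER_FUSED_STIFFNESS = 1.0e4  # N*m/deg

_DEG = 180.0 / math.pi
_GAUSS_XI = (0.5 - 0.5 / math.sqrt(3.0), 0.5 + 0.5 / math.sqrt(3.0))


class SolverError(RuntimeError):
    pass


class RigidBodyModeError(SolverError):
    pass


@dataclass
class SolveSettings:
    load_steps: int = 10
    tolerance: float = 1e-6  # relative residual
    max_iterations: int = 50
    line_search: bool = True

    def __post_init__(self):
        if self.tolerance <= 0 or self.load_steps < 1:
            raise ValueError("tolerance must be > 0 and load_steps >= 1")


def _rot(t: float) -> np.ndarray:
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]])


def _moment_nm(law: JointLaw, wedge_deg: float) -> float:
    """Joint moment as the solver sees it (fused stiffness capped)."""
    if law.state == "fused":
        return SOLVER_FUSED_STIFFNESS * (wedge_deg - law.rest_angle)
    return joint_moment(law, wedge_deg)


@dataclass
class JointElement:
    """One FSU: nonlinear rotational spring + linear shear/axial springs."""

    junction: str
    iu: int  # upper body index
    il: int  # lower body index
    a_u: np.ndarray  # disc point minus upper centroid, reference config (mm)
    a_l: np.ndarray
    ref_u: np.ndarray  # reference centroids (mm)
    ref_l: np.ndarray
    theta_built: float  # built junction wedge theta_u - theta_l, deg
    law: JointLaw
    rest_shear: float = 0.0  # mm
    rest_axial: float = 0.0

    def kinematics(self, ub, thetas0):
        du, dl = ub[self.iu, :2], ub[self.il, :2]
        tu, tl = ub[self.iu, 2], ub[self.il, 2]
        Ru, Rl = _rot(tu), _rot(tl)
        pu = self.ref_u + du + Ru @ self.a_u
        pl = self.ref_l + dl + Rl @ self.a_l
        g = pu - pl
        th_l_abs = thetas0[self.il] + tl
        e_ax = np.array([-math.sin(th_l_abs), math.cos(th_l_abs)])
        e_sh = np.array([math.cos(th_l_abs), math.sin(th_l_abs)])
        wedge_deg = self.theta_built + (tu - tl) * _DEG
        return pu, pl, g, e_ax, e_sh, wedge_deg, Ru, Rl

    def force(self, ub, thetas0):
        """Generalized internal force on [xu, zu, thu, xl, zl, thl]."""
        pu, pl, g, e_ax, e_sh, wedge, Ru, Rl = self.kinematics(ub, thetas0)
        law = self.law
        d_ax = float(g @ e_ax) - self.rest_axial
        d_sh = float(g @ e_sh) - self.rest_shear
        f_ax = law.axial_stiffness * d_ax
        f_sh = law.shear_stiffness * d_sh
        F = f_ax * e_ax + f_sh * e_sh
        # moment conjugate to a rotation in radians is simply the moment in N*mm
        M_nmm = _moment_nm(law, wedge) * 1000.0
        f = np.empty(6)
        f[0:2] = F
        f[2] = F @ (_S @ (Ru @ self.a_u)) + M_nmm
        f[3:5] = -F
        f[5] = (F @ (-_S @ (Rl @ self.a_l))
                + f_ax * float(g @ (_S @ e_ax)) + f_sh * float(g @ (_S @ e_sh))
                - M_nmm)
        return f

    def dofs(self):
        return [3 * self.iu, 3 * self.iu + 1, 3 * self.iu + 2,
                3 * self.il, 3 * self.il + 1, 3 * self.il + 2]


@dataclass
class TieElement:
    """Penalty tie between a screw head (body frame) and a rod node."""

    level: str  # vertebra level, or "pelvis" for the iliac anchor
    body: int | None  # body index; None = tied to ground (pelvis)
    node: int  # rod node index
    a_v: np.ndarray  # head point minus body centroid, reference config
    ref_body: np.ndarray  # body reference centroid (ignored for ground ties)
    head_ref: np.ndarray  # head point in reference config (spatial)
    node_ref: np.ndarray  # rod node reference position
    scale: float = 1.0  # stiffness multiplier
    # reduction is displacement-controlled: the tie's rest mismatch is
    # ramped from the initial head-to-rod gap down to zero
    rest_gap: np.ndarray = field(default_factory=lambda: np.zeros(2))
    # polyaxial: the head spins freely until locking fixes the relative
    # head/rod angle at its achieved value
    rest_rot: float = 0.0
    rot_locked: bool = False

    def head(self, ub):
        if self.body is None:
            return self.head_ref.copy(), 0.0
        d, t = ub[self.body, :2], ub[self.body, 2]
        return self.ref_body + d + _rot(t) @ self.a_v, t

    def force(self, ub, un):
        """Force on [body x,z,th, node x,z,th]; body part zero for ground."""
        kt = TIE_TRANSLATION_STIFFNESS * self.scale
        kr = TIE_ROTATION_STIFFNESS * self.scale
        ph, tv = self.head(ub)
        pn = self.node_ref + un[self.node, :2]
        tn = un[self.node, 2]
        gap = ph - pn - self.rest_gap
        F = kt * gap
        Mr = kr * (tv - tn - self.rest_rot) if self.rot_locked else 0.0
        f = np.zeros(6)
        if self.body is not None:
            f[0:2] = F
            f[2] = F @ (_S @ _rot(tv) @ self.a_v) + Mr
        f[3:5] = -F
        f[5] = -Mr
        return f, gap

    def dofs(self, n_body_dof):
        nd = [n_body_dof + 3 * self.node + k for k in range(3)]
        if self.body is None:
            return [None, None, None] + nd
        return [3 * self.body, 3 * self.body + 1, 3 * self.body + 2] + nd


class BeamSet:
    """All rod beam elements, batched.

    The rod's reference (stress-free) geometry is its contoured shape; the
    section diameter is sampled at each Gauss point from the scenario's
    diameter profile, so smooth Bezier transitions are resolved within
    elements.
    """

    def __init__(self, node_xy: np.ndarray, node_theta: np.ndarray,
                 node_s: np.ndarray, scenario: RodScenario,
                 boundary_s, n_fibers: int = 32, multiplicity: int = 2):
        self.node_xy = node_xy  # (nn,2) reference positions
        self.node_theta0 = node_theta  # (nn,) reference cross-section angles
        self.node_s = node_s
        self.nn = len(node_s)
        self.ne = self.nn - 1
        self.profile = scenario.build_profile(boundary_s,
                                              (float(node_s[0]), float(node_s[-1])))
        self.material = scenario.material
        self.n_fibers = n_fibers

        v = node_xy[1:] - node_xy[:-1]
        self.L0 = np.linalg.norm(v, axis=1)
        self.e0 = v / self.L0[:, None]
        # Gauss-point arc positions and per-GP fiber sections
        self.s_gp = np.stack([node_s[:-1] + xi * self.L0 for xi in _GAUSS_XI], axis=1)
        self.d_gp = np.asarray(self.profile.diameter_at(self.s_gp.ravel())
                               ).reshape(self.ne, 2)
        y, A = [], []
        for d in self.d_gp.ravel():
            sec = FiberSection(float(d), self.material, n_fibers, multiplicity)
            y.append(sec.y)
            A.append(sec.A_fib)
        self.y = np.array(y).reshape(self.ne, 2, n_fibers)
        self.A = np.array(A).reshape(self.ne, 2, n_fibers)
        self.B1 = np.array([(6 * xi - 4) for xi in _GAUSS_XI])  # / L0 applied later
        self.B2 = np.array([(6 * xi - 2) for xi in _GAUSS_XI])
        z = np.zeros((self.ne, 2, n_fibers))
        self.eps_p = z.copy()
        self.alpha = z.copy()
        self.last = {}

    def commit(self, trial):
        self.eps_p = trial["eps_p"]
        self.alpha = trial["alpha"]

    def _stress(self, eps):
        """Batched return map from the committed state."""
        mat = self.material
        sig_tr = mat.E * (eps - self.eps_p)
        flow = mat.flow_stress(self.alpha)
        f = np.abs(sig_tr) - flow
        yielding = f > 0.0
        H1 = mat.hardening_modulus
        dal = np.where(yielding, f / (mat.E + H1), 0.0)
        over = yielding & (self.alpha + dal > mat.eps_p_u)
        if np.any(over):
            dal = np.where(over, (np.abs(sig_tr) - mat.sigma_u) / mat.E, dal)
        alpha = self.alpha + dal
        eps_p = self.eps_p + np.sign(sig_tr) * dal
        sigma = mat.E * (eps - eps_p)
        return sigma, eps_p, alpha

    def forces(self, p1, p2, t1, t2, want_trial=False):
        """Batched internal force (ne,6) for given end states."""
        v = p2 - p1
        Lc = np.linalg.norm(v, axis=1)
        e = v / Lc[:, None]
        cross = self.e0[:, 0] * e[:, 1] - self.e0[:, 1] * e[:, 0]
        dot = np.einsum("ij,ij->i", self.e0, e)
        dbeta = np.arctan2(cross, dot)
        delta = Lc - self.L0
        phi1 = t1 - dbeta
        phi2 = t2 - dbeta
        eps0 = delta / self.L0
        kap = (self.B1[None, :] * phi1[:, None]
               + self.B2[None, :] * phi2[:, None]) / self.L0[:, None]
        eps = eps0[:, None, None] + kap[:, :, None] * self.y
        sigma, eps_p, alpha = self._stress(eps)
        N = np.einsum("egf,egf->eg", sigma, self.A)
        M = np.einsum("egf,egf,egf->eg", sigma, self.A, self.y)
        q_d = 0.5 * (N[:, 0] + N[:, 1])
        q_p1 = 0.5 * (M[:, 0] * self.B1[0] + M[:, 1] * self.B1[1])
        q_p2 = 0.5 * (M[:, 0] * self.B2[0] + M[:, 1] * self.B2[1])

        iL2 = 1.0 / (Lc * Lc)
        dbx1, dbz1 = v[:, 1] * iL2, -v[:, 0] * iL2  # d(beta)/dp1
        f = np.zeros((self.ne, 6))
        f[:, 0] = -q_d * e[:, 0] - (q_p1 + q_p2) * dbx1
        f[:, 1] = -q_d * e[:, 1] - (q_p1 + q_p2) * dbz1
        f[:, 2] = q_p1
        f[:, 3] = q_d * e[:, 0] + (q_p1 + q_p2) * dbx1
        f[:, 4] = q_d * e[:, 1] + (q_p1 + q_p2) * dbz1
        f[:, 5] = q_p2
        if want_trial:
            outer = np.max(np.abs(sigma), axis=2)  # (ne, 2)
            trial = {"eps_p": eps_p, "alpha": alpha,
                     "moment": M, "axial": N, "outer_stress": outer,
                     "plastic": np.any(alpha > 1e-12, axis=(1, 2)),
                     "ruptured": bool(np.any(alpha > self.material.eps_p_u + 1e-12))}
            return f, trial
        return f


class SystemAssembly:
    """DOF map, elements, constraints, and load set of the coupled system."""

    def __init__(self, model: SpineModel, joint_laws: dict[str, JointLaw]):
        self.model = model
        self.levels = list(LEVELS)
        self.n_body = len(self.levels)
        self.ref_xy = np.array([model.poses[lv].centroid for lv in self.levels])
        self.ref_theta = np.array([math.radians(model.poses[lv].orientation)
                                   for lv in self.levels])
        self.joints: dict[str, JointElement] = {}
        for j in JUNCTIONS:
            upper, lower = j.split("-")
            iu, il = self.levels.index(upper), self.levels.index(lower)
            pu, _ = model.poses[upper].endplate("inferior")
            pl, _ = model.poses[lower].endplate("superior")
            disc = 0.5 * (pu + pl)
            # rest_angle becomes absolute: table offsets are relative to the
            # patient's built (relaxed) wedge
            law = replace(joint_laws[j],
                          rest_angle=joint_laws[j].rest_angle + model.junction_angles[j])
            self.joints[j] = JointElement(
                junction=j, iu=iu, il=il,
                a_u=disc - self.ref_xy[iu], a_l=disc - self.ref_xy[il],
                ref_u=self.ref_xy[iu], ref_l=self.ref_xy[il],
                theta_built=model.junction_angles[j], law=law)
        self.beams: BeamSet | None = None
        self.ties: list[TieElement] = []
        self.fixed: dict[int, float] = {}
        # pelvis fixation = sacrum rigidly fixed to the (immobile) pelvis
        s1 = self.levels.index("S1")
        for k in range(3):
            self.fixed[3 * s1 + k] = 0.0
        self.f_ext = np.zeros(self.n_dof)
        #: optional configuration-dependent load, u -> force vector
        #: (used for follower gravity, which must track the deformed
        #: posture to provide its stabilizing effect)
        self.load_fn = None

    # -- DOF bookkeeping ------------------------------------------------
    @property
    def n_rod_nodes(self) -> int:
        return 0 if self.beams is None else self.beams.nn

    @property
    def n_dof(self) -> int:
        return 3 * (self.n_body + self.n_rod_nodes)

    @property
    def free_dofs(self) -> np.ndarray:
        mask = np.ones(self.n_dof, dtype=bool)
        for d in self.fixed:
            mask[d] = False
        return np.flatnonzero(mask)

    def split(self, u):
        nb = 3 * self.n_body
        ub = u[:nb].reshape(self.n_body, 3)
        un = u[nb:].reshape(-1, 3)
        return ub, un

    def body_poses(self, u) -> dict[str, VertebraPose]:
        ub, _ = self.split(u)
        poses = {}
        for i, lv in enumerate(self.levels):
            p = self.model.poses[lv]
            poses[lv] = VertebraPose(
                lv, self.ref_xy[i] + ub[i, :2],
                math.degrees(self.ref_theta[i] + ub[i, 2]), p.body_height)
        return poses

    # -- internal force and tangent -------------------------------------
    def internal_force(self, u, want_cache=False):
        ub, un = self.split(u)
        f = np.zeros(self.n_dof)
        cache = {"joint_moment_nm": {}, "joint_rotation_deg": {},
                 "tie_force_n": {}, "tie_gap_mm": {}}
        for j, el in self.joints.items():
            fe = el.force(ub, self.ref_theta)
            for a, d in enumerate(el.dofs()):
                f[d] += fe[a]
            if want_cache:
                wedge = el.theta_built + (ub[el.iu, 2] - ub[el.il, 2]) * _DEG
                cache["joint_rotation_deg"][j] = wedge
                cache["joint_moment_nm"][j] = _moment_nm(el.law, wedge)
        if self.beams is not None:
            p1 = self.beams.node_xy[:-1] + un[:-1, :2]
            p2 = self.beams.node_xy[1:] + un[1:, :2]
            fb, trial = self.beams.forces(p1, p2, un[:-1, 2], un[1:, 2],
                                          want_trial=True)
            nb = 3 * self.n_body
            for e in range(self.beams.ne):
                base1, base2 = nb + 3 * e, nb + 3 * (e + 1)
                f[base1:base1 + 3] += fb[e, :3]
                f[base2:base2 + 3] += fb[e, 3:]
            self.beams.last = trial
            if want_cache:
                cache["beam"] = trial
        for tie in self.ties:
            fe, gap = tie.force(ub, un)
            for a, d in enumerate(tie.dofs(3 * self.n_body)):
                if d is not None:
                    f[d] += fe[a]
            if want_cache:
                cache["tie_force_n"][tie.level] = float(
                    np.linalg.norm(TIE_TRANSLATION_STIFFNESS * tie.scale * gap))
                cache["tie_gap_mm"][tie.level] = float(np.linalg.norm(gap))
        if want_cache:
            return f, cache
        return f

    def tangent(self, u, h: float = 1e-6):
        """Consistent-enough tangent: per-element forward differences."""
        K = np.zeros((self.n_dof, self.n_dof))
        ub, un = self.split(u)
        for el in self.joints.values():
            dofs = el.dofs()
            f0 = el.force(ub, self.ref_theta)
            for a, d in enumerate(dofs):
                up = u.copy()
                up[d] += h
                ubp, _ = self.split(up)
                fp = el.force(ubp, self.ref_theta)
                K[np.ix_(dofs, [d])] += ((fp - f0) / h)[:, None]
        if self.beams is not None:
            nb = 3 * self.n_body
            p1 = self.beams.node_xy[:-1] + un[:-1, :2]
            p2 = self.beams.node_xy[1:] + un[1:, :2]
            t1, t2 = un[:-1, 2].copy(), un[1:, 2].copy()
            f0 = self.beams.forces(p1, p2, t1, t2)
            ne = self.beams.ne
            for a in range(6):
                p1p, p2p = p1.copy(), p2.copy()
                t1p, t2p = t1.copy(), t2.copy()
                if a < 2:
                    p1p[:, a] += h
                elif a == 2:
                    t1p += h
                elif a < 5:
                    p2p[:, a - 3] += h
                else:
                    t2p += h
                fp = self.beams.forces(p1p, p2p, t1p, t2p)
                dfe = (fp - f0) / h  # (ne, 6)
                for e in range(ne):
                    col = nb + 3 * e + a if a < 3 else nb + 3 * (e + 1) + (a - 3)
                    rows = [nb + 3 * e, nb + 3 * e + 1, nb + 3 * e + 2,
                            nb + 3 * (e + 1), nb + 3 * (e + 1) + 1, nb + 3 * (e + 1) + 2]
                    K[rows, col] += dfe[e]
        for tie in self.ties:
            dofs = tie.dofs(3 * self.n_body)
            f0, _ = tie.force(ub, un)
            for a, d in enumerate(dofs):
                if d is None:
                    continue
                up = u.copy()
                up[d] += h
                ubp, unp = self.split(up)
                fp, _ = tie.force(ubp, unp)
                for b, dr in enumerate(dofs):
                    if dr is not None:
                        K[dr, d] += (fp[b] - f0[b]) / h
        return K

    def check_well_posed(self, u=None):
        """Fail loudly if an unconstrained rigid-body mode remains."""
        u = np.zeros(self.n_dof) if u is None else u
        K = self.tangent(u)
        free = self.free_dofs
        Kff = K[np.ix_(free, free)]
        # scale rows/cols to comparable units before the singularity test
        d = np.sqrt(np.maximum(np.abs(np.diag(Kff)), 1e-30))
        Ks = Kff / d[:, None] / d[None, :]
        w, v = np.linalg.eigh(0.5 * (Ks + Ks.T))
        if w[0] < 1e-9 * w[-1]:
            mode = np.zeros(self.n_dof)
            mode[free] = v[:, 0]
            i = int(np.argmax(np.abs(mode)))
            kind = ["translation x", "translation z", "rotation"][i % 3]
            body = (self.levels[i // 3] if i < 3 * self.n_body
                    else f"rod node {(i - 3 * self.n_body) // 3}")
            raise RigidBodyModeError(
                f"unconstrained rigid-body mode: dominant {kind} at {body}")


class BeamStructure:
    """A bare rod beam structure (no spine): used for mechanics oracles.

    Shares the solver interface of :class:`SystemAssembly` so
    :func:`solve_static` works on it directly.
    """

    def __init__(self, beams: BeamSet):
        self.beams = beams
        self.fixed: dict[int, float] = {}
        self.f_ext = np.zeros(self.n_dof)
        self.load_fn = None

    @property
    def n_dof(self) -> int:
        return 3 * self.beams.nn

    @property
    def free_dofs(self) -> np.ndarray:
        mask = np.ones(self.n_dof, dtype=bool)
        for d in self.fixed:
            mask[d] = False
        return np.flatnonzero(mask)

    def internal_force(self, u, want_cache=False):
        un = u.reshape(-1, 3)
        p1 = self.beams.node_xy[:-1] + un[:-1, :2]
        p2 = self.beams.node_xy[1:] + un[1:, :2]
        fb, trial = self.beams.forces(p1, p2, un[:-1, 2], un[1:, 2], want_trial=True)
        f = np.zeros(self.n_dof)
        for e in range(self.beams.ne):
            f[3 * e: 3 * e + 3] += fb[e, :3]
            f[3 * (e + 1): 3 * (e + 1) + 3] += fb[e, 3:]
        self.beams.last = trial
        if want_cache:
            return f, {"beam": trial}
        return f

    def tangent(self, u, h: float = 1e-6):
        K = np.zeros((self.n_dof, self.n_dof))
        f0 = self.internal_force(u)
        for d in range(self.n_dof):
            up = u.copy()
            up[d] += h
            K[:, d] = (self.internal_force(up) - f0) / h
        return K


def straight_rod_structure(length: float, diameter: float, material,
                           n_elements: int = 8, n_fibers: int = 32,
                           multiplicity: int = 1) -> BeamStructure:
    """A straight horizontal rod along +x, node 0 at the origin."""
    from .rods import RodScenario
    s = np.linspace(0.0, length, n_elements + 1)
    xy = np.column_stack([s, np.zeros_like(s)])
    theta = np.full(n_elements + 1, -math.pi / 2.0)  # axis along +x
    scen = RodScenario("oracle", "constant", (diameter,), (), material)
    beams = BeamSet(xy, theta, s, scen, [], n_fibers=n_fibers,
                    multiplicity=multiplicity)
    return BeamStructure(beams)


def assemble(model: SpineModel, joint_laws: dict[str, JointLaw],
             scenario: RodScenario | None = None,
             contour_model: SpineModel | None = None,
             instrumented=None, check: bool = True) -> SystemAssembly:
    """Build the coupled system; optionally instrument it immediately."""
    asm = SystemAssembly(model, joint_laws)
    if scenario is not None:
        instrument(asm, scenario, contour_model or model, instrumented)
    if check:
        asm.check_well_posed()
    return asm


DEFAULT_INSTRUMENTED = ["T10", "T11", "T12", "L1", "L2", "L4", "L5", "S1"]
SCREW_OFFSET = np.array([-40.0, 0.0])  # mm, posterior of the centroid
PELVIS_ANCHOR_DROP = 60.0  # mm, iliac anchor below the S1 screw head


def _screw_head(model: SpineModel, level: str) -> np.ndarray:
    p = model.poses[level]
    return p.centroid + _rot(math.radians(p.orientation)) @ SCREW_OFFSET


def instrument(asm: SystemAssembly, scenario: RodScenario,
               contour_model: SpineModel,
               instrumented: list[str] | None = None,
               elements_per_span: int = 8, n_fibers: int = 32) -> None:
    """Add the contoured rod, its mesh and the locked screw ties.

    The rod's stress-free shape is a cubic spline through the planned
    screw-head positions of ``contour_model`` (the planned post-op
    geometry), from an iliac pelvis anchor up to the proximal screw.
    Ties connect the rod to the *current* model's screw heads; ramping
    their stiffness simulates reduction.
    """
    instrumented = list(DEFAULT_INSTRUMENTED if instrumented is None else instrumented)
    heads_plan = [_screw_head(contour_model, lv) for lv in reversed(instrumented)]
    anchor = heads_plan[0] + np.array([0.0, -PELVIS_ANCHOR_DROP])
    targets = [anchor] + heads_plan  # distal -> proximal
    pts = np.array(targets)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                            axis=1))])
    spline = CubicSpline(chord, pts, axis=0)
    # arc-length positions of the anchor points
    node_s, node_xy = [], []
    for i in range(len(pts) - 1):
        tt = np.linspace(chord[i], chord[i + 1], elements_per_span + 1)
        if i > 0:
            tt = tt[1:]
        node_s.extend(tt)
        node_xy.extend(spline(tt))
    node_s = np.array(node_s)
    node_xy = np.array(node_xy)
    tang = spline(node_s, 1)
    node_theta = np.arctan2(tang[:, 1], tang[:, 0]) - math.pi / 2.0
    # junction arc positions for the diameter zones: midpoint between the
    # two screw anchors bracketing the named junction
    rev = list(reversed(instrumented))  # distal -> proximal level order
    s_by_level = dict(zip(rev, chord[1:]))
    boundary_s = []
    for jname in scenario.zone_boundaries:
        upper, lower = jname.split("-")
        if upper not in s_by_level or lower not in s_by_level:
            raise SolverError(f"zone boundary {jname} not within instrumented "
                              f"span {instrumented}")
        boundary_s.append(0.5 * (s_by_level[lower] + s_by_level[upper]))
    asm.beams = BeamSet(node_xy, node_theta, node_s, scenario, boundary_s,
                        n_fibers=n_fibers)
    # ties: one per screw level + the pelvis anchor (ground)
    anchor_idx = [int(np.argmin(np.abs(node_s - c))) for c in chord]
    asm.ties = [TieElement("pelvis", None, anchor_idx[0], np.zeros(2),
                           np.zeros(2), node_xy[anchor_idx[0]].copy(),
                           node_xy[anchor_idx[0]].copy())]
    for lv, ni in zip(rev, anchor_idx[1:]):
        b = asm.levels.index(lv)
        head_now = _screw_head(asm.model, lv)
        asm.ties.append(TieElement(lv, b, ni, head_now - asm.ref_xy[b],
                                   asm.ref_xy[b], head_now.copy(),
                                   node_xy[ni].copy()))
    asm.f_ext = np.zeros(asm.n_dof)


# -- loads --------------------------------------------------------------

def gravity_vertical(asm: SystemAssembly, body_mass: float) -> np.ndarray:
    """Plain dead-weight gravity at each vertebral centroid."""
    f = np.zeros(asm.n_dof)
    for i, lv in enumerate(asm.levels):
        m = asm.model.mass_fraction[lv] * body_mass
        f[3 * i + 1] -= m * G
    return f


def follower_gravity(asm: SystemAssembly, body_mass: float,
                     u: np.ndarray | None = None) -> np.ndarray:
    """Gravity applied along the deformed inter-vertebral load path.

    The compressive force transmitted at each junction has magnitude equal
    to the cumulative supported weight and acts along the local
    inter-centroid tangent; the net load on each vertebra is the
    difference of the two junction forces, so on a straight vertical spine
    the scheme reduces to plain vertical gravity and the force reaching
    the sacrum always equals the total supported weight.
    """
    u = np.zeros(asm.n_dof) if u is None else u
    ub, _ = asm.split(u)
    xy = asm.ref_xy + ub[:, :2]
    masses = np.array([asm.model.mass_fraction[lv] * body_mass
                       for lv in asm.levels])
    P = G * np.cumsum(masses)  # P[i] = weight above junction below body i
    f = np.zeros(asm.n_dof)
    for i in range(asm.n_body - 1):  # S1 is last and fixed
        t_below = xy[i + 1] - xy[i]
        t_below = t_below / np.linalg.norm(t_below)
        F = P[i] * t_below
        if i > 0:
            t_above = xy[i] - xy[i - 1]
            t_above = t_above / np.linalg.norm(t_above)
            F = F - P[i - 1] * t_above
        f[3 * i: 3 * i + 2] += F
    return f


# -- solution -----------------------------------------------------------

@dataclass
class SolveResult:
    u: np.ndarray
    residual: float
    iterations: int
    cache: dict


def external_load(asm, u) -> np.ndarray:
    f = asm.f_ext
    if getattr(asm, "load_fn", None) is not None:
        f = f + asm.load_fn(u)
    return f


def _newton(asm: SystemAssembly, u, settings: SolveSettings, context=""):
    free = asm.free_dofs
    for d, val in asm.fixed.items():
        u[d] = val
    fe = external_load(asm, u)
    f_int = asm.internal_force(u)
    ref = max(1.0, float(np.linalg.norm(fe[free])),
              float(np.linalg.norm(f_int[free])))
    it = 0
    res = None
    for it in range(1, settings.max_iterations + 1):
        r = asm.internal_force(u) - external_load(asm, u)
        res = float(np.linalg.norm(r[free]))
        if res <= settings.tolerance * ref:
            return u, res, it - 1
        K = asm.tangent(u)
        if getattr(asm, "load_fn", None) is not None:
            # load stiffness of the configuration-dependent load, by FD
            fe0 = asm.load_fn(u)
            h = 1e-6
            for d in free:
                up = u.copy()
                up[d] += h
                K[:, d] -= (asm.load_fn(up) - fe0) / h
        Kff = K[np.ix_(free, free)]
        try:
            du = np.linalg.solve(Kff, -r[free])
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular tangent{context}: {exc}") from exc
        step = 1.0
        if settings.line_search:
            for _ in range(6):
                u_try = u.copy()
                u_try[free] += step * du
                r_try = asm.internal_force(u_try) - external_load(asm, u_try)
                if np.linalg.norm(r_try[free]) < res or step < 0.05:
                    break
                step *= 0.5
        u[free] += step * du
    r = asm.internal_force(u) - external_load(asm, u)
    res = float(np.linalg.norm(r[free]))
    if res <= settings.tolerance * ref:
        return u, res, it
    raise SolverError(
        f"Newton did not converge{context}: residual {res:.3e} "
        f"(ref {ref:.3e}) after {settings.max_iterations} iterations")


def solve_static(asm: SystemAssembly, settings: SolveSettings | None = None,
                 u0: np.ndarray | None = None, schedule=None,
                 commit: bool = True, context: str = "") -> SolveResult:
    """Incremental-load Newton solve.

    ``schedule(asm, lam, u)`` is called at the start of each load step
    with the load factor ``lam`` in (0, 1] and the current solution; it
    must set ``asm.f_ext`` (and may ramp element parameters such as tie
    stiffness or joint rest angles).  Plastic state is committed after
    every converged step.
    """
    settings = settings or SolveSettings()
    u = (np.zeros(asm.n_dof) if u0 is None else u0.copy())
    if len(u) != asm.n_dof:
        u = np.concatenate([u, np.zeros(asm.n_dof - len(u))])
    res, its = 0.0, 0
    for k in range(1, settings.load_steps + 1):
        lam = k / settings.load_steps
        if schedule is not None:
            schedule(asm, lam, u)
        u, res, it = _newton(asm, u, settings,
                             context=f"{context} [step {k}/{settings.load_steps}]")
        its += it
        if commit and asm.beams is not None and asm.beams.last:
            asm.beams.commit(asm.beams.last)
    f, cache = asm.internal_force(u, want_cache=True)
    cache["reaction_sum"] = [float((f - external_load(asm, u))[d])
                             for d in asm.fixed]
    cache["applied_load"] = external_load(asm, u)
    return SolveResult(u=u, residual=res, iterations=its, cache=cache)


def lock_ties(asm: SystemAssembly, u: np.ndarray) -> None:
    """Lock every polyaxial head at its current head/rod relative angle."""
    ub, un = asm.split(u)
    for tie in asm.ties:
        _, tv = tie.head(ub)
        tie.rest_rot = float(tv - un[tie.node, 2])
        tie.rot_locked = True


def impose_rotation(asm: SystemAssembly, level: str, theta_deg: float,
                    reference_u: np.ndarray) -> tuple[int, float, float]:
    """Fix a vertebra's sagittal rotation relative to its current pose.

    Returns (dof index, start value, target value) for ramping; the
    vertebra's translations stay free.
    """
    i = asm.levels.index(level)
    d = 3 * i + 2
    if d in asm.fixed:
        raise SolverError(f"rotation of {level} already constrained")
    start = float(reference_u[d])
    return d, start, start + math.radians(theta_deg)
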