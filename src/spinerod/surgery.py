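"""Staged surgical protocol for long thoracolumbar instrumented fusion.

Runs, per rod scenario: pre-operative standing (follower gravity),
transition to prone (unloading), posterior releases (facetectomies T10-S1,
pedicle subtraction osteotomy at L3), rod reduction with PSO compression,
return to standing, and a 10 degree forward flexion imposed at T1.  Each
stage starts from the previous stage's converged state; only the rod
section profile differs between scenarios.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (JUNCTIONS, LEVELS, SagittalProfile, SpineModel,
                       measure_profile, restack)
from .joints import JointLaw, JointStateModifier, apply_modifier
from .rods import RodScenario
from .solver import (DEFAULT_INSTRUMENTED, SolveSettings, SolverError,
                     SystemAssembly, assemble, follower_gravity, impose_rotation,
                     instrument, lock_ties, solve_static, TIE_MAX_RESIDUAL_GAP)

log = logging.getLogger(__name__)

STAGES = ("preop_standing", "prone", "released", "instrumented",
          "postop_standing", "flexed")


@dataclass(frozen=True)
class SurgicalPlan:
    """The (scenario-independent) surgical strategy."""

    instrumented: tuple[str, ...] = tuple(DEFAULT_INSTRUMENTED)
    pso_level: str = "L3"
    pso_wedge: float | None = None  # deg total; None = auto from ll_target
    max_pso_wedge: float = 35.0
    facetectomy_factor: float = 0.5
    ll_target: float | None = 48.0  # deg; None = keep released alignment
    flexion_deg: float = 10.0

    def __post_init__(self):
        if self.flexion_deg <= 0:
            raise ValueError("flexion angle must be positive")
        lo, hi = self.instrumented[0], self.instrumented[-1]
        span = LEVELS[LEVELS.index(lo): LEVELS.index(hi) + 1]
        if self.pso_level not in span:
            raise ValueError(f"PSO level {self.pso_level} outside instrumented "
                             f"span {lo}-{hi}")

    @property
    def pso_junctions(self) -> tuple[str, ...]:
        """The two junctions adjacent to the osteotomized vertebra."""
        i = LEVELS.index(self.pso_level)
        return (f"{LEVELS[i - 1]}-{LEVELS[i]}", f"{LEVELS[i]}-{LEVELS[i + 1]}")

    @property
    def facetectomy_junctions(self) -> tuple[str, ...]:
        lo, hi = self.instrumented[0], self.instrumented[-1]
        i0, i1 = JUNCTIONS.index(f"{lo}-{LEVELS[LEVELS.index(lo) + 1]}"), None
        span = [j for j in JUNCTIONS[i0:]
                if LEVELS.index(j.split("-")[0]) < LEVELS.index(hi)]
        return tuple(j for j in span if j not in self.pso_junctions)

    def fingerprint(self) -> str:
        blob = json.dumps({k: getattr(self, k) for k in
                           ("instrumented", "pso_level", "pso_wedge",
                            "max_pso_wedge", "facetectomy_factor",
                            "ll_target", "flexion_deg")},
                          sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageState:
    """Converged model state after one protocol stage."""

    stage: str
    scenario: str
    u: np.ndarray
    profile: SagittalProfile
    joint_rotation_deg: dict[str, float]
    joint_moment_nm: dict[str, float]
    screw_force_n: dict[str, float]  # per screw (left = right by symmetry)
    rod: dict | None
    residual: float
    iterations: int
    plan_fingerprint: str = ""

    def to_dict(self) -> dict:
        rod = None
        if self.rod is not None:
            rod = {k: np.asarray(v).tolist() for k, v in self.rod.items()}
        return {
            "stage": self.stage, "scenario": self.scenario,
            "profile": {"PI": self.profile.PI, "PT": self.profile.PT,
                        "SS": self.profile.SS, "TK": self.profile.TK,
                        "LL": self.profile.LL},
            "joint_rotation_deg": self.joint_rotation_deg,
            "joint_moment_nm": self.joint_moment_nm,
            "screw_force_n": self.screw_force_n,
            "rod": rod, "residual": self.residual,
            "iterations": self.iterations,
            "plan_fingerprint": self.plan_fingerprint,
        }


def _capture(asm: SystemAssembly, result, stage: str, scenario: str,
             plan_fp: str = "") -> StageState:
    cache = result.cache
    poses = asm.body_poses(result.u)
    rod = None
    if asm.beams is not None and "beam" in cache:
        b = cache["beam"]
        s_gp = asm.beams.s_gp
        rod = {"s_mm": s_gp.ravel(), "d_mm": asm.beams.d_gp.ravel(),
               "moment_nmm": b["moment"].ravel(),
               "outer_stress_mpa": b["outer_stress"].ravel(),
               "plastic": np.repeat(b["plastic"], 2),
               "anchor_s_mm": {t.level: float(asm.beams.node_s[t.node])
                               for t in asm.ties}}
    screw = {lv: f / 2.0 for lv, f in cache.get("tie_force_n", {}).items()}
    return StageState(
        stage=stage, scenario=scenario, u=result.u.copy(),
        profile=measure_profile(asm.model, poses),
        joint_rotation_deg=dict(cache.get("joint_rotation_deg", {})),
        joint_moment_nm=dict(cache.get("joint_moment_nm", {})),
        screw_force_n=screw, rod=rod,
        residual=result.residual, iterations=result.iterations,
        plan_fingerprint=plan_fp)


def calibrate_gravity_rests(asm: SystemAssembly, body_mass: float,
                            tol: float = 1e-8, max_iter: int = 10) -> None:
    """Choose joint rest offsets so the built geometry is a standing
    equilibrium under follower gravity.

    The standing radiograph shows the *loaded* spine, so the relaxed
    (rest) configuration must differ from it by exactly the gravity-induced
    deformation.  The serial chain is statically determinate: 3 rest
    parameters per junction against 3 equilibrium equations per free
    vertebra.  Solved by Newton with a finite-difference Jacobian.
    """
    f_ext = follower_gravity(asm, body_mass)
    free = asm.free_dofs
    joints = [asm.joints[j] for j in JUNCTIONS]
    u0 = np.zeros(asm.n_dof)

    def get_params():
        return np.array([v for el in joints
                         for v in (el.rest_axial, el.rest_shear,
                                   el.law.rest_angle)])

    def set_params(p):
        for k, el in enumerate(joints):
            el.rest_axial = p[3 * k]
            el.rest_shear = p[3 * k + 1]
            el.law = replace(el.law, rest_angle=p[3 * k + 2])

    def residual(p):
        set_params(p)
        return (asm.internal_force(u0) - f_ext)[free]

    p = get_params()
    r = residual(p)
    scale = max(1.0, float(np.linalg.norm(f_ext[free])))
    for _ in range(max_iter):
        if np.linalg.norm(r) <= tol * scale:
            break
        J = np.zeros((len(free), len(p)))
        h = 1e-6
        for k in range(len(p)):
            pp = p.copy()
            pp[k] += h
            J[:, k] = (residual(pp) - r) / h
        p = p - np.linalg.solve(J, r)
        r = residual(p)
    set_params(p)
    if np.linalg.norm(r) > 1e-6 * scale:
        raise SolverError("gravity rest-state calibration did not converge")


def plan_junction_targets(asm: SystemAssembly, plan: SurgicalPlan
                          ) -> tuple[dict[str, float], float]:
    """Planned post-op junction wedges over the instrumented span.

    Non-osteotomized junctions keep their released (rest) wedge; the PSO
    junctions absorb the lordosis deficit up to ``max_pso_wedge`` total,
    any overflow being spread over the facetectomized lumbar junctions
    (correction achievable through the released facets by the contoured
    rod).  Returns (targets, total PSO wedge).
    """
    rest = {j: asm.joints[j].law.rest_angle for j in JUNCTIONS}
    ll_junctions = ["L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1"]
    targets: dict[str, float] = {}
    if plan.ll_target is None and plan.pso_wedge is None:
        return targets, 0.0
    ll_rest = sum(rest[j] for j in ll_junctions)
    if plan.pso_wedge is not None:
        wedge = plan.pso_wedge
        overflow = 0.0
    else:
        deficit = plan.ll_target - ll_rest
        wedge = float(np.clip(deficit, 0.0, plan.max_pso_wedge))
        overflow = max(0.0, deficit - wedge)
    for j in plan.pso_junctions:
        targets[j] = rest[j] + wedge / 2.0
    spread = [j for j in plan.facetectomy_junctions if j in ll_junctions]
    if overflow > 0 and spread:
        for j in spread:
            targets[j] = rest[j] + overflow / len(spread)
    return targets, wedge


def run_protocol(model: SpineModel, joint_laws: dict[str, JointLaw],
                 scenario: RodScenario, plan: SurgicalPlan | None = None,
                 settings: SolveSettings | None = None,
                 gravity: bool = True) -> dict[str, StageState]:
    """Execute the full staged protocol for one rod scenario."""
    plan = plan or SurgicalPlan()
    settings = settings or SolveSettings()
    fp = plan.fingerprint()
    body_mass = model.profile.body_mass if gravity else 0.0
    states: dict[str, StageState] = {}

    asm = assemble(model, joint_laws)
    if gravity:
        calibrate_gravity_rests(asm, body_mass)

    # 1. pre-operative standing: built geometry under follower gravity
    def sched_stand(a, lam, u):
        a.f_ext = np.zeros(a.n_dof)
        a.load_fn = lambda uu, s=lam: s * follower_gravity(a, body_mass, uu)
    res = solve_static(asm, replace(settings, load_steps=2),
                       schedule=sched_stand, context=" [preop_standing]")
    states["preop_standing"] = _capture(asm, res, "preop_standing",
                                        scenario.name, fp)
    u = res.u

    # 2. prone: gravity removed (supported prone ~ unloading)
    def sched_prone(a, lam, u_):
        a.f_ext = np.zeros(a.n_dof)
        a.load_fn = lambda uu, s=(1.0 - lam): s * follower_gravity(a, body_mass, uu)
    res = solve_static(asm, settings, u0=u, schedule=sched_prone,
                       context=" [prone]")
    states["prone"] = _capture(asm, res, "prone", scenario.name, fp)
    u = res.u

    # 3. releases: facetectomies (PSO junctions are wedged during reduction)
    mod = JointStateModifier("facetectomy",
                             flexion_stiffness_factor=plan.facetectomy_factor)
    for j in plan.facetectomy_junctions:
        asm.joints[j].law = apply_modifier(asm.joints[j].law, mod)
    asm.f_ext = np.zeros(asm.n_dof)
    asm.load_fn = None
    res = solve_static(asm, replace(settings, load_steps=1), u0=u,
                       context=" [released]")
    states["released"] = _capture(asm, res, "released", scenario.name, fp)
    u = res.u

    # 4. instrumentation: contoured rod, reduction ramp, PSO compression
    targets, wedge = plan_junction_targets(asm, plan)
    # non-target junctions follow their released wedge in the planned shape
    released_rot = states["released"].joint_rotation_deg
    keep = {j: released_rot[j] for j in JUNCTIONS if j not in targets}
    planned = restack(model, {**keep, **targets})
    instrument(asm, scenario, planned, list(plan.instrumented))
    u = np.concatenate([u, np.zeros(asm.n_dof - len(u))])
    pso_rest0 = {j: asm.joints[j].law.rest_angle for j in plan.pso_junctions}
    # initial head-to-rod mismatches in the released state
    ub0, un0 = asm.split(u)
    gap0 = []
    for tie in asm.ties:
        ph, _ = tie.head(ub0)
        gap0.append(ph - (tie.node_ref + un0[tie.node, :2]))

    def sched_reduce(a, lam, u_):
        a.f_ext = np.zeros(a.n_dof)
        a.load_fn = None
        for tie, g0 in zip(a.ties, gap0):
            tie.rest_gap = (1.0 - lam) * g0
        for j in plan.pso_junctions:
            el = a.joints[j]
            el.law = replace(el.law, rest_angle=pso_rest0[j] + lam * wedge / 2.0)

    res = solve_static(asm, settings, u0=u, schedule=sched_reduce,
                       context=f" [instrumented/{scenario.name}]")
    gaps = {lv: g for lv, g in res.cache["tie_gap_mm"].items()}
    worst = max(gaps, key=gaps.get)
    if gaps[worst] > TIE_MAX_RESIDUAL_GAP:
        raise SolverError(
            f"tie target unreachable at {worst}: residual gap "
            f"{gaps[worst]:.2f} mm > {TIE_MAX_RESIDUAL_GAP} mm "
            f"({scenario.name})")
    # lock: heads fixed at their achieved angles, osteotomy fused
    lock_ties(asm, res.u)
    for j in plan.pso_junctions:
        asm.joints[j].law = apply_modifier(asm.joints[j].law,
                                           JointStateModifier("fusion"))
    res = solve_static(asm, replace(settings, load_steps=1), u0=res.u,
                       context=f" [locked/{scenario.name}]")
    states["instrumented"] = _capture(asm, res, "instrumented",
                                      scenario.name, fp)
    u = res.u

    # 5. back to standing under follower gravity
    res = solve_static(asm, settings, u0=u, schedule=sched_stand,
                       context=f" [postop_standing/{scenario.name}]")
    states["postop_standing"] = _capture(asm, res, "postop_standing",
                                         scenario.name, fp)
    u = res.u

    # 6. forward flexion imposed at T1 (translations free).  Gravity
    # stays muscle-stabilized (follower) in the flexed posture, so the
    # junctional loads measured here are the rotation-driven transfer
    # between the free spine and the construct, uniform along the
    # uninstrumented chain as in a pure-couple test.
    dof, start, _ = impose_rotation(asm, "T1", -plan.flexion_deg, u)
    target = start - math.radians(plan.flexion_deg)

    def sched_flex(a, lam, u_):
        a.f_ext = np.zeros(a.n_dof)
        a.load_fn = lambda uu: follower_gravity(a, body_mass, uu)
        a.fixed[dof] = start + lam * (target - start)

    res = solve_static(asm, settings, u0=u, schedule=sched_flex,
                       context=f" [flexed/{scenario.name}]")
    states["flexed"] = _capture(asm, res, "flexed", scenario.name, fp)
    del asm.fixed[dof]
    return states


def run_all_scenarios(model: SpineModel, joint_laws: dict[str, JointLaw],
                      scenarios: list[RodScenario],
                      plan: SurgicalPlan | None = None,
                      settings: SolveSettings | None = None,
                      gravity: bool = True
                      ) -> dict[str, dict[str, StageState]]:
    """Run the protocol for every scenario; enforce scenario isolation."""
    plan = plan or SurgicalPlan()
    out = {}
    fps = set()
    for sc in scenarios:
        log.info("running protocol for scenario %s", sc.name)
        out[sc.name] = run_protocol(model, joint_laws, sc, plan, settings,
                                    gravity=gravity)
        fps.add(next(iter(out[sc.name].values())).plan_fingerprint)
    if len(fps) > 1:
        raise SolverError("scenario isolation violated: plans differ")
    return out
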