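import math
from dataclasses import replace

import numpy as np
import pytest

from spinerod.geometry import LEVELS, SagittalProfile, build_spine
from spinerod.joints import default_joint_table
from spinerod.rods import RodMaterial, section_inertia
from spinerod.solver import (RigidBodyModeError, SolveSettings, SolverError,
                             SystemAssembly, assemble, follower_gravity,
                             gravity_vertical, impose_rotation, instrument,
                             solve_static, straight_rod_structure)

MAT = RodMaterial()


def clamped_rod(n_elements=8, L=100.0, d=6.0):
    rig = straight_rod_structure(L, d, MAT, n_elements=n_elements)
    for k in (0, 1, 2):
        rig.fixed[k] = 0.0
    return rig


class TestBeamOracles:
    def test_cantilever_tip_deflection(self):
        """Tip deflection of an end-loaded cantilever matches PL^3/3EI."""
        rig = clamped_rod()
        rig.f_ext[rig.n_dof - 2] = 10.0
        res = solve_static(rig, SolveSettings(load_steps=2))
        exact = 10 * 100 ** 3 / (3 * MAT.E * section_inertia(6.0))
        assert res.u[-2] == pytest.approx(exact, rel=0.01)

    def test_mesh_convergence(self):
        """Large-deflection tip error halves (or better) with mesh doubling."""
        def tip(ne):
            rig = clamped_rod(n_elements=ne)

            def load(asm, lam, u):
                asm.f_ext = np.zeros(asm.n_dof)
                asm.f_ext[-2] = lam * 200.0  # finite-rotation regime

            return solve_static(rig, SolveSettings(load_steps=4),
                                schedule=load).u[-2]

        ref = tip(64)
        errors = [abs(tip(ne) - ref) for ne in (2, 4, 8)]
        assert errors[1] <= 0.5 * errors[0] + 1e-12
        assert errors[2] <= 0.5 * errors[1] + 1e-12

    def test_residual_rotation_after_yield(self):
        """Loading past M_y leaves permanent rotation after elastic unload."""
        My = MAT.sigma_y * section_inertia(6.0) / 3.0
        rig = clamped_rod()

        def load(asm, lam, u):
            asm.f_ext = np.zeros(asm.n_dof)
            asm.f_ext[-1] = lam * 1.05 * My

        r1 = solve_static(rig, SolveSettings(load_steps=10), schedule=load)

        def unload(asm, lam, u):
            asm.f_ext = np.zeros(asm.n_dof)
            asm.f_ext[-1] = (1 - lam) * 1.05 * My

        r2 = solve_static(rig, SolveSettings(load_steps=10), u0=r1.u,
                          schedule=unload)
        assert abs(r2.u[-1]) > 1e-5  # residual tip rotation, rad
        assert np.any(rig.beams.alpha > 0)

    def test_elastic_path_independence(self):
        """1 load step and 10 load steps agree in the elastic regime."""
        rigs = []
        for steps in (1, 10):
            rig = clamped_rod()
            rig.f_ext[rig.n_dof - 2] = 10.0
            rigs.append(solve_static(rig, SolveSettings(load_steps=steps)).u)
        assert np.max(np.abs(rigs[0] - rigs[1])) < 1e-9


class TestAssembly:
    def test_uninstrumented_dof_count(self, default_model, joint_laws):
        asm = assemble(default_model, joint_laws)
        # 18 bodies x 3 DOF - 3 for the pelvis-fixed sacrum
        assert asm.n_dof == 54
        assert len(asm.free_dofs) == 51

    def test_instrumented_adds_rod_and_ties(self, default_model, joint_laws,
                                            scenarios):
        asm = assemble(default_model, joint_laws, scenario=scenarios[0])
        assert asm.beams is not None
        # one tie per screw (8 levels, no screws at the PSO vertebra)
        # plus the iliac anchor
        assert len(asm.ties) == 9
        assert asm.n_dof == 54 + 3 * asm.beams.nn

    def test_missing_fixation_is_a_rigid_body_mode(self, default_model,
                                                   joint_laws):
        asm = SystemAssembly(default_model, joint_laws)
        asm.fixed = {}
        with pytest.raises(RigidBodyModeError, match="rigid-body mode"):
            asm.check_well_posed()

    def test_zero_load_zero_displacement(self, default_model, joint_laws):
        asm = assemble(default_model, joint_laws)
        res = solve_static(asm, SolveSettings(load_steps=1))
        assert np.max(np.abs(res.u)) == 0.0
        assert all(abs(m) < 1e-9
                   for m in res.cache["joint_moment_nm"].values())


class TestFollowerGravity:
    def test_straight_spine_equals_vertical_gravity(self, joint_laws):
        m = build_spine(SagittalProfile(PI=40, PT=40, TK=0, LL=0))
        asm = assemble(m, joint_laws)
        f_fol = follower_gravity(asm, 60.0)
        f_vert = gravity_vertical(asm, 60.0)
        assert np.allclose(f_fol, f_vert, atol=1e-10)

    def test_total_transmitted_force_is_supported_weight(self, default_model,
                                                         joint_laws):
        asm = assemble(default_model, joint_laws)
        f = follower_gravity(asm, 60.0)
        resultant = np.hypot(f[0::3].sum(), f[1::3].sum())
        supported = 9.81 * 60.0 * sum(
            default_model.mass_fraction[lv] for lv in LEVELS if lv != "S1")
        assert resultant == pytest.approx(supported, rel=1e-12)

    def test_follower_loading_reduces_peak_flexion_moment(self, default_model):
        """On the curved spine, following the load path unloads the joints."""
        # stiffen the joints so the dead-load case has a stable equilibrium
        laws = {j: replace(law, k0=law.k0 * 60, c=law.c * 60)
                for j, law in default_joint_table().items()}

        def peak(load_maker):
            asm = assemble(default_model, laws)

            def sched(a, lam, u):
                a.f_ext = np.zeros(a.n_dof)
                a.load_fn = lambda uu, s=lam: s * load_maker(a, uu)

            res = solve_static(asm, SolveSettings(load_steps=5),
                               schedule=sched)
            return max(abs(v) for v in res.cache["joint_moment_nm"].values())

        peak_follower = peak(lambda a, u: follower_gravity(a, 60.0, u))
        peak_vertical = peak(lambda a, u: gravity_vertical(a, 60.0))
        assert peak_follower < peak_vertical


class TestEquilibriumAndConstraints:
    def test_reactions_balance_applied_loads(self, default_model, joint_laws):
        asm = assemble(default_model, joint_laws)

        def sched(a, lam, u):
            a.f_ext = np.zeros(a.n_dof)
            a.load_fn = lambda uu, s=lam: s * follower_gravity(a, 60.0, uu)

        res = solve_static(asm, SolveSettings(load_steps=5), schedule=sched)
        applied = res.cache["applied_load"]
        reactions = res.cache["reaction_sum"]
        # translational balance: reaction = -(sum of applied forces)
        fx, fz = applied[0::3].sum(), applied[1::3].sum()
        assert reactions[0] == pytest.approx(-fx, rel=1e-8, abs=1e-8)
        assert reactions[1] == pytest.approx(-fz, rel=1e-8, abs=1e-8)

    def test_imposed_rotation_bookkeeping(self, default_model, joint_laws):
        """10 deg at T1 distributes exactly over the junction rotations."""
        asm = assemble(default_model, joint_laws)
        u0 = np.zeros(asm.n_dof)
        dof, start, target = impose_rotation(asm, "T1", -10.0, u0)
        assert target == pytest.approx(start - math.radians(10.0))

        def sched(a, lam, u):
            a.f_ext = np.zeros(a.n_dof)
            a.fixed[dof] = start + lam * (target - start)

        res = solve_static(asm, SolveSettings(load_steps=5), schedule=sched)
        del asm.fixed[dof]
        rot = res.cache["joint_rotation_deg"]
        total = sum(rot[j] - asm.joints[j].theta_built for j in rot)
        assert total == pytest.approx(-10.0, abs=1e-6)
        # T1 translations remain free
        assert abs(res.u[0]) > 0 or abs(res.u[1]) > 0

    def test_conflicting_rotation_constraint_rejected(self, default_model,
                                                      joint_laws):
        asm = assemble(default_model, joint_laws)
        u0 = np.zeros(asm.n_dof)
        dof, start, target = impose_rotation(asm, "T1", -10.0, u0)
        asm.fixed[dof] = target
        with pytest.raises(SolverError, match="constrained"):
            impose_rotation(asm, "T1", -5.0, u0)
        del asm.fixed[dof]

    def test_mirrored_load_gives_mirrored_solution(self, joint_laws):
        """A symmetric straight spine responds symmetrically to +/-x loads."""
        m = build_spine(SagittalProfile(PI=40, PT=40, TK=0, LL=0))
        sols = []
        for sign in (+1.0, -1.0):
            asm = assemble(m, joint_laws)

            def sched(a, lam, u, s=sign):
                a.f_ext = np.zeros(a.n_dof)
                a.f_ext[0] = s * lam * 5.0  # anterior/posterior shear at T1

            sols.append(solve_static(asm, SolveSettings(load_steps=10),
                                     schedule=sched).u)
        up, um = sols
        assert np.allclose(up[0::3], -um[0::3], atol=1e-9)  # x mirrors
        assert np.allclose(up[2::3], -um[2::3], atol=1e-9)  # theta mirrors
        assert np.allclose(up[1::3], um[1::3], atol=1e-9)   # z preserved
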