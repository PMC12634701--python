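import math

import numpy as np
import pytest

from spinerod.rods import (DEFAULT_TRANSITION_MM, DiameterProfile,
                           FiberSection, RodMaterial, RodScenario,
                           default_scenarios, mean_flexural_rigidity,
                           moment_curvature, section_area, section_inertia)

MAT = RodMaterial()  # Ti alloy: E=113 GPa, sig_y=950, sig_u=1180 @ 10%


class TestSectionProperties:
    def test_closed_forms(self):
        assert section_inertia(6.0) == pytest.approx(63.62, abs=5e-3)
        assert section_area(6.0) == pytest.approx(math.pi * 9.0)
        for d in (1e-6, 1e-3):
            assert section_inertia(d) < 1e-10

    def test_flexural_rigidity_ratio_of_diameters(self):
        assert (section_inertia(6.0) / section_inertia(5.0)
                == pytest.approx((6 / 5) ** 4, rel=1e-12))

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            section_inertia(0.0)
        with pytest.raises(ValueError):
            section_area(-2.0)

    def test_fiber_discretization_accuracy(self):
        """>= 32 fibers reproduce A and I within 0.5%."""
        sec = FiberSection(6.0, MAT, n_fibers=32)
        assert sec.area == pytest.approx(section_area(6.0), rel=1e-9)
        assert sec.inertia == pytest.approx(section_inertia(6.0), rel=5e-3)


class TestMomentCurvature:
    def test_elastic_branch_slope(self):
        kappa = 1e-4
        M, _ = moment_curvature(6.0, MAT, kappa)
        sec = FiberSection(6.0, MAT)
        assert M == pytest.approx(MAT.E * sec.inertia * kappa, rel=1e-9)
        assert M == pytest.approx(MAT.E * section_inertia(6.0) * kappa,
                                  rel=5e-3)

    def test_first_yield_moment(self):
        My = MAT.sigma_y * section_inertia(6.0) / 3.0  # sig_y * I / c
        assert My == pytest.approx(20146, rel=1e-3)
        kap_y = MAT.sigma_y / (MAT.E * 3.0)
        M, state = moment_curvature(6.0, MAT, kap_y)
        assert M == pytest.approx(My, rel=0.01)
        M2, state2 = moment_curvature(6.0, MAT, 1.3 * kap_y)
        assert np.any(state2["alpha"] > 0)  # past first yield

    def test_plastic_moment_perfectly_plastic_limit(self):
        epp = RodMaterial(sigma_y=950, sigma_u=950.01, eps_u=0.10)
        M, _ = moment_curvature(6.0, epp, 0.1, n_fibers=48)
        Mp = 950 * 6 ** 3 / 6.0  # sig_y * d^3 / 6
        assert M == pytest.approx(Mp, rel=0.01)

    def test_odd_in_curvature(self):
        for kap in (5e-4, 3e-3, 8e-3):
            Mp, _ = moment_curvature(6.0, MAT, kap)
            Mm, _ = moment_curvature(6.0, MAT, -kap)
            assert Mm == pytest.approx(-Mp, rel=1e-12)

    def test_unloading_is_elastic_with_residual(self):
        kap_y = MAT.sigma_y / (MAT.E * 3.0)
        _, st = moment_curvature(6.0, MAT, 2.0 * kap_y)
        state = {"eps_p": st["eps_p"], "alpha": st["alpha"]}
        M0, _ = moment_curvature(6.0, MAT, 0.0, state=state)
        assert M0 < -1000.0  # residual (reversed) moment at zero curvature
        # elastic loading leaves no plastic state
        _, st_el = moment_curvature(6.0, MAT, 0.5 * kap_y)
        assert not np.any(st_el["alpha"] > 0)

    def test_rupture_flag_beyond_ultimate(self):
        _, st = moment_curvature(6.0, MAT, 0.1)
        assert st["ruptured"]

    def test_material_validation(self):
        with pytest.raises(ValueError):
            RodMaterial(sigma_y=1200, sigma_u=1180)
        with pytest.raises(ValueError):
            RodMaterial(eps_u=0.005)  # below elastic strain at sigma_u


class TestDiameterProfiles:
    def test_constant(self):
        p = DiameterProfile("constant", ((0.0, 400.0, 6.0),))
        for s in (0.0, 123.4, 400.0):
            assert p.diameter_at(s) == 6.0

    def test_stepped_single_discontinuity(self):
        p = DiameterProfile("stepped", ((0, 250, 6.0), (250, 400, 5.0)))
        assert p.diameter_at(249.999) == 6.0
        assert p.diameter_at(250.0) == 6.0  # distal-side limit at the step
        assert p.diameter_at(250.001) == 5.0

    def test_bezier_plateaus_and_c1_transition(self):
        p = DiameterProfile(
            "bezier", ((0, 150, 6.0), (150, 260, 5.5), (260, 400, 5.0)),
            transition=DEFAULT_TRANSITION_MM)
        # zone midpoints hit the named diameters exactly
        assert p.diameter_at(75.0) == pytest.approx(6.0)
        assert p.diameter_at(205.0) == pytest.approx(5.5)
        assert p.diameter_at(330.0) == pytest.approx(5.0)
        s = np.linspace(0, 400, 8001)
        d = p.diameter_at(s)
        assert np.min(d) >= 5.0 - 1e-12 and np.max(d) <= 6.0 + 1e-12
        # C1: the numerical derivative is finite and continuous
        dd = np.diff(d) / np.diff(s)
        assert np.max(np.abs(dd)) < 0.05  # mm per mm, smooth blend
        assert np.max(np.abs(np.diff(dd))) < 5e-4  # no slope jumps
        # monotone within each transition
        t = (s > 140) & (s < 160)
        assert np.all(np.diff(d[t]) <= 1e-12)

    def test_out_of_span_rejected(self):
        p = DiameterProfile("constant", ((0.0, 400.0, 6.0),))
        with pytest.raises(ValueError):
            p.diameter_at(400.5)

    def test_zone_validation(self):
        with pytest.raises(ValueError):
            DiameterProfile("stepped", ((0, 250, 6.0),))
        with pytest.raises(ValueError):
            DiameterProfile("bezier", ((0, 100, 6.0), (120, 200, 5.0)))


class TestScenarios:
    def test_five_designs_with_exact_diameters(self, scenarios):
        by_name = {s.name: s for s in scenarios}
        assert by_name["constant-6.0"].zone_diameters == (6.0,)
        assert by_name["stepped-6.0-5.0"].zone_diameters == (6.0, 5.0)
        assert by_name["stepped-6.0-5.0"].zone_boundaries == ("T11-T12",)
        assert by_name["bezier-6.0-5.5-5.0"].zone_diameters == (6.0, 5.5, 5.0)
        assert by_name["constant-5.5"].zone_diameters == (5.5,)
        assert by_name["bezier-5.5-5.0-4.75"].zone_diameters == (5.5, 5.0, 4.75)

    def test_length_averaged_rigidity_ordering(self, scenarios):
        """Mean EI orders: const6 > stepped > bezier6 > const5.5 > bezier5.5."""
        span = (0.0, 420.0)
        bounds = {1: [], 2: [280.0], 3: [170.0, 280.0], 4: [],
                  5: [170.0, 280.0]}
        ei = [mean_flexural_rigidity(s, bounds[i + 1], span)
              for i, s in enumerate(scenarios)]
        assert ei == sorted(ei, reverse=True)
        assert len(set(np.round(ei))) == 5

    def test_boundary_count_validation(self):
        with pytest.raises(ValueError):
            RodScenario("bad", "bezier", (6.0, 5.5, 5.0), ("L1-L2",))
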