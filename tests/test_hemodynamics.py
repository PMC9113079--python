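import numpy as np
import pytest

from coroflow import (
    BoundaryConditions,
    CrossSection,
    LesionSpec,
    LongitudinalProfile,
    LossModelParams,
    SegmentSpec,
    Taper,
    build_area_profile,
    expansion_loss,
    solve_flow,
    total_pressure_drop,
    vffr_sensitivity_mvr,
    viscous_resistance,
)

from .conftest import make_serial, make_single
from .oracles import fine_grid_pressure_drop, linear_network_vffr, poiseuille_resistance


class TestViscousResistance:
    def test_straight_tube_closed_form(self, fluid):
        prof = build_area_profile(SegmentSpec(3.5, 100.0))
        r = viscous_resistance(prof, fluid)
        oracle = poiseuille_resistance(fluid.viscosity_Pa_s, 100.0, 3.5)
        assert r == pytest.approx(oracle, rel=1e-10)
        assert r == pytest.approx(9.50e7, rel=2e-3)

    def test_d4_scaling(self, fluid):
        r1 = viscous_resistance(build_area_profile(SegmentSpec(3.5, 50.0)), fluid)
        r2 = viscous_resistance(build_area_profile(SegmentSpec(1.75, 50.0)), fluid)
        assert r2 / r1 == pytest.approx(16.0, rel=1e-10)

    def test_piecewise_profile_sum_of_closed_forms(self, fluid):
        # a rectangular 70% lesion is a narrow tube in series with healthy tube
        les = LesionSpec(0.7, 10.0, 25.0, profile=LongitudinalProfile.RECTANGULAR)
        prof = build_area_profile(SegmentSpec(3.5, 50.0, (les,)))
        r = viscous_resistance(prof, fluid)
        oracle = poiseuille_resistance(fluid.viscosity_Pa_s, 40.0, 3.5) + \
            poiseuille_resistance(fluid.viscosity_Pa_s, 10.0, 0.3 * 3.5)
        assert r == pytest.approx(oracle, rel=0.005)


class TestExpansionLoss:
    def test_zero_without_narrowing(self, params, fluid):
        seg = SegmentSpec(3.5, 50.0, (LesionSpec(0.0, 5.0, 25.0),))
        prof = build_area_profile(seg)
        assert expansion_loss(prof, seg.lesions[0], params, fluid, 2e-6) == 0.0

    def test_zero_without_narrowing_rectangular(self, params, fluid):
        # vena contracta must vanish with the narrowing even for sharp edges
        les = LesionSpec(0.0, 5.0, 25.0, profile=LongitudinalProfile.RECTANGULAR)
        seg = SegmentSpec(3.5, 50.0, (les,))
        prof = build_area_profile(seg)
        assert expansion_loss(prof, les, params, fluid, 2e-6) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_flow(self, params, fluid):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        assert expansion_loss(prof, seg.lesions[0], params, fluid, 0.0) == 0.0

    def test_quadratic_in_flow(self, params, fluid):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        d1 = expansion_loss(prof, seg.lesions[0], params, fluid, 1e-6)
        d2 = expansion_loss(prof, seg.lesions[0], params, fluid, 2e-6)
        assert d2 == pytest.approx(4.0 * d1, rel=1e-12)

    def test_sign_follows_flow(self, params, fluid):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        assert expansion_loss(prof, seg.lesions[0], params, fluid, -1e-6) < 0.0


class TestTotalPressureDrop:
    def test_lesion_free_is_linear(self, params, fluid):
        prof = build_area_profile(SegmentSpec(3.5, 100.0))
        q = 1.5e-6
        assert total_pressure_drop(prof, (), params, fluid, q) == pytest.approx(
            viscous_resistance(prof, fluid) * q, rel=1e-14
        )

    def test_two_identical_lesions_double_expansion(self, params, fluid):
        q = 1.2e-6
        seg1 = make_serial(1)
        seg2 = make_serial(2)
        p1, p2 = build_area_profile(seg1), build_area_profile(seg2)
        exp1 = total_pressure_drop(p1, seg1.lesions, params, fluid, q) - \
            viscous_resistance(p1, fluid) * q
        exp2 = total_pressure_drop(p2, seg2.lesions, params, fluid, q) - \
            viscous_resistance(p2, fluid) * q
        assert exp2 == pytest.approx(2.0 * exp1, rel=1e-10)

    def test_strictly_increasing_in_flow(self, params, fluid):
        seg = make_single(ds=0.8)
        prof = build_area_profile(seg)
        qs = np.linspace(0.0, 4e-6, 50)
        dps = [total_pressure_drop(prof, seg.lesions, params, fluid, q) for q in qs]
        assert np.all(np.diff(dps) > 0.0)

    @pytest.mark.parametrize("seg_factory", [
        lambda: make_single(ds=0.7),
        lambda: make_single(ds=0.8, profile=LongitudinalProfile.RECTANGULAR,
                            taper=Taper.UNIFORM),
        lambda: make_single(ds=0.7, length=30.0, taper=Taper.UNIFORM,
                            vessel_length=100.0),
        lambda: make_single(ds=0.8, cross=CrossSection.ECCENTRIC),
        lambda: make_serial(3),
    ])
    def test_matches_fine_grid_oracle(self, seg_factory, params, fluid):
        seg = seg_factory()
        prof = build_area_profile(seg)
        q = 1.3e-6
        dp = total_pressure_drop(prof, seg.lesions, params, fluid, q)
        oracle = fine_grid_pressure_drop(seg, params, fluid, q)
        assert dp == pytest.approx(oracle, rel=0.01)


class TestSolveFlow:
    def test_lesion_free_closed_form(self, params, fluid, bc):
        prof = build_area_profile(SegmentSpec(3.5, 100.0))
        sol = solve_flow(prof, (), params, fluid, bc)
        r_v = viscous_resistance(prof, fluid)
        oracle = linear_network_vffr(
            bc.inlet_pressure_Pa, bc.venous_pressure_Pa, r_v, bc.outlet_mvr_Pa_s_m3
        )
        assert sol.vffr == pytest.approx(oracle, rel=1e-12)
        assert sol.vffr == pytest.approx(0.989, abs=2e-3)

    def test_kt_zero_equals_resistance_ratio(self, fluid, bc):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        sol = solve_flow(prof, seg.lesions, LossModelParams(kt=0.0), fluid, bc)
        r_v = viscous_resistance(prof, fluid)
        expected = bc.outlet_mvr_Pa_s_m3 / (bc.outlet_mvr_Pa_s_m3 + r_v)
        assert abs(sol.vffr - expected) / expected < 1e-10

    def test_kt_zero_independent_of_inlet_pressure(self, fluid):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        vals = []
        for pa in (8000.0, 13332.2, 16000.0):
            bc = BoundaryConditions(inlet_pressure_Pa=pa)
            vals.append(
                solve_flow(prof, seg.lesions, LossModelParams(kt=0.0), fluid, bc).vffr
            )
        assert max(vals) - min(vals) < 1e-12

    def test_residual_invariant(self, params, fluid, bc):
        seg = make_serial(3, ds=0.8, taper=Taper.UNIFORM)
        prof = build_area_profile(seg)
        sol = solve_flow(prof, seg.lesions, params, fluid, bc)
        # | Pa - dP(Q) - Rmv Q - Pv | / Pa
        lhs = bc.inlet_pressure_Pa - total_pressure_drop(
            prof, seg.lesions, params, fluid, sol.flow_m3_s
        ) - bc.outlet_mvr_Pa_s_m3 * sol.flow_m3_s - bc.venous_pressure_Pa
        assert abs(lhs) / bc.inlet_pressure_Pa < 1e-8
        assert sol.converged

    def test_pressure_curve_non_increasing(self, params, fluid, bc):
        seg = make_serial(2, ds=0.8)
        prof = build_area_profile(seg)
        sol = solve_flow(prof, seg.lesions, params, fluid, bc)
        assert np.all(np.diff(sol.pressure_curve_Pa) <= 1e-9)
        assert sol.pressure_curve_Pa[0] == pytest.approx(bc.inlet_pressure_Pa)
        assert sol.pressure_curve_Pa[-1] == pytest.approx(
            sol.outlet_pressure_Pa, rel=1e-9
        )

    def test_vffr_in_unit_interval(self, params, fluid, bc):
        seg = make_single(ds=0.9)
        prof = build_area_profile(seg)
        sol = solve_flow(prof, seg.lesions, params, fluid, bc)
        assert 0.0 < sol.vffr <= 1.0

    def test_q_normal_identity(self, params, fluid, bc):
        # lesion-free: the solved flow IS the normal flow
        prof = build_area_profile(SegmentSpec(3.5, 100.0))
        sol = solve_flow(prof, (), params, fluid, bc)
        assert sol.flow_m3_s == pytest.approx(sol.q_normal_m3_s, rel=1e-10)
        # stenosed: vFFR approximates Q_sten / Q_normal when Pv = 0
        seg = make_single(ds=0.7)
        p = build_area_profile(seg)
        s = solve_flow(p, seg.lesions, params, fluid, bc)
        assert s.flow_m3_s / s.q_normal_m3_s == pytest.approx(s.vffr, abs=0.01)


class TestMvrSensitivity:
    def test_zero_delta(self, params, fluid, bc):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        lo, std, hi = vffr_sensitivity_mvr(prof, seg.lesions, params, fluid, bc, 0.0)
        assert lo == std == hi

    def test_ordering_70_percent(self, params, fluid, bc):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        lo, std, hi = vffr_sensitivity_mvr(prof, seg.lesions, params, fluid, bc, 2e9)
        assert lo < std < hi
        # low MVR reduces and high MVR raises vFFR by a few hundredths
        assert std - lo == pytest.approx(0.05, abs=0.02)
        assert hi - std == pytest.approx(0.03, abs=0.02)

    def test_linear_limit_monotone_in_mvr(self, fluid):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        r_v = viscous_resistance(prof, fluid)
        vals = []
        for r in (6.721e9, 8.721e9, 10.721e9):
            bc = BoundaryConditions(outlet_mvr_Pa_s_m3=r)
            sol = solve_flow(prof, seg.lesions, LossModelParams(kt=0.0), fluid, bc)
            assert sol.vffr == pytest.approx(r / (r + r_v), rel=1e-10)
            vals.append(sol.vffr)
        assert vals[0] < vals[1] < vals[2]

    def test_invalid_delta(self, params, fluid, bc):
        seg = make_single(ds=0.7)
        prof = build_area_profile(seg)
        with pytest.raises(ValueError):
            vffr_sensitivity_mvr(prof, seg.lesions, params, fluid, bc, 9e9)


class TestLossModelParams:
    def test_cc_ordering_enforced(self):
        with pytest.raises(ValueError):
            LossModelParams(cc_rectangular=0.9, cc_uniform=0.7)

    def test_cc_bounds(self):
        with pytest.raises(ValueError):
            LossModelParams(cc_rounded=1.2)
        with pytest.raises(ValueError):
            LossModelParams(kt=-1.0)

    def test_selection_by_outline(self, params):
        rect = LesionSpec(0.7, 5.0, 25.0, profile=LongitudinalProfile.RECTANGULAR)
        unif = LesionSpec(0.7, 5.0, 25.0, taper=Taper.UNIFORM)
        focal = LesionSpec(0.7, 5.0, 25.0)
        assert params.contraction_coefficient(rect) == params.cc_rectangular
        assert params.contraction_coefficient(unif) == params.cc_uniform
        assert params.contraction_coefficient(focal) == params.cc_rounded
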