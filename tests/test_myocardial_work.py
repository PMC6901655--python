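"""Pressure template, Laplace stress, loop areas and regional work."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyssync import synthetic_cohort as sc
from dyssync.myocardial_work import (
    LEVELS,
    PressureTemplate,
    SEPTAL_SUB_WALLS,
    LATERAL_SUB_WALLS,
    ValveEvents,
    analyze_traces,
    estimate_lv_pressure,
    laplace_stress,
    cylindrical_laplace_stress,
    loop_area,
    regional_work,
    read_traces,
    write_traces,
)

EVENTS = ValveEvents(mvc=0.05, avo=0.10, avc=0.42, mvo=0.50)


class TestPressure:
    def test_maximum_equals_sbp_exactly(self):
        _, p = estimate_lv_pressure(131.0, EVENTS, 1.0, n_samples=2001)
        assert np.max(p) == pytest.approx(131.0, abs=1e-9)

    def test_diastolic_plateau_before_mvc(self):
        t, p = estimate_lv_pressure(120.0, EVENTS, 1.0)
        assert np.allclose(p[t < EVENTS.mvc], 5.0)
        assert np.allclose(p[t > EVENTS.mvo], 5.0)

    def test_mid_isovolumic_rise_matches_template_interpolation(self):
        # at the midpoint of MVC->AVO the template's cosine rise sits at half
        # the aortic-opening fraction
        tpl = PressureTemplate.default()
        sbp = 140.0
        t_mid = 0.5 * (EVENTS.mvc + EVENTS.avo)
        _, p = estimate_lv_pressure(
            sbp, EVENTS, 1.0, times=np.array([0.0, t_mid, 1.0])
        )
        expected = 5.0 + (sbp - 5.0) * tpl.aortic_opening_frac * 0.5
        assert p[1] == pytest.approx(expected, rel=1e-12)

    def test_event_ordering_violation_rejected(self):
        bad = ValveEvents(mvc=0.2, avo=0.1, avc=0.42, mvo=0.5)
        with pytest.raises(ValueError):
            estimate_lv_pressure(120.0, bad, 1.0)

    def test_continuity_at_landmarks(self):
        t, p = estimate_lv_pressure(130.0, EVENTS, 1.0, n_samples=20001)
        assert np.max(np.abs(np.diff(p))) < 0.5  # no jumps on a fine grid


class TestLaplace:
    def test_hand_value(self):
        # P = 100 mmHg, curvature 0.025 /mm (r = 40 mm), h = 10 mm
        sigma = laplace_stress(np.array([100.0]), np.array([0.025]), np.array([10.0]))
        assert sigma[0] == pytest.approx(200.0)

    def test_doubling_thickness_halves_stress(self):
        p, c = np.full(5, 90.0), np.full(5, 0.03)
        np.testing.assert_allclose(
            laplace_stress(p, c, np.full(5, 16.0)),
            laplace_stress(p, c, np.full(5, 8.0)) / 2,
        )

    def test_zero_pressure_gives_zero_stress(self):
        assert np.all(laplace_stress(np.zeros(4), np.full(4, 0.03), np.full(4, 9.0)) == 0)

    def test_cylindrical_variant_doubles_spherical(self):
        p, c, h = np.array([100.0]), np.array([0.025]), np.array([10.0])
        assert cylindrical_laplace_stress(p, c, h)[0] == pytest.approx(400.0)

    @pytest.mark.parametrize("bad", ["curvature", "thickness"])
    def test_nonpositive_geometry_rejected(self, bad):
        c = np.full(3, 0.02 if bad != "curvature" else -0.01)
        h = np.full(3, 10.0 if bad != "thickness" else 0.0)
        with pytest.raises(ValueError):
            laplace_stress(np.full(3, 100.0), c, h)


def ellipse(n, a=10.0, b=10.0, reverse=False):
    theta = np.linspace(0, 2 * np.pi, n + 1)
    if reverse:
        theta = theta[::-1]
    return 50.0 + b * np.sin(theta), a * np.cos(theta)  # (stress, strain)


class TestLoopArea:
    def test_constant_strain_is_zero_work(self):
        t = np.linspace(0, 2 * np.pi, 101)
        assert loop_area(50 + 10 * np.sin(t), np.zeros(101)) == 0.0

    def test_ellipse_against_dense_shoelace_oracle(self):
        # analytic pi*a*b vs a 1e5-point polygon of the same ellipse
        stress, strain = ellipse(500)
        area = loop_area(stress, strain)
        s_oracle, e_oracle = ellipse(100_000)
        x, y = e_oracle[:-1], s_oracle[:-1]
        oracle = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area == pytest.approx(np.pi * 100.0, rel=3e-5)
        assert area == pytest.approx(oracle, rel=3e-5)

    def test_reversed_traversal_flips_sign(self):
        s_f, e_f = ellipse(400)
        s_r, e_r = ellipse(400, reverse=True)
        assert loop_area(s_r, e_r) == pytest.approx(-loop_area(s_f, e_f), rel=1e-12)

    @given(st.integers(0, 399))
    def test_cyclic_shift_invariance(self, shift):
        stress, strain = ellipse(400)
        s, e = stress[:-1], strain[:-1]
        s2 = np.append(np.roll(s, shift), np.roll(s, shift)[0])
        e2 = np.append(np.roll(e, shift), np.roll(e, shift)[0])
        assert loop_area(s2, e2) == pytest.approx(loop_area(stress, strain), rel=1e-9)

    def test_open_loop_rejected(self):
        stress, strain = ellipse(100)
        with pytest.raises(ValueError):
            loop_area(stress[:-5], strain[:-5])

    def test_grid_refinement_convergence(self):
        coarse = loop_area(*ellipse(250))
        fine = loop_area(*ellipse(500))
        assert abs(fine - coarse) / abs(fine) < 1e-3

    def test_physiologic_orientation_is_positive(self):
        # shortening (strain decreasing) while stress is high => positive work
        t = np.linspace(0, 2 * np.pi, 601)
        strain = 10 * np.cos(t)
        stress = 50 + 10 * np.sin(t)
        # at t just after 0, strain decreases while stress rises: ccw loop
        assert loop_area(stress, strain) > 0


class TestRegionalWork:
    def test_uniform_segments(self):
        seg = {(w, lvl): 800.0 for w in ("septal", "lateral") for lvl in LEVELS}
        res = regional_work(seg)
        assert res.regional["septal"] == 800.0
        assert res.regional["lateral"] == 800.0
        assert not res.wasted_septal

    def test_hand_mean_and_wasted_flag(self):
        seg = {("septal", lvl): w for lvl, w in zip(LEVELS, (-200.0, -100.0, 150.0))}
        seg.update({("lateral", lvl): 1000.0 for lvl in LEVELS})
        res = regional_work(seg)
        assert res.regional["septal"] == pytest.approx(-50.0)
        assert res.wasted_septal

    def test_sub_wall_layout_averages_both_septal_walls(self):
        seg = {(w, lvl): 100.0 for w in SEPTAL_SUB_WALLS for lvl in LEVELS}
        seg.update({(w, lvl): 300.0 for w in LATERAL_SUB_WALLS for lvl in LEVELS})
        res = regional_work(seg)
        assert res.regional["septal"] == 100.0
        assert res.regional["lateral"] == 300.0

    def test_nested_mapping_accepted(self):
        nested = {
            "septal": {lvl: 10.0 for lvl in LEVELS},
            "lateral": {lvl: 20.0 for lvl in LEVELS},
        }
        assert regional_work(nested).regional["septal"] == 10.0

    def test_missing_segment_rejected(self):
        seg = {("septal", "basal"): 1.0, ("septal", "mid"): 1.0}
        seg.update({("lateral", lvl): 1.0 for lvl in LEVELS})
        with pytest.raises(ValueError, match="missing"):
            regional_work(seg)


class TestWorkTraceRoundTrip:
    """make_work_traces -> pressure/stress/loop chain recovers prescriptions."""

    def make_record(self, seg_work):
        events = EVENTS
        return sc.PatientRecord(
            id="T000",
            dyssynchrony=True,
            true_mbf={"septal": 0.6, "lateral": 0.9},
            true_suv=np.array([]),
            true_wall_suv={"septal": 5.0, "lateral": 10.0},
            true_fdg_slr=0.5,
            true_work={"septal": 0.0, "lateral": 0.0},
            true_segment_work=seg_work,
            delta_esv=40.0,
            esv_pre=100.0,
            esv_post=60.0,
            reader_labels=(True, True),
            sbp=130.0,
            valve_events=events,
            cycle_length=1.0,
        )

    def test_zero_work_yields_constant_strain(self):
        seg = {(w, lvl): 0.0 for w in ("septal", "lateral") for lvl in LEVELS}
        traces = sc.make_work_traces(self.make_record(seg))
        assert np.all(traces.strain_pct[("septal", "basal")] == 0.0)
        res = analyze_traces(traces)
        assert res.regional["septal"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("work", [1000.0, -750.0, 3174.0, 12.5])
    def test_prescribed_area_recovered_within_half_percent(self, work):
        seg = {(w, lvl): work for w in ("septal", "lateral") for lvl in LEVELS}
        res = analyze_traces(sc.make_work_traces(self.make_record(seg)))
        assert res.regional["septal"] == pytest.approx(work, rel=5e-3)

    def test_unrealizable_work_rejected(self):
        seg = {(w, lvl): 1e6 for w in ("septal", "lateral") for lvl in LEVELS}
        with pytest.raises(ValueError, match="cannot be realized"):
            sc.make_work_traces(self.make_record(seg))

    def test_pressure_scaling_scales_work_linearly(self):
        # fixed geometry: scaling the pressure curve scales stress, hence work
        seg = {(w, lvl): 500.0 for w in ("septal", "lateral") for lvl in LEVELS}
        traces = sc.make_work_traces(self.make_record(seg))
        p = traces.pressure()
        k = 1.7
        w1 = loop_area(
            laplace_stress(p, traces.curvature_per_mm[("septal", "mid")],
                           traces.thickness_mm[("septal", "mid")]),
            traces.strain_pct[("septal", "mid")],
        )
        w2 = loop_area(
            laplace_stress(k * p, traces.curvature_per_mm[("septal", "mid")],
                           traces.thickness_mm[("septal", "mid")]),
            traces.strain_pct[("septal", "mid")],
        )
        assert w2 == pytest.approx(k * w1, rel=1e-12)

    def test_traces_file_round_trip(self, tmp_path):
        seg = {(w, lvl): 800.0 for w in ("septal", "lateral") for lvl in LEVELS}
        traces = sc.make_work_traces(self.make_record(seg))
        write_traces(traces, tmp_path / "tr.csv", tmp_path / "tr.json")
        back = read_traces(tmp_path / "tr.csv", tmp_path / "tr.json")
        res = analyze_traces(back)
        assert res.regional["septal"] == pytest.approx(800.0, rel=5e-3)
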