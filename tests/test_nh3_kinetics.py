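"""Two-tissue compartment model: forward model, metabolite correction, WLS fit."""

import numpy as np
import pytest

from dyssync import synthetic_cohort as sc
from dyssync.nh3_kinetics import (
    CompartmentParams,
    FrameSchedule,
    TimeActivityCurve,
    fit_region,
    frame_average_matrix,
    mbf_slr,
    metabolite_correct,
    model_tac,
    read_tacs_csv,
    read_aif_csv,
    tissue_curve,
)


@pytest.fixture(scope="module")
def aif():
    t = np.arange(0.0, 600.0 + 0.25, 0.5)
    return sc.make_input_function(t, sc.AifShape())


class TestSchedule:
    def test_default_schedule_layout(self):
        s = FrameSchedule.default()
        assert s.n_frames == 22
        assert s.frame_end[-1] == 1800.0
        np.testing.assert_allclose(s.durations[:12], 10.0)
        np.testing.assert_allclose(s.durations[12:16], 30.0)
        np.testing.assert_allclose(s.durations[16:19], 120.0)
        np.testing.assert_allclose(s.durations[19:], [180.0, 420.0, 600.0])

    def test_first_ten_minutes_is_nineteen_frames(self):
        s = FrameSchedule.default()
        assert int(np.sum(s.mask_ending_by(600.0))) == 19

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 20.0]), np.array([10.0, 30.0]))


class TestMetaboliteCorrection:
    def test_zero_fraction_is_identity(self):
        wb = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(metabolite_correct(wb, np.zeros(3)), wb)

    def test_direct_product(self):
        assert metabolite_correct(np.array([1.0]), np.array([0.5]))[0] == 0.5

    def test_fraction_is_zero_before_two_minutes(self):
        frac = sc.metabolite_fraction_curve(np.array([0.0, 60.0, 119.9]), sc.AifShape())
        assert np.all(frac == 0.0)

    def test_fraction_nondecreasing_after_onset(self):
        t = np.arange(0, 1800.0, 1.0)
        frac = sc.metabolite_fraction_curve(t, sc.AifShape())
        assert np.all(np.diff(frac) >= 0)
        assert frac[-1] == pytest.approx(0.5)

    def test_fraction_of_one_rejected(self):
        with pytest.raises(ValueError):
            metabolite_correct(np.ones(2), np.array([0.0, 1.0]))

    def test_correction_recovers_true_arterial(self, aif):
        true_arterial = sc.gamma_variate(aif.times, 100.0, 2.0, 12.0, 10.0)
        np.testing.assert_allclose(aif.corrected(), true_arterial, rtol=1e-12)


class TestForwardModel:
    def test_zero_k1_gives_blood_only(self, aif):
        params = CompartmentParams(K1=0.0, k2=0.25, k3=0.12, spill=0.3)
        ct, meas = model_tac(params, aif.times, aif.corrected(), aif.whole_blood)
        assert np.all(ct == 0.0)
        np.testing.assert_allclose(meas, 0.3 * aif.whole_blood)

    def test_full_spill_equals_frame_averaged_blood(self, aif):
        sched = FrameSchedule.default().truncated(600.0)
        params = CompartmentParams(K1=0.6, k2=0.25, k3=0.12, spill=1.0)
        _, meas = model_tac(params, aif.times, aif.corrected(), aif.whole_blood, sched)
        W = frame_average_matrix(aif.times, sched)
        np.testing.assert_allclose(meas, W @ aif.whole_blood)

    def test_linearity_in_arterial_input(self, aif):
        params = CompartmentParams(K1=0.6, k2=0.25, k3=0.12, spill=0.0)
        ct1 = tissue_curve(params, aif.times, aif.corrected())
        ct2 = tissue_curve(params, aif.times, 2.0 * aif.corrected())
        np.testing.assert_allclose(ct2, 2.0 * ct1, rtol=1e-12)

    def test_unit_impulse_trapping_limit(self):
        # tissue(t -> inf) after a unit-area bolus is K1*k3/(k2+k3)
        t = np.arange(0.0, 3600.0, 0.5)
        dt_min = 0.5 / 60.0
        ca = np.zeros_like(t)
        ca[1] = 1.0 / dt_min  # unit area in minute units
        params = CompartmentParams(K1=0.6, k2=0.2, k3=0.1, spill=0.0)
        ct = tissue_curve(params, t, ca)
        assert ct[-1] == pytest.approx(0.6 * 0.1 / 0.3, rel=1e-3)

    def test_k2_k3_zero_analytic_limit(self, aif):
        params = CompartmentParams(K1=0.5, k2=0.0, k3=0.0, spill=0.0)
        ct = tissue_curve(params, aif.times, aif.corrected())
        from scipy.integrate import cumulative_trapezoid

        expected = 0.5 * cumulative_trapezoid(
            aif.corrected(), dx=0.5 / 60.0, initial=0.0
        )
        np.testing.assert_allclose(ct, expected, rtol=1e-12)

    def test_against_dense_convolution_oracle(self, aif):
        # exponential-propagation filter vs direct trapezoid convolution
        params = CompartmentParams(K1=0.6, k2=0.25, k3=0.12, spill=0.0)
        ct = tissue_curve(params, aif.times, aif.corrected())
        t_min = aif.times / 60.0
        dt_min = t_min[1] - t_min[0]
        lam = params.k2 + params.k3
        h = params.K1 * (params.k3 + params.k2 * np.exp(-lam * t_min)) / lam
        ca = aif.corrected()
        n = t_min.size
        dense = dt_min * (
            np.convolve(ca, h)[:n] - 0.5 * (ca[0] * h + ca * h[0])
        )
        np.testing.assert_allclose(ct, dense, rtol=2e-4, atol=1e-3)


def _noiseless_tac(aif, params, sched=None):
    sched = sched or FrameSchedule.default().truncated(600.0)
    _, frames = model_tac(params, aif.times, aif.corrected(), aif.whole_blood, sched)
    return TimeActivityCurve(sched, frames, region="septal")


class TestFit:
    def test_noiseless_round_trip_recovery(self, aif):
        truth = CompartmentParams(K1=0.6, k2=0.25, k3=0.12, spill=0.3)
        sched = FrameSchedule.default().truncated(600.0)
        tac = _noiseless_tac(aif, truth, sched)
        fit = fit_region(tac, aif.times, aif.whole_blood, aif.metabolite_fraction)
        assert fit.converged
        assert fit.params.K1 == pytest.approx(truth.K1, rel=1e-3)
        assert fit.params.k2 == pytest.approx(truth.k2, rel=1e-3)
        assert fit.params.k3 == pytest.approx(truth.k3, rel=1e-3)
        assert fit.params.spill == pytest.approx(truth.spill, rel=1e-3)
        assert fit.mbf == fit.params.K1

    def test_blood_only_tac_gives_zero_flow(self, aif):
        sched = FrameSchedule.default().truncated(600.0)
        W = frame_average_matrix(aif.times, sched)
        tac = TimeActivityCurve(sched, 0.4 * (W @ aif.whole_blood), region="septal")
        fit = fit_region(tac, aif.times, aif.whole_blood, aif.metabolite_fraction)
        assert fit.params.K1 < 1e-3

    def test_all_zero_tac_converges_to_zero_flow(self, aif):
        sched = FrameSchedule.default().truncated(600.0)
        tac = TimeActivityCurve(sched, np.zeros(sched.n_frames), region="septal")
        fit = fit_region(tac, aif.times, aif.whole_blood, aif.metabolite_fraction)
        assert fit.converged
        assert fit.params.K1 == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_true_flow(self, aif):
        fitted = []
        for k1 in (0.3, 0.6, 1.2):
            tac = _noiseless_tac(
                aif, CompartmentParams(K1=k1, k2=0.25, k3=0.12, spill=0.3)
            )
            fitted.append(
                fit_region(
                    tac, aif.times, aif.whole_blood, aif.metabolite_fraction
                ).params.K1
            )
        assert fitted[0] < fitted[1] < fitted[2]

    def test_late_frames_do_not_change_fit(self):
        # identical data within 10 min; frames beyond are ignored entirely
        t_full = np.arange(0.0, 1800.0 + 0.25, 0.5)
        aif_full = sc.make_input_function(t_full, sc.AifShape())
        truth = CompartmentParams(K1=0.8, k2=0.25, k3=0.12, spill=0.3)
        full_sched = FrameSchedule.default()
        tac_full = _noiseless_tac(aif_full, truth, full_sched)
        fit_full = fit_region(
            tac_full, aif_full.times, aif_full.whole_blood, aif_full.metabolite_fraction
        )
        short_sched = full_sched.truncated(600.0)
        tac_short = TimeActivityCurve(short_sched, tac_full.values[:19], region="septal")
        fit_short = fit_region(
            tac_short, aif_full.times, aif_full.whole_blood, aif_full.metabolite_fraction
        )
        assert fit_full.n_frames_used == fit_short.n_frames_used == 19
        assert fit_full.params.K1 == pytest.approx(fit_short.params.K1, rel=1e-9)

    def test_mean_recovery_under_default_noise(self, aif):
        # bias check: many noisy realizations at K1 = 0.6
        truth = CompartmentParams(K1=0.6, k2=0.25, k3=0.12, spill=0.3)
        sched = FrameSchedule.default().truncated(600.0)
        _, clean = model_tac(
            truth, aif.times, aif.corrected(), aif.whole_blood, sched
        )
        rng = np.random.default_rng(2024)
        sigma = 1.0 * np.sqrt(np.maximum(clean, 1e-6) / sched.durations)
        fitted = []
        for _ in range(200):
            tac = TimeActivityCurve(sched, clean + rng.normal(0.0, sigma), "septal")
            fitted.append(
                fit_region(
                    tac, aif.times, aif.whole_blood, aif.metabolite_fraction
                ).params.K1
            )
        assert np.mean(fitted) == pytest.approx(0.6, rel=0.05)


class TestMbfSlr:
    def test_equal_walls(self):
        assert mbf_slr(0.8, 0.8) == 1.0

    def test_published_group_means_quotient(self):
        assert mbf_slr(0.57, 0.92) == pytest.approx(0.6196, abs=5e-5)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            mbf_slr(0.5, 0.0)


def test_tac_and_aif_csv_interfaces(tmp_path, noiseless_cohort):
    outdir = tmp_path / "cohort"
    sc.write_cohort(noiseless_cohort, outdir)
    pid = noiseless_cohort.records[0].id
    tacs = read_tacs_csv(outdir / f"{pid}_tacs.csv")
    assert set(tacs) == {"septal", "lateral", "anterior", "inferior"}
    t, wb, mf = read_aif_csv(outdir / "aif.csv")
    fit = fit_region(tacs["septal"], t, wb, mf)
    assert fit.params.K1 == pytest.approx(
        noiseless_cohort.records[0].true_mbf["septal"], rel=1e-3
    )
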