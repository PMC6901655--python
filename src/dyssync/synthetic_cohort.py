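"""Seeded synthetic cohorts calibrated to published group distributions.

Every downstream stage of the package (kinetic fitting, polar-map
regionalization, work-loop integration, cohort statistics) is exercised on
synthetic patients generated here.  The generator's defaults reproduce the
study conditions of the source cohort: 23 patients with mechanical
dyssynchrony and 7 without; dyssynchrony-group septal/lateral MBF of
0.57 +/- 0.11 and 0.92 +/- 0.23 ml/g/min (0.61 +/- 0.23 / 0.77 +/- 0.21
without dyssynchrony); lateral FDG SUVmean 11.19 +/- 4.10 with per-patient
FDG SLR 0.5 +/- 0.1 (8.31 +/- 2.50 and 0.9 +/- 0.2 without); septal/lateral
regional work 370 +/- 816 and 3174 +/- 1033 mmHg*% (2017 +/- 685 /
2267 +/- 572), with septal work negative in 40% of dyssynchrony patients and
never otherwise; Delta LV ESV 47 +/- 14% vs -3 +/- 20%, coupled to the FDG
SLR so the pooled Pearson correlation is -0.62 in expectation.

Construction notes
------------------
* Septal FDG is built as (per-patient SLR) x (lateral SUV), both drawn, so
  the printed wall means and SLR means hold jointly; anterior/inferior walls
  are the septal-lateral midpoint plus jitter (no published values).
* Within-wall segment jitter is re-centered to zero mean, so wall means (and
  hence SLRs) round-trip exactly through the regional analysis.
* Dyssynchrony-group septal work is a two-component mixture (negative
  half-normal with weight = target negative fraction, plus a positive
  truncated normal calibrated numerically to the printed mean/SD); a single
  normal cannot satisfy mean, SD and the 40% negative fraction jointly.
* Delta ESV is generated per group as intercept + slope*(FDG SLR) + noise,
  with a common slope solved analytically from the target pooled
  correlation and the configured group moments.
* Non-positive draws of strictly positive quantities are redrawn
  (truncation); Delta ESV is untruncated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from dyssync import fdg_regional, myocardial_work
from dyssync.fdg_regional import PolarMap17, WallRegions
from dyssync.myocardial_work import (
    LEVELS,
    SUB_WALLS,
    SEPTAL_SUB_WALLS,
    LATERAL_SUB_WALLS,
    PressureTemplate,
    SegmentTraces,
    ValveEvents,
    estimate_lv_pressure,
)
from dyssync.nh3_kinetics import (
    CompartmentParams,
    FrameSchedule,
    TimeActivityCurve,
    FINE_GRID_STEP_S,
    frame_average_matrix,
    metabolite_correct,
    tissue_curve,
)

WALLS = ("septal", "lateral", "anterior", "inferior")


class CalibrationError(RuntimeError):
    """Raised when a configured distribution target is unreachable."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GroupStat:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class MbfParams:
    """Per-group per-wall resting MBF (ml/g/min)."""

    dys_septal: GroupStat = GroupStat(0.57, 0.11)
    dys_lateral: GroupStat = GroupStat(0.92, 0.23)
    nondys_septal: GroupStat = GroupStat(0.61, 0.23)
    nondys_lateral: GroupStat = GroupStat(0.77, 0.21)
    lower: float = 0.1  # redraw below this flow
    cross_wall_jitter_sd: float = 0.05  # anterior/inferior around the midpoint


@dataclass(frozen=True)
class FdgParams:
    """Per-group lateral-wall SUV and per-patient FDG SLR (dimensionless)."""

    dys_lateral: GroupStat = GroupStat(11.19, 4.10)
    dys_slr: GroupStat = GroupStat(0.5, 0.1)
    nondys_lateral: GroupStat = GroupStat(8.31, 2.50)
    nondys_slr: GroupStat = GroupStat(0.9, 0.2)
    suv_lower: float = 0.1
    slr_lower: float = 0.05
    cross_wall_jitter_sd: float = 0.5


@dataclass(frozen=True)
class WorkParams:
    """Per-group per-wall regional work density (mmHg*%)."""

    dys_septal: GroupStat = GroupStat(370.0, 816.0)
    dys_lateral: GroupStat = GroupStat(3174.0, 1033.0)
    nondys_septal: GroupStat = GroupStat(2017.0, 685.0)
    nondys_lateral: GroupStat = GroupStat(2267.0, 572.0)
    dys_septal_negative_fraction: float = 0.40
    negative_scale: float = 500.0  # half-normal scale of the wasted-work component
    cross_wall_jitter_sd: float = 300.0
    segment_jitter_sd: float = 150.0


@dataclass(frozen=True)
class DesvParams:
    """Delta LV ESV (%) per group, coupled to FDG SLR."""

    dys: GroupStat = GroupStat(47.0, 14.0)
    nondys: GroupStat = GroupStat(-3.0, 20.0)
    target_corr: float = -0.62  # pooled Pearson r with FDG SLR
    esv_pre: GroupStat = GroupStat(115.0, 35.0)  # ml, baseline end-systolic volume
    esv_pre_lower: float = 30.0


@dataclass(frozen=True)
class KineticDefaults:
    """Forward-model constants for TAC synthesis."""

    k2_per_min: float = 0.25
    k3_per_min: float = 0.12
    spill: Mapping[str, float] = field(
        default_factory=lambda: {
            "septal": 0.35,
            "lateral": 0.25,
            "anterior": 0.25,
            "inferior": 0.25,
        }
    )

    def __post_init__(self) -> None:
        for wall, s in self.spill.items():
            if not 0 <= s < 1:
                raise ValueError(f"spill fraction for {wall!r} must be in [0, 1)")


@dataclass(frozen=True)
class AifShape:
    """Gamma-variate bolus A*(t-t0)^alpha*exp(-(t-t0)/beta), peak-normalized."""

    peak_kbq_ml: float = 100.0
    alpha: float = 2.0
    beta_s: float = 12.0
    t0_s: float = 10.0
    metabolite_onset_s: float = 120.0
    metabolite_plateau: float = 0.5
    metabolite_plateau_time_s: float = 600.0


@dataclass(frozen=True)
class NoiseParams:
    tac_noise_scale: float = 1.0  # kBq/ml per sqrt(kBq/ml per s)
    suv_segment_jitter_sd: float = 0.4


@dataclass(frozen=True)
class CohortConfig:
    n_dys: int = 23
    n_nondys: int = 7
    seed: int = 0
    mbf: MbfParams = field(default_factory=MbfParams)
    fdg: FdgParams = field(default_factory=FdgParams)
    work: WorkParams = field(default_factory=WorkParams)
    desv: DesvParams = field(default_factory=DesvParams)
    kinetics: KineticDefaults = field(default_factory=KineticDefaults)
    aif: AifShape = field(default_factory=AifShape)
    noise: NoiseParams = field(default_factory=NoiseParams)
    reader_error: float = 0.035  # per-reader flip probability
    sbp_dys: GroupStat = GroupStat(134.0, 21.0)
    sbp_nondys: GroupStat = GroupStat(120.0, 28.0)
    sbp_lower: float = 80.0
    cycle_length_s: float = 1.0
    valve_events: ValveEvents = ValveEvents(mvc=0.05, avo=0.10, avc=0.42, mvo=0.50)
    trace_samples: int = 501
    wall_thickness_mm: float = 10.0
    strain_amplitude_pct: float = 10.0
    max_stress_mmHg: float = 2000.0
    artifacts: tuple[str, ...] = ("tacs", "polar_map", "traces")

    def __post_init__(self) -> None:
        if self.n_dys + self.n_nondys < 2:
            raise ValueError("cohort must have at least 2 patients")
        if self.n_dys < 0 or self.n_nondys < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0 <= self.reader_error < 0.5:
            raise ValueError("reader error must lie in [0, 0.5)")
        unknown = set(self.artifacts) - {"tacs", "polar_map", "traces"}
        if unknown:
            raise ValueError(f"unknown artifacts: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# patient record and cohort container


@dataclass
class PatientRecord:
    id: str
    dyssynchrony: bool
    true_mbf: dict[str, float]  # per wall, ml/g/min
    true_suv: np.ndarray  # 17 segments
    true_wall_suv: dict[str, float]
    true_fdg_slr: float
    true_work: dict[str, float]  # per wall, mmHg*%
    true_segment_work: dict[tuple[str, str], float]  # 18-segment prescription
    delta_esv: float  # %
    esv_pre: float  # ml
    esv_post: float  # ml
    reader_labels: tuple[bool, bool]
    sbp: float  # mmHg
    valve_events: ValveEvents
    cycle_length: float

    def __post_init__(self) -> None:
        if self.esv_pre <= 0:
            raise ValueError("esv_pre must be positive")
        expected = 100.0 * (self.esv_pre - self.esv_post) / self.esv_pre
        if abs(expected - self.delta_esv) > 1e-6:
            raise ValueError("delta_esv inconsistent with esv_pre/esv_post")
        if any(v <= 0 for v in self.true_mbf.values()):
            raise ValueError("true MBF must be positive")


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood input curve with its metabolite contamination fraction."""

    times: np.ndarray  # s
    whole_blood: np.ndarray  # kBq/ml
    metabolite_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        wb = np.asarray(self.whole_blood, dtype=float)
        mf = np.asarray(self.metabolite_fraction, dtype=float)
        if not (t.shape == wb.shape == mf.shape):
            raise ValueError("times, whole_blood, metabolite_fraction must align")
        if np.any(wb < 0):
            raise ValueError("whole-blood activity must be non-negative")
        if np.any(mf < 0) or np.any(mf >= 1):
            raise ValueError("metabolite fraction must lie in [0, 1)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "whole_blood", wb)
        object.__setattr__(self, "metabolite_fraction", mf)

    def corrected(self) -> np.ndarray:
        return metabolite_correct(self.whole_blood, self.metabolite_fraction)


@dataclass
class SyntheticPatient:
    record: PatientRecord
    input_function: InputFunction | None = None
    tacs: dict[str, TimeActivityCurve] | None = None
    polar_map: PolarMap17 | None = None
    traces: SegmentTraces | None = None


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[SyntheticPatient]

    @property
    def records(self) -> list[PatientRecord]:
        return [p.record for p in self.patients]


# ---------------------------------------------------------------------------
# elementary generators


def gamma_variate(
    times_s: np.ndarray, peak: float, alpha: float, beta_s: float, t0_s: float
) -> np.ndarray:
    """Peak-normalized gamma-variate bolus; 0 before t0, mode at t0 + alpha*beta."""
    if alpha <= 0 or beta_s <= 0:
        raise ValueError("gamma-variate shape needs alpha > 0 and beta > 0")
    t = np.asarray(times_s, dtype=float)
    out = np.zeros_like(t)
    m = t > t0_s
    tau = t[m] - t0_s
    norm = (alpha * beta_s) ** alpha * math.exp(-alpha)  # value at the mode
    out[m] = peak * tau**alpha * np.exp(-tau / beta_s) / norm
    return out


def metabolite_fraction_curve(times_s: np.ndarray, shape: AifShape) -> np.ndarray:
    """0 before the onset (default 120 s), linear rise, then plateau."""
    t = np.asarray(times_s, dtype=float)
    rise = (t - shape.metabolite_onset_s) / (
        shape.metabolite_plateau_time_s - shape.metabolite_onset_s
    )
    return shape.metabolite_plateau * np.clip(rise, 0.0, 1.0)


def make_input_function(times_s: np.ndarray, shape: AifShape) -> InputFunction:
    """Whole-blood input whose metabolite correction recovers the true arterial
    gamma-variate exactly: whole_blood = arterial / (1 - fraction)."""
    arterial = gamma_variate(times_s, shape.peak_kbq_ml, shape.alpha, shape.beta_s, shape.t0_s)
    frac = metabolite_fraction_curve(times_s, shape)
    return InputFunction(times_s, arterial / (1.0 - frac), frac)


def _truncated_normal(
    rng: np.random.Generator, stat: GroupStat, lower: float, max_redraws: int = 10_000
) -> float:
    """Draw N(mean, sd) redrawing values <= `lower` (documented truncation)."""
    if stat.sd == 0:
        if stat.mean <= lower:
            raise CalibrationError(
                f"degenerate draw {stat.mean} at or below lower bound {lower}"
            )
        return stat.mean
    for _ in range(max_redraws):
        x = rng.normal(stat.mean, stat.sd)
        if x > lower:
            return float(x)
    raise CalibrationError("truncated draw failed: lower bound too high for the mean/SD")


def _centered_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Zero-mean jitter (re-centered), so group targets survive aggregation."""
    if sd == 0 or n < 2:
        return np.zeros(n)
    j = rng.normal(0.0, sd, size=n)
    return j - j.mean()


# ---------------------------------------------------------------------------
# numeric calibrations


@dataclass(frozen=True)
class WorkMixture:
    """Calibrated mixture for dyssynchrony-group septal work.

    With probability `negative_fraction` the work is a negative half-normal
    of scale `negative_scale`; otherwise a normal with (positive_mean,
    positive_sd) truncated to (0, inf).  Calibrated so the mixture mean and
    SD match the configured targets.
    """

    negative_fraction: float
    negative_scale: float
    positive_mean: float
    positive_sd: float

    def moments(self) -> tuple[float, float]:
        f, s = self.negative_fraction, self.negative_scale
        a = -self.positive_mean / self.positive_sd
        pos = stats.truncnorm(a, np.inf, loc=self.positive_mean, scale=self.positive_sd)
        mu_n = -s * math.sqrt(2.0 / math.pi)
        mean = f * mu_n + (1 - f) * pos.mean()
        ex2 = f * s**2 + (1 - f) * (pos.var() + pos.mean() ** 2)
        return mean, math.sqrt(ex2 - mean**2)

    def draw(self, rng: np.random.Generator) -> float:
        if rng.random() < self.negative_fraction:
            return float(-abs(rng.normal(0.0, self.negative_scale)))
        while True:
            x = rng.normal(self.positive_mean, self.positive_sd)
            if x > 0:
                return float(x)


def calibrate_work_mixture(
    target: GroupStat, negative_fraction: float, negative_scale: float
) -> WorkMixture:
    """Solve the positive component's (mean, sd) to hit the target moments.

    Starts from the closed-form solution that ignores the positive
    truncation, then refines numerically against the truncated moments.
    Raises CalibrationError if the achieved moments are > 5% off.
    """
    if not 0 < negative_fraction < 1:
        raise CalibrationError("negative fraction must lie in (0, 1)")
    f, s = negative_fraction, negative_scale
    mu_n = -s * math.sqrt(2.0 / math.pi)
    m_p0 = (target.mean - f * mu_n) / (1 - f)
    ex2_needed = (target.sd**2 + target.mean**2 - f * s**2) / (1 - f)
    var0 = ex2_needed - m_p0**2
    if var0 <= 0:
        raise CalibrationError(
            "target mean/SD unreachable with the configured negative component"
        )

    def misfit(x: np.ndarray) -> np.ndarray:
        mix = WorkMixture(f, s, float(x[0]), float(abs(x[1])))
        mean, sd = mix.moments()
        return np.array([mean - target.mean, sd - target.sd])

    sol = optimize.least_squares(misfit, x0=np.array([m_p0, math.sqrt(var0)]))
    mix = WorkMixture(f, s, float(sol.x[0]), float(abs(sol.x[1])))
    mean, sd = mix.moments()
    if abs(mean - target.mean) > 0.05 * max(abs(target.mean), 1.0) or abs(
        sd - target.sd
    ) > 0.05 * target.sd:
        raise CalibrationError(
            f"work mixture calibration failed: achieved {mean:.1f} +/- {sd:.1f}, "
            f"target {target.mean} +/- {target.sd}"
        )
    return mix


@dataclass(frozen=True)
class DesvCoupling:
    """Delta ESV = group mean + slope*(SLR - group SLR mean) + N(0, resid_sd)."""

    slope: float
    resid_sd: dict[str, float]  # per group


def calibrate_desv_coupling(
    fdg: FdgParams, desv: DesvParams, n_dys: int, n_nondys: int
) -> DesvCoupling:
    """Solve the common within-group slope from the target pooled correlation.

    Pooled moments are computed from the configured group moments with the
    group weights of the cohort; the between-group separation already
    contributes most of the negative correlation, and the slope supplies the
    remainder.  Raises CalibrationError when the implied within-group
    residual variance is negative (target correlation unreachable).
    """
    n = n_dys + n_nondys
    w = {"dys": n_dys / n, "nondys": n_nondys / n}
    mx = {"dys": fdg.dys_slr.mean, "nondys": fdg.nondys_slr.mean}
    sx = {"dys": fdg.dys_slr.sd, "nondys": fdg.nondys_slr.sd}
    my = {"dys": desv.dys.mean, "nondys": desv.nondys.mean}
    sy = {"dys": desv.dys.sd, "nondys": desv.nondys.sd}

    mx_p = sum(w[g] * mx[g] for g in w)
    my_p = sum(w[g] * my[g] for g in w)
    var_x = sum(w[g] * (sx[g] ** 2 + (mx[g] - mx_p) ** 2) for g in w)
    var_y = sum(w[g] * (sy[g] ** 2 + (my[g] - my_p) ** 2) for g in w)
    between_cov = sum(w[g] * (mx[g] - mx_p) * (my[g] - my_p) for g in w)
    target_cov = desv.target_corr * math.sqrt(var_x * var_y)
    within_x = sum(w[g] * sx[g] ** 2 for g in w)
    if within_x <= 0:
        raise CalibrationError("SLR has zero within-group variance; cannot couple")
    slope = (target_cov - between_cov) / within_x

    resid_sd = {}
    for g in w:
        resid_var = sy[g] ** 2 - slope**2 * sx[g] ** 2
        if resid_var < 0:
            raise CalibrationError(
                "target correlation unreachable given the configured group "
                f"separation (residual variance negative in group {g!r})"
            )
        resid_sd[g] = math.sqrt(resid_var)
    return DesvCoupling(slope=slope, resid_sd=resid_sd)


# ---------------------------------------------------------------------------
# per-patient artifact synthesis


def make_polar_map(
    record: PatientRecord,
    rng: np.random.Generator,
    jitter_sd: float,
    regions: WallRegions | None = None,
) -> PolarMap17:
    """17-segment SUV map whose wall means equal the patient's wall values.

    Segment jitter is re-centered within each wall, so `wall_means` recovers
    the ground truth exactly; segment 17 (apex) carries the overall mean.
    """
    regions = regions or WallRegions.default()
    values = np.zeros(17)
    for wall, segs in regions.mapping.items():
        base = record.true_wall_suv[wall]
        jit = _centered_jitter(rng, len(segs), jitter_sd)
        if np.any(base + jit < 0):  # keep SUV non-negative without moving the mean
            jit = jit * 0.9 * base / max(-np.min(jit), 1e-12)
        for s, j in zip(segs, jit):
            values[s - 1] = base + j
    apex = float(np.mean(list(record.true_wall_suv.values())))
    values[16] = max(apex + rng.normal(0.0, jitter_sd), 0.0)
    return PolarMap17(values)


def make_tacs(
    record: PatientRecord,
    input_fn: InputFunction,
    kinetics: KineticDefaults,
    noise_scale: float,
    rng: np.random.Generator,
    schedule: FrameSchedule | None = None,
) -> dict[str, TimeActivityCurve]:
    """Forward two-tissue TACs per wall with spill mixing and frame noise.

    K1 is the wall's true MBF (unity extraction).  Noise is zero-mean
    Gaussian per frame with variance proportional to activity over frame
    duration; `noise_scale` = 0 reproduces the analytic forward model.
    """
    schedule = schedule or FrameSchedule.default()
    t = input_fn.times
    ca = input_fn.corrected()
    W = frame_average_matrix(t, schedule)
    wb_frames = W @ input_fn.whole_blood
    out: dict[str, TimeActivityCurve] = {}
    for wall, mbf in record.true_mbf.items():
        params = CompartmentParams(
            K1=mbf,
            k2=kinetics.k2_per_min,
            k3=kinetics.k3_per_min,
            spill=kinetics.spill[wall],
        )
        ct = tissue_curve(params, t, ca)
        frames = (1.0 - params.spill) * (W @ ct) + params.spill * wb_frames
        if noise_scale > 0:
            sigma = noise_scale * np.sqrt(
                np.maximum(frames, 1e-6) / schedule.durations
            )
            frames = frames + rng.normal(0.0, sigma)
        out[wall] = TimeActivityCurve(schedule, frames, region=wall)
    return out


def make_work_traces(
    record: PatientRecord,
    n_samples: int = 501,
    thickness_mm: float = 10.0,
    strain_amplitude_pct: float = 10.0,
    max_stress_mmHg: float = 2000.0,
    template: PressureTemplate | None = None,
) -> SegmentTraces:
    """Emit strain/thickness/curvature traces realizing the prescribed works.

    Each segment traces a stress-strain ellipse of the prescribed signed
    area: strain eps(t) = -a + a*cos(phi), stress sigma(t) = sigma0 +/-
    b*sin(phi) with phi sweeping one revolution over the cycle (area
    pi*a*b, orientation set by the work's sign).  Thickness is held
    constant and curvature is obtained by inverting the Laplace relation
    c(t) = P(t) / (2 h sigma(t)) against the patient's estimated pressure
    curve, so downstream stress reconstruction recovers sigma exactly.
    """
    template = template or PressureTemplate.default()
    times, pressure = estimate_lv_pressure(
        record.sbp,
        record.valve_events,
        record.cycle_length,
        n_samples=n_samples,
        template=template,
    )
    phi = 2.0 * np.pi * times / record.cycle_length
    a = strain_amplitude_pct
    strain, thickness, curvature = {}, {}, {}
    for seg, w in record.true_segment_work.items():
        if w == 0:
            eps = np.zeros_like(times)
            sigma = np.full_like(times, 100.0)
        else:
            b = abs(w) / (np.pi * a)
            sigma0 = max(100.0, b + 10.0)
            if sigma0 + b > max_stress_mmHg:
                raise ValueError(
                    f"prescribed work {w:.0f} mmHg*% cannot be realized with "
                    f"stress below {max_stress_mmHg} mmHg"
                )
            eps = -a + a * np.cos(phi)
            sigma = sigma0 + np.sign(w) * b * np.sin(phi)
        strain[seg] = eps
        thickness[seg] = np.full_like(times, thickness_mm)
        curvature[seg] = pressure / (2.0 * thickness_mm * sigma)
    return SegmentTraces(
        times=times,
        strain_pct=strain,
        thickness_mm=thickness,
        curvature_per_mm=curvature,
        sbp=record.sbp,
        events=record.valve_events,
        cycle_length=record.cycle_length,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_record(
    idx: int,
    dys: bool,
    cfg: CohortConfig,
    work_mixture: WorkMixture,
    coupling: DesvCoupling,
    rng: np.random.Generator,
) -> PatientRecord:
    g = "dys" if dys else "nondys"
    mbf_sep = _truncated_normal(
        rng, cfg.mbf.dys_septal if dys else cfg.mbf.nondys_septal, cfg.mbf.lower
    )
    mbf_lat = _truncated_normal(
        rng, cfg.mbf.dys_lateral if dys else cfg.mbf.nondys_lateral, cfg.mbf.lower
    )
    mid = 0.5 * (mbf_sep + mbf_lat)
    true_mbf = {
        "septal": mbf_sep,
        "lateral": mbf_lat,
        "anterior": _truncated_normal(
            rng, GroupStat(mid, cfg.mbf.cross_wall_jitter_sd), cfg.mbf.lower
        ),
        "inferior": _truncated_normal(
            rng, GroupStat(mid, cfg.mbf.cross_wall_jitter_sd), cfg.mbf.lower
        ),
    }

    suv_lat = _truncated_normal(
        rng, cfg.fdg.dys_lateral if dys else cfg.fdg.nondys_lateral, cfg.fdg.suv_lower
    )
    slr = _truncated_normal(
        rng, cfg.fdg.dys_slr if dys else cfg.fdg.nondys_slr, cfg.fdg.slr_lower
    )
    suv_sep = slr * suv_lat
    suv_mid = 0.5 * (suv_sep + suv_lat)
    true_wall_suv = {
        "septal": suv_sep,
        "lateral": suv_lat,
        "anterior": _truncated_normal(
            rng, GroupStat(suv_mid, cfg.fdg.cross_wall_jitter_sd), cfg.fdg.suv_lower
        ),
        "inferior": _truncated_normal(
            rng, GroupStat(suv_mid, cfg.fdg.cross_wall_jitter_sd), cfg.fdg.suv_lower
        ),
    }

    if dys:
        work_sep = work_mixture.draw(rng)
        work_lat = _truncated_normal(rng, cfg.work.dys_lateral, 0.0)
    else:
        work_sep = _truncated_normal(rng, cfg.work.nondys_septal, 0.0)
        work_lat = _truncated_normal(rng, cfg.work.nondys_lateral, 0.0)
    work_mid = 0.5 * (work_sep + work_lat)
    true_work = {
        "septal": work_sep,
        "lateral": work_lat,
        "anterior": work_mid + rng.normal(0.0, cfg.work.cross_wall_jitter_sd),
        "inferior": work_mid + rng.normal(0.0, cfg.work.cross_wall_jitter_sd),
    }
    # 18-segment prescription: jitter re-centered over each principal wall
    seg_work: dict[tuple[str, str], float] = {}
    groups = {
        "septal": [(sw, lvl) for sw in SEPTAL_SUB_WALLS for lvl in LEVELS],
        "lateral": [(sw, lvl) for sw in LATERAL_SUB_WALLS for lvl in LEVELS],
        "anterior": [("anterior", lvl) for lvl in LEVELS],
        "inferior": [("inferior", lvl) for lvl in LEVELS],
    }
    for wall, segs in groups.items():
        jit = _centered_jitter(rng, len(segs), cfg.work.segment_jitter_sd)
        for (sw, lvl), j in zip(segs, jit):
            seg_work[(sw, lvl)] = true_work[wall] + j

    desv_stat = cfg.desv.dys if dys else cfg.desv.nondys
    slr_stat = cfg.fdg.dys_slr if dys else cfg.fdg.nondys_slr
    delta = (
        desv_stat.mean
        + coupling.slope * (slr - slr_stat.mean)
        + rng.normal(0.0, coupling.resid_sd[g])
    )
    esv_pre = _truncated_normal(rng, cfg.desv.esv_pre, cfg.desv.esv_pre_lower)
    esv_post = esv_pre * (1.0 - delta / 100.0)

    sbp = _truncated_normal(rng, cfg.sbp_dys if dys else cfg.sbp_nondys, cfg.sbp_lower)
    readers = tuple(
        bool(dys) ^ bool(rng.random() < cfg.reader_error) for _ in range(2)
    )
    return PatientRecord(
        id=f"P{idx:03d}",
        dyssynchrony=dys,
        true_mbf=true_mbf,
        true_suv=np.array([]),  # filled by make_polar_map path below
        true_wall_suv=true_wall_suv,
        true_fdg_slr=slr,
        true_work=true_work,
        true_segment_work=seg_work,
        delta_esv=float(delta),
        esv_pre=float(esv_pre),
        esv_post=float(esv_post),
        reader_labels=readers,  # type: ignore[arg-type]
        sbp=float(sbp),
        valve_events=cfg.valve_events,
        cycle_length=cfg.cycle_length_s,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministically from the seed.

    Returns patients in order: all dyssynchrony patients first, then the
    non-dyssynchrony group.  `config.artifacts` controls which per-patient
    artifacts (TACs, polar map, work traces) are materialized; ground-truth
    records are always produced.
    """
    work_mixture = calibrate_work_mixture(
        config.work.dys_septal,
        config.work.dys_septal_negative_fraction,
        config.work.negative_scale,
    )
    coupling = calibrate_desv_coupling(
        config.fdg, config.desv, config.n_dys, config.n_nondys
    )

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_dys + config.n_nondys)
    schedule = FrameSchedule.default()
    total_s = schedule.frame_end[-1]
    aif_times = np.arange(0.0, total_s + FINE_GRID_STEP_S / 2, FINE_GRID_STEP_S)
    input_fn = make_input_function(aif_times, config.aif)

    patients: list[SyntheticPatient] = []
    flags = [True] * config.n_dys + [False] * config.n_nondys
    for idx, (dys, ss) in enumerate(zip(flags, streams)):
        rng = np.random.default_rng(ss)
        record = _draw_record(idx, dys, config, work_mixture, coupling, rng)
        patient = SyntheticPatient(record=record, input_function=input_fn)
        if "polar_map" in config.artifacts:
            patient.polar_map = make_polar_map(
                record, rng, config.noise.suv_segment_jitter_sd
            )
            record.true_suv = patient.polar_map.values.copy()
        if "tacs" in config.artifacts:
            patient.tacs = make_tacs(
                record,
                input_fn,
                config.kinetics,
                config.noise.tac_noise_scale,
                rng,
                schedule,
            )
        if "traces" in config.artifacts:
            patient.traces = make_work_traces(
                record,
                n_samples=config.trace_samples,
                thickness_mm=config.wall_thickness_mm,
                strain_amplitude_pct=config.strain_amplitude_pct,
                max_stress_mmHg=config.max_stress_mmHg,
            )
        patients.append(patient)
    return Cohort(config=config, patients=patients)


# ---------------------------------------------------------------------------
# file interfaces


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Persist the cohort under `outdir`; returns the manifest path.

    Layout: manifest.json plus per-patient ``{id}_tacs.csv``,
    ``{id}_polarmap.csv``, ``{id}_traces.csv`` / ``{id}_traces.json``, and a
    shared ``aif.csv``.  Identical config+seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cohort.config.seed, "patients": []}
    aif_written = False
    for p in cohort.patients:
        rec = p.record
        entry = {
            "id": rec.id,
            "dyssynchrony": rec.dyssynchrony,
            "true_mbf": rec.true_mbf,
            "true_wall_suv": rec.true_wall_suv,
            "true_fdg_slr": rec.true_fdg_slr,
            "true_work": rec.true_work,
            "delta_esv": rec.delta_esv,
            "esv_pre": rec.esv_pre,
            "esv_post": rec.esv_post,
            "reader_labels": list(rec.reader_labels),
            "sbp": rec.sbp,
            "cycle_length_s": rec.cycle_length,
            "valve_events_s": rec.valve_events.as_dict(),
        }
        manifest["patients"].append(entry)
        if p.input_function is not None and not aif_written:
            pd.DataFrame(
                {
                    "time_s": p.input_function.times,
                    "whole_blood": p.input_function.whole_blood,
                    "metabolite_fraction": p.input_function.metabolite_fraction,
                }
            ).to_csv(outdir / "aif.csv", index=False, float_format="%.10g")
            aif_written = True
        if p.tacs is not None:
            sched = next(iter(p.tacs.values())).schedule
            df = pd.DataFrame(
                {"frame_start_s": sched.frame_start, "frame_end_s": sched.frame_end}
            )
            W = frame_average_matrix(p.input_function.times, sched)
            df["whole_blood"] = W @ p.input_function.whole_blood
            for wall in WALLS:
                df[wall] = p.tacs[wall].values
            df.to_csv(outdir / f"{rec.id}_tacs.csv", index=False, float_format="%.10g")
        if p.polar_map is not None:
            fdg_regional.write_polar_map_csv(p.polar_map, outdir / f"{rec.id}_polarmap.csv")
        if p.traces is not None:
            myocardial_work.write_traces(
                p.traces,
                outdir / f"{rec.id}_traces.csv",
                outdir / f"{rec.id}_traces.json",
            )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
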