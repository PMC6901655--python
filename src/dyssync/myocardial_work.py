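"""Segmental myocardial work from noninvasive stress-strain loops.

Myocardial work per unit volume is estimated segment by segment as the signed
area of the loop traced by Laplace wall stress against longitudinal strain
over one cardiac cycle.  The LV pressure curve is not measured invasively:
a fixed normalized reference waveform is time-warped to the patient's valve
event times (mitral valve closure MVC, aortic valve opening AVO, aortic valve
closure AVC, mitral valve opening MVO) and scaled to the brachial systolic
pressure.  Wall stress follows the spherical Laplace relation

    sigma(t) = P(t) / (2 * c(t) * h(t))

with ``c`` the mid-wall curvature (1/mm, radius = 1/c) and ``h`` the wall
thickness (mm).  Work is ``-closed-integral sigma d eps`` with strain in
percent on the abscissa, so shortening under high stress is positive and
systolic stretching yields negative ("wasted") work.

Segments follow an 18-segment model: 6 walls (anterior, anteroseptal,
inferoseptal, inferior, inferolateral, anterolateral) x 3 levels (basal, mid,
apical).  Regional work per wall is the mean of the wall's three level
segments; the septum is the mean of the two septal walls (anteroseptal +
inferoseptal) unless a single "septal" wall is supplied directly, and
likewise for the lateral wall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SUB_WALLS = (
    "anterior",
    "anteroseptal",
    "inferoseptal",
    "inferior",
    "inferolateral",
    "anterolateral",
)
LEVELS = ("basal", "mid", "apical")

SEPTAL_SUB_WALLS = ("anteroseptal", "inferoseptal")
LATERAL_SUB_WALLS = ("inferolateral", "anterolateral")


@dataclass(frozen=True)
class ValveEvents:
    """Valve event times (s) within one cycle: 0 <= mvc < avo < avc < mvo < T."""

    mvc: float
    avo: float
    avc: float
    mvo: float

    def validate(self, cycle_length: float) -> None:
        if not (0 <= self.mvc < self.avo < self.avc < self.mvo < cycle_length):
            raise ValueError(
                "valve events must satisfy 0 <= mvc < avo < avc < mvo < cycle length, "
                f"got {self} with cycle length {cycle_length}"
            )

    def as_dict(self) -> dict[str, float]:
        return {"mvc": self.mvc, "avo": self.avo, "avc": self.avc, "mvo": self.mvo}


@dataclass(frozen=True)
class PressureTemplate:
    """Normalized piecewise-cosine LV pressure reference waveform.

    ``diastolic_mmHg`` is the absolute low-pressure plateau outside the
    MVC-MVO interval.  The systolic part is expressed in fractions of the
    peak amplitude: the isovolumic rise reaches ``aortic_opening_frac`` at
    AVO, the dome peaks at 1.0 at fraction ``peak_position_frac`` of the
    AVO-AVC interval, ejection ends at ``aortic_closure_frac`` at AVC, and
    the isovolumic fall returns to the plateau at MVO.
    """

    diastolic_mmHg: float = 5.0
    aortic_opening_frac: float = 0.65
    aortic_closure_frac: float = 0.45
    peak_position_frac: float = 0.4

    @classmethod
    def default(cls) -> "PressureTemplate":
        raw = json.loads(
            resources.files("dyssync.data").joinpath("pressure_template.json").read_text()
        )
        return cls(
            diastolic_mmHg=raw["diastolic_mmHg"],
            aortic_opening_frac=raw["aortic_opening_frac"],
            aortic_closure_frac=raw["aortic_closure_frac"],
            peak_position_frac=raw["peak_position_frac"],
        )

    def normalized(self, times: np.ndarray, events: ValveEvents) -> np.ndarray:
        """Normalized systolic amplitude in [0, 1] at `times` (plateau = 0)."""
        t = np.asarray(times, dtype=float)
        w = np.zeros_like(t)
        w_ao, w_ac, u_pk = (
            self.aortic_opening_frac,
            self.aortic_closure_frac,
            self.peak_position_frac,
        )
        # isovolumic rise MVC -> AVO
        m = (t >= events.mvc) & (t < events.avo)
        u = (t[m] - events.mvc) / (events.avo - events.mvc)
        w[m] = w_ao * 0.5 * (1.0 - np.cos(np.pi * u))
        # ejection dome AVO -> AVC, peaking at fraction u_pk of the interval
        m = (t >= events.avo) & (t < events.avc)
        u = (t[m] - events.avo) / (events.avc - events.avo)
        rising = u < u_pk
        w_dome = np.empty_like(u)
        w_dome[rising] = w_ao + (1.0 - w_ao) * np.sin(np.pi * u[rising] / (2.0 * u_pk))
        w_dome[~rising] = w_ac + (1.0 - w_ac) * np.cos(
            np.pi * (u[~rising] - u_pk) / (2.0 * (1.0 - u_pk))
        )
        w[m] = w_dome
        # isovolumic fall AVC -> MVO
        m = (t >= events.avc) & (t < events.mvo)
        u = (t[m] - events.avc) / (events.mvo - events.avc)
        w[m] = w_ac * 0.5 * (1.0 + np.cos(np.pi * u))
        return w


def estimate_lv_pressure(
    sbp: float,
    events: ValveEvents,
    cycle_length: float,
    times: np.ndarray | None = None,
    n_samples: int = 501,
    template: PressureTemplate | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noninvasive LV pressure curve over one cycle.

    The normalized template is time-warped so its landmarks coincide with
    `events` and scaled so its maximum equals `sbp` exactly; before MVC and
    after MVO the curve sits at the template's diastolic plateau.

    Returns
    -------
    (times, pressure) in (s, mmHg).
    """
    if sbp <= 0:
        raise ValueError(f"systolic blood pressure must be positive, got {sbp}")
    events.validate(cycle_length)
    template = template or PressureTemplate.default()
    if template.diastolic_mmHg >= sbp:
        raise ValueError("sbp must exceed the diastolic plateau")
    if times is None:
        times = np.linspace(0.0, cycle_length, n_samples)
    else:
        times = np.asarray(times, dtype=float)
    w = template.normalized(times, events)
    pressure = template.diastolic_mmHg + (sbp - template.diastolic_mmHg) * w
    return times, pressure


def laplace_stress(
    pressure: np.ndarray, curvature: np.ndarray, thickness: np.ndarray
) -> np.ndarray:
    """Spherical Laplace wall stress sigma = P / (2 c h), all in mmHg/mm units."""
    p = np.asarray(pressure, dtype=float)
    c = np.asarray(curvature, dtype=float)
    h = np.asarray(thickness, dtype=float)
    if np.any(c <= 0):
        raise ValueError("curvature must be positive everywhere")
    if np.any(h <= 0):
        raise ValueError("thickness must be positive everywhere")
    return p / (2.0 * c * h)


def cylindrical_laplace_stress(
    pressure: np.ndarray, curvature: np.ndarray, thickness: np.ndarray
) -> np.ndarray:
    """Cylindrical variant sigma = P / (c h) (twice the spherical stress)."""
    return 2.0 * laplace_stress(pressure, curvature, thickness)


def loop_area(
    stress: np.ndarray, strain: np.ndarray, *, closure_tol: float = 1e-6
) -> float:
    """Signed area of the stress-strain loop (mmHg*%).

    Computed as the shoelace area with strain on the x-axis and stress on the
    y-axis, counterclockwise positive; this equals -closed-integral(sigma
    d eps), so the physiologic orientation (shortening at high stress) gives
    positive work.  Invariant under cyclic shifts of the starting sample.
    """
    sig = np.asarray(stress, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if sig.shape != eps.shape or sig.ndim != 1 or sig.size < 3:
        raise ValueError("stress and strain must be 1-d arrays of equal length >= 3")
    scale_e = max(1.0, float(np.max(np.abs(eps))))
    scale_s = max(1.0, float(np.max(np.abs(sig))))
    if abs(eps[0] - eps[-1]) > closure_tol * scale_e or abs(
        sig[0] - sig[-1]
    ) > closure_tol * scale_s:
        raise ValueError("open loop: first and last samples differ beyond tolerance")
    x, y = eps[:-1], sig[:-1]  # drop duplicated closing point
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yn - xn * y))


@dataclass(frozen=True)
class WorkResult:
    """Per-segment and per-wall work (mmHg*%), with the wasted-septal flag."""

    segment_work: Mapping[tuple[str, str], float]  # (wall, level) -> work
    regional: Mapping[str, float]  # wall -> regional work
    wasted_septal: bool


def regional_work(
    segment_works: Mapping[tuple[str, str], float] | Mapping[str, Mapping[str, float]],
) -> WorkResult:
    """Aggregate segmental works into per-wall regional work.

    Accepts either a flat mapping ``(wall, level) -> work`` or a nested
    ``wall -> {level -> work}``.  Each supplied wall must have all three
    levels.  Septal regional work is the mean of the anteroseptal and
    inferoseptal wall averages (or the single "septal" wall if given);
    lateral likewise from inferolateral/anterolateral.
    """
    flat: dict[tuple[str, str], float] = {}
    for key, value in segment_works.items():
        if isinstance(key, tuple):
            flat[key] = float(value)  # type: ignore[arg-type]
        else:
            for level, w in value.items():  # type: ignore[union-attr]
                flat[(key, level)] = float(w)

    walls = sorted({wall for wall, _ in flat})
    wall_avg: dict[str, float] = {}
    for wall in walls:
        levels = {lvl: flat[(wall, lvl)] for lvl in LEVELS if (wall, lvl) in flat}
        if set(levels) != set(LEVELS):
            missing = set(LEVELS) - set(levels)
            raise ValueError(f"wall {wall!r} is missing segments: {sorted(missing)}")
        wall_avg[wall] = float(np.mean(list(levels.values())))

    regional: dict[str, float] = {}
    if "septal" in wall_avg:
        regional["septal"] = wall_avg["septal"]
    elif all(w in wall_avg for w in SEPTAL_SUB_WALLS):
        regional["septal"] = float(np.mean([wall_avg[w] for w in SEPTAL_SUB_WALLS]))
    if "lateral" in wall_avg:
        regional["lateral"] = wall_avg["lateral"]
    elif all(w in wall_avg for w in LATERAL_SUB_WALLS):
        regional["lateral"] = float(np.mean([wall_avg[w] for w in LATERAL_SUB_WALLS]))
    for wall in ("anterior", "inferior"):
        if wall in wall_avg:
            regional[wall] = wall_avg[wall]
    if "septal" not in regional or "lateral" not in regional:
        raise ValueError(
            "segment works must cover the septal and lateral walls "
            "(either directly or via their two sub-walls)"
        )
    return WorkResult(
        segment_work=dict(flat),
        regional=regional,
        wasted_septal=regional["septal"] < 0,
    )


# ---------------------------------------------------------------------------
# trace container and the full per-patient analysis


@dataclass
class SegmentTraces:
    """Per-segment strain/thickness/curvature traces over one cycle.

    All per-segment arrays share ``times`` (uniform grid, first sample equals
    the last so loops are closed).  The pressure curve may be supplied
    directly or synthesized from ``sbp`` and ``events``.
    """

    times: np.ndarray
    strain_pct: dict[tuple[str, str], np.ndarray]
    thickness_mm: dict[tuple[str, str], np.ndarray]
    curvature_per_mm: dict[tuple[str, str], np.ndarray]
    sbp: float
    events: ValveEvents
    cycle_length: float
    pressure_mmHg: np.ndarray | None = None

    def pressure(self, template: PressureTemplate | None = None) -> np.ndarray:
        if self.pressure_mmHg is not None:
            return self.pressure_mmHg
        _, p = estimate_lv_pressure(
            self.sbp, self.events, self.cycle_length, times=self.times,
            template=template,
        )
        return p


def analyze_traces(
    traces: SegmentTraces, template: PressureTemplate | None = None
) -> WorkResult:
    """Pressure -> Laplace stress -> loop areas -> regional work, per patient."""
    p = traces.pressure(template)
    works: dict[tuple[str, str], float] = {}
    for seg in traces.strain_pct:
        sigma = laplace_stress(
            p, traces.curvature_per_mm[seg], traces.thickness_mm[seg]
        )
        works[seg] = loop_area(sigma, traces.strain_pct[seg])
    return regional_work(works)


# ---------------------------------------------------------------------------
# file interfaces: long CSV + JSON sidecar

def write_traces(traces: SegmentTraces, csv_path: str | Path, json_path: str | Path) -> None:
    rows = []
    for (wall, level), eps in traces.strain_pct.items():
        seg = f"{level}_{wall}"
        rows.append(
            pd.DataFrame(
                {
                    "segment": seg,
                    "time_s": traces.times,
                    "strain_pct": eps,
                    "thickness_mm": traces.thickness_mm[(wall, level)],
                    "curvature_per_mm": traces.curvature_per_mm[(wall, level)],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    sidecar = {
        "sbp_mmHg": traces.sbp,
        "cycle_length_s": traces.cycle_length,
        "valve_events_s": traces.events.as_dict(),
    }
    Path(json_path).write_text(json.dumps(sidecar, indent=2))


def read_traces(csv_path: str | Path, json_path: str | Path) -> SegmentTraces:
    df = pd.read_csv(csv_path)
    sidecar = json.loads(Path(json_path).read_text())
    events = ValveEvents(**sidecar["valve_events_s"])
    strain, thickness, curvature = {}, {}, {}
    times = None
    for seg, grp in df.groupby("segment", sort=True):
        level, wall = str(seg).split("_", 1)
        key = (wall, level)
        grp = grp.sort_values("time_s")
        if times is None:
            times = grp["time_s"].to_numpy()
        strain[key] = grp["strain_pct"].to_numpy()
        thickness[key] = grp["thickness_mm"].to_numpy()
        curvature[key] = grp["curvature_per_mm"].to_numpy()
    if times is None:
        raise ValueError(f"no segments found in {csv_path}")
    return SegmentTraces(
        times=times,
        strain_pct=strain,
        thickness_mm=thickness,
        curvature_per_mm=curvature,
        sbp=float(sidecar["sbp_mmHg"]),
        events=events,
        cycle_length=float(sidecar["cycle_length_s"]),
    )


def write_work_json(result: WorkResult, path: str | Path) -> None:
    payload = {
        "regional_work_mmHg_pct": {k: float(v) for k, v in result.regional.items()},
        "wasted_septal": bool(result.wasted_septal),
        "segment_work_mmHg_pct": {
            f"{lvl}_{wall}": float(w) for (wall, lvl), w in result.segment_work.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
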