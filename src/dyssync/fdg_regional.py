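"""Wall-level analysis of 17-segment FDG polar maps.

Static 18F-FDG uptake is summarized on the standard AHA 17-segment bullseye
(segments 1-6 basal, 7-12 mid, 13-16 apical, 17 apex).  The map is collapsed
into four walls — septal, lateral, anterior, inferior — with the apex
excluded, regional uptake is expressed as the unweighted mean standardized
uptake value (SUVmean) of the assigned segments, and the septal-to-lateral
ratio (SLR) is the septal SUVmean divided by the lateral SUVmean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WALLS = ("septal", "lateral", "anterior", "inferior")

#: Default wall assignment on the AHA bullseye.  Anteroseptal and inferoseptal
#: segments form the septum; inferolateral and anterolateral segments form the
#: lateral wall.  Segment 17 (apex) is always excluded.
DEFAULT_WALL_SEGMENTS: dict[str, tuple[int, ...]] = {
    "septal": (2, 3, 8, 9, 14),
    "lateral": (5, 6, 11, 12, 16),
    "anterior": (1, 7, 13),
    "inferior": (4, 10, 15),
}

APEX_SEGMENT = 17


@dataclass(frozen=True)
class PolarMap17:
    """17 segment values (SUV), indexed by AHA segment number 1-17."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (17,):
            raise ValueError(f"polar map needs exactly 17 values, got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("polar map values must be finite")
        if np.any(vals < 0):
            raise ValueError("SUV values must be non-negative")
        object.__setattr__(self, "values", vals)

    def segment(self, number: int) -> float:
        """Value of AHA segment `number` (1-17)."""
        if not 1 <= number <= 17:
            raise ValueError(f"segment number out of range: {number}")
        return float(self.values[number - 1])


@dataclass(frozen=True)
class WallRegions:
    """Mapping of AHA segments 1-16 onto the four walls; apex excluded."""

    mapping: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_WALL_SEGMENTS)
    )

    def __post_init__(self) -> None:
        seen: list[int] = []
        for wall, segs in self.mapping.items():
            if wall not in WALLS:
                raise ValueError(f"unknown wall {wall!r}")
            if len(segs) == 0:
                raise ValueError(f"wall {wall!r} has no segments")
            seen.extend(segs)
        if APEX_SEGMENT in seen:
            raise ValueError("segment 17 (apex) must be excluded")
        if sorted(seen) != list(range(1, 17)):
            raise ValueError("segments 1-16 must each be assigned to exactly one wall")

    @classmethod
    def default(cls) -> "WallRegions":
        return cls()


def wall_means(
    pmap: PolarMap17, regions: WallRegions | None = None
) -> dict[str, float]:
    """Unweighted SUVmean per wall.

    Parameters
    ----------
    pmap
        17-segment polar map.
    regions
        Segment-to-wall assignment; defaults to the AHA-derived mapping.
    """
    regions = regions or WallRegions.default()
    return {
        wall: float(np.mean([pmap.segment(s) for s in segs]))
        for wall, segs in regions.mapping.items()
    }


def fdg_slr(septal_mean: float, lateral_mean: float) -> float:
    """Septal-to-lateral FDG uptake ratio (dimensionless)."""
    if lateral_mean <= 0:
        raise ValueError(f"lateral SUVmean must be positive, got {lateral_mean}")
    return septal_mean / lateral_mean


def analyze_polar_map(
    pmap: PolarMap17, regions: WallRegions | None = None
) -> dict[str, float]:
    """Wall SUVmeans plus the FDG SLR, as a flat dict ready for reporting."""
    means = wall_means(pmap, regions)
    out = dict(means)
    out["fdg_slr"] = fdg_slr(means["septal"], means["lateral"])
    return out


# ---------------------------------------------------------------------------
# file interfaces (CSV with columns segment, suv)

def read_polar_map_csv(path: str | Path) -> PolarMap17:
    df = pd.read_csv(path)
    if not {"segment", "suv"} <= set(df.columns):
        raise ValueError("polar-map CSV needs columns 'segment' and 'suv'")
    values = np.full(17, np.nan)
    for seg, suv in zip(df["segment"].astype(int), df["suv"].astype(float)):
        if not 1 <= seg <= 17:
            raise ValueError(f"segment number out of range in CSV: {seg}")
        values[seg - 1] = suv
    return PolarMap17(values)


def write_polar_map_csv(pmap: PolarMap17, path: str | Path) -> None:
    df = pd.DataFrame(
        {"segment": np.arange(1, 18), "suv": np.round(pmap.values, 6)}
    )
    df.to_csv(path, index=False)


def write_regional_json(result: Mapping[str, float], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: float(v) for k, v in result.items()}, indent=2))
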