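"""Lumen diameters and aortic growth-rate classification.

Diameters are derived from masks as equivalent-circle diameters of
centerline-orthogonal cross-sections (robust to voxelization; manual
multiplanar measurements may be supplied instead as external values).
Growth rate is the two-point diameter change over the first-to-last scan
interval, which must span at least 180 days; growth of 3 mm/year or more
classifies a subject as a rapid grower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    CenterlinePlanes,
    GeometryError,
    LumenSegmentation,
    VoxelPlaneAssignment,
    assign_voxels_to_planes,
)

RAPID_GROWTH_MM_PER_YEAR = 3.0
MIN_INTERVAL_DAYS = 180
DAYS_PER_YEAR = 365.25


class EligibilityError(ValueError):
    """Scan interval too short for the growth-rate analysis."""


@dataclass
class DiameterSeries:
    """Serial diameter measurements of one subject.

    ``measurements`` rows: (date, max_diameter_mm, fl_diameter_mm,
    entry_tear_mm or None). Entry-tear diameter is always an external
    (manually measured) input, never computed here.
    """

    subject_id: str
    measurements: list[tuple[date, float, float | None, float | None]]
    source: str = "external"

    def __post_init__(self) -> None:
        dates = [m[0] for m in self.measurements]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("measurement dates must be strictly increasing")
        if any(m[1] <= 0 for m in self.measurements):
            raise ValueError("diameters must be positive")


@dataclass
class GrowthResult:
    growth_rate_mm_per_year: float
    interval_days: int
    rapid: bool


def measure_diameters(
    seg: LumenSegmentation,
    cl: CenterlinePlanes,
    assignment: VoxelPlaneAssignment | None = None,
    end_margin_planes: int = 3,
) -> tuple[float, float | None]:
    """Maximal aortic and false-lumen diameters from the masks.

    Each centerline plane collects the luminal voxels nearest to it; the
    cross-sectional area is voxel count x voxel volume / slab thickness
    and the diameter is that of the equal-area circle, 2*sqrt(A/pi). When
    native voxels are coarser than the plane spacing, counts are pooled
    over a window of adjacent planes at least one voxel thick so that the
    voxel-to-plane aliasing does not distort the area. The reported value
    is the maximum over planes, excluding a few planes at either end
    where the nearest-plane slab degenerates.
    """
    if assignment is None:
        assignment = assign_voxels_to_planes(seg, cl)
    voxel_volume = float(np.prod(seg.voxel_size_mm))
    spacing = float(np.diff(cl.arc_length_mm).mean()) if len(cl) > 1 else 1.0
    n_planes = len(cl)
    window = max(1, math.ceil(max(seg.voxel_size_mm) / spacing))
    window += 1 - window % 2  # odd, centered
    margin = max(end_margin_planes, window // 2 + 1)
    lo = margin if n_planes > 2 * margin + 1 else 0
    hi = n_planes - lo

    def max_diameter(mask: np.ndarray) -> float | None:
        if not mask.any():
            return None
        planes = assignment.plane_index[mask]
        counts = np.bincount(planes, minlength=n_planes).astype(float)
        pooled = np.convolve(counts, np.ones(window), mode="same")
        width = np.convolve(np.ones(n_planes), np.ones(window), mode="same") * spacing
        areas = (pooled / width * voxel_volume)[lo:hi]
        if len(areas) == 0 or areas.max() == 0:
            return None
        return float(2.0 * math.sqrt(areas.max() / math.pi))

    aorta_d = max_diameter(seg.aorta_mask)
    if aorta_d is None:
        raise GeometryError("no aortic cross-section intersects the analysis planes")
    return aorta_d, max_diameter(seg.fl_mask)


def growth_rate(series: DiameterSeries) -> GrowthResult:
    """Two-point growth rate with the >= 180-day eligibility rule."""
    if len(series.measurements) < 2:
        raise EligibilityError("need at least two diameter measurements")
    first = series.measurements[0]
    last = series.measurements[-1]
    interval_days = (last[0] - first[0]).days
    if interval_days < MIN_INTERVAL_DAYS:
        raise EligibilityError(
            f"imaging interval {interval_days} d below the {MIN_INTERVAL_DAYS}-day minimum"
        )
    rate = (last[1] - first[1]) / (interval_days / DAYS_PER_YEAR)
    return GrowthResult(
        growth_rate_mm_per_year=float(rate),
        interval_days=interval_days,
        rapid=bool(rate >= RAPID_GROWTH_MM_PER_YEAR),
    )


def load_diameter_series_csv(path: str | Path) -> list[DiameterSeries]:
    """CSV columns: subject, date (ISO), max_diameter_mm, fl_diameter_mm, entry_tear_mm."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for subject, rows in df.groupby("subject", sort=False):
        rows = rows.sort_values("date")
        measurements = [
            (
                r.date.date(),
                float(r.max_diameter_mm),
                float(r.fl_diameter_mm) if "fl_diameter_mm" in rows and pd.notna(r.fl_diameter_mm) else None,
                float(r.entry_tear_mm) if "entry_tear_mm" in rows and pd.notna(r.entry_tear_mm) else None,
            )
            for r in rows.itertuples()
        ]
        out.append(DiameterSeries(subject_id=str(subject), measurements=measurements))
    return out
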