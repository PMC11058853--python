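"""Colony readouts: occupied-pixel area, radial growth rate, cross sections.

Colony area is the number of grid cells holding at least ``min_agents_per_cell``
living agents of the colony, reported in "pixels" (grid cells) and converted
to mm^2 with the plate's px-per-mm^2 constant (55.6 at reference resolution).
The radial growth rate is the least-squares slope of the equivalent colony
radius r_t = sqrt(area_mm2 / pi) against time in days.  Cross-sectional
density profiles along a row through the colony centre reproduce the
characteristic shapes: conical for single-cell colonies, volcano-like (two
peaks around a central crater) for droplet inoculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import STEPS_PER_DAY
from .environment import DEFAULT_PX_PER_MM2


@dataclass
class AreaSeries:
    """A colony-area time series, in pixels and in mm^2."""

    colony_id: str
    steps: np.ndarray
    area_px: np.ndarray
    px_per_mm2: float = DEFAULT_PX_PER_MM2
    area_mm2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps)
        self.area_px = np.asarray(self.area_px, dtype=float)
        if self.steps.shape != self.area_px.shape:
            raise ValueError("steps and areas must have equal length")
        if (self.area_px < 0).any():
            raise ValueError("areas must be non-negative")
        self.area_mm2 = self.area_px / self.px_per_mm2

    @property
    def days(self) -> np.ndarray:
        return self.steps / STEPS_PER_DAY


def colony_area(
    xs: np.ndarray,
    ys: np.ndarray,
    n_cols: int,
    n_rows: int,
    min_agents_per_cell: int = 1,
) -> int:
    """Occupied-cell count for one colony's living agents.

    A cell counts toward the area when at least ``min_agents_per_cell``
    living agents sit on it (the in-vitro analogue only registers regions
    with enough cells to be visible; the threshold is exposed for such
    comparisons and defaults to 1).
    """
    if min_agents_per_cell < 1:
        raise ValueError("min_agents_per_cell must be >= 1")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0:
        return 0
    cells = ys.astype(np.intp) * n_cols + xs.astype(np.intp)
    counts = np.bincount(cells, minlength=n_cols * n_rows)
    return int((counts >= min_agents_per_cell).sum())


def radial_growth_rate(
    series: AreaSeries,
    window_days: tuple[float, float],
    steps_per_day: int = STEPS_PER_DAY,
) -> float:
    """Least-squares slope of the equivalent radius vs. time, in mm/day."""
    days = series.steps / steps_per_day
    a, b = window_days
    sel = (days >= a) & (days <= b)
    if sel.sum() < 2:
        raise ValueError("growth-rate window must contain at least 2 points")
    t = days[sel]
    r = np.sqrt(series.area_mm2[sel] / np.pi)
    slope, _ = np.polyfit(t, r, 1)
    return float(slope)


def cross_section_profile(density: np.ndarray, row: int) -> np.ndarray:
    """Living-agent counts along one row of the density grid."""
    density = np.asarray(density)
    if not 0 <= row < density.shape[0]:
        raise ValueError("row index outside the grid")
    return density[row, :].astype(float)


def profile_local_maxima(profile: np.ndarray, smooth: int = 3) -> list[int]:
    """Indices of local maxima after a short moving-average smoothing.

    A local maximum is a cell strictly greater than both neighbours of the
    smoothed profile.  Two maxima flanking a central dip indicate the
    volcano shape of droplet-grown colonies; a single maximum the conical
    shape of single-founder colonies.
    """
    profile = np.asarray(profile, dtype=float)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        profile = np.convolve(profile, kernel, mode="same")
    inner = profile[1:-1]
    is_max = (inner > profile[:-2]) & (inner > profile[2:])
    return [int(i) + 1 for i in np.nonzero(is_max)[0]]


def is_bimodal(profile: np.ndarray, smooth: int = 3) -> bool:
    """True when the profile shows two peaks separated by a central dip."""
    maxima = profile_local_maxima(profile, smooth=smooth)
    return len(maxima) >= 2


def inhibition_zone_ratio(density_a: np.ndarray, density_b: np.ndarray) -> float:
    """Depth of the low-density boundary between two adjacent colonies.

    Samples total living density along the straight line joining the two
    colonies' centroids and compares the minimum over the middle half of
    that segment (the boundary zone) against the smaller of the two
    colonies' median occupied-cell densities.  A ratio well below 1 marks a
    growth-inhibition zone: the colonies approach but do not grow into each
    other.
    """
    density_a = np.asarray(density_a, dtype=float)
    density_b = np.asarray(density_b, dtype=float)
    if density_a.sum() == 0 or density_b.sum() == 0:
        raise ValueError("both colonies must have living agents")
    yy, xx = np.indices(density_a.shape)

    def centroid(d):
        return (yy * d).sum() / d.sum(), (xx * d).sum() / d.sum()

    (ay, ax), (by, bx) = centroid(density_a), centroid(density_b)
    n_samples = max(int(np.hypot(by - ay, bx - ax)) * 2, 8)
    t = np.linspace(0.0, 1.0, n_samples)
    rows = np.clip(np.rint(ay + t * (by - ay)).astype(int), 0, density_a.shape[0] - 1)
    cols = np.clip(np.rint(ax + t * (bx - ax)).astype(int), 0, density_a.shape[1] - 1)
    total = density_a + density_b
    boundary = total[rows, cols][(t >= 0.25) & (t <= 0.75)]
    med_a = np.median(density_a[density_a >= 1])
    med_b = np.median(density_b[density_b >= 1])
    return float(boundary.min() / min(med_a, med_b))
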