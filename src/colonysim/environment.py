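"""Plate geometry and the two-layer nutrient lattice.

The agar plate is modelled as two stacked 2-D grids of nutrient: a *top*
layer that feeds the cells and a *deep* layer that slowly recharges the top
one.  Within a layer, nutrient spreads by Gaussian smoothing once per
simulation step; between the layers a relaxation flow drives the per-cell
top/deep ratio toward the ratio of the initial fill levels.  The plate is a
closed container: diffusion uses reflective (zero-flux) boundaries and, on
circular plates, a source-normalised masked filter, so that total nutrient
is conserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

#: default conversion between occupied grid cells ("pixels") and physical area
DEFAULT_PX_PER_MM2 = 55.6

#: Gaussian kernels are truncated at this many standard deviations
KERNEL_TRUNCATE = 4.0


@dataclass
class PlateGeometry:
    """Shape and scale of the simulated dish.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions in cells.
    shape:
        ``"circular"`` (Petri dish; mask is the inscribed disc) or
        ``"rectangular"`` (e.g. an OmniTray single-well plate).
    px_per_mm2:
        Conversion between grid cells counted as colony area ("pixels") and
        square millimetres.  The default, 55.6 px/mm^2, is the reference
        scaling for full-resolution plates; presets rendered on coarser
        grids carry their own resolution-consistent value.
    """

    n_rows: int
    n_cols: int
    shape: str = "circular"
    px_per_mm2: float = DEFAULT_PX_PER_MM2
    mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.shape not in ("circular", "rectangular"):
            raise ValueError(f"unknown plate shape: {self.shape!r}")
        if self.px_per_mm2 <= 0:
            raise ValueError("px_per_mm2 must be positive")
        if self.shape == "rectangular":
            self.mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            yy, xx = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
            cy, cx = (self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0
            r = min(self.n_rows, self.n_cols) / 2.0
            self.mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    @property
    def center(self) -> tuple[float, float]:
        """Plate centre in continuous (x, y) coordinates."""
        return (self.n_cols / 2.0, self.n_rows / 2.0)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-plate test for continuous coordinates."""
        x = np.asarray(x)
        y = np.asarray(y)
        inside = (x >= 0) & (x < self.n_cols) & (y >= 0) & (y < self.n_rows)
        out = np.zeros(np.broadcast(x, y).shape, dtype=bool)
        xi = np.clip(x[inside].astype(np.intp), 0, self.n_cols - 1)
        yi = np.clip(y[inside].astype(np.intp), 0, self.n_rows - 1)
        out[inside] = self.mask[yi, xi]
        return out

    def outer_ring(self, width: int) -> np.ndarray:
        """Boolean mask of the outermost in-plate band, ``width`` cells wide."""
        if self.shape == "rectangular":
            inner = np.zeros_like(self.mask)
            if self.n_rows > 2 * width and self.n_cols > 2 * width:
                inner[width:-width, width:-width] = True
            return self.mask & ~inner
        yy, xx = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        cy, cx = (self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0
        r = min(self.n_rows, self.n_cols) / 2.0
        inner = (yy - cy) ** 2 + (xx - cx) ** 2 <= max(r - width, 0) ** 2
        return self.mask & ~inner


@dataclass
class NutrientLayers:
    """The two nutrient grids plus their transport parameters.

    ``sigma_top``/``sigma_deep`` are the per-step Gaussian-kernel standard
    deviations (grid cells); ``flowrate`` in [0, 2) controls how fast the
    inter-layer flow relaxes each cell pair toward the init_top:init_deep
    ratio (1 equilibrates the top layer in one step, 0 decouples them).
    """

    top: np.ndarray
    deep: np.ndarray
    init_top: float
    init_deep: float
    sigma_top: float = 1.0
    sigma_deep: float = 1.0
    flowrate: float = 0.5

    def __post_init__(self) -> None:
        self.top = np.asarray(self.top, dtype=float)
        self.deep = np.asarray(self.deep, dtype=float)
        if self.top.shape != self.deep.shape:
            raise ValueError("top and deep layers must share a grid shape")
        if self.init_top <= 0 or self.init_deep <= 0:
            raise ValueError("initial layer levels must be positive")
        if self.sigma_top < 0 or self.sigma_deep < 0:
            raise ValueError("sigma must be non-negative")
        if not (0 <= self.flowrate < 2):
            raise ValueError("flowrate must lie in [0, 2)")
        if (self.top < 0).any() or (self.deep < 0).any():
            raise ValueError("nutrient values must be non-negative")

    @classmethod
    def uniform(
        cls,
        geometry: PlateGeometry,
        init_top: float,
        init_deep: float,
        sigma_top: float = 1.0,
        sigma_deep: float = 1.0,
        flowrate: float = 0.5,
    ) -> "NutrientLayers":
        """Fill every in-plate cell of both layers at its initial level."""
        top = np.where(geometry.mask, float(init_top), 0.0)
        deep = np.where(geometry.mask, float(init_deep), 0.0)
        return cls(top, deep, init_top, init_deep, sigma_top, sigma_deep, flowrate)

    def total(self) -> float:
        return float(self.top.sum() + self.deep.sum())


@dataclass
class RefeedEvent:
    """Scheduled addition of nutrient, emulating refilling the dish.

    ``region`` is ``"all"``, ``"ring:<width>"`` or an explicit boolean mask;
    ``layer`` is ``"top"``, ``"deep"`` or ``"both"``.
    """

    step: int
    amount: float
    region: object = "all"
    layer: str = "both"

    def __post_init__(self) -> None:
        if self.step < 0:
            raise ValueError("event step must be >= 0")
        if self.amount < 0:
            raise ValueError("refeed amount must be >= 0")
        if self.layer not in ("top", "deep", "both"):
            raise ValueError(f"unknown layer: {self.layer!r}")

    def region_mask(self, geometry: PlateGeometry) -> np.ndarray:
        if isinstance(self.region, str):
            if self.region == "all":
                return geometry.mask.copy()
            if self.region.startswith("ring:"):
                return geometry.outer_ring(int(self.region.split(":", 1)[1]))
            raise ValueError(f"unknown region spec: {self.region!r}")
        mask = np.asarray(self.region, dtype=bool)
        if mask.shape != geometry.mask.shape:
            raise ValueError("region mask shape does not match the plate")
        return mask & geometry.mask


def diffuse_layer(grid: np.ndarray, sigma: float, mask: np.ndarray | None = None) -> np.ndarray:
    """One round of within-layer nutrient diffusion.

    Gaussian smoothing with reflective padding, truncated at 4 sigma.  With a
    non-trivial ``mask`` (circular plate) each in-mask source cell spreads its
    nutrient over in-mask destinations only, renormalised per source cell, so
    the masked total is conserved; cells outside the mask stay at zero.

    sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    grid = np.asarray(grid, dtype=float)
    if sigma == 0:
        return grid.copy()
    if mask is None or mask.all():
        return gaussian_filter(grid, sigma, mode="reflect", truncate=KERNEL_TRUNCATE)
    weight = gaussian_filter(mask.astype(float), sigma, mode="reflect", truncate=KERNEL_TRUNCATE)
    source = np.zeros_like(grid)
    np.divide(grid, weight, out=source, where=mask)
    out = gaussian_filter(source, sigma, mode="reflect", truncate=KERNEL_TRUNCATE)
    out[~mask] = 0.0
    return out


def interlayer_flow(
    top: np.ndarray,
    deep: np.ndarray,
    init_top: float,
    init_deep: float,
    flowrate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Relax each top/deep cell pair toward the init_top:init_deep ratio.

    Per cell, with r = init_deep/init_top:

        delta = (deep / r - top) * flowrate / 2
        top'  = top + delta
        deep' = deep - delta

    The pair sum top' + deep' is exactly preserved.  Should an extreme
    flowrate drive one side negative, the transfer is clamped so both sides
    stay non-negative (sum still preserved) and a warning is emitted.
    """
    if init_top <= 0 or init_deep <= 0:
        raise ValueError("initial layer levels must be positive")
    if flowrate < 0:
        raise ValueError("flowrate must be >= 0")
    top = np.asarray(top, dtype=float)
    deep = np.asarray(deep, dtype=float)
    ratio = init_deep / init_top
    delta = (deep / ratio - top) * (flowrate / 2.0)
    new_top = top + delta
    new_deep = deep - delta
    negative = (new_top < 0) | (new_deep < 0)
    if negative.any():
        warnings.warn(
            "inter-layer flow clamped in %d cell(s) to keep nutrient non-negative"
            % int(np.count_nonzero(negative)),
            RuntimeWarning,
            stacklevel=2,
        )
        # the donor side can give at most what it holds; the pair sum is kept
        pair = top + deep
        new_top = np.clip(new_top, 0.0, pair)
        new_deep = pair - new_top
    return new_top, new_deep


def apply_refeed(layers: NutrientLayers, event: RefeedEvent, geometry: PlateGeometry) -> float:
    """Add ``event.amount`` nutrient to every region cell; returns the total added."""
    mask = event.region_mask(geometry)
    added = 0.0
    if event.layer in ("top", "both"):
        layers.top[mask] += event.amount
        added += event.amount * mask.sum()
    if event.layer in ("deep", "both"):
        layers.deep[mask] += event.amount
        added += event.amount * mask.sum()
    logger.debug("refeed at step %d: +%g units over %d cells", event.step, added, int(mask.sum()))
    return float(added)


def init_gradient_plate(
    geometry: PlateGeometry,
    init_top: float,
    init_deep: float,
    sigma_top: float,
    sigma_deep: float,
    flowrate: float,
    nutrient_fraction_rows: float = 0.2,
    concentration_multiplier: float = 1.0,
    pre_diffusion_steps: int = 0,
) -> NutrientLayers:
    """Build a plate whose nutrient sits in a top band of rows only.

    Emulates pouring rich medium into the top fifth of an otherwise plain-agar
    rectangular plate: both layers receive ``init * multiplier`` in the first
    ``nutrient_fraction_rows`` fraction of rows and zero elsewhere, then
    ``pre_diffusion_steps`` rounds of diffusion + inter-layer flow establish
    the gradient.  A multiplier of 5 on a 1/5 band carries the same total
    nutrient as a uniformly filled plate.
    """
    if concentration_multiplier <= 0:
        raise ValueError("concentration multiplier must be positive")
    band_rows = int(round(geometry.n_rows * nutrient_fraction_rows))
    if band_rows < 1:
        raise ValueError("nutrient region is empty at this grid size")
    region = np.zeros_like(geometry.mask)
    region[:band_rows, :] = True
    region &= geometry.mask
    if not region.any():
        raise ValueError("nutrient region does not intersect the plate")
    top = np.where(region, init_top * concentration_multiplier, 0.0)
    deep = np.where(region, init_deep * concentration_multiplier, 0.0)
    layers = NutrientLayers(top, deep, init_top, init_deep, sigma_top, sigma_deep, flowrate)
    for _ in range(pre_diffusion_steps):
        layers.top = diffuse_layer(layers.top, sigma_top, geometry.mask)
        layers.deep = diffuse_layer(layers.deep, sigma_deep, geometry.mask)
        layers.top, layers.deep = interlayer_flow(
            layers.top, layers.deep, init_top, init_deep, flowrate
        )
    return layers
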