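"""Plot extraction, height normalization and habitat-structure variables.

The habitat of a telemetry position is characterised at three nested scales:

* a 5-m-radius plot (clipped at 10 m, normalized, re-clipped to 5 m) for the
  vertical vegetation profile — band densities below 1 m, 1-5 m, 5-10 m,
  above 10 m, the Q90 vegetation height, the height SD (structural
  complexity) and canopy cover above 3 m;
* a 25-m-radius plot (clipped at 35 m, normalized, re-clipped to 25 m),
  rasterized into 1-m² cells, for horizontal heterogeneity — open area
  (cells with Q90 ≤ 0.5 m), variance of cell Q90 heights, and forest-edge
  (ecotone) length with forest defined as Q90 > 3 m;
* 250-m (escalating to 400-m) plots for the distance to the nearest water
  cell, water being cells that return no LiDAR points at all.

Height normalization subtracts an inverse-distance-weighted interpolation of
the k nearest ground returns (2-D neighbourhood, default k=10, power p=2);
the outer 5-m/10-m buffer absorbs edge effects and is discarded afterwards.

Undefined results (empty plots, no water within range) are returned as NaN
rather than raised, so a single bad position never aborts a feature run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import NormalizationError
from .landscape import PointCloud

logger = logging.getLogger(__name__)

#: vertical band edges [lo, hi): herb, shrub, low tree, tall tree
BANDS = ((0.0, 1.0), (1.0, 5.0), (5.0, 10.0), (10.0, np.inf))

FEATURE_COLUMNS = [
    "lt1_density",
    "d1_5_density",
    "d5_10_density",
    "gt10_density",
    "veg_height",
    "struct_complexity",
    "canopy_cover",
    "open_areas",
    "height_variation",
    "forest_edge",
    "dist_water",
]


@dataclass
class Plot:
    """A circular clip of the point cloud around one position.

    ``normalized`` marks whether z is height above ground.
    """

    center: tuple[float, float]
    radius: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    cls: np.ndarray
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.x)

    @property
    def is_ground(self) -> np.ndarray:
        from .landscape import CLASS_GROUND

        return self.cls == CLASS_GROUND

    @property
    def is_vegetation(self) -> np.ndarray:
        from .landscape import VEGETATION_CODES

        return np.isin(self.cls, list(VEGETATION_CODES))


def clip_plot(cloud: PointCloud, center: tuple[float, float], outer_radius: float) -> Plot:
    """Clip points with horizontal distance ≤ outer_radius of center.

    The boundary point (distance exactly equal to the radius) is retained.
    An empty clip is a valid (water) plot.
    """
    if outer_radius <= 0:
        raise ValueError(f"radius must be positive, got {outer_radius}")
    dx = cloud.x - center[0]
    dy = cloud.y - center[1]
    mask = dx * dx + dy * dy <= outer_radius * outer_radius
    return Plot(center, float(outer_radius), cloud.x[mask], cloud.y[mask], cloud.z[mask], cloud.cls[mask])


def normalize_heights(plot: Plot, k: int = 10, p: float = 2.0) -> Plot:
    """Replace z by height above IDW-interpolated ground.

    For each point the ground elevation is estimated from its k nearest
    ground returns in 2-D with weights d^-p; a point horizontally coincident
    with a ground return takes that return's elevation exactly.  Fewer than
    k ground points triggers a warning and uses all that are available; zero
    ground points raises :class:`NormalizationError`.
    """
    gmask = plot.is_ground
    n_ground = int(gmask.sum())
    if n_ground == 0:
        raise NormalizationError(
            f"plot at {plot.center} has no ground points; cannot normalize"
        )
    if n_ground < k:
        warnings.warn(
            f"plot at {plot.center}: only {n_ground} ground points (< k={k}); using all",
            stacklevel=2,
        )
    k_eff = min(k, n_ground)
    gx, gy, gz = plot.x[gmask], plot.y[gmask], plot.z[gmask]
    tree = cKDTree(np.column_stack([gx, gy]))
    d, idx = tree.query(np.column_stack([plot.x, plot.y]), k=k_eff)
    if k_eff == 1:
        d = d[:, None]
        idx = idx[:, None]
    gz_nb = gz[idx]
    coincident = d[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = d ** (-p)
    ghat = np.einsum("ij,ij->i", w, gz_nb) / w.sum(axis=1)
    ghat[coincident] = gz_nb[coincident, 0]
    return Plot(plot.center, plot.radius, plot.x, plot.y, plot.z - ghat, plot.cls, normalized=True)


def inner_clip(plot: Plot, inner_radius: float) -> Plot:
    """Discard the outer normalization buffer, keeping distance ≤ inner_radius."""
    if not inner_radius < plot.radius:
        raise ValueError(
            f"inner radius {inner_radius} must be smaller than plot radius {plot.radius}"
        )
    dx = plot.x - plot.center[0]
    dy = plot.y - plot.center[1]
    mask = dx * dx + dy * dy <= inner_radius * inner_radius
    return Plot(
        plot.center,
        float(inner_radius),
        plot.x[mask],
        plot.y[mask],
        plot.z[mask],
        plot.cls[mask],
        normalized=plot.normalized,
    )


# ---------------------------------------------------------------------------
# vertical-profile variables (5-m plot)
# ---------------------------------------------------------------------------

def band_density(plot: Plot, lo: float, hi: float) -> float:
    """Vegetation returns with lo ≤ h < hi as % of all returns in the plot."""
    n_total = len(plot)
    if n_total == 0:
        return float("nan")
    h = plot.z[plot.is_vegetation]
    n_band = int(((h >= lo) & (h < hi)).sum())
    return 100.0 * n_band / n_total


def vegetation_height(plot: Plot) -> float:
    """Q90 (linear-interpolation quantile) of vegetation heights; 0 if bare."""
    h = plot.z[plot.is_vegetation]
    if len(h) == 0:
        return 0.0
    return float(np.quantile(h, 0.9))


def structural_complexity(plot: Plot, ddof: int = 0) -> float:
    """Standard deviation (population by default) of vegetation heights."""
    h = plot.z[plot.is_vegetation]
    if len(h) == 0 or len(h) <= ddof:
        return float("nan")
    return float(np.std(h, ddof=ddof))


def canopy_cover(plot: Plot, threshold: float = 3.0) -> float:
    """Vegetation returns above ``threshold`` m as % of all returns."""
    n_total = len(plot)
    if n_total == 0:
        return float("nan")
    h = plot.z[plot.is_vegetation]
    return 100.0 * int((h > threshold).sum()) / n_total


def gt10_density(plot: Plot) -> float:
    """Vegetation returns at 10 m and above as % of all returns."""
    return band_density(plot, 10.0, np.inf)


# ---------------------------------------------------------------------------
# horizontal-heterogeneity variables (25-m plot, 1-m² raster)
# ---------------------------------------------------------------------------

@dataclass
class CellGrid:
    """1-m² rasterization of a plot.

    Cells are half-open [x, x+1) × [y, y+1) in landscape coordinates
    (``x0``/``y0`` are the integer origins); a cell belongs to the plot iff
    its centre lies within the plot radius.  Cells that received no returns
    of any class are flagged as water.
    """

    x0: int
    y0: int
    in_plot: np.ndarray  # (ny, nx) bool
    water: np.ndarray  # (ny, nx) bool; zero returns
    q90: np.ndarray  # (ny, nx) float; 0 where no vegetation, NaN outside plot/water
    n_points: np.ndarray  # (ny, nx) int


def rasterize_q90(plot: Plot) -> CellGrid:
    """Per-cell Q90 of vegetation heights over the plot's 1-m² cells."""
    cx, cy = plot.center
    r = plot.radius
    x0 = int(np.floor(cx - r))
    y0 = int(np.floor(cy - r))
    nx = int(np.floor(cx + r)) - x0 + 1
    ny = int(np.floor(cy + r)) - y0 + 1
    ccx = x0 + np.arange(nx) + 0.5
    ccy = y0 + np.arange(ny) + 0.5
    xx, yy = np.meshgrid(ccx, ccy)
    in_plot = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r

    ix = np.floor(plot.x).astype(int) - x0
    iy = np.floor(plot.y).astype(int) - y0
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix, iy = ix[ok], iy[ok]
    flat = iy * nx + ix
    n_points = np.bincount(flat, minlength=nx * ny).reshape(ny, nx)

    veg = plot.is_vegetation[ok]
    q90 = np.zeros((ny, nx))
    vflat = flat[veg]
    vh = plot.z[ok][veg]
    order = np.argsort(vflat, kind="stable")
    vflat, vh = vflat[order], vh[order]
    starts = np.searchsorted(vflat, np.arange(nx * ny))
    ends = np.searchsorted(vflat, np.arange(nx * ny) + 1)
    for cell in np.unique(vflat):
        q90.flat[cell] = np.quantile(vh[starts[cell] : ends[cell]], 0.9)

    water = in_plot & (n_points == 0)
    q90[~in_plot | water] = np.nan
    return CellGrid(x0, y0, in_plot, water, q90, n_points)


def open_areas(grid: CellGrid, threshold: float = 0.5) -> float:
    """Area (m²) of in-plot land cells whose vegetation Q90 ≤ threshold."""
    sel = grid.in_plot & ~grid.water
    return float(np.sum(grid.q90[sel] <= threshold))


def height_variation(grid: CellGrid, ddof: int = 0) -> float:
    """Variance (population by default) of cell Q90 over in-plot land cells."""
    vals = grid.q90[grid.in_plot & ~grid.water]
    if len(vals) == 0 or len(vals) <= ddof:
        return float("nan")
    return float(np.var(vals, ddof=ddof))


def forest_edge_length(
    grid: CellGrid, threshold: float = 3.0, mode: str = "ecotone"
) -> float:
    """Total forest-edge length (m) in the plot; forest = cell Q90 > threshold.

    ``mode="ecotone"`` (default) counts unit sides shared between a forest
    cell and an in-plot non-forest cell (water counts as non-forest); sides
    on the plot boundary are not counted.  ``mode="perimeter"`` returns
    4 × (forest cell count), a pure area proxy.
    """
    forest = grid.in_plot & ~grid.water & (grid.q90 > threshold)
    if mode == "perimeter":
        return float(4 * forest.sum())
    if mode != "ecotone":
        raise ValueError(f"unknown forest-edge mode {mode!r}")
    nonforest = grid.in_plot & ~forest
    edges = 0
    # horizontal neighbours
    edges += int(np.sum(forest[:, :-1] & nonforest[:, 1:]))
    edges += int(np.sum(nonforest[:, :-1] & forest[:, 1:]))
    # vertical neighbours
    edges += int(np.sum(forest[:-1, :] & nonforest[1:, :]))
    edges += int(np.sum(nonforest[:-1, :] & forest[1:, :]))
    return float(edges)


# ---------------------------------------------------------------------------
# distance to water (250 / 400-m plots)
# ---------------------------------------------------------------------------

class WaterGrid:
    """Global 1-m² occupancy raster; water cells are those with zero returns.

    Built once per point cloud and shared across positions, equivalent to
    rasterizing a fresh 250-m plot per position but far cheaper.
    """

    def __init__(self, cloud: PointCloud):
        minx, miny, maxx, maxy = cloud.bounds
        x0, y0 = int(np.floor(minx)), int(np.floor(miny))
        nx = max(int(np.ceil(maxx)) - x0, 1)
        ny = max(int(np.ceil(maxy)) - y0, 1)
        ix = np.clip(np.floor(cloud.x).astype(int) - x0, 0, nx - 1)
        iy = np.clip(np.floor(cloud.y).astype(int) - y0, 0, ny - 1)
        n = np.bincount(iy * nx + ix, minlength=nx * ny).reshape(ny, nx)
        self.x0, self.y0, self.nx, self.ny = x0, y0, nx, ny
        self.occupied = n > 0
        wy, wx = np.nonzero(~self.occupied)
        self.water_centers = np.column_stack([wx + x0 + 0.5, wy + y0 + 0.5])
        self._tree = cKDTree(self.water_centers) if len(self.water_centers) else None

    def cell_is_water(self, point: tuple[float, float]) -> bool:
        ix = int(np.floor(point[0])) - self.x0
        iy = int(np.floor(point[1])) - self.y0
        if 0 <= ix < self.nx and 0 <= iy < self.ny:
            return not self.occupied[iy, ix]
        return False

    def nearest_water(self, point: tuple[float, float]) -> float:
        if self._tree is None:
            return float("inf")
        d, _ = self._tree.query(point)
        return float(d)


def distance_to_water(
    cloud: PointCloud,
    point: tuple[float, float],
    radii: tuple[float, float] = (250.0, 400.0),
    grid: WaterGrid | None = None,
) -> float:
    """Distance (m) from ``point`` to the nearest zero-return (water) cell.

    The search rasterizes a plot of the first radius at 1 m²; if no water
    cell lies within it the search escalates to the second radius, and NaN
    is returned if that too is dry.  A point whose own cell is water has
    distance 0.
    """
    if grid is None:
        grid = WaterGrid(cloud)
    if grid.cell_is_water(point):
        return 0.0
    d = grid.nearest_water(point)
    for r in radii:
        if d <= r:
            return d
    return float("nan")


# ---------------------------------------------------------------------------
# full feature extraction
# ---------------------------------------------------------------------------

def vertical_profile(plot5: Plot) -> dict:
    """All 5-m-plot variables from a normalized inner-clipped plot."""
    return {
        "lt1_density": band_density(plot5, *BANDS[0]),
        "d1_5_density": band_density(plot5, *BANDS[1]),
        "d5_10_density": band_density(plot5, *BANDS[2]),
        "gt10_density": band_density(plot5, *BANDS[3]),
        "veg_height": vegetation_height(plot5),
        "struct_complexity": structural_complexity(plot5),
        "canopy_cover": canopy_cover(plot5),
    }


def horizontal_profile(plot25: Plot, edge_mode: str = "ecotone") -> dict:
    """All 25-m-plot variables from a normalized inner-clipped plot."""
    grid = rasterize_q90(plot25)
    return {
        "open_areas": open_areas(grid),
        "height_variation": height_variation(grid),
        "forest_edge": forest_edge_length(grid, mode=edge_mode),
    }


def extract_position(
    cloud: PointCloud,
    position: tuple[float, float],
    water_grid: WaterGrid | None = None,
    radii_vertical: tuple[float, float] = (10.0, 5.0),
    radii_horizontal: tuple[float, float] = (35.0, 25.0),
    radii_water: tuple[float, float] = (250.0, 400.0),
    k: int = 10,
    p: float = 2.0,
    edge_mode: str = "ecotone",
) -> dict:
    """Habitat variables for one position; NaN where a plot is undefined."""
    row = {c: float("nan") for c in FEATURE_COLUMNS}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse plots near water: use all ground pts
        try:
            p10 = clip_plot(cloud, position, radii_vertical[0])
            plot5 = inner_clip(normalize_heights(p10, k=k, p=p), radii_vertical[1])
            row.update(vertical_profile(plot5))
        except NormalizationError:
            logger.info("position %s: no ground points in vertical plot", position)
        try:
            p35 = clip_plot(cloud, position, radii_horizontal[0])
            plot25 = inner_clip(normalize_heights(p35, k=k, p=p), radii_horizontal[1])
            row.update(horizontal_profile(plot25, edge_mode=edge_mode))
        except NormalizationError:
            logger.info("position %s: no ground points in horizontal plot", position)
    row["dist_water"] = distance_to_water(cloud, position, radii_water, grid=water_grid)
    return row


def extract_features(
    cloud: PointCloud,
    positions: Sequence[tuple[float, float]] | np.ndarray,
    labels: Iterable[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run the full clip → normalize → re-clip → metrics chain per position.

    Returns one row per position with all 11 variables plus the
    presence/background label; per-position failures yield NaN cells, never
    abort the run.
    """
    positions = np.asarray(positions, dtype=float)
    water_grid = WaterGrid(cloud)
    rows = [
        extract_position(cloud, (float(px), float(py)), water_grid=water_grid, **kwargs)
        for px, py in positions
    ]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if labels is not None:
        df["label"] = list(labels)
    return df
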