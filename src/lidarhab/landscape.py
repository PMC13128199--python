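"""Synthetic riparian landscape generator.

Produces classified airborne-laser-scanning-like point clouds over a
parameterized habitat mosaic (water channel, meadow, herb layer, reedbed,
shrub patches, forest), together with ground-truth rasters of the habitat
structure in every 1-m² cell.  The truth rasters are the oracle against
which the LiDAR metrics are validated: because the generator draws
vegetation heights from known per-cell distributions, every structural
variable has a closed-form expected value.

Conventions
-----------
* Planar metric coordinates; the landscape occupies [0, width] × [0, height].
* 1-m² cells, half-open [i, i+1) × [j, j+1); the cell centre is (i+.5, j+.5).
* Water is represented by the *absence* of returns: water cells emit no
  points of any class, mimicking the "no data" signature of open water in
  national ALS products.
* Classes use ASPRS codes: 2 = ground, 3 = vegetation, 9 = water, 1 = other.
* Ground points are a jittered grid — at least one per land cell — so k-NN
  ground interpolation is well-posed everywhere.
* Tree crowns are vertical point columns with return heights uniform between
  40% and 100% of the cell's canopy height.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Polygon, box

from .errors import ConfigError, PointCloudParseError

CLASS_GROUND = 2
CLASS_VEGETATION = 3
CLASS_WATER = 9
CLASS_OTHER = 1

#: vegetation-return class codes accepted on input (low/medium/high vegetation)
VEGETATION_CODES = frozenset({3, 4, 5})

_CLASS_NAMES = {
    "ground": CLASS_GROUND,
    "vegetation": CLASS_VEGETATION,
    "water": CLASS_WATER,
    "other": CLASS_OTHER,
}

#: per-zone defaults: (vegetation density pt/m², height range key)
_ZONE_DEFAULTS = {
    "meadow": (3.0, "meadow_height_range"),
    "herb": (7.0, "herb_height_range"),
    "reedbed": (7.0, "reedbed_height_range"),
    "shrub": (7.0, "shrub_height_range"),
    "forest": (7.0, "tree_height_range"),
}

#: fraction of local canopy height at which forest returns start (crown base)
CROWN_BASE_FRACTION = 0.4


@dataclass
class Zone:
    """A labelled vegetation zone.

    ``label`` selects the default vegetation density and height range from
    the landscape config; ``density`` and ``height_range`` override them.
    """

    label: str
    polygon: Polygon
    density: float | None = None
    height_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.label not in _ZONE_DEFAULTS:
            raise ConfigError(
                f"unknown zone label {self.label!r}; expected one of "
                f"{sorted(_ZONE_DEFAULTS)}"
            )


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Densities are in points per m²; heights in metres.  All randomness is
    driven by the single integer ``seed``.
    """

    extent_m: tuple[float, float] = (300.0, 300.0)
    water_channel: Sequence[tuple[float, float]] | None = None
    water_width_m: float = 10.0
    zones: list[Zone] = field(default_factory=list)
    ground_density: float = 2.5
    meadow_height_range: tuple[float, float] = (0.05, 0.4)
    herb_height_range: tuple[float, float] = (0.1, 1.0)
    reedbed_height_range: tuple[float, float] = (0.5, 2.5)
    shrub_height_range: tuple[float, float] = (1.0, 5.0)
    tree_height_range: tuple[float, float] = (10.0, 22.0)
    ground_elevation_model: str = "field"  # constant | slope | field
    ground_elevation_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ConfigError(f"extent must be positive, got {self.extent_m}")
        if self.ground_density < 0:
            raise ConfigError("ground_density must be >= 0")
        for name in (
            "meadow_height_range",
            "herb_height_range",
            "reedbed_height_range",
            "shrub_height_range",
            "tree_height_range",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be ordered low < high, got ({lo}, {hi})")
        if self.ground_elevation_model not in ("constant", "slope", "field"):
            raise ConfigError(
                f"unknown ground_elevation_model {self.ground_elevation_model!r}"
            )
        ext = box(0, 0, w, h)
        for z in self.zones:
            if z.density is not None and z.density < 0:
                raise ConfigError(f"zone {z.label!r} density must be >= 0")
            if not z.polygon.within(ext.buffer(1e-6)):
                raise ConfigError(f"zone {z.label!r} lies outside the extent")

    def zone_density(self, zone: Zone) -> float:
        if zone.density is not None:
            return zone.density
        return _ZONE_DEFAULTS[zone.label][0]

    def zone_height_range(self, zone: Zone) -> tuple[float, float]:
        if zone.height_range is not None:
            return zone.height_range
        return getattr(self, _ZONE_DEFAULTS[zone.label][1])


@dataclass
class PointCloud:
    """Classified returns over a planar metric grid."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    cls: np.ndarray
    bounds: tuple[float, float, float, float]  # minx, miny, maxx, maxy

    def __len__(self) -> int:
        return len(self.x)

    @property
    def is_ground(self) -> np.ndarray:
        return self.cls == CLASS_GROUND

    @property
    def is_vegetation(self) -> np.ndarray:
        return np.isin(self.cls, list(VEGETATION_CODES))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "z": self.z, "class": self.cls})

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.x[mask], self.y[mask], self.z[mask], self.cls[mask], self.bounds)


@dataclass
class TruthRasters:
    """Per-cell ground truth of the generated landscape.

    Vegetation heights in cell (i, j) are uniform on [h_lo, h_hi] with
    expected ``veg_density`` returns per m², on top of ``ground_density``
    ground returns; bare cells have veg_density 0.  From these the expected
    value of every structural metric follows in closed form.
    """

    ground_elev: np.ndarray  # (ny, nx)
    water: np.ndarray  # bool
    veg_density: np.ndarray
    h_lo: np.ndarray
    h_hi: np.ndarray
    ground_density: float
    zone_id: np.ndarray  # -1 bare, else index into config.zones

    @property
    def shape(self) -> tuple[int, int]:
        return self.ground_elev.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        return np.arange(nx) + 0.5, np.arange(ny) + 0.5

    def band_fraction(self, lo: float, hi: float) -> np.ndarray:
        """Expected fraction of returns that are vegetation in [lo, hi)."""
        span = np.where(self.veg_density > 0, self.h_hi - self.h_lo, 1.0)
        overlap = np.clip(np.minimum(self.h_hi, hi) - np.maximum(self.h_lo, lo), 0, None)
        p_band = np.where(self.veg_density > 0, overlap / span, 0.0)
        total = self.veg_density + self.ground_density
        frac = np.where(total > 0, self.veg_density * p_band / np.maximum(total, 1e-300), 0.0)
        return np.where(self.water, np.nan, frac)

    def band_density_pct(self, lo: float, hi: float) -> np.ndarray:
        """Expected band density in % of total returns, NaN on water."""
        return 100.0 * self.band_fraction(lo, hi)

    @property
    def veg_q90(self) -> np.ndarray:
        """True 90th percentile of the vegetation-height distribution; 0 where bare."""
        q = self.h_lo + 0.9 * (self.h_hi - self.h_lo)
        q = np.where(self.veg_density > 0, q, 0.0)
        return np.where(self.water, np.nan, q)


def _rasterize_zones(config: LandscapeConfig, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    """Zone index per cell (-1 = bare ground); later zones override earlier."""
    xx, yy = np.meshgrid(cx, cy)
    zone_id = np.full(xx.shape, -1, dtype=int)
    for i, zone in enumerate(config.zones):
        inside = shapely.contains_xy(zone.polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
        zone_id[inside] = i
    return zone_id


def _water_mask(config: LandscapeConfig, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    if config.water_channel is None:
        return np.zeros((len(cy), len(cx)), dtype=bool)
    channel = LineString(config.water_channel).buffer(config.water_width_m / 2.0)
    xx, yy = np.meshgrid(cx, cy)
    return shapely.contains_xy(channel, xx.ravel(), yy.ravel()).reshape(xx.shape)


def _ground_elevation(
    config: LandscapeConfig, cx: np.ndarray, cy: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    xx, yy = np.meshgrid(cx, cy)
    params = config.ground_elevation_params
    if config.ground_elevation_model == "constant":
        return np.full(xx.shape, float(params.get("z0", 0.0)))
    if config.ground_elevation_model == "slope":
        gx = float(params.get("gx", 0.002))
        gy = float(params.get("gy", 0.001))
        z0 = float(params.get("z0", 0.0))
        return z0 + gx * xx + gy * yy
    # smooth random field: low-pass filtered white noise, rescaled
    amp = float(params.get("amplitude", 0.4))
    sigma = float(params.get("sigma", 20.0))
    noise = rng.standard_normal(xx.shape)
    smooth = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth * (amp / sd)
    return smooth + float(params.get("z0", 0.0))


def generate_landscape(config: LandscapeConfig) -> tuple[PointCloud, TruthRasters]:
    """Generate a classified point cloud and its ground-truth rasters.

    Deterministic for a given config (including its seed).  Water cells emit
    zero returns; every land cell carries at least one ground return.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.extent_m
    nx, ny = int(round(width)), int(round(height))
    cx = np.arange(nx) + 0.5
    cy = np.arange(ny) + 0.5

    water = _water_mask(config, cx, cy)
    zone_id = _rasterize_zones(config, cx, cy)
    elev = _ground_elevation(config, cx, cy, rng)

    # per-cell vegetation density and height-range rasters
    veg_density = np.zeros((ny, nx))
    h_lo = np.zeros((ny, nx))
    h_hi = np.zeros((ny, nx))
    for i, zone in enumerate(config.zones):
        sel = zone_id == i
        dens = config.zone_density(zone)
        lo, hi = config.zone_height_range(zone)
        veg_density[sel] = dens
        if zone.label == "forest":
            # per-cell canopy height; returns span the crown 40-100%
            canopy = rng.uniform(lo, hi, size=int(sel.sum()))
            h_lo[sel] = CROWN_BASE_FRACTION * canopy
            h_hi[sel] = canopy
        else:
            h_lo[sel] = lo
            h_hi[sel] = hi
    veg_density[water] = 0.0

    elev_interp = RegularGridInterpolator(
        (cy, cx), elev, method="linear", bounds_error=False, fill_value=None
    )

    land = ~water
    jj, ii = np.nonzero(land)  # row (y), col (x) indices of land cells

    # --- ground returns: jittered grid (>=1 per land cell) + Poisson excess
    n_extra = rng.poisson(max(config.ground_density - 1.0, 0.0), size=len(ii))
    counts_g = 1 + n_extra
    cell_x = np.repeat(ii, counts_g)
    cell_y = np.repeat(jj, counts_g)
    gx = cell_x + rng.uniform(0, 1, size=len(cell_x))
    gy = cell_y + rng.uniform(0, 1, size=len(cell_y))
    gz = elev_interp(np.column_stack([gy, gx]))

    # --- vegetation returns
    lam = veg_density[jj, ii]
    counts_v = rng.poisson(lam)
    vcell_x = np.repeat(ii, counts_v)
    vcell_y = np.repeat(jj, counts_v)
    vx = vcell_x + rng.uniform(0, 1, size=len(vcell_x))
    vy = vcell_y + rng.uniform(0, 1, size=len(vcell_y))
    vlo = np.repeat(h_lo[jj, ii], counts_v)
    vhi = np.repeat(h_hi[jj, ii], counts_v)
    vh = rng.uniform(vlo, vhi)
    vz = elev_interp(np.column_stack([vy, vx])) + vh

    x = np.concatenate([gx, vx])
    y = np.concatenate([gy, vy])
    z = np.concatenate([gz, vz])
    cls = np.concatenate(
        [
            np.full(len(gx), CLASS_GROUND, dtype=np.int16),
            np.full(len(vx), CLASS_VEGETATION, dtype=np.int16),
        ]
    )
    cloud = PointCloud(x, y, z, cls, bounds=(0.0, 0.0, float(width), float(height)))
    truth = TruthRasters(
        ground_elev=elev,
        water=water,
        veg_density=veg_density,
        h_lo=h_lo,
        h_hi=h_hi,
        ground_density=float(config.ground_density),
        zone_id=zone_id,
    )
    return cloud, truth


def default_config(seed: int = 0, extent: tuple[float, float] = (300.0, 300.0)) -> LandscapeConfig:
    """A riparian mosaic: channel, meadows, herb band, reedbed, shrubs, forest.

    The layout scales with the extent so smaller desk-scale landscapes keep
    all habitat types.
    """
    w, h = extent
    sx, sy = w / 300.0, h / 300.0

    def B(x0, y0, x1, y1):
        return box(x0 * sx, y0 * sy, x1 * sx, y1 * sy)

    channel = [(0.0, 150.0 * sy), (0.33 * w, 160.0 * sy), (0.66 * w, 140.0 * sy), (w, 150.0 * sy)]
    zones = [
        Zone("meadow", B(0, 170, 300, 300)),
        Zone("herb", B(0, 115, 300, 170)),
        Zone("reedbed", B(0, 95, 120, 115)),
        Zone("shrub", B(150, 60, 220, 115)),
        Zone("shrub", B(40, 215, 90, 265)),
        Zone("forest", B(220, 0, 300, 115)),
        Zone("forest", B(0, 0, 150, 40)),
    ]
    return LandscapeConfig(
        extent_m=(float(w), float(h)),
        water_channel=channel,
        water_width_m=10.0 * min(sx, sy),
        zones=zones,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# point-cloud I/O (CSV dialect: header x,y,z,class; metres; '.' decimal)
# ---------------------------------------------------------------------------

def write_pointcloud(cloud: PointCloud, path, format: str = "csv") -> None:
    """Write a point cloud; only the CSV dialect is supported."""
    if format != "csv":
        raise ConfigError(f"unsupported point-cloud format {format!r}; use 'csv'")
    cloud.to_dataframe().to_csv(path, index=False, float_format="%.3f")


def read_pointcloud(path, format: str = "csv") -> PointCloud:
    """Read a CSV point cloud, validating every record.

    Malformed coordinates or class labels raise :class:`PointCloudParseError`
    naming the 1-based file line of the offending record.  Class labels may
    be ASPRS codes (2 ground, 3/4/5 vegetation, 9 water) or the names
    ``ground``/``vegetation``/``water``/``other``.
    """
    if format != "csv":
        raise ConfigError(f"unsupported point-cloud format {format!r}; use 'csv'")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    expected = ["x", "y", "z", "class"]
    if list(df.columns[:4]) != expected:
        raise PointCloudParseError(
            f"{path}: expected header {','.join(expected)}, got {','.join(df.columns)}"
        )
    coords = {}
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +1 header, +1 1-based
            raise PointCloudParseError(
                f"{path}: line {line}: non-numeric value {df[col].iloc[line - 2]!r} in column {col!r}"
            )
        coords[col] = vals.to_numpy(dtype=float)
    cls_raw = df["class"].astype(str).str.strip().str.lower()
    cls = pd.to_numeric(cls_raw, errors="coerce")
    named = cls_raw.map(_CLASS_NAMES)
    cls = cls.fillna(named)
    if cls.isna().any():
        line = int(np.nonzero(cls.isna().to_numpy())[0][0]) + 2
        raise PointCloudParseError(
            f"{path}: line {line}: unknown class label {df['class'].iloc[line - 2]!r}"
        )
    cls_arr = cls.to_numpy(dtype=np.int16)
    x, y = coords["x"], coords["y"]
    if len(x):
        bounds = (float(x.min()), float(y.min()), float(x.max()), float(y.max()))
    else:
        bounds = (0.0, 0.0, 0.0, 0.0)
    return PointCloud(x, y, coords["z"], cls_arr, bounds)


def pointcloud_from_csv_text(text: str) -> PointCloud:
    """Parse the CSV dialect from an in-memory string (convenience for tests)."""
    return read_pointcloud(io.StringIO(text))
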