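"""Plot chain and habitat-variable contracts against brute-force oracles."""

import numpy as np
import pytest

from lidarhab.errors import NormalizationError
from lidarhab.landscape import PointCloud
from lidarhab.metrics import (
    CellGrid,
    Plot,
    WaterGrid,
    band_density,
    canopy_cover,
    clip_plot,
    distance_to_water,
    extract_features,
    forest_edge_length,
    height_variation,
    inner_clip,
    normalize_heights,
    open_areas,
    rasterize_q90,
    structural_complexity,
    vegetation_height,
)

from conftest import random_cloud
from oracles import (
    brute_band_pct,
    brute_clip,
    brute_edge_length,
    brute_idw_ground,
    brute_nearest_water,
    brute_quantile,
    brute_sd,
)


def _plot(x, y, z, cls, center=(0.0, 0.0), radius=5.0, normalized=True):
    return Plot(
        center,
        radius,
        np.asarray(x, float),
        np.asarray(y, float),
        np.asarray(z, float),
        np.asarray(cls, np.int16),
        normalized=normalized,
    )


# --- clipping ---------------------------------------------------------------

def test_clip_retains_points_within_radius():
    cloud = PointCloud(
        np.array([3.0, 7.0, 12.0]), np.zeros(3), np.zeros(3),
        np.full(3, 2, np.int16), (0, 0, 12, 0),
    )
    plot = clip_plot(cloud, (0.0, 0.0), 10.0)
    assert sorted(plot.x) == [3.0, 7.0]


def test_clip_boundary_point_is_retained():
    cloud = PointCloud(
        np.array([10.0]), np.array([0.0]), np.array([0.0]),
        np.array([2], np.int16), (0, 0, 10, 0),
    )
    assert len(clip_plot(cloud, (0.0, 0.0), 10.0)) == 1


def test_clip_matches_exhaustive_distance_scan(rng):
    cloud = random_cloud(rng, n=2000, extent=40)
    center = (20.0, 18.0)
    plot = clip_plot(cloud, center, 9.0)
    keep = brute_clip(cloud.x, cloud.y, center, 9.0)
    assert sorted(plot.x) == pytest.approx(sorted(cloud.x[keep]))
    inner = inner_clip(plot, 4.0)
    keep_in = brute_clip(cloud.x, cloud.y, center, 4.0)
    assert sorted(inner.x) == pytest.approx(sorted(cloud.x[keep_in]))


def test_empty_clip_is_valid_water_plot():
    cloud = PointCloud(np.array([50.0]), np.array([50.0]), np.array([0.0]),
                       np.array([2], np.int16), (0, 0, 50, 50))
    assert len(clip_plot(cloud, (0.0, 0.0), 5.0)) == 0


# --- normalization ----------------------------------------------------------

def test_normalize_flat_ground():
    p = _plot([0, 1, 2, 0.5], [0, 0, 0, 0], [5, 5, 5, 7], [2, 2, 2, 3],
              normalized=False)
    with pytest.warns(UserWarning):  # fewer than k=10 ground points
        out = normalize_heights(p)
    veg_h = out.z[out.cls == 3]
    assert veg_h == pytest.approx([2.0])
    assert np.abs(out.z[out.cls == 2]).max() < 1e-12


def test_point_above_ground_return_takes_it_exactly():
    # sloping ground; vegetation point exactly above the middle ground return
    gx = [0.0, 1.0, 2.0]
    gz = [0.0, 0.5, 1.0]
    p = _plot(gx + [1.0], [0, 0, 0, 0], gz + [4.0], [2, 2, 2, 3], normalized=False)
    with pytest.warns(UserWarning):
        out = normalize_heights(p)
    assert out.z[-1] == pytest.approx(4.0 - 0.5, abs=1e-12)


def test_idw_matches_direct_formula(rng):
    n_g, n_v = 40, 25
    gx = rng.uniform(0, 20, n_g)
    gy = rng.uniform(0, 20, n_g)
    gz = 0.1 * gx + 0.05 * gy  # linear slope
    vx = rng.uniform(2, 18, n_v)
    vy = rng.uniform(2, 18, n_v)
    vz = rng.uniform(1, 10, n_v)
    p = _plot(
        np.concatenate([gx, vx]), np.concatenate([gy, vy]),
        np.concatenate([gz, vz]),
        [2] * n_g + [3] * n_v, center=(10, 10), radius=20, normalized=False,
    )
    out = normalize_heights(p, k=10, p=2.0)
    for i in range(n_g, n_g + n_v):
        ghat = brute_idw_ground(p.x[i], p.y[i], gx, gy, gz, k=10, p=2.0)
        assert out.z[i] == pytest.approx(p.z[i] - ghat, abs=1e-9)


def test_no_ground_points_raises():
    p = _plot([0, 1], [0, 0], [1, 2], [3, 3], normalized=False)
    with pytest.raises(NormalizationError):
        normalize_heights(p)


def test_normalization_buffer_gives_locality(herb_landscape):
    """Metrics at a position do not change when the cloud outside the outer
    radius is edited: the buffer isolates the plot from the rest."""
    cloud, _ = herb_landscape
    pos = (40.0, 40.0)
    row_full = _vertical_row(cloud, pos)
    far = (cloud.x - pos[0]) ** 2 + (cloud.y - pos[1]) ** 2 > 10.0**2
    edited = PointCloud(
        cloud.x.copy(), cloud.y.copy(),
        np.where(far, cloud.z + 50.0, cloud.z), cloud.cls.copy(), cloud.bounds,
    )
    row_edited = _vertical_row(edited, pos)
    assert row_full == pytest.approx(row_edited, abs=1e-12)


def _vertical_row(cloud, pos):
    plot5 = inner_clip(normalize_heights(clip_plot(cloud, pos, 10.0)), 5.0)
    return [
        band_density(plot5, 0, 1),
        vegetation_height(plot5),
        structural_complexity(plot5),
    ]


# --- vertical profile -------------------------------------------------------

def test_band_density_examples():
    # 4 vegetation points below 1 m among 10 total returns -> 40%
    z = [0.2, 0.5, 0.7, 0.9, 2, 3, 0, 0, 0, 0]
    cls = [3, 3, 3, 3, 3, 3, 2, 2, 2, 2]
    p = _plot(range(10), [0] * 10, z, cls)
    assert band_density(p, 0, 1) == pytest.approx(40.0)
    assert band_density(p, 5, 10) == 0.0
    assert np.isnan(band_density(_plot([], [], [], []), 0, 1))


def test_band_densities_and_ground_share_sum_to_100(rng):
    cloud = random_cloud(rng, n=500, extent=10)
    p = _plot(cloud.x, cloud.y, cloud.z, cloud.cls, center=(5, 5), radius=8)
    bands = [band_density(p, 0, 1), band_density(p, 1, 5),
             band_density(p, 5, 10), band_density(p, 10, np.inf)]
    below_zero = 100.0 * ((p.z < 0) & p.is_vegetation).sum() / len(p)
    ground_share = 100.0 * (~p.is_vegetation).sum() / len(p)
    assert sum(bands) + ground_share + below_zero == pytest.approx(100.0, abs=1e-9)


def test_band_density_matches_brute_force(rng):
    for _ in range(10):
        cloud = random_cloud(rng, n=200, extent=10)
        p = _plot(cloud.x, cloud.y, cloud.z, cloud.cls, center=(5, 5), radius=8)
        veg_h = p.z[p.is_vegetation]
        for lo, hi in ((0, 1), (1, 5), (5, 10), (10, np.inf)):
            assert band_density(p, lo, hi) == pytest.approx(
                brute_band_pct(veg_h, len(p), lo, hi), rel=1e-12
            )


def test_q90_linear_interpolation_value():
    p = _plot(range(10), [0] * 10, range(1, 11), [3] * 10)
    assert vegetation_height(p) == pytest.approx(9.1)
    assert vegetation_height(p) == pytest.approx(brute_quantile(range(1, 11), 0.9))


def test_q90_constant_and_bare_conventions():
    p = _plot([0, 1], [0, 0], [2.0, 2.0], [3, 3])
    assert vegetation_height(p) == 2.0
    bare = _plot([0], [0], [0.0], [2])
    assert vegetation_height(bare) == 0.0


def test_structural_complexity_examples(rng):
    assert structural_complexity(_plot([0, 1], [0, 0], [2, 2], [3, 3])) == 0.0
    assert structural_complexity(_plot([0, 1], [0, 0], [0, 2], [3, 3])) == pytest.approx(1.0)
    h = rng.uniform(0, 10, 50)
    p = _plot(range(50), [0] * 50, h, [3] * 50)
    assert structural_complexity(p) == pytest.approx(brute_sd(h), rel=1e-12)
    assert np.isnan(structural_complexity(_plot([0], [0], [1], [2])))


def test_canopy_cover_counts_only_above_threshold():
    z = [4.0, 2.0, 0.0, 0.0]
    p = _plot(range(4), [0] * 4, z, [3, 3, 2, 2])
    assert canopy_cover(p) == pytest.approx(25.0)


# --- rasterization and horizontal profile -----------------------------------

def _grid_from_masks(q90, water=None):
    q90 = np.asarray(q90, float)
    in_plot = np.ones_like(q90, bool)
    water = np.zeros_like(q90, bool) if water is None else np.asarray(water, bool)
    q = q90.copy()
    q[water] = np.nan
    return CellGrid(0, 0, in_plot, water, q, n_points=np.where(water, 0, 1))


def test_rasterize_empty_plot_flags_all_water():
    p = _plot([], [], [], [], center=(2.0, 2.0), radius=1.5)
    grid = rasterize_q90(p)
    assert grid.water[grid.in_plot].all()


def test_rasterize_single_cell_quantile_and_half_open_convention():
    # ten vegetation points in cell [3,4)x[3,4); one at x exactly 3.0
    xs = np.full(10, 3.5)
    xs[0] = 3.0
    p = _plot(xs, np.full(10, 3.5), range(1, 11), [3] * 10,
              center=(3.5, 3.5), radius=1.0)
    grid = rasterize_q90(p)
    i, j = 3 - grid.x0, 3 - grid.y0
    assert grid.q90[j, i] == pytest.approx(9.1)
    assert grid.n_points[j, i] == 10


def test_open_areas_conventions():
    assert open_areas(_grid_from_masks([[0, 0], [0, 0]])) == 4.0  # bare = open
    assert open_areas(_grid_from_masks([[4, 4], [4, 4]])) == 0.0
    checker = [[0, 1], [1, 0]]
    assert open_areas(_grid_from_masks(checker)) == 2.0


def test_open_areas_counts_in_plot_cells_of_bare_circle():
    p = _plot([], [], [], [], center=(0.0, 0.0), radius=25.0)
    grid = rasterize_q90(p)
    # bare (all-water here) cells are excluded; with ground points they count
    n_cells = int(grid.in_plot.sum())
    centers_x, centers_y = np.meshgrid(
        grid.x0 + np.arange(grid.in_plot.shape[1]) + 0.5,
        grid.y0 + np.arange(grid.in_plot.shape[0]) + 0.5,
    )
    manual = ((centers_x**2 + centers_y**2) <= 25.0**2).sum()
    assert n_cells == manual


def test_height_variation_examples(rng):
    assert height_variation(_grid_from_masks([[2, 2], [2, 2]])) == 0.0
    assert height_variation(_grid_from_masks([[0, 2]])) == pytest.approx(1.0)
    vals = rng.uniform(0, 5, (6, 6))
    assert height_variation(_grid_from_masks(vals)) == pytest.approx(
        brute_sd(vals.ravel()) ** 2, rel=1e-9
    )


def test_forest_edge_isolated_cell_and_block():
    q = np.zeros((5, 5))
    q[2, 2] = 5.0
    assert forest_edge_length(_grid_from_masks(q)) == 4.0
    q2 = np.zeros((4, 4))
    q2[1:3, 1:3] = 5.0
    assert forest_edge_length(_grid_from_masks(q2)) == 8.0


def test_forest_edge_matches_brute_scan_and_bound(rng):
    for _ in range(5):
        q = np.where(rng.uniform(size=(8, 8)) < 0.4, 5.0, 0.0)
        grid = _grid_from_masks(q)
        forest = grid.in_plot & ~grid.water & (grid.q90 > 3.0)
        expected = brute_edge_length(forest, grid.in_plot)
        assert forest_edge_length(grid) == expected
        assert forest_edge_length(grid) <= 4 * forest.sum()


def test_forest_edge_boundary_sides_not_counted():
    # full forest: no internal ecotone at all
    q = np.full((3, 3), 5.0)
    assert forest_edge_length(_grid_from_masks(q)) == 0.0


def test_forest_edge_perimeter_mode():
    q = np.zeros((4, 4))
    q[1:3, 1:3] = 5.0
    assert forest_edge_length(_grid_from_masks(q), mode="perimeter") == 16.0


def test_water_counts_as_nonforest_neighbour():
    q = np.zeros((3, 3))
    q[1, 1] = 5.0
    water = np.zeros((3, 3), bool)
    water[1, 0] = True
    assert forest_edge_length(_grid_from_masks(q, water)) == 4.0


# --- distance to water ------------------------------------------------------

def _cloud_with_gap(extent=30, gap=None):
    """Dense ground grid with an optional rectangular zero-return gap."""
    xs, ys = np.meshgrid(np.arange(extent) + 0.5, np.arange(extent) + 0.5)
    x, y = xs.ravel(), ys.ravel()
    if gap is not None:
        x0, y0, x1, y1 = gap
        keep = ~((x >= x0) & (x < x1) & (y >= y0) & (y < y1))
        x, y = x[keep], y[keep]
    z = np.zeros(len(x))
    return PointCloud(x, y, z, np.full(len(x), 2, np.int16), (0, 0, extent, extent))


def test_distance_to_water_due_east():
    cloud = _cloud_with_gap(gap=(25, 14, 26, 16))
    # water cell centred at (25.5, 14.5); query from (15.5, 14.5)
    assert distance_to_water(cloud, (15.5, 14.5), radii=(250, 400)) == pytest.approx(10.0)


def test_distance_to_water_no_water_returns_nan():
    cloud = _cloud_with_gap(gap=None)
    assert np.isnan(distance_to_water(cloud, (15.0, 15.0), radii=(5.0, 8.0)))


def test_point_in_water_cell_has_distance_zero():
    cloud = _cloud_with_gap(gap=(10, 10, 12, 12))
    assert distance_to_water(cloud, (10.9, 10.2)) == 0.0


def test_distance_escalates_to_larger_radius():
    cloud = _cloud_with_gap(extent=30, gap=(27, 14, 28, 16))
    d = distance_to_water(cloud, (5.5, 14.5), radii=(10.0, 400.0))
    assert d == pytest.approx(22.0)
    assert np.isnan(distance_to_water(cloud, (5.5, 14.5), radii=(10.0, 20.0)))


def test_distance_matches_exhaustive_scan(rng):
    for _ in range(5):
        extent = 20
        cloud = _cloud_with_gap(extent=extent)
        drop = rng.uniform(size=len(cloud.x)) < 0.1
        cloud = cloud.subset(~drop)
        grid = WaterGrid(cloud)
        wm = ~grid.occupied
        if not wm.any():
            continue
        point = tuple(rng.uniform(2, extent - 2, 2))
        got = distance_to_water(cloud, point, radii=(250, 400))
        want = brute_nearest_water(point, wm, grid.x0, grid.y0)
        if grid.cell_is_water(point):
            assert got == 0.0
        else:
            assert got == pytest.approx(want, rel=1e-12)


# --- full extraction --------------------------------------------------------

def test_extract_features_row_count_and_labels(herb_landscape):
    cloud, _ = herb_landscape
    positions = [(30, 30), (50, 50), (60, 20)]
    df = extract_features(cloud, positions, labels=["presence", "background", "presence"])
    assert len(df) == 3
    assert list(df["label"]) == ["presence", "background", "presence"]
    # no water in this landscape: dist_water undefined, all else defined
    assert df.drop(columns=["label", "dist_water"]).notna().all().all()
    assert df["dist_water"].isna().all()


def test_extract_matches_truth_on_homogeneous_herb(herb_landscape):
    """On a homogeneous herb layer the extracted variables sit within
    sampling tolerance of the generator truth."""
    cloud, truth = herb_landscape
    df = extract_features(cloud, [(40, 40)])
    row = df.iloc[0]
    assert row["lt1_density"] == pytest.approx(truth.band_density_pct(0, 1)[40, 40], abs=5.0)
    assert row["veg_height"] == pytest.approx(truth.veg_q90[40, 40], abs=0.15)
    assert row["d1_5_density"] <= 1.0
    # true Q90 is 0.91 m > 0.5, but a cell's empirical Q90 over a handful of
    # returns occasionally dips below 0.5: open area stays a small fraction
    n_cells = 1963  # cells with centre within 25 m
    assert row["open_areas"] < 0.15 * n_cells
    assert row["forest_edge"] == 0.0
    assert np.isnan(row["dist_water"])  # no water anywhere in this landscape
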