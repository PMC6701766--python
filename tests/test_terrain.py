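"""Terrain attribute derivation, circular smoothing, standardization."""

import numpy as np
import pytest

from pedovox.grids import CovariateStack, ElevationGrid, LayerInfo
from pedovox import terrain
from pedovox.terrain import (SmoothingConfig, apply_standardization, circular_kernel,
                             derive_base_attributes, flow_accumulation, replicate_to,
                             smooth_multiscale, standardize)


def _stack_from(arrays: dict) -> CovariateStack:
    s = CovariateStack()
    for name, v in arrays.items():
        s.add(name, np.asarray(v, dtype=float))
    return s


def test_constant_dem_has_zero_slope():
    dem = ElevationGrid(np.full((9, 9), 150.0))
    stack = derive_base_attributes(dem, catalogue=("slope",))
    assert np.allclose(stack["slope"], 0.0)


def test_inclined_plane_slope_is_analytic():
    """z = 0.1 x gives slope arctan(0.1) = 5.71 degrees on interior cells."""
    dem = ElevationGrid(np.tile(0.1 * 5.0 * np.arange(12), (12, 1)), cell_size_cm=500.0)
    stack = derive_base_attributes(dem, catalogue=("slope", "eastness", "northness"))
    interior = stack["slope"][1:-1, 1:-1]
    assert np.allclose(interior, np.degrees(np.arctan(0.1)), atol=1e-9)
    # plane dips to the west: steepest descent points west
    assert np.allclose(stack["eastness"][1:-1, 1:-1], -1.0, atol=1e-9)


def test_eastness_northness_unit_circle(small_dem):
    stack = derive_base_attributes(small_dem, catalogue=("slope", "eastness", "northness"))
    sloped = stack["slope"] > 1e-9
    norm = stack["eastness"][sloped] ** 2 + stack["northness"][sloped] ** 2
    assert np.allclose(norm, 1.0)


def test_rotation_maps_eastness_to_northness(small_dem):
    """Rotating the DEM 90 deg counterclockwise turns east-facing into
    north-facing cells."""
    rot = ElevationGrid(np.rot90(small_dem.values), cell_size_cm=small_dem.cell_size_cm)
    orig = derive_base_attributes(small_dem, catalogue=("eastness", "northness"))
    rotd = derive_base_attributes(rot, catalogue=("eastness", "northness"))
    assert np.allclose(np.rot90(orig["eastness"]), rotd["northness"], atol=1e-9)


def test_flow_accumulation_conserves_area(small_dem):
    acc = flow_accumulation(small_dem)
    z = small_dem.values
    cell_area = small_dem.cell_size_m ** 2
    # outlets: no strictly lower 8-neighbour
    zp = np.pad(z, 1, mode="constant", constant_values=np.inf)
    lower = np.zeros(z.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            lower |= zp[1 + dr:zp.shape[0] - 1 + dr, 1 + dc:zp.shape[1] - 1 + dc] < z
    total_outlet = acc[~lower].sum()
    assert total_outlet == pytest.approx(z.size * cell_area, rel=1e-9)


def test_flat_dem_twi_floors_slope(caplog):
    dem = ElevationGrid(np.full((8, 8), 10.0))
    with caplog.at_level("WARNING"):
        stack = derive_base_attributes(dem, catalogue=("slope", "twi"))
    assert np.all(np.isfinite(stack["twi"]))


def brute_force_circular_mean(values, radius):
    out = np.empty_like(values, dtype=float)
    n, m = values.shape
    for i in range(n):
        for j in range(m):
            acc, cnt = 0.0, 0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if di * di + dj * dj <= radius * radius:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < n and 0 <= jj < m and np.isfinite(values[ii, jj]):
                            acc += values[ii, jj]
                            cnt += 1
            out[i, j] = acc / cnt if cnt else np.nan
    return out


@pytest.mark.parametrize("radius", [1, 2, 4, 6])
def test_smoothing_matches_brute_force(radius):
    rng = np.random.default_rng(radius)
    values = rng.normal(size=(15, 15))
    values[3, 4] = np.nan  # one nodata hole
    stack = _stack_from({"v": values})
    out = smooth_multiscale(stack, SmoothingConfig(radii=(radius,)))
    expected = brute_force_circular_mean(values, radius)
    expected[3, 4] = np.nan
    assert np.allclose(out[f"v_r{radius}"], expected, equal_nan=True)


def test_radius_one_is_plus_shaped():
    k = circular_kernel(1)
    assert k.sum() == 5  # centre + 4 orthogonal neighbours
    rng = np.random.default_rng(0)
    v = rng.normal(size=(7, 7))
    out = smooth_multiscale(_stack_from({"v": v}), SmoothingConfig(radii=(1,)))["v_r1"]
    i, j = 3, 3
    manual = np.mean([v[i, j], v[i - 1, j], v[i + 1, j], v[i, j - 1], v[i, j + 1]])
    assert out[i, j] == pytest.approx(manual)


def test_58_layers_times_5_radii_gives_290(small_dem):
    base = derive_base_attributes(small_dem)
    padded = replicate_to(base, 58)
    assert len(padded) == 58
    out = smooth_multiscale(padded, SmoothingConfig(radii=(1, 2, 4, 6, 8)))
    assert len(out) == 290


def test_constant_layer_unchanged_by_smoothing():
    stack = _stack_from({"c": np.full((10, 10), 3.3)})
    out = smooth_multiscale(stack, SmoothingConfig(radii=(1, 2, 4)))
    for name in out.names:
        assert np.allclose(out[name], 3.3)


def test_smoothing_is_linear():
    rng = np.random.default_rng(5)
    a, b = 2.0, -0.7
    l1, l2 = rng.normal(size=(2, 12, 12))
    combo = smooth_multiscale(_stack_from({"v": a * l1 + b * l2}),
                              SmoothingConfig(radii=(2,)))["v_r2"]
    s1 = smooth_multiscale(_stack_from({"v": l1}), SmoothingConfig(radii=(2,)))["v_r2"]
    s2 = smooth_multiscale(_stack_from({"v": l2}), SmoothingConfig(radii=(2,)))["v_r2"]
    assert np.allclose(combo, a * s1 + b * s2)


def test_oversized_radius_rejected():
    stack = _stack_from({"v": np.zeros((8, 8))})
    with pytest.raises(ValueError, match="half-extent"):
        smooth_multiscale(stack, SmoothingConfig(radii=(5,)))


def test_standardize_moments_and_round_trip():
    rng = np.random.default_rng(6)
    stack = _stack_from({"a": rng.normal(3, 2, (9, 9)), "b": rng.uniform(0, 10, (9, 9))})
    std, stats = standardize(stack)
    for name in std.names:
        assert abs(np.nanmean(std[name])) < 1e-10
        assert abs(np.nanstd(std[name]) - 1) < 1e-10
    again = apply_standardization(stack, stats)
    for name in std.names:
        assert np.allclose(again[name], std[name])


def test_constant_layer_dropped_with_warning(caplog):
    stack = _stack_from({"a": np.arange(16.0).reshape(4, 4), "flat": np.full((4, 4), 2.0)})
    with caplog.at_level("WARNING"):
        std, _ = standardize(stack)
    assert "flat" not in std.names
    assert any("constant" in r.message for r in caplog.records)
    with pytest.raises(ValueError):
        standardize(_stack_from({"flat": np.full((4, 4), 2.0)}))
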