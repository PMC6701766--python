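"""Terrain analysis: base attribute derivation, multi-scale smoothing, standardization.

Base morphometry (slope, aspect-derived eastness/northness, curvatures) comes
from a local quadratic surface fitted to the 3x3 window (Evans' method).
Catchment area uses top-down multiple-flow-direction accumulation (Freeman
style, slope-weighted with exponent 1.1). Combined attributes:

    TWI = ln(specific catchment area / tan(slope))
    LS  = (SCA / 22.13)^0.4 * (sin(slope) / 0.0896)^1.3

Vertical distance to channel network follows the steepest-descent path from
each cell to the first channel cell (accumulation above a contributing-area
threshold, default 1 ha) and reports the elevation drop.

Every attribute can then be expanded across scales with circular mean
filters (neighbourhood = cells whose centre distance <= radius, truncated at
grid edges) and the resulting stack centred and scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import CovariateStack, ElevationGrid, LayerInfo

log = logging.getLogger(__name__)

DEFAULT_CATALOGUE = (
    "slope", "eastness", "northness",
    "plan_curvature", "profile_curvature", "tangential_curvature",
    "catchment_area", "twi", "ls_factor", "vertical_channel_distance",
)

_SLOPE_EPS = 1e-6  # rad; floor for tan(slope) in TWI on flat cells


def _evans_derivatives(z: np.ndarray, h: float):
    """Partial derivatives of the best-fit quadratic surface over each 3x3 window.

    Edge rows/columns use replicated padding. x increases eastward (columns),
    y increases northward (rows decrease).
    """
    zp = np.pad(z, 1, mode="edge")
    n = zp[:-2, 1:-1]; s = zp[2:, 1:-1]; w = zp[1:-1, :-2]; e = zp[1:-1, 2:]
    nw = zp[:-2, :-2]; ne = zp[:-2, 2:]; sw = zp[2:, :-2]; se = zp[2:, 2:]
    c = z
    zx = (ne + e + se - nw - w - sw) / (6 * h)
    zy = (nw + n + ne - sw - s - se) / (6 * h)
    zxx = (nw + ne + w + e + sw + se - 2 * (n + c + s)) / (3 * h**2)
    zyy = (nw + n + ne + sw + s + se - 2 * (w + c + e)) / (3 * h**2)
    zxy = (ne + sw - nw - se) / (4 * h**2)
    return zx, zy, zxx, zyy, zxy


_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flow_accumulation(dem: ElevationGrid, exponent: float = 1.1) -> np.ndarray:
    """Top-down multiple-flow-direction accumulated area (m^2 per cell).

    Cells are processed from highest to lowest; each cell's accumulated area
    (its own cell area plus inflow) is distributed among strictly lower
    neighbours proportionally to slope^exponent. Cells with no lower
    neighbour (pits, outlets) retain their accumulation, so total area is
    conserved at the sinks.
    """
    z = dem.values
    valid = dem.mask
    h = dem.cell_size_m
    cell_area = h * h
    acc = np.where(valid, cell_area, 0.0)
    nrow, ncol = z.shape
    order = np.argsort(z, axis=None, kind="stable")[::-1]
    dists = {d: h * np.hypot(d[0], d[1]) for d in _D8}
    zf = z.ravel()
    for flat in order:
        r, c = divmod(int(flat), ncol)
        if not valid[r, c]:
            continue
        zc = zf[flat]
        weights, targets = [], []
        for dr, dc in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc]:
                dz = zc - z[rr, cc]
                if dz > 0:
                    weights.append((dz / dists[(dr, dc)]) ** exponent)
                    targets.append((rr, cc))
        if not targets:
            continue
        w = np.array(weights)
        share = acc[r, c] * w / w.sum()
        for (rr, cc), s in zip(targets, share):
            acc[rr, cc] += s
    acc[~valid] = np.nan
    return acc


def _downstream_pointer(dem: ElevationGrid) -> np.ndarray:
    """Steepest-descent (D8) downstream neighbour as flat index; -1 where none."""
    z = dem.values
    valid = dem.mask
    h = dem.cell_size_m
    nrow, ncol = z.shape
    ptr = np.full(z.shape, -1, dtype=np.int64)
    for r in range(nrow):
        for c in range(ncol):
            if not valid[r, c]:
                continue
            best, best_grad = -1, 0.0
            for dr, dc in _D8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc]:
                    grad = (z[r, c] - z[rr, cc]) / (h * np.hypot(dr, dc))
                    if grad > best_grad:
                        best_grad, best = grad, rr * ncol + cc
            ptr[r, c] = best
    return ptr


def vertical_channel_distance(dem: ElevationGrid, acc: np.ndarray,
                              channel_threshold_m2: float = 10_000.0) -> np.ndarray:
    """Elevation above the nearest downslope channel cell.

    Channel cells are those whose accumulated area exceeds the threshold
    (default 1 ha). Cells whose flow path ends in a non-channel pit use the
    pit elevation as local base level. If no cell exceeds the threshold the
    single highest-accumulation cell is used as channel.
    """
    z = dem.values
    valid = dem.mask
    channels = valid & (acc >= channel_threshold_m2)
    if not channels.any():
        flat = np.nanargmax(np.where(valid, acc, -np.inf))
        channels.ravel()[flat] = True
    ptr = _downstream_pointer(dem)
    base = np.full(z.shape, np.nan)
    zf, bf, chf, pf = z.ravel(), base.ravel(), channels.ravel(), ptr.ravel()
    order = np.argsort(z, axis=None, kind="stable")  # ascending: downstream first
    for flat in order:
        r, c = divmod(int(flat), z.shape[1])
        if not valid[r, c]:
            continue
        if chf[flat] or pf[flat] < 0:
            bf[flat] = zf[flat]
        else:
            bf[flat] = bf[pf[flat]]
    out = z - base
    out[~valid] = np.nan
    return out


def derive_base_attributes(dem: ElevationGrid, catalogue=DEFAULT_CATALOGUE,
                           channel_threshold_m2: float = 10_000.0) -> CovariateStack:
    """Compute the requested base terrain attributes from the DEM (radius 0 layers)."""
    unknown = set(catalogue) - set(DEFAULT_CATALOGUE)
    if unknown:
        raise ValueError(f"unknown terrain attributes: {sorted(unknown)}")
    z = dem.values
    valid = dem.mask
    h = dem.cell_size_m
    zx, zy, zxx, zyy, zxy = _evans_derivatives(np.where(valid, z, np.nanmean(z)), h)
    g2 = zx**2 + zy**2
    slope_rad = np.arctan(np.sqrt(g2))
    flat = g2 == 0
    if flat[valid].all() and ("twi" in catalogue or "ls_factor" in catalogue):
        log.warning("flat DEM: slope floored at %.0e rad for TWI/LS", _SLOPE_EPS)

    stack = CovariateStack(cell_size_cm=dem.cell_size_cm, origin=dem.origin)

    def add(name, vals, estimator):
        vals = np.where(valid, vals, np.nan)
        stack.add(name, vals, LayerInfo(base=name, estimator=estimator, radius=0))

    needs_flow = {"catchment_area", "twi", "ls_factor", "vertical_channel_distance"} & set(catalogue)
    acc = flow_accumulation(dem) if needs_flow else None
    sca = acc / h if acc is not None else None  # specific catchment area (m)

    for name in catalogue:
        if name == "slope":
            add(name, np.degrees(slope_rad), "evans_quadratic")
        elif name in ("eastness", "northness"):
            # azimuth of steepest descent, clockwise from north
            az = np.arctan2(-zx, -zy)
            vals = np.sin(az) if name == "eastness" else np.cos(az)
            add(name, np.where(flat, 0.0, vals), "evans_quadratic")
        elif name in ("plan_curvature", "profile_curvature", "tangential_curvature"):
            with np.errstate(divide="ignore", invalid="ignore"):
                if name == "profile_curvature":
                    k = -(zxx * zx**2 + 2 * zxy * zx * zy + zyy * zy**2) / (
                        g2 * (1 + g2) ** 1.5)
                elif name == "plan_curvature":
                    k = -(zxx * zy**2 - 2 * zxy * zx * zy + zyy * zx**2) / g2**1.5
                else:
                    k = -(zxx * zy**2 - 2 * zxy * zx * zy + zyy * zx**2) / (
                        g2 * np.sqrt(1 + g2))
            add(name, np.where(flat, 0.0, k), "evans_quadratic")
        elif name == "catchment_area":
            add(name, acc, "mfd_topdown")
        elif name == "twi":
            tan_s = np.maximum(np.tan(slope_rad), _SLOPE_EPS)
            add(name, np.log(np.maximum(sca, h) / tan_s), "sca_over_tan_slope")
        elif name == "ls_factor":
            sin_s = np.maximum(np.sin(slope_rad), _SLOPE_EPS)
            add(name, (np.maximum(sca, h) / 22.13) ** 0.4 * (sin_s / 0.0896) ** 1.3,
                "moore_burch")
        elif name == "vertical_channel_distance":
            add(name, vertical_channel_distance(dem, acc, channel_threshold_m2), "d8_path")
    return stack


# ---------------------------------------------------------------------------
# multi-scale smoothing

@dataclass(frozen=True)
class SmoothingConfig:
    """Circular mean-filter radii in pixels (reference: 1, 2, 4, 6, 8)."""

    radii: tuple[int, ...] = (1, 2, 4, 6, 8)

    def __post_init__(self) -> None:
        r = self.radii
        if not r or any(int(x) != x or x <= 0 for x in r) or list(r) != sorted(set(r)):
            raise ValueError("radii must be strictly increasing positive integers")


def circular_kernel(radius: int) -> np.ndarray:
    """Binary footprint of cells whose centre distance <= radius."""
    ax = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(ax, ax)
    return (dx**2 + dy**2 <= radius**2).astype(float)


def _circular_mean(values: np.ndarray, radius: int) -> np.ndarray:
    """Mean over the circular neighbourhood, truncated at edges, nodata-aware."""
    k = circular_kernel(radius)
    valid = np.isfinite(values)
    num = ndimage.convolve(np.where(valid, values, 0.0), k, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), k, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def smooth_multiscale(stack: CovariateStack, config: SmoothingConfig = SmoothingConfig(),
                      keep_original: bool = False) -> CovariateStack:
    """Expand every layer across the configured radii with circular mean filters.

    Output holds |layers| x |radii| smoothed layers (the radius-0 originals are
    not duplicated into the output unless ``keep_original``).
    """
    if len(stack) == 0:
        raise ValueError("empty covariate stack")
    half_extent = min(stack.shape) // 2
    if max(config.radii) > half_extent:
        raise ValueError(f"radius {max(config.radii)} exceeds grid half-extent {half_extent}")
    out = stack.copy_geometry()
    if keep_original:
        for name in stack.names:
            out.add(name, stack[name], stack.info(name))
    for name in stack.names:
        info = stack.info(name)
        for r in config.radii:
            out.add(f"{name}_r{r}", _circular_mean(stack[name], r),
                    LayerInfo(base=info.base, estimator=info.estimator, radius=r))
    return out


def replicate_to(stack: CovariateStack, n_layers: int) -> CovariateStack:
    """Pad a stack to ``n_layers`` by duplicating attributes under distinct
    provenance tags (used where a count-compatible catalogue is required)."""
    if n_layers < len(stack):
        raise ValueError("cannot shrink stack")
    out = stack.copy_geometry()
    for name in stack.names:
        out.add(name, stack[name], stack.info(name))
    i = 0
    while len(out) < n_layers:
        name = stack.names[i % len(stack)]
        info = stack.info(name)
        dup = f"{name}_v{i // len(stack) + 2}"
        out.add(dup, stack[name], LayerInfo(base=info.base,
                                            estimator=f"{info.estimator}_v{i // len(stack) + 2}",
                                            radius=info.radius))
        i += 1
    return out


# ---------------------------------------------------------------------------
# centring / scaling

@dataclass
class StandardizationStats:
    """Per-layer mean and sd used for centring and scaling."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform_matrix(self, X: np.ndarray, names: list[str]) -> np.ndarray:
        mu = np.array([self.means[n] for n in names])
        sd = np.array([self.sds[n] for n in names])
        return (X - mu) / sd


def standardize(stack: CovariateStack) -> tuple[CovariateStack, StandardizationStats]:
    """Centre and scale every layer to mean 0, sd 1 over its valid cells.

    Constant layers are dropped with a warning; an all-constant stack is an
    error.
    """
    out = stack.copy_geometry()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in stack.names:
        v = stack[name]
        ok = np.isfinite(v)
        mu = float(v[ok].mean())
        sd = float(v[ok].std())
        if sd == 0:
            log.warning("dropping constant covariate layer %r", name)
            continue
        out.add(name, (v - mu) / sd, stack.info(name))
        means[name], sds[name] = mu, sd
    if len(out) == 0:
        raise ValueError("all covariate layers are constant")
    return out, StandardizationStats(means=means, sds=sds)


def apply_standardization(stack: CovariateStack, stats: StandardizationStats) -> CovariateStack:
    out = stack.copy_geometry()
    for name in stack.names:
        if name in stats.means:
            out.add(name, (stack[name] - stats.means[name]) / stats.sds[name], stack.info(name))
    return out
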