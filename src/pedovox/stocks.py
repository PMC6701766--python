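"""SOC stock computation and aggregation.

Per voxel, the carbon stock in grams is

    stock = SOC/100 * BD * cell_size_cm^2 * dz_cm

(SOC in mass %, BD in g cm^-3). At the reference geometry (500 cm cells,
5 cm slabs) one voxel represents 1.25 m^3 of soil. Coarse-fragment
correction is deliberately omitted (negligible coarse fraction at the
emulated site). Aggregation sums voxel stocks over a depth interval and an
optional spatial mask and reports areal density in Mg ha^-1; a voxel
labelled with lower-corner depth d covers the slab (d - dz, d], so a 0 cm
level contributes no volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import VoxelModel

G_PER_MG = 1e6
CM2_PER_HA = 1e8


@dataclass
class StockModel:
    """Depth-indexed grids of carbon stock, g per voxel."""

    depths_cm: np.ndarray
    values: np.ndarray          # (n_depths, H, W), g per voxel
    cell_size_cm: float
    dz_cm: float

    @property
    def voxel_volume_m3(self) -> float:
        return self.cell_size_cm**2 * self.dz_cm / 1e6

    def to_dataset(self):
        import xarray as xr
        h, w = self.values.shape[1:]
        return xr.Dataset(
            {"stock_g": (("depth_cm", "y", "x"), self.values)},
            coords={"depth_cm": self.depths_cm, "y": np.arange(h), "x": np.arange(w)},
            attrs={"cell_size_cm": self.cell_size_cm, "dz_cm": self.dz_cm,
                   "units": "g per voxel",
                   "depth_convention": "lower corner of voxel"},
        )


def voxel_stock(soc: VoxelModel, bd: VoxelModel) -> StockModel:
    """Combine SOC (%) and BD (g cm^-3) voxel models into stock (g per voxel)."""
    if soc.values.shape != bd.values.shape or not np.allclose(soc.depths_cm, bd.depths_cm):
        raise ValueError("SOC and BD voxel models are not aligned in grid and depth")
    if soc.cell_size_cm != bd.cell_size_cm or soc.step_cm != bd.step_cm:
        raise ValueError("SOC and BD voxel models have different geometry")
    stock = soc.values / 100.0 * bd.values * soc.cell_size_cm**2 * soc.step_cm
    return StockModel(depths_cm=soc.depths_cm, values=stock,
                      cell_size_cm=soc.cell_size_cm, dz_cm=soc.step_cm)


def aggregate_stock(stock, depth_range_cm: tuple[float, float] | None = None,
                    mask: np.ndarray | None = None) -> float:
    """Areal carbon density in Mg ha^-1.

    ``stock`` is a StockModel (summed over the voxels whose slab lies inside
    ``depth_range_cm`` and over the masked area), or a 1-D sequence of
    pre-aggregated per-increment densities in Mg ha^-1 (simply summed).
    """
    if not isinstance(stock, StockModel):
        densities = np.asarray(stock, dtype=float)
        if densities.ndim != 1:
            raise ValueError("expected a StockModel or a 1-D density sequence")
        return float(densities.sum())

    if depth_range_cm is None:
        raise ValueError("depth_range_cm is required for a StockModel")
    d_from, d_to = depth_range_cm
    dz = stock.dz_cm
    # voxel at level d covers (d - dz, d]: include levels with d_from < d <= d_to
    sel = (stock.depths_cm > d_from + 1e-9) & (stock.depths_cm <= d_to + 1e-9)
    covered = (min(stock.depths_cm.max(), d_to) - max(stock.depths_cm.min() - dz, d_from))
    if not sel.any() or d_to - d_from > covered + 1e-9:
        raise ValueError("depth range not covered by the stock model")
    layer_valid = np.isfinite(stock.values[sel])
    cell_valid = layer_valid.all(axis=0)
    if mask is not None:
        if mask.shape != cell_valid.shape:
            raise ValueError("mask not aligned with the stock grid")
        cell_valid &= mask.astype(bool)
    total_g = float(np.nansum(stock.values[sel][:, cell_valid]))
    area_cm2 = cell_valid.sum() * stock.cell_size_cm**2
    if area_cm2 == 0:
        raise ValueError("empty mask")
    return total_g / G_PER_MG / (area_cm2 / CM2_PER_HA)


def layer_densities(stock: StockModel, mask: np.ndarray | None = None) -> dict[float, float]:
    """Per-slab areal densities (Mg ha^-1), keyed by the slab's lower-corner depth."""
    out = {}
    for d in stock.depths_cm:
        if d == 0:
            continue  # the 0 cm level carries no volume
        out[float(d)] = aggregate_stock(stock, (d - stock.dz_cm, d), mask=mask)
    return out
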