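"""Gridded data containers shared across the package.

Conventions (used everywhere): cell-centre registration, row 0 is the
northernmost row, horizontal distances in metres, depths positive downward
in centimetres. Nodata cells are carried as NaN in memory; the ``nodata``
attribute only matters for file interchange.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ElevationGrid:
    """Single-band elevation raster (m a.s.l.).

    Parameters
    ----------
    values : 2-D float array, NaN where nodata.
    cell_size_cm : edge length of a square cell in cm (reference 500).
    origin : (x, y) map coordinates of the centre of the upper-left cell.
    nodata : sentinel written to files in place of NaN.
    """

    values: np.ndarray
    cell_size_cm: float = 500.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if self.cell_size_cm <= 0:
            raise ValueError("cell_size_cm must be positive")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("non-nodata elevation values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size_m(self) -> float:
        return self.cell_size_cm / 100.0

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True on valid (non-nodata) cells."""
        return ~np.isnan(self.values)

    def cell_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (m) of cell centres; row 0 northernmost."""
        x0, y0 = self.origin
        return x0 + np.asarray(col) * self.cell_size_m, y0 - np.asarray(row) * self.cell_size_m

    def xy_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        col = np.rint((np.asarray(x, dtype=float) - x0) / self.cell_size_m).astype(int)
        row = np.rint((y0 - np.asarray(y, dtype=float)) / self.cell_size_m).astype(int)
        return row, col


@dataclass(frozen=True)
class LayerInfo:
    """Provenance of one covariate layer."""

    base: str
    estimator: str = ""
    radius: int = 0


class CovariateStack:
    """Named, grid-aligned covariate layers with provenance.

    Layers are 2-D arrays sharing the geometry of the source DEM; NaN marks
    nodata. Insertion order is preserved and defines design-matrix column
    order.
    """

    def __init__(self, cell_size_cm: float = 500.0, origin: tuple[float, float] = (0.0, 0.0)):
        self.cell_size_cm = cell_size_cm
        self.origin = origin
        self._layers: dict[str, np.ndarray] = {}
        self._info: dict[str, LayerInfo] = {}

    def add(self, name: str, values: np.ndarray, info: LayerInfo | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self._layers:
            first = next(iter(self._layers.values()))
            if values.shape != first.shape:
                raise ValueError(f"layer {name!r} shape {values.shape} != stack shape {first.shape}")
        self._layers[name] = values
        self._info[name] = info or LayerInfo(base=name)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def shape(self) -> tuple[int, int]:
        if not self._layers:
            raise ValueError("empty stack has no shape")
        return next(iter(self._layers.values())).shape

    def info(self, name: str) -> LayerInfo:
        return self._info[name]

    def __len__(self) -> int:
        return len(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def items(self):
        return self._layers.items()

    @property
    def mask(self) -> np.ndarray:
        """Valid where every layer is valid."""
        m = np.ones(self.shape, dtype=bool)
        for v in self._layers.values():
            m &= ~np.isnan(v)
        return m

    def design_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """n x p matrix of covariate values at the given cells, columns in layer order."""
        return np.column_stack([self._layers[n][rows, cols] for n in self.names])

    def full_matrix(self, mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Matrix over all valid cells plus the flat index of each row."""
        m = self.mask if mask is None else (self.mask & mask)
        idx = np.flatnonzero(m.ravel())
        rows, cols = np.unravel_index(idx, self.shape)
        return self.design_matrix(rows, cols), idx

    def copy_geometry(self) -> "CovariateStack":
        return CovariateStack(cell_size_cm=self.cell_size_cm, origin=self.origin)


@dataclass
class IncrementScheme:
    """Ordered, contiguous sampling depth increments in cm."""

    increments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_bottom = None
        for top, bottom in self.increments:
            if bottom <= top:
                raise ValueError(f"increment ({top}, {bottom}) not increasing")
            if prev_bottom is not None and top != prev_bottom:
                raise ValueError("increments must be contiguous and non-overlapping")
            prev_bottom = bottom

    @property
    def mid_depths_cm(self) -> np.ndarray:
        return np.array([(t + b) / 2.0 for t, b in self.increments])

    @property
    def thicknesses_cm(self) -> np.ndarray:
        return np.array([b - t for t, b in self.increments])

    def __len__(self) -> int:
        return len(self.increments)


#: the reference sampling scheme: 0-5, 5-10, 10-20, 20-30, 30-50 cm
STANDARD_INCREMENTS = IncrementScheme(((0, 5), (5, 10), (10, 20), (20, 30), (30, 50)))


@dataclass
class PlotSet:
    """Sampled plot locations as cell indices; a subset carries bulk density."""

    plot_ids: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    has_bd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.plot_ids)
        if not (len(self.rows) == len(self.cols) == len(self.has_bd) == n):
            raise ValueError("plot arrays must have equal length")
        cells = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(cells) != n:
            raise ValueError("plot cells must be unique")

    def __len__(self) -> int:
        return len(self.plot_ids)

    def bd_subset(self) -> "PlotSet":
        m = self.has_bd.astype(bool)
        return PlotSet(self.plot_ids[m], self.rows[m], self.cols[m], self.has_bd[m])


@dataclass
class ProfileDataset:
    """Per-plot depth-increment measurements of one soil property.

    ``values[i, j]`` is the measurement at plot i, increment j.
    """

    property_name: str
    units: str
    plots: PlotSet
    increments: IncrementScheme
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.plots), len(self.increments)):
            raise ValueError("values must be (n_plots, n_increments)")
        if np.any(self.values <= 0):
            raise ValueError(f"{self.property_name} values must be positive")

    @property
    def n_plots(self) -> int:
        return len(self.plots)


# ---------------------------------------------------------------------------
# raster interchange (TIFF with a JSON metadata header in ImageDescription)

def write_raster(path, arrays: np.ndarray, *, cell_size_cm: float, origin: tuple[float, float],
                 nodata: float = -9999.0, band_names: list[str] | None = None,
                 band_meta: list[dict] | None = None) -> None:
    """Write a single- or multi-band float raster.

    ``arrays`` is (H, W) or (bands, H, W); NaN is replaced by ``nodata`` on
    disk and restored on read.
    """
    arrays = np.asarray(arrays, dtype=np.float64)
    if arrays.ndim == 2:
        arrays = arrays[None]
    data = np.where(np.isnan(arrays), nodata, arrays)
    meta = {
        "cell_size_cm": cell_size_cm,
        "origin": list(origin),
        "nodata": nodata,
        "band_names": band_names or [f"band_{i}" for i in range(arrays.shape[0])],
        "band_meta": band_meta or [{} for _ in range(arrays.shape[0])],
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))


def read_raster(path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(np.float64)
        meta = json.loads(tif.pages[0].description)
    if data.ndim == 2:
        data = data[None]
    data = np.where(data == meta["nodata"], np.nan, data)
    return data, meta


def write_dem(path, dem: ElevationGrid) -> None:
    write_raster(path, dem.values, cell_size_cm=dem.cell_size_cm, origin=dem.origin,
                 nodata=dem.nodata, band_names=["elevation_m"])


def read_dem(path) -> ElevationGrid:
    data, meta = read_raster(path)
    return ElevationGrid(data[0], cell_size_cm=meta["cell_size_cm"],
                         origin=tuple(meta["origin"]), nodata=meta["nodata"])


def write_stack(path, stack: CovariateStack) -> None:
    arrays = np.stack([stack[n] for n in stack.names])
    band_meta = [vars(stack.info(n)) for n in stack.names]
    write_raster(path, arrays, cell_size_cm=stack.cell_size_cm, origin=stack.origin,
                 band_names=stack.names, band_meta=band_meta)


def read_stack(path) -> CovariateStack:
    data, meta = read_raster(path)
    stack = CovariateStack(cell_size_cm=meta["cell_size_cm"], origin=tuple(meta["origin"]))
    for i, name in enumerate(meta["band_names"]):
        bm = meta["band_meta"][i] or {"base": name}
        stack.add(name, data[i], LayerInfo(**bm))
    return stack
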