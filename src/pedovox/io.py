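"""Tabular interchange: profile datasets and fitted-coefficient tables as CSV.

Profile CSV columns: plot_id, x, y, property, top_cm, bottom_cm, value.
Coordinates are map metres; plots are snapped to the nearest cell centre of
the supplied grid geometry.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import ElevationGrid, IncrementScheme, PlotSet, ProfileDataset

log = logging.getLogger(__name__)

PROFILE_COLUMNS = ["plot_id", "x", "y", "property", "top_cm", "bottom_cm", "value"]

# plausibility windows per property; values outside are accepted with a warning
SANITY_RANGES = {"SOC": (0.05, 15.0), "BD": (0.3, 2.5)}
UNITS = {"SOC": "%", "BD": "g cm^-3"}


def save_profiles(path, dataset: ProfileDataset, dem: ElevationGrid) -> None:
    x, y = dem.cell_xy(dataset.plots.rows, dataset.plots.cols)
    rows = []
    for i, pid in enumerate(dataset.plots.plot_ids):
        for j, (top, bottom) in enumerate(dataset.increments.increments):
            rows.append({"plot_id": pid, "x": x[i], "y": y[i],
                         "property": dataset.property_name,
                         "top_cm": top, "bottom_cm": bottom,
                         "value": dataset.values[i, j]})
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def load_profiles(path, dem: ElevationGrid) -> ProfileDataset:
    """Read and validate a profile CSV, snapping plots to the DEM grid."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile file missing column(s): {missing}")
    props = df["property"].unique()
    if len(props) != 1:
        raise ValueError(f"expected one property per file, found {list(props)}")
    prop = str(props[0])

    bad = df[~df["value"].apply(lambda v: np.isreal(v) and np.isfinite(v))]
    if len(bad):
        raise ValueError(f"non-numeric value(s) at row(s) {bad.index.tolist()}")
    dup = df.duplicated(subset=["plot_id", "top_cm", "bottom_cm"])
    if dup.any():
        raise ValueError(f"duplicate (plot, increment) at row(s) {df.index[dup].tolist()}")

    incs = sorted({(t, b) for t, b in zip(df["top_cm"], df["bottom_cm"])})
    scheme = IncrementScheme(tuple(incs))
    pids = sorted(df["plot_id"].unique())
    pivot = df.set_index(["plot_id", "top_cm", "bottom_cm"])["value"]
    values = np.empty((len(pids), len(incs)))
    for i, pid in enumerate(pids):
        for j, (t, b) in enumerate(incs):
            try:
                values[i, j] = pivot[(pid, t, b)]
            except KeyError:
                raise ValueError(f"plot {pid} is missing increment ({t}, {b})") from None

    lo, hi = SANITY_RANGES.get(prop, (0.0, np.inf))
    out_of_range = (values < lo) | (values > hi)
    if out_of_range.any():
        log.warning("%d %s value(s) outside the plausible range [%g, %g]",
                    int(out_of_range.sum()), prop, lo, hi)

    coords = df.drop_duplicates("plot_id").set_index("plot_id").loc[pids]
    rows, cols = dem.xy_to_cell(coords["x"].to_numpy(), coords["y"].to_numpy())
    nrow, ncol = dem.shape
    if np.any((rows < 0) | (rows >= nrow) | (cols < 0) | (cols >= ncol)):
        raise ValueError("plot coordinates fall outside the grid")
    plots = PlotSet(plot_ids=np.asarray(pids), rows=rows, cols=cols,
                    has_bd=np.ones(len(pids), dtype=bool))
    return ProfileDataset(property_name=prop, units=UNITS.get(prop, ""),
                          plots=plots, increments=scheme, values=values)


def save_fits(path, coef_table: pd.DataFrame, family: str) -> None:
    out = coef_table.copy()
    out.insert(1, "family", family)
    out.to_csv(path, index=False)
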