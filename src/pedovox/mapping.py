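"""The two spatial prediction pipelines.

2.5D (multi-layer) reference: one tuned model per sampled depth increment,
predicting the property directly at the increment's mid-depth.

3D: fit a depth function to every profile, model each coefficient spatially
with the shared cross-validation folds, then solve the functions at every
grid cell over a regular depth grid to obtain a voxel model. Negative
polynomial predictions are clamped to a floor (default 0 for SOC); the
logarithmic and exponential families never need clamping.

Internal validation compares model output with the measured profile values at
the increment mid-depths (function evaluation for 3D, the layer grid for
2.5D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import depthfn
from .grids import CovariateStack, ProfileDataset
from .learners import (CVResult, FoldAssignment, LearnerSpec, Oracle,
                       predict_surface, tune_and_fit)
from .metrics import compute_metrics, nrmse

log = logging.getLogger(__name__)

MAX_PROFILE_FAILURE_FRACTION = 0.2


@dataclass
class LayerPredictions:
    """2.5D result: one predicted grid (and CV summary) per increment mid-depth."""

    property_name: str
    mid_depths_cm: np.ndarray
    grids: dict[float, np.ndarray]
    cv: dict[float, CVResult | None]

    def cv_table(self) -> pd.DataFrame:
        rows = []
        for d in self.mid_depths_cm:
            c = self.cv[d]
            rows.append({"depth_cm": d,
                         "r2": c.r2 if c else np.nan,
                         "rmse": c.rmse if c else np.nan})
        df = pd.DataFrame(rows)
        mean = {"depth_cm": "mean", "r2": df["r2"].mean(), "rmse": df["rmse"].mean()}
        return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)


@dataclass
class CoefficientFields:
    """3D intermediate: one predicted grid per depth-function coefficient."""

    family: str
    grids: dict[str, np.ndarray]
    cv: dict[str, CVResult | None]
    fitted_coefficients: pd.DataFrame  # per-plot fitted values used as responses

    def cv_table(self) -> pd.DataFrame:
        rows = []
        for c in depthfn.coef_names(self.family):
            r = self.cv[c]
            rows.append({"coefficient": c,
                         "r2": r.r2 if r else np.nan,
                         "rmse": r.rmse if r else np.nan,
                         "nrmse": r.nrmse if r else np.nan})
        df = pd.DataFrame(rows)
        mean = {"coefficient": "mean", "r2": df["r2"].mean(),
                "rmse": np.nan, "nrmse": df["nrmse"].mean()}
        return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)

    def evaluate_at_depths(self, depths_cm) -> dict[float, np.ndarray]:
        """Solve the depth function at given depths over the whole grid."""
        coefs = [self.grids[c] for c in depthfn.coef_names(self.family)]
        return {float(d): depthfn.evaluate(x_cm=float(d), family=self.family,
                                           coefficients=coefs)
                for d in np.atleast_1d(depths_cm)}


@dataclass
class VoxelModel:
    """Depth-indexed stack of grids; ``values[i]`` is the grid at depths_cm[i]
    (depth convention: the lower corner of the voxel)."""

    property_name: str
    depths_cm: np.ndarray
    values: np.ndarray            # (n_depths, H, W)
    step_cm: float
    clamp_count: int
    cell_size_cm: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.depths_cm) > 0):
            raise ValueError("depth levels must be strictly increasing")

    def layer(self, depth_cm: float) -> np.ndarray:
        i = int(np.flatnonzero(np.isclose(self.depths_cm, depth_cm))[0])
        return self.values[i]

    def to_dataset(self):
        """xarray representation (dims depth x y x x) for NetCDF-style export."""
        import xarray as xr
        h, w = self.values.shape[1:]
        return xr.Dataset(
            {self.property_name: (("depth_cm", "y", "x"), self.values)},
            coords={"depth_cm": self.depths_cm,
                    "y": np.arange(h), "x": np.arange(w)},
            attrs={"step_cm": self.step_cm, "clamp_count": self.clamp_count,
                   "cell_size_cm": self.cell_size_cm,
                   "depth_convention": "lower corner of voxel"},
        )


def _plot_matrix(dataset: ProfileDataset, stack: CovariateStack) -> np.ndarray:
    return stack.design_matrix(dataset.plots.rows, dataset.plots.cols)


def run_25d(dataset: ProfileDataset, stack: CovariateStack, learner,
            folds: FoldAssignment | None = None) -> LayerPredictions:
    """Fit one tuned model per depth increment and predict its surface.

    ``learner`` is a LearnerSpec, or an Oracle keyed by mid-depth for
    plumbing verification.
    """
    mids = dataset.increments.mid_depths_cm
    if np.any(~np.isfinite(dataset.values)):
        raise ValueError("dataset has missing increment values")
    X = _plot_matrix(dataset, stack)
    grids: dict[float, np.ndarray] = {}
    cv: dict[float, CVResult | None] = {}
    for j, d in enumerate(mids):
        d = float(d)
        if isinstance(learner, Oracle):
            grids[d] = learner.surface(d)
            cv[d] = None
            continue
        fitted, res = tune_and_fit(learner, X, dataset.values[:, j], folds,
                                   feature_names=stack.names)
        grids[d] = predict_surface(fitted, stack)
        cv[d] = res
    return LayerPredictions(property_name=dataset.property_name,
                            mid_depths_cm=mids.astype(float), grids=grids, cv=cv)


def run_3d(dataset: ProfileDataset, stack: CovariateStack, family: str, learner,
           folds: FoldAssignment | None = None,
           depth_from_cm: float = 0.0, depth_to_cm: float = 50.0, step_cm: float = 5.0,
           clamp_floor: float | None = 0.0) -> tuple[CoefficientFields, VoxelModel]:
    """Full 3D pipeline: per-profile depth-function fits, spatial modelling of
    each coefficient, voxel solution over the depth grid."""
    fits, failed = depthfn.fit_dataset(dataset, family)
    if failed:
        log.warning("excluded %d plots with failed %s fits: %s", len(failed), family, failed)
    if len(failed) > MAX_PROFILE_FAILURE_FRACTION * dataset.n_plots:
        raise RuntimeError(f"more than {MAX_PROFILE_FAILURE_FRACTION:.0%} of profiles "
                           f"failed the {family} fit; aborting")
    kept = np.array([pid not in set(failed) for pid in dataset.plots.plot_ids])
    rows, cols = dataset.plots.rows[kept], dataset.plots.cols[kept]
    X = stack.design_matrix(rows, cols)
    sub_folds = folds.subset(kept) if folds is not None else None

    coef_table = pd.DataFrame(
        [{"plot_id": f.plot_id, **f.spec.as_dict(), "r2": f.r2, "rmse": f.rmse}
         for f in fits])

    grids: dict[str, np.ndarray] = {}
    cv: dict[str, CVResult | None] = {}
    for cname in depthfn.coef_names(family):
        if isinstance(learner, Oracle):
            grids[cname] = learner.surface(cname)
            cv[cname] = None
            continue
        y = coef_table[cname].to_numpy()
        fitted, res = tune_and_fit(learner, X, y, sub_folds, feature_names=stack.names)
        rng = float(y.max() - y.min())
        res.nrmse = nrmse(res.rmse, rng) if rng > 0 else np.nan
        grids[cname] = predict_surface(fitted, stack)
        cv[cname] = res

    fields = CoefficientFields(family=family, grids=grids, cv=cv,
                               fitted_coefficients=coef_table)
    voxels = solve_voxels(fields, depth_from_cm=depth_from_cm, depth_to_cm=depth_to_cm,
                          step_cm=step_cm, clamp_floor=clamp_floor,
                          property_name=dataset.property_name,
                          cell_size_cm=stack.cell_size_cm)
    return fields, voxels


def solve_voxels(fields: CoefficientFields, depth_from_cm: float = 0.0,
                 depth_to_cm: float = 50.0, step_cm: float = 5.0,
                 clamp_floor: float | None = 0.0, property_name: str = "SOC",
                 cell_size_cm: float = 500.0) -> VoxelModel:
    """Solve the depth functions at every cell over a regular depth grid.

    Depth levels run from ``depth_from_cm`` to ``depth_to_cm`` inclusive
    (lower-corner convention); the reference grid 0-50 cm by 5 cm yields 11
    levels. Values below ``clamp_floor`` are set to the floor and counted;
    pass ``clamp_floor=None`` to disable clamping.
    """
    span = depth_to_cm - depth_from_cm
    n_steps = span / step_cm
    if span <= 0 or abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step_cm must evenly divide the depth interval")
    levels = depth_from_cm + step_cm * np.arange(round(n_steps) + 1)
    if fields.family == "log" and levels[0] <= 0:
        raise ValueError("log depth function is undefined at 0 cm; "
                         "start the depth grid at step_cm")
    layers = fields.evaluate_at_depths(levels)
    values = np.stack([layers[float(d)] for d in levels])
    clamp_count = 0
    if clamp_floor is not None:
        below = values < clamp_floor
        below &= np.isfinite(values)
        clamp_count = int(below.sum())
        values = np.where(below, clamp_floor, values)
    return VoxelModel(property_name=property_name, depths_cm=levels.astype(float),
                      values=values, step_cm=step_cm, clamp_count=clamp_count,
                      cell_size_cm=cell_size_cm)


def internal_validation(model: CoefficientFields | LayerPredictions,
                        dataset: ProfileDataset) -> pd.DataFrame:
    """Observed-vs-predicted check at the increment mid-depths of the input
    dataset (one row per depth plus a mean row)."""
    if dataset.n_plots == 0:
        raise ValueError("empty dataset")
    mids = dataset.increments.mid_depths_cm
    rows_ix, cols_ix = dataset.plots.rows, dataset.plots.cols
    if isinstance(model, CoefficientFields):
        layers = model.evaluate_at_depths(mids)
    else:
        layers = {float(d): model.grids[float(d)] for d in mids}
    out = []
    for j, d in enumerate(mids):
        pred = layers[float(d)][rows_ix, cols_ix]
        obs = dataset.values[:, j]
        ms = compute_metrics(obs, pred)
        out.append({"depth_cm": float(d), "r2": ms.r2, "rmse": ms.rmse, "n": ms.n})
    df = pd.DataFrame(out)
    mean = {"depth_cm": "mean", "r2": df["r2"].mean(), "rmse": df["rmse"].mean(),
            "n": int(df["n"].sum())}
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)
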