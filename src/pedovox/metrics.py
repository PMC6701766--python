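"""Evaluation statistics: R^2, RMSE, range-normalised RMSE, Lin's concordance.

R^2 defaults to the squared Pearson correlation between observed and
predicted (the convention used alongside concordance statistics in model
inter-comparison); the explained-variance form 1 - SSE/SST is available via
``r2_method="ss"``. Lin's concordance correlation coefficient

    rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean(x) - mean(y))^2)

uses sample (n-1) moments and penalises both poor correlation and deviation
from the 1:1 line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MetricSet:
    r2: float
    rmse: float
    n: int
    nrmse: float | None = None
    ccc: float | None = None
    r2_defined: bool = True


def _clean(observed, predicted):
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least 2 finite pairs")
    return x, y


def compute_metrics(observed, predicted, r2_method: str = "pearson") -> MetricSet:
    x, y = _clean(observed, predicted)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    if r2_method == "pearson":
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        if sx == 0 or sy == 0:
            return MetricSet(r2=np.nan, rmse=rmse, n=x.size, r2_defined=False)
        r = float(np.corrcoef(x, y)[0, 1])
        r2 = r * r
    elif r2_method == "ss":
        ss_tot = float(np.sum((x - x.mean()) ** 2))
        if ss_tot == 0:
            return MetricSet(r2=np.nan, rmse=rmse, n=x.size, r2_defined=False)
        r2 = 1.0 - float(np.sum((x - y) ** 2)) / ss_tot
    else:
        raise ValueError("r2_method must be 'pearson' or 'ss'")
    return MetricSet(r2=r2, rmse=rmse, n=x.size)


def nrmse(rmse: float, value_range: float) -> float:
    """RMSE divided by the observed range (max - min) of the target."""
    if value_range <= 0:
        raise ValueError("value range must be positive")
    return rmse / value_range


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with sample (n-1) moments."""
    x, y = _clean(x, y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both vectors constant: concordance undefined")
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    return 2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2)


def compare_layers(pred_3d: dict[float, np.ndarray], pred_25d: dict[float, np.ndarray],
                   mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-depth agreement between a voxel model's depth intersections and the
    layered reference predictions.

    Both inputs map mid-depth (cm) to a prediction grid on the same geometry.
    Returns one row per depth plus a mean row, columns r2 / ccc / rmse / n.
    """
    d3, d25 = set(pred_3d), set(pred_25d)
    if d3 != d25:
        raise ValueError(f"depth mismatch: {sorted(d3)} vs {sorted(d25)}")
    rows = []
    for depth in sorted(pred_3d):
        a, b = pred_3d[depth], pred_25d[depth]
        if a.shape != b.shape:
            raise ValueError("grids not aligned")
        ok = np.isfinite(a) & np.isfinite(b)
        if mask is not None:
            ok &= mask
        x, y = b[ok], a[ok]  # observed role: the 2.5D reference
        ms = compute_metrics(x, y)
        rows.append({"depth_cm": depth, "r2": ms.r2, "ccc": lin_ccc(x, y),
                     "rmse": ms.rmse, "n": ms.n})
    df = pd.DataFrame(rows)
    mean_row = {"depth_cm": "mean", "r2": df["r2"].mean(), "ccc": df["ccc"].mean(),
                "rmse": df["rmse"].mean(), "n": int(df["n"].sum())}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
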