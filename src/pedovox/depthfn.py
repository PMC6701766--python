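"""Soil-profile depth functions: representation, fitting, evaluation, integration.

Four families describe how a property (SOC %, bulk density g cm^-3) varies
with depth x (cm) in a single profile:

    poly3:  f(x) = c0 + c1*x + c2*x^2 + c3*x^3
    poly2:  f(x) = c0 + c1*x + c2*x^2
    log:    f(x) = c1 * ln(c2 * x)          (x > 0)
    exp:    f(x) = exp(c1 + c2 * x)

c0 is the property value at the surface; c1..c3 are dimensionless shape
coefficients. All families are fitted by linear least squares: polynomials
directly on the polynomial design, the exponential on ln(value) vs depth,
and the logarithmic on value vs ln(depth). Fit metrics are always reported
on the original property scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FAMILIES = ("poly3", "poly2", "log", "exp")

_COEF_NAMES = {
    "poly3": ("c0", "c1", "c2", "c3"),
    "poly2": ("c0", "c1", "c2"),
    "log": ("c1", "c2"),
    "exp": ("c1", "c2"),
}


def coef_names(family: str) -> tuple[str, ...]:
    try:
        return _COEF_NAMES[family]
    except KeyError:
        raise ValueError(f"unknown depth-function family {family!r}") from None


def n_coefficients(family: str) -> int:
    return len(coef_names(family))


@dataclass(frozen=True)
class DepthFunctionSpec:
    """One depth function: a family tag plus its coefficients (in canonical order)."""

    family: str
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        names = coef_names(self.family)
        if len(self.coefficients) != len(names):
            raise ValueError(
                f"{self.family} expects {len(names)} coefficients, got {len(self.coefficients)}")
        if self.family == "log":
            c1, c2 = self.coefficients
            if c1 == 0:
                raise ValueError("log family requires c1 != 0")
            if c2 <= 0:
                raise ValueError("log family requires c2 > 0")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(coef_names(self.family), self.coefficients))


def evaluate(spec: DepthFunctionSpec | None = None, x_cm=None, *, family: str | None = None,
             coefficients=None):
    """Evaluate a depth function at depth(s) x_cm.

    Either a spec, or ``family`` plus ``coefficients`` (each coefficient may
    be an array, enabling whole-grid evaluation at one depth).
    """
    if spec is not None:
        family, coefficients = spec.family, spec.coefficients
    x = np.asarray(x_cm, dtype=float)
    if np.any(x < 0):
        raise ValueError("depth must be >= 0")
    c = [np.asarray(ci, dtype=float) for ci in coefficients]
    if family == "poly3":
        return c[0] + c[1] * x + c[2] * x**2 + c[3] * x**3
    if family == "poly2":
        return c[0] + c[1] * x + c[2] * x**2
    if family == "log":
        if np.any(x <= 0):
            raise ValueError("log depth function is undefined at x <= 0")
        return c[0] * np.log(c[1] * x)
    if family == "exp":
        return np.exp(c[0] + c[1] * x)
    raise ValueError(f"unknown family {family!r}")


def integrate(spec: DepthFunctionSpec, a_cm: float, b_cm: float) -> float:
    """Closed-form integral of the property over depth [a_cm, b_cm] (property * cm)."""
    if not (0 <= a_cm < b_cm):
        raise ValueError("require 0 <= a < b")
    fam, c = spec.family, spec.coefficients
    if fam in ("poly3", "poly2"):
        def F(x):
            out = 0.0
            for k, ck in enumerate(c):
                out += ck * x ** (k + 1) / (k + 1)
            return out
        return F(b_cm) - F(a_cm)
    if fam == "exp":
        c1, c2 = c
        if abs(c2) < 1e-12:
            return np.exp(c1) * (b_cm - a_cm)
        return (np.exp(c1 + c2 * b_cm) - np.exp(c1 + c2 * a_cm)) / c2
    if fam == "log":
        if a_cm <= 0:
            raise ValueError("log depth function requires a > 0")
        c1, c2 = c

        def F(x):
            return c1 * (x * np.log(c2 * x) - x)
        return F(b_cm) - F(a_cm)
    raise ValueError(f"unknown family {fam!r}")


@dataclass
class FittedProfile:
    """Least-squares depth-function fit for one soil profile."""

    plot_id: object
    spec: DepthFunctionSpec
    mid_depths_cm: np.ndarray
    observed: np.ndarray
    residuals: np.ndarray = field(init=False)
    r2: float = field(init=False)
    rmse: float = field(init=False)

    def __post_init__(self) -> None:
        pred = evaluate(self.spec, self.mid_depths_cm)
        self.residuals = self.observed - pred
        ss_res = float(np.sum(self.residuals**2))
        ss_tot = float(np.sum((self.observed - self.observed.mean()) ** 2))
        self.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        self.rmse = float(np.sqrt(np.mean(self.residuals**2)))


def fit(values, mid_depths_cm, family: str, plot_id=None) -> FittedProfile:
    """Fit one family to one profile by (linearized) ordinary least squares."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(mid_depths_cm, dtype=float)
    p = n_coefficients(family)
    if y.size != x.size:
        raise ValueError("values and depths must have equal length")
    if y.size < p:
        raise ValueError(f"{family} needs >= {p} observations, got {y.size}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite profile values")

    if family in ("poly3", "poly2"):
        deg = 3 if family == "poly3" else 2
        X = np.vander(x, deg + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coefs = tuple(beta)
    elif family == "exp":
        if np.any(y <= 0):
            raise ValueError("exp family requires positive values (log-linearized fit)")
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
        coefs = (float(beta[0]), float(beta[1]))
    elif family == "log":
        if np.any(x <= 0):
            raise ValueError("log family requires positive depths")
        X = np.column_stack([np.ones_like(x), np.log(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        a, c1 = float(beta[0]), float(beta[1])
        if abs(c1) < 1e-12:
            raise ValueError("log family fit degenerate: c1 ~ 0, c2 undefined")
        coefs = (c1, float(np.exp(a / c1)))
    else:
        raise ValueError(f"unknown family {family!r}")

    return FittedProfile(plot_id=plot_id, spec=DepthFunctionSpec(family, coefs),
                         mid_depths_cm=x, observed=y)


def fit_dataset(dataset, family: str) -> tuple[list[FittedProfile], list[object]]:
    """Fit every profile of a ProfileDataset; returns (fits, failed plot_ids)."""
    mids = dataset.increments.mid_depths_cm
    fits, failed = [], []
    for i in range(dataset.n_plots):
        pid = dataset.plots.plot_ids[i]
        try:
            fits.append(fit(dataset.values[i], mids, family, plot_id=pid))
        except ValueError:
            failed.append(pid)
    return fits, failed


def pooled_fit_quality(fits: list[FittedProfile]) -> dict[str, float]:
    """R^2 and RMSE pooled over all profiles x increments, on the property scale.

    R^2 here is 1 - SSE/SST about the pooled grand mean, so constant
    (grand-mean) predictions score exactly 0.
    """
    if not fits:
        raise ValueError("no fits to pool")
    fam = fits[0].spec.family
    if any(f.spec.family != fam for f in fits):
        raise ValueError("all profiles must be fitted with the same family")
    obs = np.concatenate([f.observed for f in fits])
    res = np.concatenate([f.residuals for f in fits])
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return {
        "family": fam,
        "r2": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "rmse": float(np.sqrt(np.mean(res**2))),
        "n": int(obs.size),
    }
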