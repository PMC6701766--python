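"""Depth-function representation, fitting, evaluation and integration."""

import numpy as np
import pytest

from pedovox import depthfn

MIDS = np.array([2.5, 7.5, 15.0, 25.0, 40.0])


@pytest.mark.parametrize("family, coefs, x, expected", [
    ("poly3", (2.0, 0.0, 0.0, 0.0), 17.0, 2.0),
    ("exp", (np.log(3.0), 0.0), 31.0, 3.0),
    ("log", (1.0, 1.0), np.e, 1.0),
    ("poly2", (1.0, 2.0, 3.0), 2.0, 1 + 4 + 12),
])
def test_evaluation_matches_formula(family, coefs, x, expected):
    assert depthfn.evaluate(depthfn.DepthFunctionSpec(family, coefs), x) == pytest.approx(expected)


def test_log_rejected_at_nonpositive_depth():
    spec = depthfn.DepthFunctionSpec("log", (1.0, 2.0))
    with pytest.raises(ValueError):
        depthfn.evaluate(spec, 0.0)


@pytest.mark.parametrize("family, coefs", [
    ("poly3", (1.0, -0.05, 0.002, -0.00002)),
    ("poly2", (2.0, -0.06, 0.0008)),
    ("exp", (1.0, -0.05)),
    ("log", (0.3, 12.0)),
])
def test_noiseless_in_family_fit_is_exact(family, coefs):
    """Exact-recovery: generating from a spec and refitting recovers every
    coefficient to 1e-8 with zero RMSE."""
    truth = depthfn.DepthFunctionSpec(family, coefs)
    values = depthfn.evaluate(truth, MIDS)
    fitted = depthfn.fit(values, MIDS, family)
    assert np.allclose(fitted.spec.coefficients, coefs, atol=1e-8)
    assert fitted.rmse == pytest.approx(0.0, abs=1e-9)


def test_underdetermined_fit_rejected():
    with pytest.raises(ValueError, match="observations"):
        depthfn.fit([1.0, 0.9, 0.8], [2.5, 7.5, 15.0], "poly3")


def test_exp_fit_rejects_nonpositive_values():
    with pytest.raises(ValueError, match="positive"):
        depthfn.fit([1.0, 0.5, -0.1, 0.2, 0.1], MIDS, "exp")


def test_log_fit_rejects_degenerate_slope():
    # constant profile: slope of value on ln(depth) is ~0, c2 undefined
    with pytest.raises(ValueError, match="c1"):
        depthfn.fit([1.0] * 5, MIDS, "log")


def test_pooled_quality_perfect_and_grand_mean():
    truth = depthfn.DepthFunctionSpec("exp", (1.0, -0.04))
    values = depthfn.evaluate(truth, MIDS)
    perfect = depthfn.fit(values, MIDS, "exp")
    pooled = depthfn.pooled_fit_quality([perfect])
    assert pooled["r2"] == pytest.approx(1.0)
    assert pooled["rmse"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        depthfn.pooled_fit_quality([])


def test_pooled_rmse_hand_example():
    """obs {2,1.5,1,0.5} vs pred {2,1,1,1}: RMSE = sqrt(0.5/4) = 0.3536."""
    obs = np.array([2.0, 1.5, 1.0, 0.5])
    pred = np.array([2.0, 1.0, 1.0, 1.0])
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    assert rmse == pytest.approx(0.3536, abs=1e-4)
    # and a fit object pooling must agree with direct computation
    fp = depthfn.FittedProfile(plot_id=1,
                               spec=depthfn.DepthFunctionSpec("poly3", (2.0, 0, 0, 0)),
                               mid_depths_cm=np.array([1.0, 2.0, 3.0, 4.0]), observed=obs)
    assert fp.rmse == pytest.approx(np.sqrt(np.mean((obs - 2.0) ** 2)))


@pytest.mark.parametrize("family, coefs", [
    ("poly3", (2.0, 0.0, 0.0, 0.0)),
    ("poly3", (1.0, -0.05, 0.002, -0.00002)),
    ("poly2", (2.0, -0.06, 0.0008)),
    ("exp", (1.0, -0.05)),
    ("exp", (0.0, 0.0)),
    ("log", (0.3, 12.0)),
])
def test_integral_matches_riemann_sum(family, coefs):
    """Closed-form antiderivative vs a 1e5-panel midpoint Riemann sum."""
    spec = depthfn.DepthFunctionSpec(family, coefs)
    a, b = (5.0, 50.0) if family == "log" else (0.0, 50.0)
    n = 100_000
    x = a + (np.arange(n) + 0.5) * (b - a) / n
    riemann = float(np.sum(depthfn.evaluate(spec, x)) * (b - a) / n)
    closed = depthfn.integrate(spec, a, b)
    assert closed == pytest.approx(riemann, rel=1e-6)


def test_integral_trivial_values():
    const = depthfn.DepthFunctionSpec("poly3", (2.0, 0.0, 0.0, 0.0))
    assert depthfn.integrate(const, 0, 50) == pytest.approx(100.0)
    flat_exp = depthfn.DepthFunctionSpec("exp", (0.0, 0.0))
    assert depthfn.integrate(flat_exp, 0, 10) == pytest.approx(10.0)


def test_integral_additivity():
    spec = depthfn.DepthFunctionSpec("exp", (1.2, -0.04))
    whole = depthfn.integrate(spec, 0, 50)
    parts = depthfn.integrate(spec, 0, 20) + depthfn.integrate(spec, 20, 50)
    assert whole == pytest.approx(parts, rel=1e-12)


def test_voxel_sum_converges_to_integral():
    """Summing point evaluations x slab thickness approaches the closed form
    as the vertical resolution shrinks."""
    spec = depthfn.DepthFunctionSpec("exp", (1.0, -0.04))
    closed = depthfn.integrate(spec, 0, 50)
    errors = []
    for step in (5.0, 1.0, 0.2):
        levels = np.arange(step, 50 + step / 2, step)
        approx = float(np.sum(depthfn.evaluate(spec, levels)) * step)
        errors.append(abs(approx - closed))
    assert errors[0] > errors[1] > errors[2]
    # lower-corner evaluation is a right-endpoint sum: error shrinks ~ step
    assert errors[2] < 0.05 * errors[0]


def test_ols_residual_orthogonality():
    """Residuals are orthogonal to the design on the fitting scale."""
    rng = np.random.default_rng(0)
    values = depthfn.evaluate(depthfn.DepthFunctionSpec("poly2", (2.0, -0.05, 0.001)), MIDS)
    noisy = values + rng.normal(0, 0.1, MIDS.size)
    f = depthfn.fit(noisy, MIDS, "poly2")
    X = np.vander(MIDS, 3, increasing=True)
    res = noisy - depthfn.evaluate(f.spec, MIDS)
    assert np.allclose(X.T @ res, 0.0, atol=1e-8)
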