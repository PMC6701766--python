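"""2.5D and 3D pipelines, voxel solution, clamping, internal validation."""

import numpy as np
import pytest

from pedovox import depthfn
from pedovox.grids import STANDARD_INCREMENTS
from pedovox.learners import LearnerSpec, Oracle, assign_folds
from pedovox.mapping import (CoefficientFields, internal_validation, run_25d, run_3d,
                             solve_voxels)

MIDS = STANDARD_INCREMENTS.mid_depths_cm


def _constant_fields(family, coefs, shape=(6, 6)):
    grids = {name: np.full(shape, c) for name, c in
             zip(depthfn.coef_names(family), coefs)}
    return CoefficientFields(family=family, grids=grids, cv={}, fitted_coefficients=None)


def test_depth_grid_has_11_levels():
    fields = _constant_fields("exp", (1.0, -0.04))
    vox = solve_voxels(fields, 0, 50, 5)
    assert len(vox.depths_cm) == 11
    assert vox.depths_cm[0] == 0 and vox.depths_cm[-1] == 50


def test_log_family_rejects_zero_level():
    fields = _constant_fields("log", (0.3, 12.0))
    with pytest.raises(ValueError, match="step_cm"):
        solve_voxels(fields, 0, 50, 5)
    vox = solve_voxels(fields, 5, 50, 5, clamp_floor=None)
    assert len(vox.depths_cm) == 10


def test_polynomial_clamping_at_constructed_root():
    """poly3 crossing zero at 35 cm: every level >= 40 cm clamps to 0."""
    coefs = (3.5, -0.1, 0.0, 0.0)  # linear in disguise: zero at x = 35
    fields = _constant_fields("poly3", coefs, shape=(4, 5))
    vox = solve_voxels(fields, 0, 50, 5, clamp_floor=0.0)
    raw = solve_voxels(fields, 0, 50, 5, clamp_floor=None)
    levels_below = np.array([depthfn.evaluate(x_cm=d, family="poly3", coefficients=coefs) < 0
                             for d in vox.depths_cm])
    assert vox.clamp_count == levels_below.sum() * 20
    for i, d in enumerate(vox.depths_cm):
        if levels_below[i]:
            assert np.all(vox.values[i] == 0.0)
    # clamping is max(value, floor): it never pulls a voxel below its raw
    # value, and leaves everything at or above the floor untouched
    assert np.all(vox.values >= raw.values - 1e-15)
    assert np.array_equal(vox.values[raw.values >= 0], raw.values[raw.values >= 0])
    assert np.array_equal(raw.values,
                          np.stack([depthfn.evaluate(x_cm=d, family="poly3",
                                                     coefficients=[g for g in fields.grids.values()])
                                    for d in raw.depths_cm]))


def test_exp_family_never_clamps():
    fields = _constant_fields("exp", (2.0, -0.2))
    vox = solve_voxels(fields, 0, 50, 5, clamp_floor=0.0)
    assert vox.clamp_count == 0


def test_uneven_step_rejected():
    fields = _constant_fields("exp", (1.0, -0.04))
    with pytest.raises(ValueError, match="divide"):
        solve_voxels(fields, 0, 50, 7)


def test_run_25d_oracle_reproduces_truth(noiseless_soc, small_exp_truth, small_stack):
    truth_layers = {float(d): depthfn.evaluate(
        x_cm=float(d), family="exp",
        coefficients=[small_exp_truth.fields[c] for c in ("c1", "c2")]) for d in MIDS}
    oracle = Oracle(truth_layers)
    layers = run_25d(noiseless_soc, small_stack, oracle)
    assert sorted(layers.grids) == [2.5, 7.5, 15.0, 25.0, 40.0]
    r, c = noiseless_soc.plots.rows, noiseless_soc.plots.cols
    for j, d in enumerate(MIDS):
        assert np.allclose(layers.grids[float(d)][r, c], noiseless_soc.values[:, j])


def test_run_3d_oracle_end_to_end_identity(noiseless_soc, small_exp_truth, small_stack):
    """Noiseless exp data + oracle coefficient surfaces: the voxel model
    reproduces the simulated profiles exactly at the mid-depths."""
    oracle = Oracle({c: small_exp_truth.fields[c] for c in ("c1", "c2")})
    fields, vox = run_3d(noiseless_soc, small_stack, "exp", oracle)
    assert vox.clamp_count == 0
    assert set(fields.grids) == {"c1", "c2"}
    r, c = noiseless_soc.plots.rows, noiseless_soc.plots.cols
    layers = fields.evaluate_at_depths(MIDS)
    for j, d in enumerate(MIDS):
        assert np.allclose(layers[float(d)][r, c], noiseless_soc.values[:, j], atol=1e-12)
    iv = internal_validation(fields, noiseless_soc)
    assert np.allclose(iv["r2"][:5].astype(float), 1.0)
    assert np.allclose(iv["rmse"][:5].astype(float), 0.0, atol=1e-12)


def test_run_3d_family_arity_and_cv_nrmse(noiseless_soc, small_stack):
    spec = LearnerSpec("rf", {"mtry": [3]}, seed=0)
    folds = assign_folds(noiseless_soc.n_plots, 5, seed=1)
    fields, _ = run_3d(noiseless_soc, small_stack, "poly3", spec, folds)
    assert len(fields.grids) == 4
    table = fields.cv_table()
    assert list(table["coefficient"]) == ["c0", "c1", "c2", "c3", "mean"]
    assert np.all(np.isfinite(table["nrmse"][:4].astype(float)))
    # nRMSE definition: rmse / range of the fitted coefficient
    for cname in ("c0", "c1"):
        y = fields.fitted_coefficients[cname]
        expected = fields.cv[cname].rmse / (y.max() - y.min())
        assert fields.cv[cname].nrmse == pytest.approx(expected)


def test_internal_validation_rows_and_mean(noiseless_soc, small_exp_truth, small_stack):
    oracle = Oracle({c: small_exp_truth.fields[c] for c in ("c1", "c2")})
    fields, _ = run_3d(noiseless_soc, small_stack, "exp", oracle)
    iv = internal_validation(fields, noiseless_soc)
    assert list(iv["depth_cm"]) == [2.5, 7.5, 15.0, 25.0, 40.0, "mean"]
    assert iv["r2"].iloc[5] == pytest.approx(iv["r2"][:5].astype(float).mean())


def test_25d_cv_table_structure(noiseless_soc, small_stack):
    spec = LearnerSpec("rf", {"mtry": [3]}, seed=0)
    folds = assign_folds(noiseless_soc.n_plots, 5, seed=1)
    layers = run_25d(noiseless_soc, small_stack, spec, folds)
    table = layers.cv_table()
    assert list(table["depth_cm"]) == [2.5, 7.5, 15.0, 25.0, 40.0, "mean"]
    assert table["rmse"].iloc[5] == pytest.approx(table["rmse"][:5].astype(float).mean())
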