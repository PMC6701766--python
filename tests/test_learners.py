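"""Regression engines, fold assignment, RBF bandwidth heuristic, tuning."""

import itertools

import numpy as np
import pytest

from pedovox.grids import CovariateStack
from pedovox.learners import (FoldAssignment, LearnerSpec, MarsRegressor, Oracle,
                              assign_folds, default_learner_spec, estimate_rbf_sigma,
                              predict_surface, tune_and_fit)


def test_fold_sizes_67_into_10():
    folds = assign_folds(67, 10, seed=0)
    sizes = sorted(np.bincount(folds.labels, minlength=10).tolist())
    assert sizes == [6, 6, 6, 7, 7, 7, 7, 7, 7, 7]


def test_folds_partition_and_determinism():
    folds = assign_folds(25, 4, seed=3)
    all_test = np.concatenate([folds.test_indices(f) for f in range(4)])
    assert sorted(all_test.tolist()) == list(range(25))
    again = assign_folds(25, 4, seed=3)
    assert np.array_equal(folds.labels, again.labels)
    with pytest.raises(ValueError):
        assign_folds(5, 6)


def test_rbf_sigma_two_points_and_homogeneity():
    X = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
    sig = estimate_rbf_sigma(X)
    assert np.allclose(sig, 1 / 25.0)
    s = 7.0
    assert np.allclose(estimate_rbf_sigma(s * X), sig / s**2)
    with pytest.raises(ValueError, match="identical"):
        estimate_rbf_sigma(np.ones((5, 3)))


def test_rbf_sigma_matches_brute_force_unit_square():
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    d2 = [np.sum((a - b) ** 2) for a, b in itertools.combinations(X, 2)]
    expected = np.quantile(1.0 / np.array(d2), [0.1, 0.5, 0.9])
    assert np.allclose(estimate_rbf_sigma(X), expected)


def test_single_grid_point_always_selected():
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(30, 4)), rng.normal(size=30)
    spec = LearnerSpec("rf", {"mtry": [2]}, seed=0)
    folds = assign_folds(30, 5, seed=1)
    fitted, cv = tune_and_fit(spec, X, y, folds)
    assert cv.selected == {"mtry": 2}
    assert len(cv.records) == 1


def test_rf_recovers_linear_signal():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(200, 5))
    y = 2.0 * X[:, 0] + rng.normal(0, 0.1, 200)
    folds = assign_folds(200, 10, seed=2)
    spec = default_learner_spec("rf", X, seed=0)
    _, cv = tune_and_fit(spec, X, y, folds)
    assert cv.r2 > 0.7


def test_shared_folds_give_identical_test_sets():
    folds = assign_folds(40, 5, seed=9)
    sets_a = [tuple(folds.test_indices(f)) for f in range(5)]
    sets_b = [tuple(folds.test_indices(f)) for f in range(5)]
    assert sets_a == sets_b


def test_out_of_fold_never_trains_on_own_fold():
    """A model trained without fold f cannot have memorised fold f's marker
    value: give fold 0 an extreme response and check its oof prediction stays
    near the remaining data's scale."""
    rng = np.random.default_rng(1)
    n = 40
    X = rng.normal(size=(n, 3))
    folds = assign_folds(n, 5, seed=0)
    y = np.zeros(n)
    y[folds.test_indices(0)] = 1000.0
    spec = LearnerSpec("rf", {"mtry": [3]}, seed=0)
    _, cv = tune_and_fit(spec, X, y, folds)
    oof_fold0 = cv.oof_predictions[folds.test_indices(0)]
    assert np.all(oof_fold0 < 500.0)


def test_mars_constant_response_predicts_constant():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(25, 3))
    model = MarsRegressor(max_terms=9).fit(X, np.full(25, 4.2))
    assert np.allclose(model.predict(rng.normal(size=(10, 3))), 4.2)


def test_mars_recovers_hinge_function():
    rng = np.random.default_rng(3)
    X = rng.uniform(-2, 2, size=(150, 3))
    y = 3.0 * np.maximum(X[:, 1] - 0.3, 0) + 1.0
    model = MarsRegressor(max_terms=9).fit(X, y)
    pred = model.predict(X)
    assert np.sqrt(np.mean((pred - y) ** 2)) < 0.05 * y.std()


def test_rf_stability_across_seeds():
    """Large forests are stable: pooled CV RMSE varies < 5% between seeds."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(67, 10))
    y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(0, 0.3, 67)
    folds = assign_folds(67, 10, seed=5)
    rmses = []
    for seed in (0, 1):
        spec = LearnerSpec("rf", {"mtry": [3]}, seed=seed)
        _, cv = tune_and_fit(spec, X, y, folds)
        rmses.append(cv.rmse)
    assert abs(rmses[0] - rmses[1]) / rmses[0] < 0.05


def test_svm_invariant_to_affine_rescaling():
    """With stats recomputed, rescaling raw covariates leaves standardized
    predictions unchanged."""
    rng = np.random.default_rng(4)
    raw = rng.normal(size=(50, 4))
    y = raw[:, 0] + rng.normal(0, 0.1, 50)
    folds = assign_folds(50, 5, seed=0)

    def standardized_predictions(X_raw):
        Xs = (X_raw - X_raw.mean(0)) / X_raw.std(0)
        spec = default_learner_spec("svm_rbf", Xs, seed=0)
        fitted, _ = tune_and_fit(spec, Xs, y, folds)
        return fitted.predict(Xs)

    p1 = standardized_predictions(raw)
    p2 = standardized_predictions(raw * np.array([3.0, 0.5, 10.0, 1.0]) + 7.0)
    assert np.allclose(p1, p2, atol=1e-8)


def test_predict_surface_contract():
    rng = np.random.default_rng(6)
    stack = CovariateStack()
    a = rng.normal(size=(8, 8))
    a[0, 0] = np.nan
    stack.add("a", a)
    stack.add("b", rng.normal(size=(8, 8)))
    X, _ = stack.full_matrix()
    y = np.full(X.shape[0], 2.5)
    spec = LearnerSpec("rf", {"mtry": [1]}, seed=0)
    folds = assign_folds(len(y), 5, seed=0)
    fitted, _ = tune_and_fit(spec, X, y, folds, feature_names=stack.names)
    surf = predict_surface(fitted, stack)
    assert np.isnan(surf[0, 0])
    assert np.allclose(surf[~np.isnan(surf)], 2.5)
    # name mismatch rejected
    other = CovariateStack()
    other.add("x", np.zeros((8, 8)))
    other.add("y", np.zeros((8, 8)))
    with pytest.raises(ValueError, match="names"):
        predict_surface(fitted, other)


def test_grid_validation():
    with pytest.raises(ValueError):
        LearnerSpec("rf", {})
    with pytest.raises(ValueError):
        LearnerSpec("nonsense", {"a": [1]})
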