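"""LDA, leave-one-out cross-validation and greedy feature selection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ibdquant.classify import (
    GreedyLDASelector,
    TwoClassLDA,
    fit_lda,
    load_model,
    loo_cv,
    predict_indices,
    save_model,
    select_features,
)
from ibdquant.errors import DegenerateClassesError, FeatureMismatchError
from ibdquant.types import FeatureTable, IndexLabels


def test_one_dimensional_closed_form():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([0, 0, 2, 2])
    model = fit_lda(X, y, standardize=False)
    # midpoint of class means (-1.5, 1.5) -> threshold at 0
    assert model.threshold_ == pytest.approx(model.weights_[0] * 0.0)
    assert model.predict([[-1.5]])[0] == 0
    assert model.predict([[1.5]])[0] == 2
    # the exact midpoint ties toward level_0
    mid = (np.array([-1.5]) + np.array([1.5])) / 2
    assert model.predict([mid])[0] == 0


def test_identical_means_falls_back_to_majority():
    X = np.array([[1.0], [1.0], [1.0], [1.0], [1.0]])
    y = np.array([0, 0, 2, 2, 2])
    with pytest.warns(UserWarning):
        model = fit_lda(X, y)
    assert model.degenerate_
    assert (model.predict(X) == 2).all()


def test_population_direction_recovered():
    rng = np.random.default_rng(0)
    cov = np.array([[2.0, 0.8], [0.8, 1.0]])
    delta = np.array([1.0, 0.5])
    L = np.linalg.cholesky(cov)
    n = 4000
    X0 = rng.standard_normal((n, 2)) @ L.T
    X1 = rng.standard_normal((n, 2)) @ L.T + delta
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    model = fit_lda(X, y, reg_lambda=0.0)
    w = model.effective_weights_
    target = np.linalg.solve(cov, delta)
    cos = w @ target / (np.linalg.norm(w) * np.linalg.norm(target))
    assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0


def test_projection_monotone_and_orders_training_classes():
    rng = np.random.default_rng(1)
    X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(2, 1, (20, 3))])
    y = np.array([0] * 20 + [2] * 20)
    model = fit_lda(X, y)
    ld = model.project(X)
    assert ld[y == 2].mean() > model.threshold_ > ld[y == 0].mean()
    x0 = X[0]
    step = model.effective_weights_
    assert model.project([x0 + step])[0] > model.project([x0])[0]


def test_prediction_affine_invariant_per_feature():
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(1.5, 1, (15, 4))])
    y = np.array([0] * 15 + [1] * 15)
    model = fit_lda(X, y, reg_lambda=0.0)
    Xt = X.copy()
    Xt[:, 2] = 30.0 * Xt[:, 2] - 7.0
    model_t = fit_lda(Xt, y, reg_lambda=0.0)
    np.testing.assert_array_equal(model.predict(X), model_t.predict(Xt))
    np.testing.assert_allclose(model.decision_function(X),
                               model_t.decision_function(Xt), atol=1e-8)


def test_agreement_with_reference_lda():
    """Independent cross-check against sklearn's LDA on balanced data."""
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1.2, 1, (30, 3))])
    y = np.array([0] * 30 + [1] * 30)
    ours = fit_lda(X, y, reg_lambda=0.0)
    ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
    assert (ours.predict(X) == ref.predict(X)).mean() == 1.0


def test_loo_cv_contracts():
    rng = np.random.default_rng(4)
    # perfect separation
    X = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(10, 0.01, 10)])[:, None]
    y = np.array([0] * 10 + [1] * 10)
    acc, ld = loo_cv(X, y)
    assert acc == 1.0
    assert np.isfinite(ld).all()
    # constant feature, unbalanced classes -> majority fraction
    Xc = np.ones((12, 1))
    yc = np.array([0] * 9 + [1] * 3)
    acc_c, _ = loo_cv(Xc, yc)
    assert acc_c == pytest.approx(9 / 12)
    with pytest.raises(DegenerateClassesError):
        loo_cv(np.zeros((3, 1)), np.array([0, 0, 1]))


def test_loo_cv_does_not_leak_held_out_sample():
    """Twin samples with opposite labels must both be misclassified: each
    held-out twin is dominated by its training-set twin of the other class."""
    rng = np.random.default_rng(5)
    y = np.array([0] * 10 + [1] * 10 + [0, 1])
    X = (y * 2.0 + rng.normal(0, 0.05, size=y.size))[:, None]
    X[-2, 0] = 1.0  # twin pair sitting exactly between the classes
    X[-1, 0] = 1.0
    acc, ld = loo_cv(X, y)
    preds_correct = np.sign(ld) == np.sign(y * 2 - 1)
    assert preds_correct[:-2].all()
    assert acc <= 20 / 22  # at least the twins cannot both be right


def make_table(n=24, n_noise=10, seed=6):
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [2] * (n // 2))
    data = {"separator": y + rng.normal(0, 0.05, n)}
    for i in range(n_noise):
        data[f"noise_{i:02d}"] = rng.normal(size=n)
    frame = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
    meta = {c: {"family": "geometry" if c == "separator" else "irp",
                "roi": "n/a", "modality": "n/a"} for c in frame.columns}
    labels = {f"s{i}": IndexLabels(int(y[i]), 0, 0) for i in range(n)}
    return FeatureTable(data=frame, meta=meta), labels


def test_selection_finds_separating_feature():
    table, labels = make_table()
    result = select_features(table, labels, "architecture")
    assert result.selected_features[0] == "separator"
    assert result.loo_accuracy == 1.0
    assert result.trace[0][0] == "separator"


def test_selection_respects_max_features_and_families():
    table, labels = make_table()
    capped = select_features(table, labels, "architecture", max_features=1)
    assert len(capped.selected_features) <= 1
    geo = select_features(table, labels, "architecture", families="geometry_only")
    assert set(geo.selected_features) <= {"separator"}


def test_predict_indices_column_order_invariant():
    table, labels = make_table()
    models = {}
    for idx in ("architecture", "chronicity", "activity"):
        y = np.array([getattr(labels[s], "architecture") for s in table.sample_ids])
        model = fit_lda(table.data[["separator"]], np.where(y > 0, 1, 0)
                        if idx == "activity" else y)
        models[idx] = model
    row = table.data.iloc[0]
    pred_a = predict_indices(row, models)
    pred_b = predict_indices(row[::-1], models)  # reversed feature order
    assert pred_a == pred_b
    with pytest.raises(FeatureMismatchError):
        models["architecture"].predict(pd.DataFrame({"other": [1.0]}))


def test_model_json_roundtrip(tmp_path):
    table, labels = make_table()
    y = np.array([labels[s].architecture for s in table.sample_ids])
    model = fit_lda(table.data[["separator", "noise_00"]], y)
    save_model(model, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    np.testing.assert_allclose(back.weights_, model.weights_)
    np.testing.assert_array_equal(back.predict(table.data), model.predict(table.data))


def test_sklearn_estimator_protocol():
    est = TwoClassLDA(reg_lambda=0.01, standardize=False)
    params = est.get_params()
    assert params == {"reg_lambda": 0.01, "standardize": False}
    cloned = clone(est)
    assert cloned.get_params() == params
    sel = clone(GreedyLDASelector(max_features=5))
    assert sel.get_params()["max_features"] == 5
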