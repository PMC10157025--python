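"""Cost-sensitive SVM: separable toys, null behavior, feature sweep."""

import numpy as np
import pytest

from wmius.classify import (ClassifierConfig, auc_vs_k_sweep, best_k,
                            predict_scores, train_classifier)
from wmius.errors import DegenerateLabelError, ShapeError
from wmius.metrics import roc_auc


def test_separable_symmetric_1d_threshold_at_zero():
    X = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])[:, None]
    X += np.random.default_rng(0).normal(0, 0.05, X.shape)
    y = np.array([0] * 20 + [1] * 20)
    model = train_classifier(X, y, ClassifierConfig(kernel="linear"), seed=0)
    s = predict_scores(model, X)
    assert roc_auc(s, y) == 1.0
    assert np.sign(predict_scores(model, np.array([[0.3]]))) == 1
    assert np.sign(predict_scores(model, np.array([[-0.3]]))) == -1


def test_shuffled_labels_yield_chance_auc():
    from sklearn.model_selection import StratifiedKFold

    aucs = []
    for draw in range(4):  # average several draws to shrink the null spread
        rng = np.random.default_rng(draw)
        X = rng.standard_normal((200, 5))
        y = rng.integers(0, 2, 200)  # independent of X
        for tr, te in StratifiedKFold(4, shuffle=True, random_state=0).split(X, y):
            m = train_classifier(X[tr], y[tr], seed=0)
            aucs.append(roc_auc(predict_scores(m, X[te]), y[te]))
    assert 0.4 <= np.mean(aucs) <= 0.6


def test_max_margin_matches_analytic_solution():
    # support vectors (1,1) / (-1,-1): the max-margin separator is
    # w = (1/2, 1/2), b = 0  (textbook hand-derived QP solution)
    X = np.array([[1.0, 1.0], [2.0, 2.0], [-1.0, -1.0], [-2.0, -2.0]])
    y = np.array([1, 1, 0, 0])
    from sklearn.svm import SVC

    svc = SVC(kernel="linear", C=1e6).fit(X, y)
    assert np.allclose(svc.coef_, [[0.5, 0.5]], atol=1e-6)
    assert np.allclose(svc.intercept_, 0.0, atol=1e-6)


def test_scores_deterministic_and_width_checked():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((40, 6))
    y = (X[:, 0] > 0).astype(int)
    m = train_classifier(X, y, seed=3)
    assert np.array_equal(predict_scores(m, X), predict_scores(m, X))
    with pytest.raises(ShapeError):
        predict_scores(m, X[:, :4])
    const = predict_scores(m, np.zeros((5, 6)))
    assert np.allclose(const, const[0])


def test_selection_ignores_out_of_model_columns():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((60, 8))
    y = (X[:, 2] + 0.3 * rng.standard_normal(60) > 0).astype(int)
    sel = [2, 5]
    m = train_classifier(X, y, seed=0, selected=sel)
    base = predict_scores(m, X)
    X_aug = X.copy()
    X_aug[:, [0, 7]] = 999.0  # out-of-model columns
    assert np.allclose(base, predict_scores(m, X_aug))


def test_single_class_training_rejected():
    X = np.zeros((10, 3))
    with pytest.raises(DegenerateLabelError):
        train_classifier(X, np.zeros(10))


def test_cost_weighting_helps_minority_sensitivity():
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n_maj, n_min = 80, 20
        X = np.concatenate([rng.normal(-1, 1.2, n_maj), rng.normal(1, 1.2, n_min)])[:, None]
        y = np.array([0] * n_maj + [1] * n_min)
        mw = train_classifier(X, y, ClassifierConfig(kernel="linear"), seed=0)
        mu = train_classifier(
            X, y, ClassifierConfig(kernel="linear", class_weight=None), seed=0)
        sens_w = np.mean(predict_scores(mw, X[y == 1][:, ]) > 0)
        sens_u = np.mean(predict_scores(mu, X[y == 1][:, ]) > 0)
        wins += sens_w >= sens_u
    assert wins >= 8


def test_auc_vs_k_sweep_shapes_and_degenerate_grid():
    rng = np.random.default_rng(6)
    n, p, k_inf = 160, 30, 6
    X = rng.standard_normal((n, p))
    y = rng.integers(0, 2, n)
    X[:, :k_inf] += y[:, None] * 1.2
    order = np.arange(p)  # informative features already first
    tr = np.arange(0, n, 2)
    te = np.arange(1, n, 2)
    curve = auc_vs_k_sweep(X[tr], y[tr], X[te], y[te], order,
                           [1, k_inf, p], seed=0)
    ks = [k for k, _ in curve]
    assert ks == [1, k_inf, p]
    auc1 = dict(curve)[1]
    auck = dict(curve)[k_inf]
    assert auck >= auc1 - 0.02  # more informative features never much worse
    single = auc_vs_k_sweep(X[tr], y[tr], X[te], y[te], order, [p], seed=0)
    full_model = train_classifier(X[tr], y[tr], seed=0, selected=order[:p])
    full_auc = roc_auc(predict_scores(full_model, X[te]), y[te])
    assert np.isclose(single[0][1], full_auc)
    assert best_k(curve) in ks
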