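"""MLP/RBF classifiers: splits, separable fixtures, invariances."""

import numpy as np
import pytest

from vagdx.networks import (DEFAULT_MLP_GRID, ErrorFunction, Family,
                            NetworkSpec, SplitConfig, accuracy, model_search,
                            predict, predict_proba, split_dataset, train_mlp,
                            train_rbf)


@pytest.fixture(scope="module")
def blobs():
    """Two Gaussian blobs 4 sigma apart: linearly separable by construction."""
    rng = np.random.default_rng(0)
    n = 100
    X0 = rng.normal(loc=0.0, scale=1.0, size=(n, 2))
    X1 = rng.normal(loc=4.0, scale=1.0, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    return X, y


def test_split_sizes_disjoint_exhaustive():
    y = np.array([0] * 66 + [1] * 34)
    tr, te, va = split_dataset(y, SplitConfig(seed=1))
    assert (tr.size, te.size, va.size) == (70, 15, 15)
    all_idx = np.concatenate([tr, te, va])
    assert np.array_equal(np.sort(all_idx), np.arange(100))
    # stratification: each subset holds both classes
    for subset in (tr, te, va):
        assert set(y[subset]) == {0, 1}
    tr2, te2, va2 = split_dataset(y, SplitConfig(seed=1))
    np.testing.assert_array_equal(tr, tr2)
    np.testing.assert_array_equal(te, te2)


def test_split_impossible_stratification_rejected():
    y = np.array([0] * 11 + [1])
    with pytest.raises(ValueError):
        split_dataset(y, SplitConfig(seed=0))


def test_bad_split_fractions_rejected():
    with pytest.raises(ValueError):
        SplitConfig(train_frac=0.5, test_frac=0.3, val_frac=0.3)


def _mlp_spec(n_in, **kw):
    base = dict(family=Family.MLP, n_in=n_in, n_hidden=8,
                hidden_activation="tanh", error_function=ErrorFunction.ENTROPY,
                output_activation="softmax", max_iter=200)
    base.update(kw)
    return NetworkSpec(**base)


def test_mlp_separable_blobs_reach_full_training_accuracy(blobs):
    X, y = blobs
    model = train_mlp(_mlp_spec(2), X, y, seed=0)
    assert accuracy(model, X, y) == 1.0


def test_mlp_sos_exponential_variant_trains(blobs):
    X, y = blobs
    spec = _mlp_spec(2, error_function=ErrorFunction.SOS,
                     output_activation="exponential", hidden_activation="linear",
                     max_iter=50)
    model = train_mlp(spec, X, y, seed=0)
    assert accuracy(model, X, y) >= 0.95


def test_mlp_constant_inputs_learn_class_priors():
    rng = np.random.default_rng(2)
    X = np.zeros((90, 3))
    y = (np.arange(90) < 30).astype(int)   # class-1 prior = 1/3
    model = train_mlp(_mlp_spec(3), X, y, seed=1)
    p = predict_proba(model, X)
    np.testing.assert_allclose(p[0], p[-1], atol=1e-9)
    assert p[0, 1] == pytest.approx(1 / 3, abs=0.05)


def test_mlp_deterministic_given_seed(blobs):
    X, y = blobs
    a = train_mlp(_mlp_spec(2), X, y, seed=3)
    b = train_mlp(_mlp_spec(2), X, y, seed=3)
    for k in a.parameters:
        np.testing.assert_array_equal(a.parameters[k], b.parameters[k])


def test_rbf_interpolation_with_small_widths():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 2))
    y = rng.integers(0, 2, 30)
    spec = NetworkSpec(family=Family.RBF, n_in=2, n_hidden=30,
                       hidden_activation="gauss")
    model = train_rbf(spec, X, y, seed=0, width_scale=0.05)
    assert accuracy(model, X, y) == 1.0
    p = predict_proba(model, X)
    assert np.all(p[np.arange(30), y] > 0.5)


def test_rbf_blobs_generalize(blobs):
    X, y = blobs
    tr, te, va = split_dataset(y, SplitConfig(seed=5))
    spec = NetworkSpec(family=Family.RBF, n_in=2, n_hidden=14,
                       hidden_activation="gauss")
    model = train_rbf(spec, X[tr], y[tr], seed=0)
    assert accuracy(model, X[te], y[te]) >= 0.95


def test_rbf_too_many_centers_rejected():
    spec = NetworkSpec(family=Family.RBF, n_in=2, n_hidden=50,
                       hidden_activation="gauss")
    with pytest.raises(ValueError):
        train_rbf(spec, np.zeros((10, 2)), np.zeros(10, int), seed=0)


def test_predict_proba_rows_sum_to_one(blobs):
    X, y = blobs
    for trainer, spec in (
            (train_mlp, _mlp_spec(2)),
            (train_rbf, NetworkSpec(family=Family.RBF, n_in=2, n_hidden=10,
                                    hidden_activation="gauss"))):
        model = trainer(spec, X, y, seed=0)
        p = predict_proba(model, X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-12)
        assert np.all(p >= 0)
    with pytest.raises(ValueError, match="dimension"):
        predict_proba(model, np.zeros((3, 5)))


def test_feature_scaling_absorbed_by_standardizer(blobs):
    X, y = blobs
    Xs = X.copy()
    Xs[:, 0] *= 10.0
    a = train_mlp(_mlp_spec(2), X, y, seed=6)
    b = train_mlp(_mlp_spec(2), Xs, y, seed=6)
    np.testing.assert_array_equal(predict(a, X), predict(b, Xs))


def test_model_search_leaderboard(blobs):
    X, y = blobs
    splits = split_dataset(y, SplitConfig(seed=7))
    single = [{"n_hidden": 5, "hidden_activation": "tanh",
               "error_function": "Entropy", "output_activation": "softmax",
               "max_iter": 100}]
    best, board = model_search(X, y, Family.MLP, splits, grid=single, seed=0)
    assert len(board) == 1
    assert best.spec.name == "MLP 2-5-2"
    best_m, board_m = model_search(X, y, Family.MLP, splits, seed=0)
    assert len(board_m) == len(DEFAULT_MLP_GRID)
    assert board_m["name"].str.match(r"MLP \d+-\d+-2").all()
    best_val = board_m["validation_accuracy_pct"].max()
    tr, te, va = splits
    assert 100 * accuracy(best_m, X[va], y[va]) == pytest.approx(best_val)
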