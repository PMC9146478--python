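"""NCA: kernel/distance/probability identities, gradient, weight recovery."""

import math

import numpy as np
import pytest

from vagdx.nca import (LabeledDataset, fit_nca, kernel, loo_probabilities,
                       objective, objective_gradient, select_features,
                       weighted_distance)


def make_recovery_dataset(n=60, n_noise=4, seed=0, shift=3.0):
    """Feature 0 separates the classes; the rest are i.i.d. noise."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 1 + n_noise))
    X[:, 0] += shift * y
    return LabeledDataset(X=X, y=y,
                          feature_names=[f"f{i}" for i in range(1 + n_noise)])


def random_dataset(n=6, d=3, seed=1):
    rng = np.random.default_rng(seed)
    return LabeledDataset(X=rng.normal(size=(n, d)), y=rng.integers(0, 2, n),
                          feature_names=[f"f{i}" for i in range(d)])


def test_weighted_distance_examples():
    assert weighted_distance([1.0, 2.0], [1.0, 2.0], np.array([3.0, 4.0])) == 0.0
    assert weighted_distance([1.0, 0.0], [0.0, 2.0], np.zeros(2)) == 0.0
    assert weighted_distance([1.0, 0.0], [0.0, 2.0], np.array([1.0, 2.0])) == 9.0


def test_kernel_values_and_monotonicity():
    assert kernel(0.0, 2.0) == 1.0
    assert kernel(1.0, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)
    assert kernel(2.0, 1.0) < kernel(1.0, 1.0)
    with pytest.raises(ValueError):
        kernel(1.0, 0.0)


def test_loo_probabilities_uniform_when_weights_zero():
    ds = random_dataset(n=8, d=3, seed=2)
    P, p = loo_probabilities(ds, np.zeros(3), sigma=1.0)
    np.testing.assert_allclose(np.diag(P), 0.0)
    np.testing.assert_allclose(P.sum(axis=1), 1.0, rtol=1e-12)
    off = P[~np.eye(8, dtype=bool)]
    np.testing.assert_allclose(off, 1 / 7, rtol=1e-12)
    for i in range(8):
        n_same = np.sum(ds.y == ds.y[i]) - 1
        assert p[i] == pytest.approx(n_same / 7, rel=1e-12)


def test_loo_probabilities_two_points():
    same = LabeledDataset(X=[[0.0], [1.0]], y=[1, 1], feature_names=["f"])
    _, p = loo_probabilities(same, np.ones(1), 1.0)
    np.testing.assert_allclose(p, [1.0, 1.0])
    diff = LabeledDataset(X=[[0.0], [1.0]], y=[0, 1], feature_names=["f"])
    _, p = loo_probabilities(diff, np.ones(1), 1.0)
    np.testing.assert_allclose(p, [0.0, 0.0])


def test_row_stochasticity_random_weights():
    rng = np.random.default_rng(3)
    for _ in range(20):
        ds = random_dataset(n=int(rng.integers(4, 20)),
                            d=int(rng.integers(1, 6)),
                            seed=int(rng.integers(1e6)))
        P, p = loo_probabilities(ds, rng.normal(size=ds.d), sigma=0.7)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, rtol=1e-9)
        assert np.all((p >= 0) & (p <= 1 + 1e-12))


def test_objective_at_zero_weights_and_penalty_monotonicity():
    ds = random_dataset(n=10, d=4, seed=5)
    expected = sum((np.sum(ds.y == ds.y[i]) - 1) / (ds.n - 1)
                   for i in range(ds.n))
    assert objective(ds, np.zeros(4), 1.0, lam=7.3) == pytest.approx(expected)
    w = np.ones(4)
    f_small = objective(ds, w, 1.0, lam=0.1)
    f_big = objective(ds, w, 1.0, lam=1.0)
    assert f_big <= f_small


def test_gradient_matches_finite_differences():
    sigma, lam = 0.8, 0.05
    for seed in (1, 2, 3):
        ds = random_dataset(n=6, d=3, seed=seed)
        rng = np.random.default_rng(seed + 100)
        w = rng.uniform(0.2, 1.5, ds.d)
        g = objective_gradient(ds, w, sigma, lam)
        h = 1e-6
        for l in range(ds.d):
            e = np.zeros(ds.d)
            e[l] = h
            fd = (objective(ds, w + e, sigma, lam)
                  - objective(ds, w - e, sigma, lam)) / (2 * h)
            assert g[l] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_gradient_zero_at_origin():
    ds = random_dataset(n=8, d=4, seed=9)
    np.testing.assert_allclose(objective_gradient(ds, np.zeros(4), 1.0, 0.3), 0.0)


def test_gradient_pure_penalty_on_identical_points():
    """With all points identical the kernel term is weight-independent, so
    the gradient reduces to the penalty derivative -2*lam*w."""
    ds = LabeledDataset(X=np.zeros((6, 3)), y=[0, 1, 0, 1, 0, 1],
                        feature_names=["a", "b", "c"])
    w = np.array([0.5, -1.2, 2.0])
    g = objective_gradient(ds, w, 1.0, lam=0.7)
    np.testing.assert_allclose(g, -2 * 0.7 * w, atol=1e-10)


def test_weight_recovery_on_informative_feature():
    ds = make_recovery_dataset(n=60, n_noise=4, seed=0)
    model = fit_nca(ds, seed=0)
    w2 = model.w**2
    assert w2[0] > w2[1:].max()
    assert 0 in model.selected
    assert sum(1 for i in (1, 2, 3, 4) if i not in model.selected) >= 2


def test_duplicate_feature_shares_mass():
    ds = make_recovery_dataset(n=60, n_noise=4, seed=1)
    X = ds.X.copy()
    X[:, 1] = X[:, 0]
    ds2 = LabeledDataset(X=X, y=ds.y, feature_names=ds.feature_names)
    model = fit_nca(ds2, seed=0)
    w2 = model.w**2
    assert w2[0] + w2[1] > w2[2:].sum()


def test_lambda_shrinkage():
    ds = make_recovery_dataset(n=40, n_noise=3, seed=2)
    grid = np.array([1e-4, 1e-3, 1e-2, 1e-1])
    masses = []
    for lam in grid:
        model = fit_nca(ds, lam_grid=np.array([lam]), seed=0)
        masses.append(float(np.sum(model.w**2)))
    assert all(b <= a * (1 + 1e-6) + 1e-9 for a, b in zip(masses, masses[1:]))


def test_permutation_null_weights_below_informative():
    ds = make_recovery_dataset(n=60, n_noise=4, seed=3)
    model = fit_nca(ds, seed=0)
    informative = model.w[0] ** 2
    rng = np.random.default_rng(4)
    ds_perm = LabeledDataset(X=ds.X, y=rng.permutation(ds.y),
                             feature_names=ds.feature_names)
    null = fit_nca(ds_perm, seed=0)
    assert np.max(null.w**2) < informative


def test_select_features_threshold():
    ds = random_dataset(n=6, d=3, seed=6)
    model = fit_nca(ds, lam_grid=np.array([1e-3]), n_folds=2, seed=0)
    model.w = np.array([3.0, 0.1, 0.05])
    assert select_features(model, 0.1) == [0]
    assert select_features(model, 0.0) == [0, 1, 2]
    model.w = np.array([1.0, 1.0, 1.0])
    assert select_features(model, 0.5) == [0, 1, 2]
    model.w = np.zeros(3)
    with pytest.warns(RuntimeWarning):
        assert select_features(model, 0.1) == []


def test_empty_lambda_grid_rejected():
    ds = random_dataset(n=10, d=2, seed=7)
    with pytest.raises(ValueError, match="empty"):
        fit_nca(ds, lam_grid=np.array([]))
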