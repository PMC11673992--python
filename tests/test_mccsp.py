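"""Multi-class CSP: algebraic identities, oracles, planted recovery."""

import numpy as np
import pytest

from emocsp import (MCCSP, SimConfig, center_trial, class_covariance,
                    class_spatial_filter, composite_row_split, fit_mccsp,
                    make_ground_truth, project, simulate_class_segment,
                    whitening_transform)


def random_psd(rng, c):
    A = rng.standard_normal((c, c))
    return A @ A.T + 1e-3 * np.eye(c)


class TestCenterTrial:
    def test_constant_matrix_zeroed(self):
        assert np.allclose(center_trial(np.full((5, 3), 7.0)), 0.0)

    def test_idempotent(self, rng):
        X = center_trial(rng.standard_normal((20, 4)))
        assert np.allclose(center_trial(X), X, atol=1e-12)

    def test_row_and_column_means_vanish(self, rng):
        X = center_trial(rng.standard_normal((10, 4)))
        assert np.abs(X.mean(axis=1)).max() < 1e-12
        assert np.abs(X.mean(axis=0)).max() < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_trial(np.empty((0, 3)))


class TestClassCovariance:
    def test_single_trial_exact_product(self, rng):
        X = rng.standard_normal((6, 3))
        assert np.allclose(class_covariance([X]), X.T @ X)

    def test_sum_linearity(self, rng):
        X = rng.standard_normal((6, 3))
        R = class_covariance([X] * 4)
        assert np.allclose(R, 4 * X.T @ X)

    def test_zero_trials_zero_matrix(self):
        assert np.allclose(class_covariance([np.zeros((5, 3))]), 0.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            class_covariance([rng.standard_normal((5, 3)),
                              rng.standard_normal((6, 3))])

    def test_trace_norm_option(self, rng):
        X = rng.standard_normal((6, 3))
        R = class_covariance([X], trace_norm=True)
        assert np.trace(R) == pytest.approx(1.0)


class TestWhitening:
    def test_identity_input_orthonormal_rows(self):
        wt = whitening_transform(np.eye(4))
        assert np.allclose(wt.W @ wt.W.T, np.eye(4), atol=1e-10)

    def test_diagonal_closed_form(self):
        wt = whitening_transform(np.diag([4.0, 1.0]))
        # rows are (1/2, 0) and (0, 1) up to order/sign
        assert np.allclose(sorted(np.abs(wt.W).max(axis=1)), [0.5, 1.0])
        assert np.allclose(wt.W @ np.diag([4.0, 1.0]) @ wt.W.T, np.eye(2),
                           atol=1e-10)

    def test_random_psd_reconstruction(self, rng):
        for _ in range(10):
            R = random_psd(rng, 6)
            wt = whitening_transform(R)
            err = np.linalg.norm(wt.W @ R @ wt.W.T - np.eye(wt.rank))
            assert err < 1e-8

    def test_rank_deficiency_dropped(self):
        R = np.diag([2.0, 1.0, 0.0])
        wt = whitening_transform(R)
        assert wt.rank == 2
        assert wt.W.shape == (2, 3)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            whitening_transform(np.zeros((3, 3)))


class TestClassSpatialFilter:
    def test_diagonal_selects_extremes(self):
        S = np.diag([0.9, 0.5, 0.1])
        SF, SP = class_spatial_filter(S, np.eye(3), m=1)
        # filters pick axes 1 and 3
        picked = {int(np.argmax(np.abs(row))) for row in SF}
        assert picked == {0, 2}
        assert np.allclose(SF @ SP, np.eye(2), atol=1e-10)

    def test_degenerate_equal_classes_still_orthonormal(self):
        S = np.eye(4) / 3.0
        SF, _ = class_spatial_filter(S, np.eye(4), m=2)
        assert SF.shape == (4, 4)
        assert np.allclose(SF @ SF.T, np.eye(4), atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            class_spatial_filter(np.eye(3), np.eye(3), m=2)

    def test_eigensystem_matches_characteristic_polynomial(self, rng):
        # independent oracle for C <= 3: roots of det(S - lambda I)
        from emocsp.mccsp import _eigh_desc
        for _ in range(20):
            S = random_psd(rng, 3)
            vals, vecs = _eigh_desc(S)
            c2 = -np.trace(S)
            c1 = 0.5 * (np.trace(S) ** 2 - np.trace(S @ S))
            c0 = -np.linalg.det(S)
            roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1]
            assert np.allclose(vals, roots, atol=1e-8)
            for k in range(3):
                assert np.linalg.norm(S @ vecs[:, k] -
                                      vals[k] * vecs[:, k]) < 1e-8


def planted_epochs(seed, n_channels=6, n_trials=30, t_samples=250):
    cfg = SimConfig(n_channels=n_channels, seed=seed, pink_scale=0.05,
                    white_scale=0.02)
    gt = make_ground_truth(cfg, seed)
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(3):
        for _ in range(n_trials):
            X.append(simulate_class_segment(
                cls, t_samples / cfg.fs, gt, cfg,
                seed=int(rng.integers(0, 2**31 - 1))))
            y.append(cls)
    return np.stack(X), np.array(y), gt


class TestFitMCCSP:
    def test_planted_filter_alignment(self):
        # top filter of each class aligns with the inverse-mixing row of
        # that class's dominant source
        X, y, gt = planted_epochs(seed=0)
        bank = fit_mccsp(X, y, m=1, car=False)
        Ainv = gt.unmixing()
        for i in range(3):
            f = bank.filters[i][0]
            target = Ainv[i]
            cos = abs(f @ target) / (np.linalg.norm(f)
                                     * np.linalg.norm(target))
            assert cos > 0.95

    def test_identical_class_data_gives_uniform_eigenvalues(self, rng):
        X1 = rng.standard_normal((10, 50, 4))
        X = np.concatenate([X1, X1, X1])
        y = np.repeat([0, 1, 2], 10)
        bank = fit_mccsp(X, y, m=1)
        for v in bank.class_eigvals:
            assert np.allclose(v, 1.0 / 3.0, atol=1e-10)

    def test_composite_mode_preserves_channel_count(self):
        X, y, _ = planted_epochs(seed=1, n_channels=6)
        bank = fit_mccsp(X, y, mode="composite")
        Z = project(bank, X[:4])
        assert Z.shape == (4, 250, 6)

    def test_composite_split_19_channels(self):
        assert composite_row_split(19, 3) == [7, 6, 6]
        assert composite_row_split(6, 3) == [2, 2, 2]

    def test_whitened_class_covariances_sum_to_identity(self):
        X, y, _ = planted_epochs(seed=2)
        bank = fit_mccsp(X, y)
        S_sum = np.sum(bank.S, axis=0)
        assert np.linalg.norm(S_sum - np.eye(S_sum.shape[0])) < 1e-8

    def test_two_class_eigenvalue_complementarity(self, rng):
        X = rng.standard_normal((40, 100, 5))
        y = np.repeat([0, 1], 20)
        bank = fit_mccsp(X, y, m=2)
        # classic CSP: shared eigenvectors, lambda_1 + lambda_2 = 1
        v0 = np.sort(bank.class_eigvals[0])
        v1 = np.sort(bank.class_eigvals[1])[::-1]
        assert np.allclose(v0 + v1, 1.0, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((5, 20, 3))
        with pytest.raises(ValueError):
            fit_mccsp(X, np.zeros(5))


class TestProject:
    def test_identity_filter_is_identity(self, rng):
        X, y, _ = planted_epochs(seed=3, n_channels=4, n_trials=5)
        bank = fit_mccsp(X, y)
        bank.composite_filter = np.eye(4)
        assert np.allclose(project(bank, X[:2]), X[:2])

    def test_single_row_filter_manual_dot(self, rng):
        X, y, _ = planted_epochs(seed=4, n_channels=4, n_trials=5)
        bank = fit_mccsp(X, y)
        w = rng.standard_normal(4)
        bank.composite_filter = w[None, :]
        Z = project(bank, X[0])
        assert np.allclose(Z[:, 0], X[0] @ w)

    def test_channel_mismatch_rejected(self):
        X, y, _ = planted_epochs(seed=5, n_channels=4, n_trials=5)
        bank = fit_mccsp(X, y)
        with pytest.raises(ValueError):
            project(bank, np.zeros((2, 10, 7)))


class TestEstimatorInterface:
    def test_fit_transform_shapes_and_params(self):
        X, y, _ = planted_epochs(seed=6, n_channels=5, n_trials=8)
        est = MCCSP(m=2, mode="composite")
        Z = est.fit(X, y).transform(X)
        assert Z.shape == X.shape
        assert est.get_params()["m"] == 2
        est.set_params(m=1)
        assert est.m == 1

    def test_variance_ordering_property_over_seeds(self):
        # own-class trials project with the largest variance onto the
        # own-class top filters
        wins = 0
        for seed in range(20):
            X, y, _ = planted_epochs(seed=seed, n_channels=6, n_trials=15)
            bank = fit_mccsp(X, y, m=1, car=False)
            ok = True
            for i in range(3):
                f = bank.filters[i][0]
                var = [np.mean([(x @ f).var() for x in X[y == c]])
                       for c in range(3)]
                ok = ok and (np.argmax(var) == i)
            wins += ok
        assert wins >= 19
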