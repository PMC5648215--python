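"""NIPALS PLS, scaling, VIP, cross-validated Q2Y, errors, and PCA."""

import numpy as np
import pytest

from ftirchem.chemometrics import (
    FitError, scale_columns, dummy_code, fit_pls, fit_pls_raw, q2y,
    rmsee, rmsep, rmse_to_months, vip_scores, select_by_vip, pca,
    save_model, load_model, venetian_blinds_folds,
)


class TestScaling:
    def test_uv_gives_unit_sd_zero_mean(self, rng):
        X = rng.normal(3, 5, size=(20, 6))
        Xs, spec = scale_columns(X, "uv")
        np.testing.assert_allclose(Xs.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(0, ddof=1), 1, atol=1e-12)

    def test_pareto_divides_by_sqrt_sd(self, rng):
        x = rng.normal(size=40)
        x = (x - x.mean()) / x.std(ddof=1) * 4.0  # sd exactly 4
        X = np.column_stack([x, rng.normal(size=40)])
        Xs, spec = scale_columns(X, "pareto")
        np.testing.assert_allclose(spec.column_scales[0], 2.0, atol=1e-9)
        np.testing.assert_allclose(Xs[:, 0], x / 2.0, atol=1e-9)

    def test_stored_spec_reproduces_fit_output(self, rng):
        X = rng.normal(size=(15, 4))
        Xs, spec = scale_columns(X, "uv")
        np.testing.assert_allclose(spec.apply(X), Xs, atol=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(FitError):
            scale_columns(np.ones((1, 3)), "uv")

    def test_constant_column_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.raises(FitError, match="constant"):
            scale_columns(X, "uv")


class TestDummyCoding:
    def test_two_class_single_column(self):
        Y, classes = dummy_code(["5yr", "6yr", "6yr"])
        assert classes == ["5yr", "6yr"]
        np.testing.assert_array_equal(Y, [[0.0], [1.0], [1.0]])

    def test_three_class_one_hot(self):
        Y, classes = dummy_code(["TR", "RH", "LR"])
        assert Y.shape == (3, 3)
        np.testing.assert_allclose(Y.sum(axis=1), 1.0)
        # each row is an indicator for its own class
        for i, lab in enumerate(["TR", "RH", "LR"]):
            assert Y[i, classes.index(lab)] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dummy_code(["5yr", "5yr"])


class TestNipals:
    def test_exact_linear_relation_r2y_one(self, rng):
        # orthogonal predictors: one component recovers y = c*x_j exactly
        Q, _ = np.linalg.qr(rng.normal(size=(10, 4)))
        Xc = Q
        y = 2.5 * Xc[:, [1]]
        model = fit_pls(Xc, y, 1)
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-9)

    def test_first_weight_matches_svd_of_cross_covariance(self, rng):
        # independent oracle: dominant left singular vector of X'Y
        for _ in range(10):
            n, p, m = 8, 5, 2
            X = rng.normal(size=(n, p))
            Y = rng.normal(size=(n, m))
            Xc, Yc = X - X.mean(0), Y - Y.mean(0)
            model = fit_pls(Xc, Yc, 1)
            U, _, _ = np.linalg.svd(Xc.T @ Yc)
            w_ref = U[:, 0]
            w_ref *= np.sign(w_ref[np.argmax(np.abs(w_ref))])
            np.testing.assert_allclose(model.weights[:, 0], w_ref, atol=1e-6)

    def test_r2y_monotone_in_components(self, rng):
        X = rng.normal(size=(12, 8))
        Y = rng.normal(size=(12, 2))
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        r2 = [fit_pls(Xc, Yc, A).r2y_cum for A in range(1, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))
        assert 0 <= r2[0] <= r2[-1] <= 1 + 1e-12

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(15, 10))
        Y = rng.normal(size=(15, 2))
        model = fit_pls(X - X.mean(0), Y - Y.mean(0), 5)
        G = model.scores.T @ model.scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off <= 1e-8 * np.diag(G).max()

    def test_coefficients_reproduce_recursion_predictions(self, rng):
        # B-path predictions equal explicit component-wise reconstruction
        X = rng.normal(size=(12, 6))
        Y = rng.normal(size=(12, 2))
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        model = fit_pls(Xc, Yc, 3)
        T, C = model.scores, model.y_loadings
        np.testing.assert_allclose(Xc @ model.coefficients, T @ C.T, atol=1e-9)

    def test_matches_sklearn_pls(self, rng):
        # dual route: same model through the scikit-learn implementation
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(14, 7))
        Y = rng.normal(size=(14, 2))
        Xc = X - X.mean(0)
        mine = fit_pls(Xc, Y - Y.mean(0), 3)
        sk = PLSRegression(n_components=3, scale=False, tol=1e-12,
                           max_iter=5000).fit(X, Y)
        np.testing.assert_allclose(Xc @ mine.coefficients,
                                   sk.predict(X) - Y.mean(0), atol=1e-5)

    def test_component_count_bounds(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=(6, 1))
        with pytest.raises(FitError):
            fit_pls(X - X.mean(0), y - y.mean(0), 6)
        with pytest.raises(FitError):
            fit_pls(X - X.mean(0), y - y.mean(0), 0)


class TestPredict:
    def test_training_residuals_consistent_with_r2y(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=(15, 1))
        model = fit_pls_raw(X, y, 2)
        resid = y - model.predict(X)
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert 1 - resid.ravel() @ resid.ravel() / ss_tot == \
            pytest.approx(model.r2y_cum, abs=1e-9)

    def test_center_only_shift_linearity(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=(10, 1))
        Xs, spec = scale_columns(X, "center_only")
        model = fit_pls(Xs, y - y.mean(), 2, x_scaling=spec,
                        y_means=np.array([y.mean()]))
        shift = np.full(5, 0.7)
        base = model.predict(X[[0]])
        shifted = model.predict(X[[0]] + shift)
        expected_delta = (shift @ model.coefficients)[None, :]
        np.testing.assert_allclose(shifted - base, expected_delta, atol=1e-9)

    def test_two_class_threshold_calls(self, rng):
        X = rng.normal(size=(10, 4))
        labels = ["a"] * 5 + ["b"] * 5
        Y, classes = dummy_code(labels)
        model = fit_pls_raw(X, Y, 1, class_labels=classes)
        # force predictions through the threshold semantics
        model.coefficients[:] = 0
        model.y_means[:] = 0.2
        assert model.classify(X) == ["a"] * 10
        model.y_means[:] = 0.8
        assert model.classify(X) == ["b"] * 10


class TestQ2y:
    def test_perfect_linear_signal_gives_one(self, rng):
        # with a full set of components PLS reaches the least-squares fit,
        # so noise-free linear responses cross-validate perfectly
        X = rng.normal(size=(21, 5))
        y = X[:, [2]] * 3.0
        assert q2y(X, y, 5, scaling="center_only") == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_negative_in_expectation(self):
        # simulation oracle: mean Q2Y over repetitions below zero
        rng = np.random.default_rng(123)
        vals = []
        for _ in range(200):
            X = rng.normal(size=(30, 8))
            y = rng.normal(size=(30, 1))
            vals.append(q2y(X, y, 2))
        assert np.mean(vals) < 0

    def test_q2y_not_above_r2y_on_stochastic_fixtures(self, rng):
        for _ in range(5):
            X = rng.normal(size=(24, 10))
            y = (X[:, [0]] + rng.normal(scale=1.0, size=(24, 1)))
            model = fit_pls_raw(X, y, 2)
            assert q2y(X, y, 2) <= model.r2y_cum + 1e-9

    def test_venetian_blinds_partition(self):
        folds = venetian_blinds_folds(10, 3)
        assert sorted(np.concatenate(folds).tolist()) == list(range(10))
        assert folds[0].tolist() == [0, 3, 6, 9]

    def test_fold_count_validated(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=(6, 1))
        with pytest.raises(ValueError):
            q2y(X, y, 1, n_folds=7)


class TestErrors:
    def test_rmsee_hand_formula(self, rng):
        # residuals (0.1, -0.1, 0.1, -0.1) with A=1: sqrt(0.04/2)
        X = rng.normal(size=(4, 3))
        y = rng.normal(size=(4, 1))
        model = fit_pls_raw(X, y, 1)
        resid = np.array([0.1, -0.1, 0.1, -0.1])[:, None]
        y_fake = model.predict(X) + resid
        assert rmsee(model, X, y_fake) == pytest.approx(np.sqrt(0.04 / 2), abs=1e-9)

    def test_rmsep_zero_for_perfect_prediction(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=(8, 1))
        model = fit_pls_raw(X, y, 1)
        assert rmsep(model, X, model.predict(X)) == 0.0

    def test_rmsep_invariant_to_row_order(self, rng):
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=(8, 1))
        model = fit_pls_raw(X, y, 2)
        Xt = rng.normal(size=(6, 4))
        yt = rng.normal(size=(6, 1))
        perm = rng.permutation(6)
        assert rmsep(model, Xt, yt) == pytest.approx(
            rmsep(model, Xt[perm], yt[perm]), abs=1e-12)

    def test_rmsee_needs_degrees_of_freedom(self, rng):
        X = rng.normal(size=(3, 4))
        y = rng.normal(size=(3, 1))
        model = fit_pls_raw(X, y, 2)
        with pytest.raises(FitError):
            rmsee(model, X, y)


class TestMonthsConversion:
    @pytest.mark.parametrize("rmse_val, months", [
        (0.044, 0.528),   # published tap-root age model
        (0.036, 0.432),   # published rhizome age model
        (0.096, 1.152),   # published lateral-root age model
        (0.077, 0.924),   # published tap-root RMSEE
        (0.0, 0.0),
    ])
    def test_class_units_to_months(self, rmse_val, months):
        assert rmse_to_months(rmse_val) == pytest.approx(months, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rmse_to_months(-0.1)


class TestVip:
    def test_uniform_weights_give_unit_vip(self):
        # A=1 with equal-magnitude weights: every VIP is exactly 1
        n, p = 10, 6
        rng = np.random.default_rng(5)
        t = rng.normal(size=n)
        X = np.outer(t, np.ones(p))
        y = t[:, None]
        model = fit_pls(X, y, 1)
        vip = vip_scores(model)
        np.testing.assert_allclose(vip.vip, 1.0, atol=1e-9)

    def test_mean_squared_vip_is_one(self, rng):
        X = rng.normal(size=(12, 9))
        Y = rng.normal(size=(12, 2))
        model = fit_pls(X - X.mean(0), Y - Y.mean(0), 3)
        vip = vip_scores(model)
        assert (vip.vip ** 2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_formula(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 1))
        model = fit_pls(X - X.mean(0), Y - Y.mean(0), 2)
        vip = vip_scores(model).vip
        W, ssy = model.weights, model.ssy_per_component
        p = W.shape[1 - 1]
        expected = np.sqrt(
            p * sum(ssy[a] * (W[:, a] / np.linalg.norm(W[:, a])) ** 2
                    for a in range(2)) / ssy.sum())
        np.testing.assert_allclose(vip, expected, atol=1e-9)

    def test_selection_boundary_semantics(self, rng):
        vip = np.array([0.5, 1.0, 1.5])
        assert select_by_vip(vip, 0.0).retained_count == 3
        assert select_by_vip(vip, 2.0).retained_count == 0
        # strict inequality: exactly-1.0 scores fall at cutoff 1.0
        assert select_by_vip(vip, 1.0).retained_count == 1


class TestPca:
    def test_rank_one_matrix_first_component_explains_all(self, rng):
        t = rng.normal(size=8)
        X = np.outer(t, rng.normal(size=5))
        scores, loadings, frac = pca(X, 2)
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(10, 6))
        scores, _, _ = pca(X, 4)
        G = scores.T @ scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off <= 1e-8 * np.diag(G).max()

    def test_agrees_with_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(6, 4))
        _, loadings, frac = pca(X, 3)
        C = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(frac, evals[:3] / evals.sum(), atol=1e-9)
        for a in range(3):
            v = evecs[:, a] * np.sign(evecs[np.argmax(np.abs(evecs[:, a])), a])
            np.testing.assert_allclose(np.abs(loadings[:, a] @ v), 1.0, atol=1e-9)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(rng.normal(size=(5, 3)), 5)


class TestSerialization:
    def test_model_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=(12, 1))
        model = fit_pls_raw(X, y, 2, variable_ids=np.arange(5) + 1000.0,
                            class_labels=["5yr", "6yr"])
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        Xnew = rng.normal(size=(3, 5))
        np.testing.assert_allclose(back.predict(Xnew), model.predict(Xnew),
                                   atol=1e-12)
        assert back.class_labels == model.class_labels
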