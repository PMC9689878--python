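import numpy as np
import pytest

from spectrace.pls import (
    PLSDAModel,
    compute_metrics,
    cross_validate,
    fit_plsda,
    one_hot,
    permutation_test,
    predict,
    select_lv_by_q2,
    vip_scores,
)


def _nipals_oracle(X, Y, n_components, tol=1e-14, max_iter=5000):
    """Textbook power-iteration NIPALS, written independently."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    Ws, Ts = [], []
    for _ in range(n_components):
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))]
        for _ in range(max_iter):
            w = X.T @ u
            w = w / np.linalg.norm(w)
            t = X @ w
            c = Y.T @ t / (t @ t)
            u_new = Y @ c / (c @ c)
            if np.linalg.norm(u_new - u) < tol * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        w = X.T @ u
        w = w / np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / (t @ t)
        c = Y.T @ t / (t @ t)
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, c)
        Ws.append(w)
        Ts.append(t)
    return np.column_stack(Ws), np.column_stack(Ts)


def _labelled_clusters(seed=0, n_per=10, p=4, k=2, sep=6.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n_per * k, p))
    for c in range(k):
        X[c * n_per : (c + 1) * n_per, 0] += sep * c
    labels = np.repeat([f"c{c}" for c in range(k)], n_per)
    return X, labels


class TestFitPredict:
    def test_two_separated_clusters_classified_perfectly(self):
        X, labels = _labelled_clusters(seed=1)
        model = fit_plsda(X, labels, 1)
        pred, _ = predict(model, X)
        assert (pred == labels).all()

    def test_full_rank_fit_interpolates_y(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 7))
        labels = np.array(["a", "a", "b", "b", "c", "c", "d", "d"])
        model = fit_plsda(X, labels, 7)
        Y, _ = one_hot(labels)
        _, yhat = predict(model, X)
        assert np.abs(Y - yhat).max() < 1e-8

    def test_weights_and_scores_match_power_iteration_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        model = fit_plsda(X, labels, 3)
        Y, _ = one_hot(labels)
        W_ref, T_ref = _nipals_oracle(X, Y, 3)
        for a in range(3):
            sign = np.sign(W_ref[:, a] @ model.W[:, a])
            np.testing.assert_allclose(model.W[:, a], sign * W_ref[:, a], atol=1e-9)
            np.testing.assert_allclose(model.T[:, a], sign * T_ref[:, a], atol=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(4).normal(size=(6, 3))
        with pytest.raises(ValueError):
            fit_plsda(X, np.array(["a"] * 6), 1)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            fit_plsda(np.ones((6, 3)), np.array(["a", "b"] * 3), 1)

    def test_dimension_mismatch_rejected(self):
        X, labels = _labelled_clusters(seed=5)
        model = fit_plsda(X, labels, 1)
        with pytest.raises(ValueError):
            predict(model, X[:, :2])

    def test_tie_breaks_to_lowest_class_index(self):
        # crafted model whose prediction is exactly the centered-Y mean
        model = PLSDAModel(
            classes=np.array(["a", "b"]),
            x_mean=np.zeros(3),
            y_mean=np.array([0.5, 0.5]),
            W=np.array([[1.0], [0.0], [0.0]]),
            T=np.zeros((4, 1)),
            P=np.array([[1.0], [0.0], [0.0]]),
            C=np.zeros((2, 1)),
        )
        pred, yhat = predict(model, np.zeros((1, 3)))
        np.testing.assert_allclose(yhat, [[0.5, 0.5]])
        assert pred[0] == "a"

    def test_coefficient_prediction_equals_sequential_projection(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        labels = np.array(["a", "b", "c"] * 4)
        model = fit_plsda(X, labels, 3)
        Xc = X - model.x_mean
        # sequential: extract scores by walking the deflated weights
        yhat_seq = np.tile(model.y_mean, (12, 1))
        Xres = Xc.copy()
        for a in range(3):
            t = Xres @ model.W[:, a]
            yhat_seq += np.outer(t, model.C[:, a])
            Xres -= np.outer(t, model.P[:, a])
        _, yhat = predict(model, X)
        np.testing.assert_allclose(yhat, yhat_seq, atol=1e-10)

    def test_deflation_exact_at_full_rank(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(9, 4))
        labels = np.array(["a", "b", "c"] * 3)
        model = fit_plsda(X, labels, 4)
        Xc = X - model.x_mean
        residual = Xc - model.T @ model.P.T
        assert np.linalg.norm(residual) < 1e-8 * np.linalg.norm(Xc)


class TestCrossValidate:
    def test_loo_press_matches_explicit_refit_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        labels = np.array(["a", "b"] * 5)
        cv = cross_validate(X, labels, 2, k_folds=10, seed=0)
        Y, classes = one_hot(labels)
        press = 0.0
        for i in range(10):
            mask = np.ones(10, dtype=bool)
            mask[i] = False
            sub = fit_plsda(X[mask], labels[mask], 2)
            _, yhat = predict(sub, X[i : i + 1])
            press += float(np.sum((Y[i] - yhat[0]) ** 2))
        assert cv.press == pytest.approx(press, rel=1e-10)

    def test_pure_noise_labels_give_nonpositive_q2_in_expectation(self):
        q2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 6))
            labels = rng.permutation(np.array(["a", "b"] * 12))
            q2s.append(cross_validate(X, labels, 2, seed=seed).q2)
        assert np.mean(q2s) <= 0.0

    def test_perfect_linear_structure_recovers_q2_near_one(self):
        rng = np.random.default_rng(9)
        labels = np.repeat(["a", "b", "c"], 10)
        Y, _ = one_hot(labels)
        X = np.column_stack([Y, rng.normal(0, 0.01, (30, 3))])
        cv = cross_validate(X, labels, 3, seed=0)
        assert cv.q2 > 0.99

    def test_rmsecv_consistent_with_press(self):
        X, labels = _labelled_clusters(seed=10, n_per=8)
        cv = cross_validate(X, labels, 2, seed=1)
        assert cv.rmsecv == pytest.approx(np.sqrt(cv.press / (16 * 2)), rel=1e-12)


class TestSelectLV:
    def test_first_global_maximum_is_chosen(self, monkeypatch):
        import spectrace.pls as plsmod

        curve = iter([0.1, 0.3, 0.25])

        def fake_cv(X, labels, A, k_folds=7, seed=0):
            return plsmod.CVResult(q2=next(curve), rmsecv=0.0, press=0.0, n_samples=0, n_classes=0)

        monkeypatch.setattr(plsmod, "cross_validate", fake_cv)
        chosen, _ = plsmod.select_lv_by_q2(None, None, 3)
        assert chosen == 2

    def test_decreasing_curve_selects_one(self, monkeypatch):
        import spectrace.pls as plsmod

        curve = iter([0.5, 0.4, 0.3])
        monkeypatch.setattr(
            plsmod,
            "cross_validate",
            lambda *a, **k: plsmod.CVResult(next(curve), 0.0, 0.0, 0, 0),
        )
        chosen, _ = plsmod.select_lv_by_q2(None, None, 3)
        assert chosen == 1

    def test_recovers_latent_dimension_on_low_rank_data(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p, r = 36, 12, 3
            T = rng.normal(size=(n, r))
            P = rng.normal(size=(r, p))
            labels = np.array([f"c{v}" for v in (T[:, 0] > 0).astype(int) + 2 * (T[:, 1] > 0)])
            X = T @ P + rng.normal(0, 0.05, (n, p))
            chosen, _ = select_lv_by_q2(X, labels, 8, seed=seed)
            hits += chosen in (2, 3, 4)
        assert hits >= 18


class TestVIP:
    def test_mean_square_is_one(self):
        X, labels = _labelled_clusters(seed=11, p=6)
        model = fit_plsda(X, labels, 3)
        vip = vip_scores(model)
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_single_component_closed_form(self):
        X, labels = _labelled_clusters(seed=12, p=5)
        model = fit_plsda(X, labels, 1)
        vip = vip_scores(model)
        np.testing.assert_allclose(vip, np.sqrt(5) * np.abs(model.W[:, 0]), atol=1e-10)

    def test_matches_from_scratch_formula_oracle(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(14, 8))
        labels = np.array(["a", "b"] * 7)
        model = fit_plsda(X, labels, 3)
        ssy = np.array(
            [
                np.sum(model.T[:, a] ** 2) * np.sum(model.C[:, a] ** 2)
                for a in range(3)
            ]
        )
        expected = np.sqrt(
            8
            * sum(
                ssy[a] * (model.W[:, a] / np.linalg.norm(model.W[:, a])) ** 2
                for a in range(3)
            )
            / ssy.sum()
        )
        np.testing.assert_allclose(vip_scores(model), expected, atol=1e-9)


class TestMetrics:
    def test_perfect_training_fit_metrics(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(8, 7))
        labels = np.array(["a", "a", "b", "b", "c", "c", "d", "d"])
        model = fit_plsda(X, labels, 7)
        m = compute_metrics(model, X, labels, X, labels, None)
        assert m.rmsee == pytest.approx(0.0, abs=1e-8)
        assert m.r2 == pytest.approx(1.0, abs=1e-8)
        assert m.train_accuracy == 100.0
        assert m.rmsep == pytest.approx(m.rmsee, abs=1e-8)

    def test_empty_test_set_rejected(self):
        X, labels = _labelled_clusters(seed=15)
        model = fit_plsda(X, labels, 1)
        with pytest.raises(ValueError):
            compute_metrics(model, X, labels, X[:0], labels[:0], None)

    def test_q2_never_exceeds_r2_across_small_suite(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(21, 8))
            labels = np.array(["a", "b", "c"] * 7)
            X[labels == "b", 0] += 1.5
            X[labels == "c", 1] += 1.5
            for A in (1, 3):
                model = fit_plsda(X, labels, A)
                cv = cross_validate(X, labels, A, seed=seed)
                m = compute_metrics(model, X, labels, X, labels, cv)
                assert m.q2 <= m.r2 + 1e-10


class TestPermutation:
    def test_exactly_200_permuted_fits_recorded(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(16, 3))
        labels = np.array(["a", "b"] * 8)
        X[labels == "b"] += 2.0
        verdict = permutation_test(X, labels, 1, n_permutations=200, seed=0)
        assert verdict.n_permutations == 200
        assert len(verdict.r2) == 201  # 200 permutations + the original model
        assert np.isfinite(verdict.r2_intercept) and np.isfinite(verdict.q2_intercept)

    def test_informative_data_gives_negative_q2_intercept(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, k = 60, 3
            y = rng.integers(0, k, n)
            X = rng.normal(size=(n, 30))
            for c in range(k):
                X[y == c, c * 3 : (c + 1) * 3] += 2.0
            labels = np.array([f"c{v}" for v in y])
            verdict = permutation_test(X, labels, 3, n_permutations=30, seed=seed)
            hits += verdict.q2_intercept < 0
        assert hits >= 18

    def test_too_few_permutations_rejected(self):
        X, labels = _labelled_clusters(seed=17)
        with pytest.raises(ValueError):
            permutation_test(X, labels, 1, n_permutations=5)


class TestAgainstSklearn:
    def test_predictions_match_sklearn_pls_regression(self):
        """Dual-route check: our NIPALS vs scikit-learn's PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(18)
        X = rng.normal(size=(20, 6))
        labels = np.array(["a", "b", "c", "d"] * 5)
        Y, _ = one_hot(labels)
        model = fit_plsda(X, labels, 3)
        _, ours = predict(model, X)
        ref = (
            PLSRegression(n_components=3, scale=False, tol=1e-12, max_iter=5000)
            .fit(X, Y)
            .predict(X)
        )
        np.testing.assert_allclose(ours, ref, atol=1e-6)
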