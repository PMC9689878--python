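import numpy as np
import pytest

from spectrace.varsel import (
    ChainExhaustedError,
    EmptySelectionError,
    SelectionResult,
    cars,
    compare_selections,
    edf_ratio,
    select_vip,
    spa,
    spa_chain,
)


class TestSelectVIP:
    def test_threshold_is_strict(self):
        res = select_vip(np.array([0.5, 1.0, 1.2]))
        np.testing.assert_array_equal(res.indices, [2])

    def test_zero_threshold_selects_all_positive(self):
        res = select_vip(np.array([0.2, 0.9, 1.4]), threshold=0.0)
        np.testing.assert_array_equal(res.indices, [0, 1, 2])

    def test_empty_selection_raises(self):
        with pytest.raises(EmptySelectionError):
            select_vip(np.array([0.1, 0.2]))

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            select_vip(np.array([1.5, np.nan]))


class TestSPAChain:
    def test_orthogonal_columns_picked_by_decreasing_norm(self):
        X = np.diag([1.0, 4.0, 2.0, 3.0])
        chain = spa_chain(X, 0, 4)
        np.testing.assert_array_equal(chain, [0, 1, 3, 2])

    def test_duplicated_column_never_follows_its_twin(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 5))
        X[:, 3] = X[:, 1]
        chain = spa_chain(X, 1, 4)
        assert 3 not in chain

    def test_matches_qr_pivot_oracle(self):
        """The chain equals greedy Gram-Schmidt with explicit residuals."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 6))
        start = 2
        chain = spa_chain(X, start, 5)
        # oracle: orthonormalize chosen set via QR, pick max residual norm
        chosen = [start]
        for _ in range(4):
            Q, _ = np.linalg.qr(X[:, chosen])
            residual = X - Q @ (Q.T @ X)
            norms = np.linalg.norm(residual, axis=0)
            norms[chosen] = -1.0
            chosen.append(int(np.argmax(norms)))
        np.testing.assert_array_equal(chain, chosen)

    def test_projected_norms_nonincreasing_along_chain(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 7))
        chain = spa_chain(X, 0, 6)
        # residual norm of each picked column at its pick time
        norms = []
        Q = np.zeros((10, 0))
        for idx in chain:
            r = X[:, idx] - Q @ (Q.T @ X[:, idx])
            norms.append(np.linalg.norm(r))
            Q = np.linalg.qr(np.column_stack([Q, r]))[0]
        assert all(norms[i] >= norms[i + 1] - 1e-10 for i in range(1, len(norms) - 1))
        # full column rank of the selected set
        assert np.linalg.matrix_rank(X[:, chain]) == len(chain)

    def test_rank_exhaustion_raises(self):
        X = np.ones((4, 3)) * np.array([1.0, 2.0, 3.0])  # rank 1
        with pytest.raises(ChainExhaustedError):
            spa_chain(X, 0, 3)


class TestSPA:
    @staticmethod
    def _planted(seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 15
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, p))
        X[:, 7] = y * 2.0 - 1.0
        return X, np.array([f"c{v}" for v in y])

    def test_planted_predictive_variable_recovered(self):
        hits = 0
        for seed in range(20):
            X, labels = self._planted(seed)
            res = spa(X, labels, max_vars=4, n_components=2, seed=seed)
            hits += 7 in set(res.indices.tolist())
        assert hits >= 18

    def test_max_vars_one_equals_exhaustive_single_variable_scan(self):
        X, labels = self._planted(3)
        res = spa(X, labels, max_vars=1, n_components=1, seed=0)
        # oracle: evaluate every single variable with the same split/model
        from spectrace.pls import fit_plsda, one_hot, predict
        from spectrace.sampling import kennard_stone

        n = X.shape[0]
        cal = kennard_stone(X, int(np.floor(n * 0.7 + 0.5)))
        val = np.setdiff1d(np.arange(n), cal)
        best = (np.inf, None)
        for j in range(X.shape[1]):
            model = fit_plsda(X[cal][:, [j]], labels[cal], 1)
            Y, _ = one_hot(labels[val], classes=model.classes)
            _, yhat = predict(model, X[val][:, [j]])
            rmse = float(np.sqrt(np.mean((Y - yhat) ** 2)))
            if rmse < best[0]:
                best = (rmse, j)
        assert res.indices.tolist() == [best[1]]
        assert res.score == pytest.approx(best[0], rel=1e-10)

    def test_reported_score_is_curve_minimum(self):
        X, labels = self._planted(4)
        res = spa(X, labels, max_vars=5, n_components=2, seed=1)
        assert res.score == pytest.approx(min(res.curve["rmse"]), rel=1e-12)


class TestEDF:
    def test_first_run_ratio_is_one(self):
        assert edf_ratio(1, 50, 1557) == pytest.approx(1.0)

    def test_last_run_ratio_is_two_over_p(self):
        assert edf_ratio(50, 50, 50) == pytest.approx(0.04)

    def test_geometric_midpoint_closed_form(self):
        # log-linear decay: halfway in run index = geometric mean of endpoints
        N, p = 51, 50
        mid = edf_ratio(26, N, p)
        assert mid == pytest.approx(np.sqrt(1.0 * 2.0 / p), rel=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            edf_ratio(1, 1, 50)
        with pytest.raises(ValueError):
            edf_ratio(0, 10, 50)
        with pytest.raises(ValueError):
            edf_ratio(2, 10, 1)


class TestCARS:
    @staticmethod
    def _planted(seed):
        rng = np.random.default_rng(100 + seed)
        n, p = 60, 50
        y = rng.integers(0, 3, n)
        X = rng.normal(size=(n, p))
        informative = [5, 20, 41]
        for k, col in enumerate(informative):
            X[:, col] = (y == k).astype(float) * 2.0 + rng.normal(0, 0.3, n)
        return X, np.array([f"c{v}" for v in y]), informative

    def test_planted_variables_recovered(self):
        hits = 0
        for seed in range(20):
            X, labels, informative = self._planted(seed)
            res = cars(X, labels, n_runs=30, n_components=3, seed=seed)
            hits += set(informative) <= set(res.indices.tolist())
        assert hits >= 16

    def test_first_run_retains_all_variables(self):
        X, labels, _ = self._planted(0)
        res = cars(X, labels, n_runs=20, n_components=3, seed=0)
        assert res.curve["n_retained"][0] == X.shape[1]

    def test_retained_counts_follow_edf_and_never_increase(self):
        X, labels, _ = self._planted(1)
        res = cars(X, labels, n_runs=20, n_components=3, seed=1)
        counts = res.curve["n_retained"]
        assert all(counts[i] >= counts[i + 1] for i in range(len(counts) - 1))
        p = X.shape[1]
        for i, c in enumerate(counts, start=1):
            assert c <= max(2, int(np.ceil(edf_ratio(i, 20, p) * p)))

    def test_returned_score_is_minimum_of_recorded_runs(self):
        X, labels, _ = self._planted(2)
        res = cars(X, labels, n_runs=15, n_components=3, seed=2)
        assert res.score == pytest.approx(min(res.curve["rmsecv"]), rel=1e-12)


class TestCompareSelections:
    @staticmethod
    def _mk(method, idx, p=10):
        return SelectionResult(
            method=method, indices=np.asarray(idx), curve={}, grid_points=p
        )

    def test_identical_sets(self):
        out = compare_selections([self._mk("vip", [1, 2]), self._mk("spa", [1, 2])])
        assert out["n_common"] == out["n_union"] == 2

    def test_disjoint_sets(self):
        out = compare_selections([self._mk("vip", [1, 2]), self._mk("spa", [3, 4])])
        assert out["pairwise"]["vip&spa"] == 0
        assert out["n_common"] == 0

    def test_three_way_common(self):
        out = compare_selections(
            [self._mk("vip", [1, 2, 3]), self._mk("spa", [2, 3, 4]), self._mk("cars", [3, 5])]
        )
        assert out["common_to_all"] == [3]
        assert out["n_common"] == 1

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            compare_selections([self._mk("vip", [1], p=10), self._mk("spa", [1], p=20)])
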