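import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qsar3d as q
from qsar3d.pls import nipals_fit, preprocess, select_components


class TestPreprocess:
    def test_constant_column_dropped(self):
        X = np.column_stack([np.ones(6), np.arange(6.0) * 5])
        y = np.arange(6.0)
        Xs, yc, state = preprocess(X, y, min_variation=2.0)
        assert state.mask.tolist() == [False, True]

    def test_high_variation_column_retained(self):
        rng = np.random.default_rng(0)
        X = rng.normal(scale=5.0, size=(10, 3))
        _, _, state = preprocess(X, rng.normal(size=10), min_variation=2.0)
        assert state.mask.all()

    def test_block_scaling_equalises_field_variance(self):
        rng = np.random.default_rng(1)
        X = np.hstack([rng.normal(scale=10.0, size=(12, 4)),
                       rng.normal(scale=0.5, size=(12, 4))])
        slices = {"big": slice(0, 4), "small": slice(4, 8)}
        Xs, _, state = preprocess(X, rng.normal(size=12), 0.0, slices)
        var_big = Xs[:, :4].var(axis=0, ddof=1).sum()
        var_small = Xs[:, 4:].var(axis=0, ddof=1).sum()
        assert var_big == pytest.approx(var_small, rel=1e-10)
        assert var_big == pytest.approx(1.0, rel=1e-10)

    def test_all_filtered_is_error(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="filtered out"):
            preprocess(X, np.arange(5.0), min_variation=2.0)


class TestNipals:
    def test_univariate_slope_matches_least_squares(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 1))
        y = 2.5 * x[:, 0] + rng.normal(scale=0.1, size=15)
        res = nipals_fit(x, y, 1)
        slope, icept = np.polyfit(x[:, 0], y, 1)
        # PLS with one X variable and one component IS simple regression
        assert res.coefficients[0] == pytest.approx(slope, rel=1e-8)
        np.testing.assert_allclose(res.predict(x), slope * x[:, 0] + icept, atol=1e-8)

    def test_exact_linear_recovery(self, small_matrix):
        X, _ = small_matrix
        beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ beta + 4.2
        res = nipals_fit(X, y, 5)
        assert np.abs(res.resid).max() < 1e-8

    def test_scores_mutually_orthogonal(self, small_matrix):
        X, y = small_matrix
        res = nipals_fit(X, y, 4)
        T = res.scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_duplicated_column_same_predictions(self, small_matrix):
        # at full rank the column space (and hence the projection) is unchanged
        X, y = small_matrix
        res1 = nipals_fit(X, y, 5)
        Xdup = np.hstack([X, X[:, [0]]])
        res2 = nipals_fit(Xdup, y, 5)
        np.testing.assert_allclose(
            res2.predict(Xdup), res1.predict(X), atol=1e-8
        )

    def test_full_rank_equals_least_squares(self, small_matrix):
        """At n_components = rank(X), PLS collapses to the OLS solution."""
        X, y = small_matrix
        res = nipals_fit(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.pinv(Xc) @ (y - y.mean())
        pred_ols = Xc @ beta + y.mean()
        np.testing.assert_allclose(res.predict(X), pred_ols, atol=1e-8)

    def test_matches_sklearn_reference(self, small_matrix):
        """Cross-check against an independent PLS implementation."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = small_matrix
        for c in (1, 2, 3):
            ours = nipals_fit(X, y, c)
            ref = sklearn_pls.PLSRegression(n_components=c, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_zero_components_predicts_mean(self, small_matrix):
        X, y = small_matrix
        res = nipals_fit(X, y, 0)
        np.testing.assert_allclose(res.predict(X), np.full(len(y), y.mean()), atol=1e-12)

    def test_row_of_column_means_predicts_mean(self, small_matrix):
        X, y = small_matrix
        res = nipals_fit(X, y, 3)
        assert res.predict(X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-10)

    def test_column_order_invariance(self, small_matrix):
        X, y = small_matrix
        perm = [3, 1, 4, 0, 2]
        res1 = nipals_fit(X, y, 3)
        res2 = nipals_fit(X[:, perm], y, 3)
        np.testing.assert_allclose(res2.predict(X[:, perm]), res1.predict(X), atol=1e-10)

    def test_too_many_components_rejected(self, small_matrix):
        X, y = small_matrix
        with pytest.raises(ValueError, match="exceeds"):
            nipals_fit(X, y, 8)

    def test_column_count_mismatch_on_predict(self, small_matrix):
        X, y = small_matrix
        res = nipals_fit(X, y, 2)
        with pytest.raises(ValueError, match="column count"):
            res.predict(np.zeros((2, 7)))


class TestCrossValidation:
    def test_loo_matches_bruteforce_oracle(self, small_matrix):
        """LOO q^2 equals an independent refit-per-row reference (sklearn)."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = small_matrix
        cv = q.cross_validate(y, X, max_components=3, scheme="loo", min_variation=0.0)
        n = len(y)
        for c in (1, 2, 3):
            press = 0.0
            for i in range(n):
                keep = np.delete(np.arange(n), i)
                Xt, yt = X[keep], y[keep]
                # same preprocessing convention: centred, one uniform block scale
                scale = 1.0 / np.sqrt(Xt.var(axis=0, ddof=1).sum())
                ref = sklearn_pls.PLSRegression(n_components=c, scale=False).fit(
                    Xt * scale, yt
                )
                press += float(y[i] - ref.predict(X[[i]] * scale).ravel()[0]) ** 2
            q2_ref = 1 - press / ((y - y.mean()) ** 2).sum()
            assert cv.q2_by_components[c - 1] == pytest.approx(q2_ref, abs=1e-10)

    def test_noiseless_one_factor_data(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=6))
        y = 3.0 + 2.0 * t
        cv = q.cross_validate(y, X, max_components=2, min_variation=0.0)
        assert cv.q2_by_components[0] >= 0.99

    def test_permuted_response_has_no_predictivity(self, small_matrix):
        X, y = small_matrix
        rng = np.random.default_rng(5)
        q2s = [
            q.cross_validate(rng.permutation(y), X, max_components=2,
                             min_variation=0.0).q2_by_components[0]
            for _ in range(20)
        ]
        assert np.mean(q2s) <= 0.2

    def test_group_cv_seeded_and_deterministic(self, small_matrix):
        X, y = small_matrix
        a = q.cross_validate(y, X, 2, scheme="groups", n_groups=4, seed=9,
                             min_variation=0.0)
        b = q.cross_validate(y, X, 2, scheme="groups", n_groups=4, seed=9,
                             min_variation=0.0)
        assert a.q2_by_components == b.q2_by_components

    def test_too_many_groups_rejected(self, small_matrix):
        X, y = small_matrix
        with pytest.raises(ValueError, match="group count"):
            q.cross_validate(y, X, 2, scheme="groups", n_groups=50)

    def test_q2_not_above_r2(self, noisy_series):
        _, _, activities, _, block = noisy_series
        model = q.FieldPLS(activities, block, min_variation=0.0)
        cv = model.cross_validate(5)
        res = model.fit(cv.chosen_components)
        assert cv.q2 <= res.rsquared + 1e-12


class TestComponentSelection:
    @pytest.mark.parametrize(
        "q2s,expected",
        [
            ([0.50, 0.60, 0.62], 2),   # +20% adopt, +3.3% stop
            ([0.70], 1),
            ([0.8, 0.7, 0.6], 1),      # monotonically decreasing
            ([0.3, 0.5, 0.7, 0.72], 3),
        ],
    )
    def test_ten_percent_rule(self, q2s, expected):
        assert select_components(q2s) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_components([])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=8))
    def test_selection_within_range_and_no_worse_than_one(self, q2s):
        c = select_components(q2s)
        assert 1 <= c <= len(q2s)
        assert q2s[c - 1] >= q2s[0]


class TestFitStatistics:
    def test_perfect_fit(self):
        X = np.random.default_rng(6).normal(size=(10, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        res = nipals_fit(X, y, 3)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)
        assert res.see == pytest.approx(0.0, abs=1e-8)

    def test_reference_table_comfa_statistics(self, reference_records):
        """Published training pairs reproduce the printed r2/SEE/F triple."""
        train = [r for r in reference_records if r.role == "train"]
        y = np.array([r.exp_pec50 for r in train])
        p = np.array([r.comfa_pred for r in train])
        r2, see, f = q.regression_stats(y, p, 5)
        assert r2 == pytest.approx(0.973, abs=0.002)
        assert see == pytest.approx(0.106, abs=0.001)
        assert f == pytest.approx(250.674, rel=0.01)

    def test_single_field_contribution_is_total(self, small_matrix):
        X, y = small_matrix
        res = nipals_fit(X, y, 2, field_slices={"only": slice(0, 5)})
        assert res.field_contributions == {"only": pytest.approx(100.0)}

    def test_contributions_sum_to_100(self, noisy_series):
        _, _, activities, _, block = noisy_series
        res = q.FieldPLS(activities, block, min_variation=0.0).fit(3)
        assert sum(res.field_contributions.values()) == pytest.approx(100.0, abs=0.01)

    def test_dof_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            q.regression_stats(np.arange(4.0), np.arange(4.0), 5)

    def test_summary_renders(self, small_matrix):
        X, y = small_matrix
        text = nipals_fit(X, y, 2).summary()
        assert "PLS regression results" in text
        assert "SEE" in text
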