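"""Statistical-core oracles: PCA vs independent eigensolver, textbook
t-test, bootstrap calibration, Fisher LDA closed forms, LOOCV fold
enumeration, AUC pair-counting, diagnostic metrics and OLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from breathdisc.stats import (bootstrap_validate, compute_metrics,
                              compute_roc, confounder_regression, fit_lda,
                              fit_pca, loocv, mann_whitney_auc,
                              project_pca, select_components)


def brute_force_auc(scores, labels):
    """O(n^2) pairwise concordance with ties counted 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    pos = s[y == classes[1]]
    neg = s[y == classes[0]]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestPCA:
    def test_two_perfectly_correlated_features(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2.0 * x + 1.0])
        m = fit_pca(X)
        np.testing.assert_allclose(m.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert m.retained == 1

    def test_matches_independent_svd_oracle(self, rng):
        X = rng.standard_normal((20, 5))
        m = fit_pca(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        _, sv, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = sv ** 2 / (len(X) - 1)
        V = Vt.T
        for j in range(5):  # same deterministic sign convention
            k = np.argmax(np.abs(V[:, j]))
            if V[k, j] < 0:
                V[:, j] = -V[:, j]
        np.testing.assert_allclose(m.eigenvalues, eig, atol=1e-8)
        np.testing.assert_allclose(m.loadings, V, atol=1e-8)

    def test_matches_sklearn_pca(self, rng):
        from sklearn.decomposition import PCA

        X = rng.standard_normal((40, 6)) * [1, 2, 3, 1, 2, 3] + 5
        m = fit_pca(X)
        Z = (X - m.mean_) / m.scale_
        sk = PCA().fit(Z)
        np.testing.assert_allclose(m.eigenvalues, sk.explained_variance_,
                                   atol=1e-8)
        np.testing.assert_allclose(np.abs(m.loadings),
                                   np.abs(sk.components_.T), atol=1e-8)

    def test_reconstruction_and_variance_partition(self, rng):
        X = rng.standard_normal((30, 7))
        m = fit_pca(X)
        Z = (X - m.mean_) / m.scale_
        scores_all = Z @ m.loadings
        np.testing.assert_allclose(scores_all @ m.loadings.T, Z, atol=1e-8)
        assert m.explained_variance_ratio.sum() == pytest.approx(1.0)
        assert np.all(np.diff(m.eigenvalues) <= 1e-12)

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = rng.standard_normal((25, 4))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_pca(X)
        assert m.dropped_features == (2,)
        assert m.mean_.size == 3

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.standard_normal((1, 5)))
        X = rng.standard_normal((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_pca(X)


class TestProjection:
    def test_training_scores_centered(self, rng):
        X = rng.standard_normal((40, 5))
        m = fit_pca(X)
        S = project_pca(m, X)
        np.testing.assert_allclose(S.mean(axis=0), 0.0, atol=1e-10)

    def test_mean_subject_maps_to_origin(self, rng):
        X = rng.standard_normal((40, 5))
        m = fit_pca(X)
        np.testing.assert_allclose(project_pca(m, m.mean_[None, :]), 0.0,
                                   atol=1e-12)

    def test_heldout_projection_is_frozen_matrix_product(self, rng):
        X = rng.standard_normal((40, 5))
        m = fit_pca(X)
        H = rng.standard_normal((7, 5)) + 3
        expected = ((H - m.mean_) / m.scale_) @ m.loadings[:, :m.retained]
        np.testing.assert_allclose(project_pca(m, H), expected, atol=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        m = fit_pca(rng.standard_normal((20, 5)))
        with pytest.raises(ValueError, match="dimension"):
            project_pca(m, rng.standard_normal((3, 4)))


class TestTTestSelection:
    def test_identical_groups_null(self):
        x = np.linspace(-1, 1, 10)
        scores = np.concatenate([x, x])[:, None]
        labels = np.repeat([0, 1], 10)
        (res,) = select_components(scores, labels)
        assert res.t == 0.0
        assert res.p == 1.0
        assert not res.selected

    def test_extreme_separation_selected(self, rng):
        scores = np.concatenate([rng.standard_normal(50),
                                 rng.standard_normal(50) + 10.0])[:, None]
        (res,) = select_components(scores, np.repeat([0, 1], 100 // 2))
        assert res.selected and res.p < 1e-6

    def test_matches_textbook_formula_and_scipy(self, rng):
        x0 = np.array([4.2, 5.1, 3.9, 4.8, 5.5])
        x1 = np.array([6.0, 5.7, 6.4, 5.9])
        scores = np.concatenate([x0, x1])[:, None]
        labels = np.array([0] * 5 + [1] * 4)
        (res,) = select_components(scores, labels)
        sp2 = (4 * x0.var(ddof=1) + 3 * x1.var(ddof=1)) / 7
        t_hand = (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 4))
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        t_sp, p_sp = sps.ttest_ind(x0, x1, equal_var=True)
        assert abs(res.t) == pytest.approx(abs(t_sp), abs=1e-12)
        assert res.p == pytest.approx(p_sp, abs=1e-12)

    def test_zero_variance_group_uses_welch(self):
        scores = np.concatenate([np.full(5, 2.0),
                                 [2.5, 3.0, 2.8, 3.2]])[:, None]
        (res,) = select_components(scores, np.array([0] * 5 + [1] * 4))
        assert "welch_fallback" in res.flags
        assert np.isfinite(res.p)


class TestBootstrap:
    def test_saturated_effect_full_support(self, rng):
        scores = np.concatenate([rng.standard_normal(50),
                                 rng.standard_normal(50) + 10.0])[:, None]
        labels = np.repeat([0, 1], 50)
        sup = bootstrap_validate(scores, labels, n_boot=200, seed=0)
        assert sup[0] == 1.0

    def test_deterministic_under_seed(self, rng):
        scores = rng.standard_normal((60, 3))
        labels = np.repeat([0, 1], 30)
        a = bootstrap_validate(scores, labels, n_boot=300, seed=7)
        b = bootstrap_validate(scores, labels, n_boot=300, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_support_near_alpha_when_groups_match(self):
        """For data whose observed t is exactly 0, the bootstrap
        rejection fraction approximates the test level alpha."""
        rng = np.random.default_rng(5)
        band = 3 * np.sqrt(0.05 * 0.95 / 1000)
        for k in range(5):
            x0 = rng.standard_normal(150)
            x1 = rng.standard_normal(150)
            x1 = x1 - x1.mean() + x0.mean()
            sup = bootstrap_validate(np.concatenate([x0, x1]),
                                     np.repeat([0, 1], 150),
                                     n_boot=1000, seed=k)[0]
            assert abs(sup - 0.05) < band + 0.01

    def test_support_monotone_in_effect_size(self):
        rng = np.random.default_rng(9)
        base0 = rng.standard_normal(100)
        base1 = rng.standard_normal(100)
        sups = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            scores = np.concatenate([base0, base1 + delta])[:, None]
            sups.append(bootstrap_validate(scores, np.repeat([0, 1], 100),
                                           n_boot=500, seed=1)[0])
        assert all(b >= a - 1e-12 for a, b in zip(sups, sups[1:]))
        assert sups[-1] == 1.0


class TestLDA:
    def test_symmetric_1d_closed_form(self, rng):
        x0 = rng.normal(0.0, 0.5, 200)
        x0 = x0 - x0.mean() - 1.0   # mean exactly -1
        x1 = -x0                    # mirror: mean exactly +1, same spread
        scores = np.concatenate([x0, x1])
        labels = np.repeat([0, 1], 200)
        m = fit_lda(scores, labels)
        assert m.weights[0] > 0
        assert m.threshold == pytest.approx(0.0, abs=1e-10)
        assert m.predict(np.array([[1.0]]))[0] == 1
        assert m.predict(np.array([[-1.0]]))[0] == 0

    def test_spherical_weights_parallel_to_mean_difference(self, rng):
        mu0, mu1 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        X = np.vstack([rng.standard_normal((300, 2)) + mu0,
                       rng.standard_normal((300, 2)) + mu1])
        y = np.repeat([0, 1], 300)
        m = fit_lda(X, y)
        d = m.class_means[1] - m.class_means[0]
        cos = m.weights @ d / np.linalg.norm(m.weights) / np.linalg.norm(d)
        assert cos > 0.99

    def test_predictions_match_sklearn_equal_priors(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.standard_normal((40, 3)),
                       rng.standard_normal((40, 3)) + [1.0, 0.5, -0.7]])
        y = np.repeat([0, 1], 40)
        mine = fit_lda(X, y)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        H = rng.standard_normal((200, 3)) + 0.5
        np.testing.assert_array_equal(mine.predict(H), sk.predict(H))

    def test_singular_covariance_gets_ridge(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([x, x])  # rank-1 pooled covariance
        y = np.repeat([0, 1], 10)
        m = fit_lda(X, y)
        assert m.ridge > 0
        assert np.all(np.isfinite(m.weights))


class TestLOOCV:
    def test_separable_classes_perfect(self, rng):
        scores = np.concatenate([rng.normal(-5, 0.1, 20),
                                 rng.normal(5, 0.1, 20)])
        acc, heldout, preds = loocv(scores, np.repeat([0, 1], 20))
        assert acc == 100.0
        assert np.array_equal(preds, np.repeat([0, 1], 20))

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal((200, 2))
        labels = rng.permutation(np.repeat([0, 1], 100))
        acc, _, _ = loocv(scores, labels)
        assert 39.4 <= acc <= 60.6  # 50% +/- 3 binomial SDs

    def test_six_subject_manual_fold_enumeration(self):
        scores = np.array([[0.1], [0.4], [0.9], [1.6], [2.2], [2.6]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        acc, heldout, preds = loocv(scores, labels)
        exp_scores = np.empty(6)
        exp_preds = np.empty(6, dtype=int)
        for i in range(6):
            m = np.arange(6) != i
            fold = fit_lda(scores[m], labels[m])
            exp_scores[i] = fold.decision(scores[i:i + 1])[0]
            exp_preds[i] = 1 if exp_scores[i] > 0 else 0
        np.testing.assert_allclose(heldout, exp_scores, atol=1e-12)
        np.testing.assert_array_equal(preds, exp_preds)
        assert acc == 100.0 * np.mean(exp_preds == labels)

    def test_requires_three_per_class(self):
        with pytest.raises(ValueError, match="n >= 3"):
            loocv(np.arange(4.0), np.array([0, 0, 1, 1]))


class TestROC:
    def test_perfect_ranking(self):
        r = compute_roc(np.array([2.0, 3.0, 0.0, 1.0]),
                        np.array([1, 1, 0, 0]))
        assert r.auc == 1.0

    def test_all_ties_is_half(self):
        r = compute_roc(np.full(20, 1.5), np.repeat([0, 1], 10))
        assert r.auc == 0.5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.lists(hst.integers(min_value=0, max_value=8),
                     min_size=4, max_size=60))
    def test_auc_equals_pair_counting(self, values):
        scores = np.array(values, float)
        labels = np.array([0, 1] * (len(values) // 2)
                          + [0] * (len(values) % 2))
        assert mann_whitney_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)
        r = compute_roc(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels),
                                      abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            compute_roc(np.arange(5.0), np.zeros(5))

    def test_ci_contains_auc_and_is_ordered(self, rng):
        scores = np.concatenate([rng.standard_normal(40),
                                 rng.standard_normal(40) + 1.0])
        labels = np.repeat([0, 1], 40)
        r = compute_roc(scores, labels)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        rb = compute_roc(scores, labels, ci_method="bootstrap", n_boot=200,
                         seed=4)
        rb2 = compute_roc(scores, labels, ci_method="bootstrap", n_boot=200,
                          seed=4)
        assert rb.ci95 == rb2.ci95
        assert rb.ci95[0] <= rb.auc <= rb.ci95[1]

    def test_lda_score_auc_approaches_gaussian_optimum(self):
        """AUC of the discriminant score converges to Phi(delta/sqrt(2))
        for Mahalanobis distance delta between equal-covariance groups."""
        rng = np.random.default_rng(12)
        for delta in (1.0, 2.0):
            X = np.vstack([rng.standard_normal((3000, 2)),
                           rng.standard_normal((3000, 2)) + [delta, 0.0]])
            y = np.repeat([0, 1], 3000)
            m = fit_lda(X, y)
            auc = mann_whitney_auc(m.decision(X), y)
            assert auc == pytest.approx(sps.norm.cdf(delta / np.sqrt(2)),
                                        abs=0.02)


class TestMetrics:
    def test_reported_sens_spec_give_printed_lrs(self):
        # 86% sensitivity / 89% specificity as confusion counts
        y = np.repeat([1, 0], 100)
        p = np.concatenate([np.repeat([1, 0], [86, 14]),
                            np.repeat([1, 0], [11, 89])])
        m = compute_metrics(p, y, positive=1)
        assert m.sensitivity_pct == pytest.approx(86.0)
        assert m.specificity_pct == pytest.approx(89.0)
        assert m.lr_pos == pytest.approx(0.86 / 0.11, abs=1e-12)
        assert m.lr_neg == pytest.approx(0.14 / 0.89, abs=1e-12)
        pub = m.to_public_dict()
        assert pub["lr_pos"] == 7.82 and pub["lr_neg"] == 0.16

    def test_thirty_three_of_thirty_seven(self):
        y = np.repeat([1, 0], [37, 63])
        p = np.concatenate([np.repeat([1, 0], [33, 4]), np.zeros(63, int)])
        m = compute_metrics(p, y, positive=1)
        assert m.sensitivity_pct == pytest.approx(100 * 33 / 37)
        assert m.to_public_dict()["sensitivity_pct"] == 89

    def test_perfect_classifier_edge_cases(self):
        y = np.repeat([0, 1], 10)
        m = compute_metrics(y, y, positive=1)
        assert m.sensitivity_pct == 100.0 and m.specificity_pct == 100.0
        assert m.lr_neg == 0.0 and np.isinf(m.lr_pos)

    def test_invariants_hold(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        m = compute_metrics(p, y, positive=1)
        assert m.tp + m.fp + m.tn + m.fn == 50
        assert m.accuracy_pct == pytest.approx(100 * (m.tp + m.tn) / 50)
        sens, spec = m.sensitivity_pct / 100, m.specificity_pct / 100
        if 0 < spec < 1:
            assert m.lr_pos == pytest.approx(sens / (1 - spec))
            assert m.lr_neg == pytest.approx((1 - sens) / spec)


class TestConfounderRegression:
    def _covariates(self, rng, n):
        import pandas as pd

        return pd.DataFrame({
            "age": rng.normal(64, 9, n),
            "sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(26, 5, n),
            "smoking_status": rng.choice(["never", "former", "current"], n),
            "pack_years": rng.lognormal(3.5, 0.4, n),
            "fev1_pct_pred": rng.normal(65, 19, n),
        })

    def test_exact_linear_dependence_recovered(self, rng):
        cov = self._covariates(rng, 120)
        scores = (2.0 * cov["age"].to_numpy())[:, None]
        res = confounder_regression(scores, cov)
        age = res.table.query("term == 'age' and component == 1")
        assert age["estimate"].iloc[0] == pytest.approx(2.0, abs=1e-8)
        assert res.r_squared[1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        cov = self._covariates(rng, 60)[["age", "bmi", "pack_years",
                                         "fev1_pct_pred", "sex",
                                         "smoking_status"]]
        scores = rng.standard_normal((60, 2))
        res = confounder_regression(scores, cov)
        import pandas as pd

        X = pd.get_dummies(cov, drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        beta = np.linalg.lstsq(X.to_numpy(), scores[:, 0], rcond=None)[0]
        got = res.table.query("component == 1")["estimate"].to_numpy()
        np.testing.assert_allclose(np.sort(got), np.sort(beta), atol=1e-8)

    def test_null_covariates_uniform_pvalues(self):
        rng = np.random.default_rng(21)
        cov = self._covariates(rng, 400)
        scores = rng.standard_normal((400, 8))
        res = confounder_regression(scores, cov)
        slopes = res.table.query("term != 'const'")
        frac = (slopes["p_value"] < 0.05).mean()
        n = len(slopes)
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n) + 0.02

    def test_missing_rows_dropped_and_counted(self, rng):
        cov = self._covariates(rng, 50)
        cov.loc[3, "age"] = np.nan
        res = confounder_regression(rng.standard_normal((50, 1)), cov)
        assert res.n_dropped_rows == 1
        assert res.n_used == 49

    def test_aliased_column_dropped(self, rng):
        cov = self._covariates(rng, 80)
        cov["bmi"] = 2.0 * cov["age"] + 1.0
        res = confounder_regression(rng.standard_normal((80, 1)), cov)
        assert "bmi" in res.aliased_terms
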