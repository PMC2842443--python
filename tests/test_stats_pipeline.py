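"""GLM, permutation omnibus, PCA/LDA classification, canonical scores."""

import numpy as np
import pytest
from scipy import stats as sps

from tractsurf.stats_pipeline import (
    DesignMatrix, bonferroni_threshold, canonical_scores, classification_metrics,
    classify_maps, lda_loocv, pca_reduce, pearson_corr, permutation_omnibus,
    pooled_t_test, select_pcs, vertexwise_glm,
)


@pytest.fixture
def labels():
    return np.array([0] * 10 + [1] * 8)


class TestDesignMatrix:
    def test_layout_intercept_diagnosis_covariates(self, labels):
        cov = np.arange(18, dtype=float)[:, None]
        d = DesignMatrix(labels, covariates=cov)
        X = d.matrix()
        assert X.shape == (18, 3)
        np.testing.assert_array_equal(X[:, 0], 1.0)
        np.testing.assert_array_equal(X[:, 1], labels)
        np.testing.assert_array_equal(X[:, 2], cov.ravel())

    def test_rank_deficient_raises(self, labels):
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(labels, covariates=labels.astype(float)[:, None])


class TestVertexwiseGlm:
    def test_matches_pooled_t_without_covariates(self, labels):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(18, 6))
        Y[labels == 1] += 0.8
        res = vertexwise_glm(Y, DesignMatrix(labels))
        for j in range(6):
            t_ref, p_ref = sps.ttest_ind(Y[labels == 1, j], Y[labels == 0, j],
                                         equal_var=True)
            assert res.t[j] == pytest.approx(t_ref, rel=1e-10)
            assert res.p[j] == pytest.approx(p_ref, rel=1e-10)
        assert res.df == 16

    def test_hand_computed_ols_oracle(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        cov = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])[:, None]
        Y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0])[:, None]
        res = vertexwise_glm(Y, DesignMatrix(y, covariates=cov))
        X = np.column_stack([np.ones(6), y, cov.ravel()])
        beta = np.linalg.lstsq(X, Y.ravel(), rcond=None)[0]
        assert res.coef[0] == pytest.approx(beta[1], abs=1e-10)

    def test_equal_group_means_give_zero_t(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        base = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.concatenate([base, base])[:, None]   # identical group samples
        res = vertexwise_glm(Y, DesignMatrix(labels))
        assert res.t[0] == pytest.approx(0.0, abs=1e-10)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="3 more subjects"):
            vertexwise_glm(np.zeros((4, 2)), DesignMatrix(np.array([0, 0, 1, 1])))


class TestPermutationOmnibus:
    def test_zero_observed_count_gives_p_one(self, labels):
        Y = np.random.default_rng(3).normal(size=(18, 4))
        res = permutation_omnibus(Y, DesignMatrix(labels), alpha=1e-12, n_perm=100)
        assert res.observed_count == 0
        assert res.overall_p == 1.0

    def test_strong_effect_gives_small_p(self, labels):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(18, 20))
        Y[labels == 1] += 3.0
        res = permutation_omnibus(Y, DesignMatrix(labels), n_perm=500, seed=7)
        assert res.observed_count == 20
        assert res.overall_p < 0.01

    def test_seed_reproducibility(self, labels):
        Y = np.random.default_rng(5).normal(size=(18, 10))
        a = permutation_omnibus(Y, DesignMatrix(labels), n_perm=200, seed=11)
        b = permutation_omnibus(Y, DesignMatrix(labels), n_perm=200, seed=11)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)
        assert a.overall_p == b.overall_p

    def test_add_one_estimator_never_zero(self, labels):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(18, 20))
        Y[labels == 1] += 5.0
        res = permutation_omnibus(Y, DesignMatrix(labels), n_perm=200, seed=0,
                                  add_one=True)
        assert res.overall_p >= 1.0 / 201

    def test_small_n_perm_warns(self, labels):
        Y = np.random.default_rng(7).normal(size=(18, 5))
        with pytest.warns(UserWarning, match="coarse"):
            permutation_omnibus(Y, DesignMatrix(labels), n_perm=50)


class TestPca:
    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 30))
        pca = pca_reduce(X)
        np.testing.assert_allclose(pca.scores @ pca.components, X - pca.mean,
                                   atol=1e-10)

    def test_at_most_n_minus_one_components(self):
        X = np.random.default_rng(9).normal(size=(7, 50))
        assert pca_reduce(X).scores.shape[1] <= 6

    def test_components_orthonormal(self):
        X = np.random.default_rng(10).normal(size=(10, 25))
        V = pca_reduce(X).components
        np.testing.assert_allclose(V @ V.T, np.eye(len(V)), atol=1e-10)

    def test_explained_variance_sorted(self):
        ev = pca_reduce(np.random.default_rng(11).normal(size=(15, 40))).explained_variance
        assert np.all(np.diff(ev) <= 1e-12)


class TestSelection:
    def test_pooled_t_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        t, p = pooled_t_test(x, y)
        sp2 = (np.sum((x - 2) ** 2) + np.sum((y - 5) ** 2)) / 5
        t_hand = (2 - 5) / np.sqrt(sp2 * (1 / 3 + 1 / 4))
        assert t == pytest.approx(t_hand, rel=1e-12)

    def test_planted_component_selected(self, labels):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(18, 5))
        scores[labels == 1, 2] += 4.0
        sel, pv = select_pcs(scores, labels)
        assert 2 in sel
        assert pv[2] < 1e-4

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            select_pcs(np.zeros((4, 2)), np.array([1, 1, 1, 1]))


class TestClassificationMetrics:
    def test_hand_case(self):
        # 12 controls (9 called control), 8 AD (6 called AD)
        m = classification_metrics((9, 3, 6, 2))
        assert m["accuracy_pct"] == 75.0
        assert m["sensitivity_pct"] == 75.0
        assert m["specificity_pct"] == 75.0
        prec, rec = 9 / 11, 9 / 12
        assert m["f_score"] == round(2 * prec * rec / (prec + rec), 3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            classification_metrics((1, -1, 1, 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_metrics((0, 0, 0, 0))


class TestLdaLoocv:
    def test_separable_data_perfect(self, labels):
        X = labels[:, None] * 10.0 + np.random.default_rng(13).normal(size=(18, 2))
        res = lda_loocv(X, labels)
        assert res.accuracy_pct == 100.0
        assert (res.tp, res.fn, res.tn, res.fp) == (10, 0, 8, 0)

    def test_subject_order_invariance(self, labels):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(18, 3))
        X[labels == 1] += 1.0
        base = lda_loocv(X, labels)
        perm = rng.permutation(18)
        shuffled = lda_loocv(X[perm], labels[perm])
        assert base.accuracy_pct == shuffled.accuracy_pct
        assert (base.tp, base.fn) == (shuffled.tp, shuffled.fn)

    def test_empty_feature_set_rejected(self, labels):
        with pytest.raises(ValueError, match="empty feature set"):
            lda_loocv(np.zeros((18, 0)), labels)


class TestClassifyMaps:
    def test_paper_mode_on_separable_maps(self, labels):
        rng = np.random.default_rng(15)
        maps = rng.normal(size=(18, 60))
        maps[labels == 1] += 1.5
        res, sel = classify_maps(maps, labels, mode="paper")
        assert res.accuracy_pct >= 80.0
        assert sel.size >= 1

    def test_nested_mode_never_sees_test_subject(self, labels):
        rng = np.random.default_rng(16)
        maps = rng.normal(size=(18, 60))
        maps[labels == 1] += 1.5
        res, _ = classify_maps(maps, labels, mode="nested")
        assert res.accuracy_pct >= 70.0

    def test_unknown_mode_rejected(self, labels):
        with pytest.raises(ValueError, match="paper.*nested"):
            classify_maps(np.random.default_rng(17).normal(size=(18, 5)),
                          labels, mode="loo")


class TestCanonical:
    def test_collinear_with_fisher_discriminant(self, labels):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(18, 4))
        X[labels == 1] += [1.0, -0.5, 0.3, 0.0]
        res = canonical_scores(X, labels)
        # Fisher direction: pooled within-class covariance^-1 @ mean difference
        mu0, mu1 = X[labels == 0].mean(axis=0), X[labels == 1].mean(axis=0)
        Xc = np.vstack([X[labels == 0] - mu0, X[labels == 1] - mu1])
        Sw = Xc.T @ Xc
        fisher = np.linalg.solve(Sw, mu1 - mu0)
        cos = abs(res.weights @ fisher) / (
            np.linalg.norm(res.weights) * np.linalg.norm(fisher))
        assert cos > 0.999

    def test_ad_group_mean_score_higher(self, labels):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(18, 3))
        X[labels == 1] -= 2.0   # effect direction should not matter for the sign fix
        res = canonical_scores(X, labels)
        assert res.scores[labels == 1].mean() > res.scores[labels == 0].mean()

    def test_feature_scaling_leaves_scores_equivalent(self, labels):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(18, 3))
        X[labels == 1] += 1.0
        a = canonical_scores(X, labels).scores
        b = canonical_scores(X * np.array([10.0, 0.1, 3.0]), labels).scores
        r, _ = pearson_corr(a, b)
        assert abs(r) > 0.999

    def test_mmse_correlation_attached(self, labels):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(18, 2))
        X[labels == 1] += 2.0
        mmse = 29.0 - 5.0 * labels + rng.normal(0, 0.5, 18)
        res = canonical_scores(X, labels, mmse=mmse)
        assert res.pearson_r < -0.5
        assert res.p < 0.05


class TestCorrelationAndThresholds:
    def test_pearson_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        r, _ = pearson_corr(x, y)
        r_hand = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
        assert r == pytest.approx(r_hand, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_bonferroni_simple(self):
        assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)

    def test_bonferroni_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 5)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
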