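import numpy as np
import pytest
from scipy import special

from nmrmet.multivariate import (
    CVResult,
    LoadingProfile,
    ModelSpec,
    ResponseMatrix,
    correlation_loadings,
    cv_anova,
    fit_opls,
    fit_pca,
    fit_pls,
    permutation_test,
    q2y_loo,
    score_distances,
    select_discriminant,
)


def match_up_to_sign(A, B, atol):
    for j in range(A.shape[1]):
        assert np.allclose(A[:, j], B[:, j], atol=atol) or np.allclose(
            A[:, j], -B[:, j], atol=atol
        ), f"component {j} differs beyond sign"


def centered(rng, n, p, scale=1.0):
    X = rng.normal(0, scale, (n, p))
    return X - X.mean(axis=0)


class TestPCA:
    def test_matches_svd_oracle_on_toy_matrix(self, rng):
        X = centered(rng, 6, 4)
        model = fit_pca(X, 3)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        match_up_to_sign(model.T_pred, U[:, :3] * s[:3], 1e-8)
        match_up_to_sign(model.P, Vt[:3].T, 1e-8)

    def test_rank_one_matrix_fully_explained(self, rng):
        t = rng.normal(size=8)
        p = rng.normal(size=5)
        X = np.outer(t - t.mean(), p)
        model = fit_pca(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        cos = abs(model.P[:, 0] @ p) / np.linalg.norm(p)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_explained_variance_non_increasing(self, rng):
        model = fit_pca(centered(rng, 10, 7), 5)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_scores_orthogonal(self, rng):
        model = fit_pca(centered(rng, 10, 7), 4)
        G = model.T_pred.T @ model.T_pred
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) < 1e-8 * np.max(np.diag(G)))

    def test_outlier_has_largest_score_distance(self, rng):
        X = centered(rng, 12, 6)
        X[3, 2] += 10 * X[:, 2].std()
        model = fit_pca(X - X.mean(axis=0), 3)
        assert int(np.argmax(score_distances(model))) == 3

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(centered(rng, 5, 3), 5)


class TestPLS:
    def test_exact_linear_response_r2_one(self, rng):
        X = centered(rng, 20, 5)
        beta = rng.normal(size=5)
        y = X @ beta
        model = fit_pls(X, y, 5)
        assert model.R2Y == pytest.approx(1.0, abs=1e-8)

    def test_single_column_matches_least_squares(self, rng):
        x = centered(rng, 15, 1)
        y = 2.5 * x[:, 0] + rng.normal(0, 0.1, 15)
        model = fit_pls(x, y, 1)
        yc = y - y.mean()
        slope = (x[:, 0] @ yc) / (x[:, 0] @ x[:, 0])
        pred = model.predict(x)[:, 0]
        assert np.allclose(pred, x[:, 0] * slope + y.mean(), atol=1e-10)

    def test_planted_two_group_separation_on_first_component(self, rng):
        n = 10
        X = rng.normal(0, 1, (2 * n, 30))
        X[:n, :5] += 4.0
        X = X - X.mean(axis=0)
        y = np.array([-1.0] * n + [1.0] * n)
        model = fit_pls(X, y, 1)
        t = model.T_pred[:, 0] * np.sign(model.C[0, 0])
        assert t[:n].max() < t[n:].min()

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(centered(rng, 8, 4), np.ones(8), 1)

    def test_multiclass_dummy_response(self, rng):
        Y = ResponseMatrix.from_labels(
            [f"s{i}" for i in range(9)], ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        )
        assert Y.Y.shape == (9, 3)
        assert np.all(Y.Y.sum(axis=1) == 1)
        X = centered(rng, 9, 6) + 3 * Y.Y @ rng.normal(size=(3, 6))
        model = fit_pls(X - X.mean(axis=0), Y, 2)
        assert 0 <= model.R2Y <= 1


class TestOPLS:
    def test_zero_orthogonal_equals_pls1_scores(self, rng):
        X = centered(rng, 14, 20)
        y = np.array([-1.0] * 7 + [1.0] * 7)
        opls = fit_opls(X, y, 0)
        pls = fit_pls(X, y, 1)
        t_o = opls.T_pred[:, 0]
        t_p = pls.T_pred[:, 0]
        scale = np.linalg.norm(t_p) / np.linalg.norm(t_o)
        assert np.allclose(t_o * scale, t_p, atol=1e-10) or np.allclose(
            -t_o * scale, t_p, atol=1e-10
        )

    def test_orthogonal_filtering_raises_predictive_correlation(self, rng):
        # X = y-direction + a strong structured direction orthogonal to y
        n, p = 20, 50
        y = np.array([-1.0] * 10 + [1.0] * 10)
        confound = rng.normal(0, 1, n)
        confound -= confound @ y / (y @ y) * y  # orthogonalize against y
        X = np.outer(y, rng.normal(0, 1, p)) + 5 * np.outer(confound, rng.normal(0, 1, p))
        X += rng.normal(0, 0.1, (n, p))
        X = X - X.mean(axis=0)
        pls = fit_pls(X, y, 1)
        opls = fit_opls(X, y, 1)
        corr_pls = abs(np.corrcoef(pls.T_pred[:, 0], y)[0, 1])
        corr_opls = abs(np.corrcoef(opls.T_pred[:, 0], y)[0, 1])
        assert corr_opls > corr_pls

    def test_orthogonal_scores_uncorrelated_with_response(self, rng):
        X = centered(rng, 16, 25)
        y = np.array([-1.0] * 8 + [1.0] * 8)
        model = fit_opls(X, y, 3)
        for k in range(model.n_orthogonal):
            assert abs(np.corrcoef(model.T_orth[:, k], y)[0, 1]) < 1e-8

    def test_orthogonal_scores_orthogonal_to_predictive_image(self, rng):
        X = centered(rng, 16, 25)
        y = np.array([-1.0] * 8 + [1.0] * 8)
        model = fit_opls(X, y, 2)
        # predictive image of the filtered matrix = T_pred
        t_pred = model.T_pred[:, 0]
        for k in range(model.n_orthogonal):
            t_o = model.T_orth[:, k]
            assert abs(t_o @ t_pred) / (np.linalg.norm(t_o) * np.linalg.norm(t_pred)) < 1e-8

    def test_more_than_two_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_opls(centered(rng, 9, 5), np.array([0.0, 1, 2] * 3), 0)

    def test_too_many_orthogonal_components_rejected(self, rng):
        y = np.array([-1.0] * 4 + [1.0] * 4)
        with pytest.raises(ValueError, match="n_orthogonal"):
            fit_opls(centered(rng, 8, 5), y, 6)

    def test_constant_x_gives_mean_only_model(self):
        X = np.zeros((8, 5))
        y = np.array([-1.0] * 4 + [1.0] * 4)
        with pytest.warns(UserWarning, match="mean-only"):
            model = fit_opls(X, y, 0)
        assert model.R2Y == pytest.approx(0.0)
        assert np.allclose(model.predict(X), 0.0)


class TestQ2YLoo:
    def test_noise_free_linear_response_is_predictable(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = X @ rng.normal(size=5)
        cv = q2y_loo(X, y, ModelSpec("pls", 5, 0))
        assert cv.q2y > 0.99

    def test_null_cohorts_mostly_nonpositive(self):
        # dimensions comparable to a real bucket table (variables >> samples)
        neg = 0
        reps = 50
        for i in range(reps):
            r = np.random.default_rng(1000 + i)
            X = r.normal(0, 1, (16, 2000))
            y = np.array([-1.0] * 8 + [1.0] * 8)
            if q2y_loo(X, y, ModelSpec("opls", 1, 1)).q2y <= 0:
                neg += 1
        assert neg >= 0.9 * reps

    def test_q2_not_above_r2_across_designs(self, rng):
        from nmrmet.preprocess import scale as scale_table

        for sep in (0.0, 0.5, 1.0, 3.0):
            X = rng.normal(0, 1, (16, 20))
            X[:8, :4] += sep
            y = np.array([-1.0] * 8 + [1.0] * 8)
            Xc = (X - X.mean(axis=0)) / X.std(axis=0)
            r2 = fit_opls(Xc, y, 1).R2Y
            q2 = q2y_loo(X, y, ModelSpec("opls", 1, 1)).q2y
            assert q2 <= r2 + 1e-10

    def test_invariant_to_sample_ordering(self, rng):
        X = rng.normal(0, 1, (12, 15))
        y = np.array([-1.0] * 6 + [1.0] * 6)
        q_ref = q2y_loo(X, y, ModelSpec("opls", 1, 1)).q2y
        perm = rng.permutation(12)
        q_perm = q2y_loo(X[perm], y[perm], ModelSpec("opls", 1, 1)).q2y
        assert q_perm == pytest.approx(q_ref, abs=1e-10)

    def test_fold_dropping_entire_class_rejected(self, rng):
        X = rng.normal(0, 1, (5, 6))
        y = np.array([-1.0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="entire class"):
            q2y_loo(X, y, ModelSpec("opls", 1, 0))

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            q2y_loo(rng.normal(size=(2, 3)), np.array([-1.0, 1.0]), ModelSpec("opls", 1, 0))


class TestPermutationTest:
    def test_constant_x_never_passes(self):
        X = np.zeros((10, 6))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        with pytest.warns(UserWarning):
            report = permutation_test(X, y, ModelSpec("opls", 1, 0), n_permutations=49, seed=1)
        assert not report.passes
        assert np.all(report.permuted_Q2Y == report.observed_Q2Y)

    def test_strong_planted_cohort_passes(self, rng):
        X = rng.normal(0, 1, (16, 40))
        X[8:, :6] += 3.0
        y = np.array([-1.0] * 8 + [1.0] * 8)
        report = permutation_test(X, y, ModelSpec("opls", 1, 1), n_permutations=199, seed=5)
        assert report.passes
        assert report.observed_Q2Y > report.percentile_99
        assert report.p_value == pytest.approx(1 / 200)

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.normal(0, 1, (12, 10))
        y = np.array([-1.0] * 6 + [1.0] * 6)
        r1 = permutation_test(X, y, ModelSpec("opls", 1, 0), n_permutations=120, seed=3)
        r2 = permutation_test(X, y, ModelSpec("opls", 1, 0), n_permutations=120, seed=3)
        assert np.array_equal(r1.permuted_Q2Y, r2.permuted_Q2Y)
        assert r1.p_value == r2.p_value

    def test_few_permutations_warns(self, rng):
        X = rng.normal(0, 1, (12, 10))
        y = np.array([-1.0] * 6 + [1.0] * 6)
        with pytest.warns(UserWarning, match="percentile"):
            permutation_test(X, y, ModelSpec("opls", 1, 0), n_permutations=50, seed=0)


class TestCVAnova:
    def test_perfect_prediction_tiny_p(self):
        cv = CVResult(q2y=1.0, press=1e-12, ss_total=10.0, n_samples=20,
                      spec=ModelSpec("opls", 1, 1), predictions=np.zeros((20, 1)))
        assert cv_anova(cv) < 1e-6

    def test_matches_f_cdf_oracle(self):
        # hand-built: SS_total = 10, PRESS = 1, n = 20, k = 2 components
        cv = CVResult(q2y=0.9, press=1.0, ss_total=10.0, n_samples=20,
                      spec=ModelSpec("opls", 1, 1), predictions=np.zeros((20, 1)))
        p = cv_anova(cv)
        F = ((10.0 - 1.0) / 2) / (1.0 / 17)
        d1, d2 = 2, 17
        # independent oracle: F survival via the regularized incomplete beta
        expected = special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * F))
        assert p == pytest.approx(expected, rel=1e-10)

    def test_press_above_total_gives_p_one(self):
        cv = CVResult(q2y=-0.2, press=12.0, ss_total=10.0, n_samples=20,
                      spec=ModelSpec("opls", 1, 1), predictions=np.zeros((20, 1)))
        assert cv_anova(cv) == 1.0

    def test_null_mostly_insignificant(self):
        insig = 0
        reps = 40
        for i in range(reps):
            r = np.random.default_rng(2000 + i)
            X = r.normal(0, 1, (12, 20))
            y = np.array([-1.0] * 6 + [1.0] * 6)
            cv = q2y_loo(X, y, ModelSpec("opls", 1, 0))
            if cv_anova(cv) >= 0.05:
                insig += 1
        assert insig >= 0.85 * reps

    def test_zero_residual_flagged(self):
        cv = CVResult(q2y=1.0, press=0.0, ss_total=10.0, n_samples=20,
                      spec=ModelSpec("opls", 1, 0), predictions=np.zeros((20, 1)))
        with pytest.warns(UserWarning, match="lower bound"):
            p = cv_anova(cv)
        assert p > 0


class TestCorrelationLoadings:
    def test_bucket_equal_to_coding_gives_r_one(self):
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        X = np.column_stack([y, -y])
        prof = correlation_loadings(X, y, bucket_centers=[1.0, 2.0])
        assert prof.R[0] == pytest.approx(1.0)
        assert prof.R[1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_oracle(self, rng):
        X = rng.normal(0, 1, (6, 4))
        y = np.array([-1.0, -1, -1, 1, 1, 1])
        prof = correlation_loadings(X, y, bucket_centers=np.arange(4.0))
        for j in range(4):
            x = X[:, j]
            xm, ym = x - x.mean(), y - y.mean()
            r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            cov = (xm * ym).sum() / (len(y) - 1)
            assert prof.R[j] == pytest.approx(r, abs=1e-12)
            assert prof.covariance[j] == pytest.approx(cov, abs=1e-12)

    def test_zero_variance_bucket_flagged(self):
        y = np.array([-1.0, -1, 1, 1])
        X = np.column_stack([np.full(4, 3.0), y])
        prof = correlation_loadings(X, y, bucket_centers=[1.0, 2.0])
        assert prof.zero_variance[0] and not prof.zero_variance[1]
        assert prof.R[0] == 0.0

    def test_r_bounded(self, rng):
        prof = correlation_loadings(
            rng.normal(0, 1, (10, 50)), rng.normal(size=10), bucket_centers=np.arange(50.0)
        )
        assert np.all(np.abs(prof.R) <= 1.0)


class TestSelectDiscriminant:
    def profile(self, R, centers=None):
        R = np.asarray(R, dtype=float)
        centers = np.arange(R.size, dtype=float) if centers is None else np.asarray(centers)
        return LoadingProfile(
            bucket_centers=centers,
            covariance=R.copy(),
            R=R,
            zero_variance=np.zeros(R.size, bool),
        )

    def test_table_like_value_selected(self):
        prof = self.profile([-0.708, 0.1])
        out = select_discriminant(prof, {"succinate": [0], "lactate": [1]})
        assert out == [("succinate", -0.708)]

    def test_threshold_inclusive(self):
        prof = self.profile([0.5])
        assert select_discriminant(prof, {"m": [0]}) == [("m", 0.5)]

    def test_all_below_threshold_empty(self):
        prof = self.profile([0.3, -0.49, 0.1])
        assert select_discriminant(prof, {"a": [0], "b": [1], "c": [2]}) == []

    def test_missing_metabolite_skipped_with_warning(self):
        prof = self.profile([0.9])
        with pytest.warns(UserWarning, match="ghost"):
            out = select_discriminant(prof, {"ghost": [], "real": [0]})
        assert out == [("real", 0.9)]

    def test_tie_broken_toward_lower_ppm(self):
        prof = self.profile([0.6, -0.6], centers=[2.0, 1.0])
        # same |R|: the bucket at 1.0 ppm wins, giving the signed value -0.6
        assert select_discriminant(prof, {"m": [0, 1]}) == [("m", -0.6)]

    def test_sorted_by_absolute_r_descending(self):
        prof = self.profile([0.6, -0.9, 0.7])
        out = select_discriminant(prof, {"a": [0], "b": [1], "c": [2]})
        assert [m for m, _ in out] == ["b", "c", "a"]

    def test_intensity_filter_drops_baseline_buckets(self):
        prof = self.profile([0.9, 0.2], centers=[1.0, 1.001])
        intens = np.array([1.0, 100.0])  # bucket 0 is baseline-level
        out = select_discriminant(prof, {"m": [0, 1]}, intensities=intens)
        assert out == []  # only the strong bucket (R=0.2) is considered
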