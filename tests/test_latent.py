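import numpy as np
import pytest

from csfmet.latent import (
    OPLS,
    PLSDA,
    FitError,
    fit_opls,
    fit_plsda,
    pca_scores,
    q2_cv,
    y_related_profile,
)


def svd_pls_oracle(X, Y, n_components):
    """Independent PLS2 reference: per component the weight is the dominant
    left singular vector of the X-Y cross-covariance, followed by the
    standard rank-one deflation."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    W, T, P = [], [], []
    for _ in range(n_components):
        U, _, _ = np.linalg.svd(X.T @ Y, full_matrices=False)
        w = U[:, 0]
        t = X @ w
        p = X.T @ t / (t @ t)
        c = Y.T @ t / (t @ t)
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, c)
        W.append(w)
        T.append(t)
        P.append(p)
    return np.column_stack(W), np.column_stack(T), np.column_stack(P)


def _align_signs(A, B):
    signs = np.sign((A * B).sum(axis=0))
    return B * signs


class TestPLS:
    def test_matches_svd_oracle_on_small_fixture(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        Y = rng.normal(size=(6, 2))
        res = PLSDA(X, Y).fit(2)
        W, T, P = svd_pls_oracle(X, Y, 2)
        np.testing.assert_allclose(res.weights, _align_signs(res.weights, W),
                                   atol=1e-8)
        np.testing.assert_allclose(res.scores, _align_signs(res.scores, T),
                                   atol=1e-8)
        np.testing.assert_allclose(res.loadings, _align_signs(res.loadings, P),
                                   atol=1e-8)

    def test_pls1_first_weight_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        res = PLSDA(X, y).fit(1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_expected = Xc.T @ yc
        w_expected /= np.linalg.norm(w_expected)
        cos = abs(w_expected @ res.weights[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_separable_classes_separate_on_t1(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-4, 0.3, size=(15, 2)),
                       rng.normal(4, 0.3, size=(15, 2))])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        res = fit_plsda(X, labels, 1)
        t1 = res.scores[:, 0]
        assert max(t1[:15]) < min(t1[15:]) or min(t1[:15]) > max(t1[15:])

    def test_score_orthogonality_property(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = rng.normal(size=(25, 10))
            Y = rng.normal(size=(25, 3))
            res = PLSDA(X, Y).fit(4)
            G = res.scores.T @ res.scores
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_r2y_increases_with_components(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        Y = X @ rng.normal(size=(8, 2)) + 0.5 * rng.normal(size=(30, 2))
        r2 = [PLSDA(X, Y).fit(a).r2y_cum for a in (1, 2, 3)]
        assert r2[0] < r2[1] < r2[2] <= 1.0

    def test_class_prediction_on_training_data(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 0.5, size=(10, 3)),
                       rng.normal(2, 0.5, size=(10, 3))])
        labels = np.array(["neg"] * 10 + ["pos"] * 10)
        res = fit_plsda(X, labels, 1)
        assert (res.predict_classes(X) == labels).all()


class TestOPLS:
    def test_zero_orth_reduces_to_plsda(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            X = rng.normal(size=(20, 7))
            labels = rng.choice(["a", "b", "c"], size=20)
            pls = fit_plsda(X, labels, 2)
            opls = fit_opls(X, labels, 2, 0)
            np.testing.assert_allclose(np.abs(opls.scores), np.abs(pls.scores),
                                       atol=1e-8)

    def test_orthogonal_variation_is_filtered(self):
        """X built as predictive + y-orthogonal structure: the orthogonal
        component absorbs the y-orthogonal part, |corr(T_o, y)| < 1e-8."""
        rng = np.random.default_rng(7)
        n = 40
        y = rng.normal(size=n)
        t_o = rng.normal(size=n)
        t_o -= t_o @ y / (y @ y) * y  # exactly orthogonal to y
        c = rng.normal(size=6)
        p_o = rng.normal(size=6)
        X = np.outer(y, c) + 3 * np.outer(t_o, p_o) + 0.01 * rng.normal(size=(n, 6))
        res = fit_opls(X, y, 1, 1)
        yc = y - y.mean()
        r = res.orth_scores[:, 0] @ yc / (
            np.linalg.norm(res.orth_scores[:, 0]) * np.linalg.norm(yc))
        assert abs(r) < 1e-8

    def test_orth_scores_uncorrelated_with_every_dummy(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 12))
        labels = rng.choice(["a", "b", "c", "d"], size=30)
        res = fit_opls(X, labels, 3, 2)
        Y = res.model.Y
        for k in range(res.n_orth):
            t_o = res.orth_scores[:, k]
            for j in range(Y.shape[1]):
                r = t_o @ Y[:, j] / (np.linalg.norm(t_o) * np.linalg.norm(Y[:, j]))
                assert abs(r) < 1e-8

    def test_predictive_plus_orthogonal_score_plane(self, prepped):
        """The 4-class model yields the T1 (predictive) / T2 axes used for
        score scatter plots."""
        ds, _, X = prepped
        groups = ds.samples.loc[X.index, "group"].to_numpy()
        res = OPLS(X.to_numpy(), groups, feature_names=list(X.columns)).fit(3, 2)
        assert res.scores.shape == (len(X), 3)
        assert res.orth_scores.shape == (len(X), 2)
        assert 0 < res.r2y_cum <= 1

    def test_excessive_orth_rank_raises(self):
        X = np.outer(np.arange(6.0), np.ones(3))  # rank 1
        y = np.arange(6.0)
        with pytest.raises((FitError, ValueError)):
            fit_opls(X, y, 1, 4)


class TestQ2:
    def test_noiseless_linear_system(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 5))
        y = X @ rng.normal(size=5)
        assert q2_cv(X, y, a_pred=3, folds=7, seed=0) >= 0.99

    def test_permuted_response_near_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 10))
        y = X @ rng.normal(size=10) + 0.1 * rng.normal(size=60)
        q2s = []
        for _ in range(20):
            q2s.append(q2_cv(X, rng.permutation(y), 2, folds=5, seed=1))
        assert np.mean(q2s) <= 0.1

    def test_leave_one_out_runs(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 4))
        y = X @ np.ones(4) + rng.normal(size=15)
        q2 = q2_cv(X, y, 1, folds=15, seed=0)
        assert np.isfinite(q2)

    def test_row_order_invariance_with_sample_ids(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(28, 6))
        labels = np.array((["a"] * 14) + (["b"] * 14))
        ids = [f"s{i:02d}" for i in range(28)]
        q_ref = q2_cv(X, labels, 1, folds=4, seed=3, sample_ids=ids)
        perm = rng.permutation(28)
        q_shuf = q2_cv(X[perm], labels[perm], 1, folds=4, seed=3,
                       sample_ids=[ids[i] for i in perm])
        assert q_shuf == pytest.approx(q_ref, abs=1e-10)

    def test_fold_losing_a_class_raises(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 3))
        labels = np.array(["a"] * 9 + ["b"] * 1)
        with pytest.raises(ValueError, match="class"):
            q2_cv(X, labels, 1, folds=5, seed=0)


class TestVIPAndPcorr:
    def test_equal_weights_give_unit_vip(self):
        rng = np.random.default_rng(14)
        t = rng.normal(size=30)
        X = np.outer(t, np.ones(5)) + 1e-9 * rng.normal(size=(30, 5))
        y = t + 0.01 * rng.normal(size=30)
        v = PLSDA(X, y).fit(1).vip()
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-4)

    def test_mean_square_identity(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            X = rng.normal(size=(25, 9))
            labels = rng.choice(["a", "b", "c"], size=25)
            v = fit_plsda(X, labels, 3).vip()
            assert np.mean(v.to_numpy() ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_pcorr_perfect_and_zero(self):
        rng = np.random.default_rng(16)
        t = rng.normal(size=50)
        ortho = rng.normal(size=50)
        ortho -= ortho @ t / (t @ t) * t
        X = np.column_stack([t, ortho, rng.normal(size=50)])
        y = t + 0.01 * rng.normal(size=50)
        res = PLSDA(X, y).fit(1)
        pc = res.pcorr()
        assert pc.iloc[0] == pytest.approx(1.0, abs=1e-3)
        assert abs(pc.iloc[1]) < 0.05

    def test_pcorr_matches_direct_formula(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        res = PLSDA(X, y).fit(1)
        t1 = res.scores[:, 0]
        expected = [np.corrcoef(t1, X[:, j])[0, 1] for j in range(5)]
        np.testing.assert_allclose(res.pcorr().to_numpy(), expected, atol=1e-10)

    def test_pcorr_requires_single_component(self):
        rng = np.random.default_rng(18)
        res = PLSDA(rng.normal(size=(12, 4)), rng.normal(size=(12, 2))).fit(2)
        with pytest.raises(ValueError, match="1 predictive"):
            res.pcorr()


class TestYRelatedProfile:
    def test_designed_edss_couplers_recovered(self, prepped):
        """The monoacylglycerols carry the two largest positive weights and
        the designed negative couplers get negative weights."""
        ds, _, X = prepped
        edss = ds.samples.loc[X.index, "edss"].to_numpy()
        prof = y_related_profile(X.to_numpy(), edss,
                                 feature_names=list(X.columns))
        top2 = prof["weight"].sort_values(ascending=False).index[:2]
        assert set(top2) == {"1-monostearin", "1-monopalmitin"}
        for met in ("ethanolamine", "threose", "1,5-anhydroglucitol"):
            assert prof.loc[met, "weight"] < 0

    def test_noise_edss_below_permutation_null(self, prepped):
        ds, _, X = prepped
        rng = np.random.default_rng(19)
        fake = rng.normal(3, 1.5, size=len(X)).clip(0)
        prof = y_related_profile(X.to_numpy(), fake,
                                 feature_names=list(X.columns))
        null_max = []
        for _ in range(30):
            p = y_related_profile(X.to_numpy(), rng.permutation(fake),
                                  feature_names=list(X.columns))
            null_max.append(np.abs(p["weight"]).max())
        assert np.abs(prof["weight"]).max() <= np.quantile(null_max, 0.95) * 1.5

    def test_all_missing_edss_rejected(self):
        rng = np.random.default_rng(20)
        with pytest.raises(ValueError, match="missing"):
            y_related_profile(rng.normal(size=(10, 3)), np.full(10, np.nan))


class TestPCA:
    def test_line_explains_all_variance(self):
        t = np.linspace(-1, 1, 12)
        X = np.outer(t, [1.0, 2.0, -1.0])
        scores, ratio = pca_scores(X, 2)
        assert ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigh_oracle_up_to_sign(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 6))
        scores, _ = pca_scores(X, 3)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        expected = Xc @ Vt[:3].T
        np.testing.assert_allclose(np.abs(scores), np.abs(expected), atol=1e-8)

    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(8, 4))
        X[3] = X[5]
        scores, _ = pca_scores(X, 2)
        np.testing.assert_allclose(scores[3], scores[5], atol=1e-12)
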