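"""Chemometric core: NIPALS oracles, diagnostics, CV, acceptance rules."""

import numpy as np
import pytest
from scipy import stats

from metabosig.pls import (
    ModelQuality, classify_status, cross_validate, cv_anova, evaluate_model,
    fit_oplsda, fit_pls, jackknife_ci, optimize_by_exclusion, pca_screen,
    pcorr, top_discriminants, vip,
)
from metabosig.preprocess import FeatureTable

from conftest import make_class_table, make_regression_table


def _table_from(X, y, y_kind="continuous"):
    return FeatureTable(
        X=np.asarray(X, float), features=[f"f{i}" for i in range(X.shape[1])],
        y=np.asarray(y), level="V1", sample_ids=[f"s{i}" for i in range(X.shape[0])],
        response_name="y", y_kind=y_kind,
    )


class TestPcaScreen:
    def test_dominant_direction(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(50)
        load = rng.standard_normal(8)
        X = np.outer(t, load) + 0.05 * rng.standard_normal((50, 8))
        res = pca_screen(_table_from(X, np.zeros(50)), n_comp=2)
        assert res.explained_variance_ratio[0] > 0.9

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 6))
        res = pca_screen(_table_from(X, np.zeros(30)), n_comp=4)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(4), atol=1e-9
        )

    def test_outlier_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 5))
        X[7, 0] += 10.0
        res = pca_screen(_table_from(X, np.zeros(40)), n_comp=2)
        # oracle: direct Hotelling T2 from the eigendecomposition
        assert res.outliers[7]
        assert res.t2[7] == res.t2.max()

    def test_constant_table_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            pca_screen(_table_from(np.ones((10, 3)), np.zeros(10)), 1)


class TestFitPls:
    def test_single_component_weight_matches_xty(self):
        # closed-form oracle: w1 proportional to X'y
        for seed in range(5):
            tab = make_regression_table(seed, n=10, p=6, noise=0.3)
            fit = fit_pls(tab, 1)
            yc = tab.y - tab.y.mean()
            w_oracle = tab.X.T @ yc
            w_oracle /= np.linalg.norm(w_oracle)
            cos = abs(fit.W[:, 0] @ w_oracle)
            assert cos > 1 - 1e-9

    def test_noiseless_linear_y_fully_explained(self):
        tab = make_regression_table(3, n=40, p=5, noise=0.0)
        fit = fit_pls(tab, 4)
        assert fit.r2y_cum >= 0.999
        assert fit.converged

    def test_score_orthogonality(self):
        tab = make_regression_table(4, n=30, p=8, noise=0.5)
        fit = fit_pls(tab, 3)
        G = fit.T.T @ fit.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_zero_variance_y_errors(self):
        tab = _table_from(np.random.default_rng(0).standard_normal((10, 3)),
                          np.ones(10))
        with pytest.raises(ValueError):
            fit_pls(tab, 1)


class TestOplsda:
    def test_equals_plsda_without_orthogonal_structure(self):
        # X built purely from the class direction + tiny noise
        rng = np.random.default_rng(5)
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        ynum = np.array([0.0] * 20 + [1.0] * 20)
        X = np.outer(ynum - 0.5, rng.standard_normal(6))
        X += 0.01 * rng.standard_normal(X.shape)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        tab = _table_from(X, y, "class")
        f_pls = fit_pls(tab, 1)
        f_opls = fit_oplsda(tab, 1)
        r = np.corrcoef(f_pls.T[:, 0], f_opls.T[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_orthogonal_variation_captured_in_orthogonal_block(self):
        # oracle construction: X = y c' + g p_o' + noise with g ⟂ y
        rng = np.random.default_rng(6)
        n, p = 60, 10
        ynum = np.array([0.0] * 30 + [1.0] * 30)
        yc = ynum - ynum.mean()
        g = rng.standard_normal(n)
        g -= g @ yc / (yc @ yc) * yc          # exactly class-orthogonal
        c_dir = np.zeros(p); c_dir[:3] = [1, 1, 1]
        o_dir = np.zeros(p); o_dir[5:] = rng.standard_normal(5)
        X_clean = np.outer(yc, c_dir) + 0.05 * rng.standard_normal((n, p))
        X_orth = X_clean + 3.0 * np.outer(g, o_dir)
        scale = lambda M: (M - M.mean(0)) / M.std(0, ddof=1)
        y = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        fit_clean = fit_oplsda(_table_from(scale(X_clean), y, "class"), 1)
        fit_orth = fit_oplsda(_table_from(scale(X_orth), y, "class"), 1)
        # orthogonal score recovers the injected structured direction
        r = abs(np.corrcoef(fit_orth.T_o[:, 0], g)[0, 1])
        assert r > 0.9
        assert abs(fit_orth.r2y_cum - fit_clean.r2y_cum) < 0.02

    def test_predictive_and_orthogonal_scores_uncorrelated(self):
        tab = make_class_table(7, n_per=25, n_noise=15, n_informative=3)
        fit = fit_oplsda(tab, 2)
        for a in range(2):
            assert abs(np.corrcoef(fit.T[:, 0], fit.T_o[:, a])[0, 1]) < 1e-8

    def test_excessive_n_orth_errors(self):
        tab = make_class_table(8, n_per=5, n_noise=4)
        with pytest.raises(ValueError):
            fit_oplsda(tab, 40)


class TestVipPcorr:
    def test_vip_mean_square_is_one(self):
        for seed in range(10):
            tab = make_regression_table(seed, n=25, p=12, noise=0.4)
            fit = fit_pls(tab, 2)
            assert np.mean(fit.vip ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_informative_feature_has_max_vip(self):
        # brute-force oracle on a small matrix: recompute the VIP formula
        tab = make_regression_table(9, n=10, p=5, noise=0.05,
                                    coefs=[2.0, 0, 0, 0, 0])
        fit = fit_pls(tab, 2)
        assert int(np.argmax(fit.vip)) == 0
        ssy = np.array([(fit.T[:, a] @ fit.T[:, a]) * fit.C[a] ** 2
                        for a in range(2)])
        wn = fit.W / np.linalg.norm(fit.W, axis=0)
        expected = np.sqrt(5 * (wn ** 2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip(fit), expected, atol=1e-9)

    def test_duplicated_columns_equal_vip(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 4))
        X = np.hstack([X, X[:, [0]]])
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        fit = fit_pls(_table_from(X, y), 2)
        assert fit.vip[0] == pytest.approx(fit.vip[4], abs=1e-9)

    def test_pcorr_extremes_and_null(self):
        rng = np.random.default_rng(11)
        tab = make_regression_table(11, n=200, p=6, noise=0.2)
        fit = fit_pls(tab, 1)
        t1 = fit.T[:, 0]
        X = np.column_stack([t1, -t1, rng.standard_normal(200)])
        r = pcorr(fit, _table_from(X, tab.y))
        assert r[0] == pytest.approx(1.0, abs=1e-9)
        assert r[1] == pytest.approx(-1.0, abs=1e-9)
        assert abs(r[2]) < 0.25


class TestCrossValidation:
    def test_noiseless_q2_near_one(self):
        tab = make_regression_table(12, n=70, p=5, noise=0.0)
        cv = cross_validate(tab, 3, folds=7, fold_seed=0)
        assert cv.q2_cum > 0.99

    def test_mean_prediction_gives_zero_q2(self):
        # PRESS computed against the mean-only model equals SS by definition
        tab = make_regression_table(13, n=35, p=4, noise=0.5)
        cv = cross_validate(tab, 1, folds=7)
        assert cv.ss0 > 0
        zero_q2 = 1.0 - cv.ss0 / cv.ss0
        assert zero_q2 == 0.0

    def test_permuted_labels_give_low_q2(self):
        tab = make_class_table(14, n_per=30, n_noise=20, n_informative=3)
        rng = np.random.default_rng(14)
        q2s = []
        for _ in range(20):
            perm = rng.permutation(tab.n_samples)
            shuffled = FeatureTable(
                X=tab.X, features=tab.features, y=tab.y[perm], level="V1",
                sample_ids=tab.sample_ids, response_name="perm", y_kind="class",
            )
            q2s.append(cross_validate(shuffled, 1, folds=7, fold_seed=1).q2_cum)
        assert np.median(q2s) <= 0.05

    def test_each_sample_predicted_once(self):
        tab = make_regression_table(15, n=29, p=4)
        cv = cross_validate(tab, 1, folds=7)
        assert len(np.unique(cv.fold_ids)) == 7
        assert np.bincount(cv.fold_ids).sum() == 29

    def test_q2_not_above_r2y(self):
        for seed in range(5):
            tab = make_regression_table(20 + seed, n=40, p=10, noise=0.8)
            fit = fit_pls(tab, 2)
            cv = cross_validate(tab, 2, folds=7, fold_seed=seed)
            assert cv.q2_cum <= fit.r2y_cum + 1e-9

    def test_multiplicative_rule_close_to_additive(self):
        tab = make_regression_table(16, n=50, p=6, noise=0.3)
        add = cross_validate(tab, 2, folds=7, q2_rule="additive")
        mul = cross_validate(tab, 2, folds=7, q2_rule="multiplicative")
        assert abs(add.q2_cum - mul.q2_cum) < 0.15


class TestCvAnova:
    def test_press_equal_ss0_gives_f_zero_p_one(self):
        cv = cross_validate(make_regression_table(17, n=30, p=4), 1, folds=5)
        cv.press = cv.ss0
        F, p = cv_anova(cv)
        assert F == 0.0 and p == 1.0

    def test_strong_signal_highly_significant(self):
        tab = make_regression_table(18, n=60, p=6, noise=0.05)
        cv = cross_validate(tab, 2, folds=7)
        assert cv.q2_cum > 0.9
        F, p = cv_anova(cv)
        # oracle: direct F-tail computation
        df0, df = 59, 57
        F_direct = ((cv.ss0 - cv.press) / 2) / (cv.press / df)
        assert F == pytest.approx(F_direct)
        assert p == pytest.approx(stats.f.sf(F_direct, 2, df))
        assert p < 1e-6

    def test_p_monotone_in_signal_strength(self):
        ps = []
        for noise in (2.0, 0.5, 0.1):
            tab = make_regression_table(19, n=50, p=5, noise=noise)
            ps.append(cv_anova(cross_validate(tab, 1, folds=7))[1])
        assert ps[0] > ps[1] > ps[2]


class TestStatusRules:
    @pytest.mark.parametrize("q2,r2y,eig,expected", [
        (-0.1, 0.6, 1.0, "rejected"),
        (-1e-9, 0.9, 0.5, "rejected"),
        (0.02, 0.6, 3.0, "rejected"),
        (0.02, 0.6, 1.5, "acceptable"),
        (0.045, 0.3, 2.5, "rejected"),
        (0.2, 0.4, 5.0, "acceptable"),
        (0.45, 0.6, 5.0, "robust"),
        (0.41, 0.51, 0.1, "robust"),
        (0.45, 0.45, 1.0, "acceptable"),
        (0.39, 0.9, 1.0, "acceptable"),
    ])
    def test_threshold_grid(self, q2, r2y, eig, expected):
        q = ModelQuality(q2_cum=q2, r2x_cum=0.5, r2y_cum=r2y, cv_anova_F=1.0,
                         cv_anova_p=0.5, eigenvalues=np.array([eig]))
        assert classify_status(q) == expected


class TestJackknife:
    def test_identical_submodels_zero_se(self):
        cv = cross_validate(make_regression_table(21, n=35, p=4), 1, folds=7)
        cv.sub_weights = np.tile(cv.sub_weights[0], (7, 1))
        ci = jackknife_ci(cv)
        np.testing.assert_allclose(ci.se, 0.0, atol=1e-12)

    def test_sign_flipped_submodel_aligned(self):
        cv = cross_validate(make_regression_table(22, n=35, p=4), 1, folds=7)
        base = np.tile(cv.sub_weights[0], (7, 1))
        base[3] *= -1
        cv.sub_weights = base
        ci = jackknife_ci(cv)
        np.testing.assert_allclose(ci.se, 0.0, atol=1e-12)
        assert not ci.unstable

    def test_ci_width_shrinks_with_noise(self):
        # 3-point noise sweep, widths averaged over replicate tables
        widths = []
        for noise in (3.0, 1.0, 0.2):
            w = []
            for seed in (23, 123, 223, 323, 423):
                tab = make_regression_table(seed, n=56, p=5, noise=noise)
                ci = jackknife_ci(cross_validate(tab, 1, folds=7))
                w.append(float(np.mean(ci.ci_upper - ci.ci_lower)))
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]


class TestExclusionAndTop:
    def test_exclusion_improves_q2_and_keeps_informative(self):
        tab = make_class_table(24, n_per=25, n_noise=50, n_informative=5,
                               effect=1.2)
        res = optimize_by_exclusion(tab, fold_seed=0)
        informative = {f"inf{i}" for i in range(5)}
        assert len(informative & set(res.features)) >= 4
        full = evaluate_model(tab, fold_seed=0)
        assert res.quality.q2_cum >= full[1].q2_cum
        # returned Q2 is the max over the visited sequence
        visited = [q for _, q in res.log] + [full[1].q2_cum]
        assert res.quality.q2_cum == pytest.approx(max(visited))

    def test_all_noise_never_robust(self):
        tab = make_class_table(25, n_per=20, n_noise=30, n_informative=0)
        res = optimize_by_exclusion(tab, fold_seed=0)
        assert res.quality.status != "robust"

    def test_exclusion_deterministic(self):
        tab = make_class_table(26, n_per=15, n_noise=20, n_informative=2)
        a = optimize_by_exclusion(tab, fold_seed=3)
        b = optimize_by_exclusion(tab, fold_seed=3)
        assert a.log == b.log
        assert a.features == b.features

    def test_top_discriminants(self):
        tab = make_class_table(27, n_per=20, n_noise=21, n_informative=3)
        fit = fit_pls(tab, 1)
        top = top_discriminants(fit, 15)
        assert len(top) == 15
        assert top_discriminants(fit, 0) == []
        with pytest.warns(UserWarning, match="exceeds"):
            allf = top_discriminants(fit, 999)
        assert len(allf) == 24

    def test_duplicated_columns_rank_adjacent(self):
        rng = np.random.default_rng(28)
        X = rng.standard_normal((30, 5))
        X = np.hstack([X, X[:, [2]]])
        y = X[:, 2] + 0.2 * rng.standard_normal(30)
        fit = fit_pls(_table_from(X, y), 1)
        top = top_discriminants(fit, 6)
        assert abs(top.index("f2") - top.index("f5")) == 1
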