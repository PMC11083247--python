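"""Supervised stack: split, SVM/SVR tuning, RF, PLS, metrics, spectralprints."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from waxprint import learn
from waxprint.learn import RfConfig, SplitSpec, SvmConfig

SMALL_GRID = SvmConfig(log2_C_grid=(-2.0, 0.0, 2.0, 4.0), log2_sigma_grid=(-4.0, -2.0, 0.0, 2.0))


def two_blob_data(rng, n_per=15, p=6, gap=4.0):
    X = np.vstack(
        [rng.normal(0, 1, (n_per, p)), rng.normal(gap, 1, (n_per, p))]
    )
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


class TestSplit:
    def test_paper_partition_sizes(self, study_matrix):
        matrix, meta = study_matrix
        Xtr, Xte, ytr, yte = learn.split_data(matrix, meta["grade"].to_numpy())
        assert len(Xtr) == 55 and len(Xte) == 20
        assert set(ytr) == set(yte) == set(meta["grade"])

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitSpec(train_fraction=1.0)

    def test_seeded_determinism(self, study_matrix):
        matrix, meta = study_matrix
        y = meta["grade"].to_numpy()
        a = learn.split_data(matrix, y, SplitSpec(seed=4))
        b = learn.split_data(matrix, y, SplitSpec(seed=4))
        c = learn.split_data(matrix, y, SplitSpec(seed=5))
        assert list(a[0].index) == list(b[0].index)
        assert list(a[0].index) != list(c[0].index)


class TestSvmTuning:
    def test_default_grid_has_1681_combinations(self):
        assert SvmConfig().n_combinations == 1681
        assert len(SvmConfig().log2_C_grid) == 41

    def test_separable_data_reaches_perfect_cv(self, rng):
        X, y = two_blob_data(rng)
        C, sigma, surface = learn.tune_svm(X, y, SMALL_GRID, "classify", seed=0)
        assert surface["score"].max() == 1.0

    def test_selection_matches_external_replay(self, rng):
        X, y = two_blob_data(rng, gap=1.0)  # imperfect separation -> real ties
        C, sigma, surface = learn.tune_svm(X, y, SMALL_GRID, "classify", seed=0)
        # independent replay: recompute every combination with the same folds
        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        folds = list(
            StratifiedKFold(5, shuffle=True, random_state=0).split(np.zeros(len(y)), y)
        )
        best = None
        for lc in SMALL_GRID.log2_C_grid:
            for ls in SMALL_GRID.log2_sigma_grid:
                accs = []
                for tr, te in folds:
                    est = SVC(C=2.0**lc, gamma=2.0**ls).fit(X[tr], y[tr])
                    accs.append(np.mean(est.predict(X[te]) == y[te]))
                cand = (-np.mean(accs), 2.0**lc, 2.0**ls)
                if best is None or cand < best:
                    best = cand
        assert (C, sigma) == (best[1], best[2])

    def test_regression_selects_minimum_rmse(self, rng):
        X = rng.normal(0, 1, (30, 4))
        y = X[:, 0] * 2.0
        # discretize response so folds can stratify
        y = np.round(y)
        C, sigma, surface = learn.tune_svm(X, y, SMALL_GRID, "regress", seed=0)
        row = surface[(surface["C"] == C) & (surface["sigma"] == sigma)]
        assert row["score"].iloc[0] == surface["score"].min()


class TestSvmModels:
    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 3))
        with pytest.raises(ValueError, match="two classes"):
            learn.train_svm(X, np.repeat("a", 10), C=1.0, sigma=1.0)

    def test_nonpositive_hyperparameters_rejected(self, rng):
        X, y = two_blob_data(rng)
        with pytest.raises(ValueError, match="positive"):
            learn.train_svm(X, y, C=-1.0, sigma=1.0)

    def test_classifier_reports_support_vectors_and_kappa(self, rng):
        X, y = two_blob_data(rng)
        res = learn.train_svm(X, y, C=4.0, sigma=0.1, seed=0)
        assert 0 < res.n_support_vectors <= len(y)
        assert res.cv_metrics["accuracy"] == 1.0
        assert res.cv_metrics["kappa"] == 1.0

    def test_svr_on_noiseless_linear_response(self, rng):
        X = rng.uniform(-1, 1, (40, 3))
        y = np.round(2 * X[:, 0], 1)
        res = learn.train_svr(X, y, C=100.0, sigma=1.0, epsilon=0.1, seed=0)
        pred = res.predict(X)
        # epsilon-insensitive loss tolerates residuals up to the tube width
        assert np.sqrt(np.mean((pred - y) ** 2)) <= 0.2


class TestKappa:
    def test_perfect_agreement(self):
        assert learn.cohen_kappa(["a", "b", "a"], ["a", "b", "a"]) == 1.0

    def test_closed_form_oracle(self):
        # confusion matrix [[25, 5], [10, 10]]:
        # p_o = 0.7, p_e = (30*35 + 20*15)/50^2 = 0.54, kappa = 0.16/0.46
        actual = np.array(["x"] * 30 + ["y"] * 20)
        predicted = np.array(["x"] * 25 + ["y"] * 5 + ["x"] * 10 + ["y"] * 10)
        expected = (0.7 - 0.54) / (1 - 0.54)
        assert learn.cohen_kappa(predicted, actual) == pytest.approx(expected)

    def test_agrees_with_sklearn(self, rng):
        for _ in range(10):
            a = rng.choice(list("abc"), 40)
            p = rng.choice(list("abc"), 40)
            assert learn.cohen_kappa(p, a) == pytest.approx(
                cohen_kappa_score(a, p), abs=1e-12
            )

    def test_chance_level_near_zero(self, rng):
        kappas = []
        for _ in range(200):
            a = np.repeat(list("abcde"), 15)
            p = rng.permutation(a)
            kappas.append(learn.cohen_kappa(p, a))
        assert abs(np.mean(kappas)) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            learn.cohen_kappa([], [])


class TestRegressionMetrics:
    def test_exact_prediction(self):
        rmse, r2 = learn.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rmse == 0.0 and r2 == pytest.approx(1.0)

    def test_constant_offset_documents_convention(self):
        # squared-correlation R^2 ignores a constant bias; RMSE does not
        y = np.array([0.0, 1.0, 2.0, 3.0])
        rmse, r2 = learn.regression_metrics(y + 5.0, y)
        assert rmse == pytest.approx(5.0)
        assert r2 == pytest.approx(1.0)
        assert learn.r_squared_classic(y + 5.0, y) < 0

    def test_formula_oracle(self, rng):
        pred = rng.normal(0, 1, 30)
        act = rng.normal(0, 1, 30)
        rmse, r2 = learn.regression_metrics(pred, act)
        assert rmse == pytest.approx(np.sqrt(np.mean((pred - act) ** 2)))
        assert r2 == pytest.approx(np.corrcoef(pred, act)[0, 1] ** 2)

    def test_zero_variance_actuals_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            learn.regression_metrics([1.0, 2.0], [3.0, 3.0])


class TestRandomForest:
    def test_mtry_defaults_match_conventions(self):
        raw_c, int_c = RfConfig.mtry_default(501, "classify")
        raw_r, int_r = RfConfig.mtry_default(501, "regress")
        assert raw_c == pytest.approx(22.38, abs=0.005)
        assert int_c == 22
        assert int_r == 167

    def test_mtry_cannot_exceed_predictors(self, rng):
        X, y = two_blob_data(rng, p=4)
        with pytest.raises(ValueError, match="exceeds"):
            learn.rf_fit(X, y, RfConfig(mtry=10), "classify")

    def test_planted_markers_top_importance_ranks(self, quiet_matrix):
        matrix, meta = quiet_matrix
        Xtr, _, ytr, _ = learn.split_data(matrix, meta["grade"].to_numpy(),
                                          SplitSpec(seed=1))
        res = learn.rf_fit(Xtr, ytr, task="classify", seed=1)
        top8 = set(res.importances.sort_values(ascending=False).index[:8])
        planted = {79, 91, 92, 95, 97, 118, 157, 188, 221}
        assert len(top8 & planted) >= 7

    def test_oob_error_reported_and_bounded(self, quiet_matrix):
        matrix, meta = quiet_matrix
        Xtr, _, ytr, _ = learn.split_data(matrix, meta["grade"].to_numpy(),
                                          SplitSpec(seed=1))
        res = learn.rf_fit(Xtr, ytr, task="classify", seed=1)
        assert 0.0 <= res.oob_error <= 0.3

    def test_sweep_produces_requested_curve(self, rng):
        X, y = two_blob_data(rng, n_per=10)
        curve = learn.rf_sweep(X, y, RfConfig(ntree_grid=(2, 10, 20)), "classify", seed=0)
        assert list(curve["ntree"]) == [2, 10, 20]
        assert curve["score"].between(0, 1).all()


class TestImportanceReduce:
    def _result(self, importances):
        return learn.ModelResult(
            algorithm="random_forest", task="classify", hyperparameters={},
            cv_metrics={}, importances=pd.Series(importances),
        )

    def test_threshold_zero_keeps_everything(self):
        res = self._result({101: 100.0, 102: 30.0, 103: 1.0})
        assert learn.importance_reduce(res, threshold=0) == [101, 102, 103]

    def test_empty_selection_falls_back_with_warning(self):
        res = self._result({101: 50.0, 102: 30.0, 103: 10.0})
        with pytest.warns(UserWarning, match="falling back"):
            sel = learn.importance_reduce(res, threshold=99, top_k=2)
        assert sel == [101, 102]

    def test_reduced_refit_uses_only_selected_channels(self, quiet_matrix):
        matrix, meta = quiet_matrix
        y = meta["grade"].to_numpy()
        Xtr, Xte, ytr, yte = learn.split_data(matrix, y, SplitSpec(seed=1))
        full = learn.rf_fit(Xtr, ytr, task="classify", seed=1)
        sel = learn.importance_reduce(full)
        reduced = learn.rf_fit(
            Xtr[sel], ytr, RfConfig(mtry=max(1, int(np.sqrt(len(sel))))),
            "classify", seed=1,
        )
        assert reduced.feature_names == sel
        assert reduced.model.n_features_in_ == len(sel)
        assert reduced.evaluate(Xte[sel], yte)["accuracy"] >= 0.8

    def test_selected_markers_differ_across_grades(self, quiet_matrix):
        matrix, meta = quiet_matrix
        y = meta["grade"].to_numpy()
        X = matrix.values.T
        table = learn.marker_anova(X, y, [79, 92, 97, 157])
        assert (table["p"] < 0.05).all()


class TestPls:
    def test_rank_one_latent_structure_needs_one_component(self, rng):
        # X concentrated on a single latent direction that also drives y
        t = rng.normal(0, 1, 40)
        p = rng.normal(0, 1, 10)
        X = np.outer(t, p) + rng.normal(0, 0.01, (40, 10))
        y = t + rng.normal(0, 0.01, 40)
        res = learn.pls_fit(X, y, max_components=5, seed=0)
        curve = res.cv_metrics["curve"]
        assert res.hyperparameters["n_components"] <= 2
        assert curve["cv_rmse"].min() < 0.05

    def test_coefficients_match_pls1_svd_oracle(self, rng):
        # independent PLS1 implementation (power-iteration free, deflation)
        X = rng.normal(0, 1, (20, 8))
        y = rng.normal(0, 1, 20)
        A = 3

        def pls1(X, y, a):
            Xc = X - X.mean(0)
            yc = y - y.mean()
            W, P, Q = [], [], []
            Xk = Xc.copy()
            for _ in range(a):
                w = Xk.T @ yc
                w /= np.linalg.norm(w)
                t = Xk @ w
                p = Xk.T @ t / (t @ t)
                q = yc @ t / (t @ t)
                Xk = Xk - np.outer(t, p)
                W.append(w), P.append(p), Q.append(q)
            W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
            return W @ np.linalg.solve(P.T @ W, Q)

        from sklearn.cross_decomposition import PLSRegression

        beta = pls1(X, y, A)
        sk = PLSRegression(n_components=A, scale=False).fit(X, y)
        assert np.allclose(sk.coef_.ravel(), beta, atol=1e-8)

    def test_dominant_channel_reaches_full_importance(self, study_matrix):
        matrix, meta = study_matrix
        blends = meta["blend_pct"].to_numpy(dtype=float)
        Xtr, _, ytr, _ = learn.split_data(matrix, blends, SplitSpec(seed=1))
        res = learn.pls_fit(Xtr, ytr, max_components=10, seed=1)
        assert int(res.importances.idxmax()) == 91
        assert res.importances.max() == 100.0

    def test_component_bounds_validated(self, rng):
        X = rng.normal(0, 1, (10, 5))
        y = rng.normal(0, 1, 10)
        with pytest.raises(ValueError, match=">= 1"):
            learn.pls_fit(X, y, max_components=0)
        with pytest.raises(ValueError, match="rank"):
            learn.pls_fit(X, y, max_components=50)


class TestSpectralprint:
    def test_grade_none_peaks_at_97(self, study_matrix):
        matrix, meta = study_matrix
        sp = learn.extract_spectralprint(
            matrix, [79, 92, 95, 97, 118, 157, 188, 221], meta["grade"].to_numpy()
        )
        assert sp.argmax_channel("None") == 97
        assert sp.argmax_channel("Very Strong") == 92
        assert sp.table.to_numpy().max() <= 1.0

    def test_single_sample_grade_equals_its_own_values(self, study_matrix):
        matrix, meta = study_matrix
        labels = np.array(["one" if i == 0 else "rest" for i in range(len(meta))])
        mz_set = [92, 97, 157]
        sp = learn.extract_spectralprint(matrix, mz_set, labels)
        own = matrix.values.iloc[:, 0]
        expected = np.array([own[mz] for mz in mz_set])
        assert np.allclose(sp.table.loc["one"], expected / expected.max())

    def test_means_match_groupwise_loop(self, study_matrix):
        matrix, meta = study_matrix
        grades = meta["grade"].to_numpy()
        mz_set = [92, 97]
        sp = learn.extract_spectralprint(matrix, mz_set, grades)
        for grade in np.unique(grades):
            cols = matrix.values.loc[:, grades == grade]
            means = np.array([cols.loc[mz].mean() for mz in mz_set])
            assert np.allclose(sp.table.loc[grade], means / means.max())

    def test_unknown_channel_rejected(self, study_matrix):
        matrix, meta = study_matrix
        with pytest.raises(ValueError, match="not on the m/z axis"):
            learn.extract_spectralprint(matrix, [999], meta["grade"].to_numpy())
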