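"""NIPALS PCA (missing-aware, cross-validated retention) and OPLS-DA."""

import numpy as np
import pandas as pd
import pytest

from metabosense.models import (crossvalidate_pca, fit_oplsda, fit_pca,
                                fit_pca_retained, predict_oplsda,
                                stratified_folds)
from metabosense.pretreat import PretreatmentSpec, scale
from conftest import geometry_dataset, make_feature_table


def centered_table(X, groups=None):
    return scale(make_feature_table(X, groups=groups), PretreatmentSpec(scaling="center"))


class TestPCA:
    def test_equals_truncated_svd_on_complete_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(24, 200))
        pt = centered_table(X)
        model = fit_pca(pt, 5)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(5):
            ref = U[:, a] * S[a]
            err = min(np.abs(model.scores[:, a] - ref).max(),
                      np.abs(model.scores[:, a] + ref).max())
            assert err < 1e-6
            lerr = min(np.abs(model.loadings[:, a] - Vt[a]).max(),
                       np.abs(model.loadings[:, a] + Vt[a]).max())
            assert lerr < 1e-6

    def test_loadings_orthonormal_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        pt = centered_table(rng.normal(size=(30, 40)))
        m = fit_pca(pt, 4)
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-8)
        G = m.scores.T @ m.scores
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-6

    def test_rank_one_matrix_recovered_exactly(self):
        t = np.linspace(-1, 1, 12)
        p = np.linspace(1, 2, 7)
        X = np.outer(t, p)
        pt = centered_table(X + 5.0)  # centering removes the offset
        m = fit_pca(pt, 1)
        assert m.r2x[0] == pytest.approx(1.0, abs=1e-10)
        cos = abs(np.dot(m.loadings[:, 0], p / np.linalg.norm(p)))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_rank_one_with_missing_cells_recovered(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.normal(size=20), rng.normal(size=30))
        X[rng.uniform(size=X.shape) < 0.10] = np.nan
        pt = centered_table(X)
        m = fit_pca(pt, 1)
        assert m.r2x[0] >= 0.99

    def test_variance_bookkeeping_sums_to_one(self):
        rng = np.random.default_rng(2)
        pt = centered_table(rng.normal(size=(15, 10)))
        m = fit_pca(pt, 6)
        residual = np.nansum(m.residuals ** 2)
        total = np.nansum(pt.modeling_matrix().to_numpy() ** 2)
        assert sum(m.r2x) + residual / total == pytest.approx(1.0, abs=1e-8)


class TestPCACrossValidation:
    def test_pure_noise_keeps_at_most_one_weak_component(self):
        q2_first = []
        retained = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pt = centered_table(rng.normal(size=(24, 30)))
            cv = crossvalidate_pca(pt, 4)
            retained.append(cv.n_retained)
            q2_first.append(cv.q2[0])
        assert np.median(retained) <= 1
        assert np.median(q2_first) <= 0.05

    def test_planted_rank_two_is_retained(self):
        rng = np.random.default_rng(5)
        T = rng.normal(size=(24, 2)) * [8.0, 5.0]
        P = np.linalg.qr(rng.normal(size=(40, 2)))[0]
        X = T @ P.T + rng.normal(0, 0.05, (24, 40))
        cv = crossvalidate_pca(centered_table(X), 5)
        assert cv.n_retained == 2

    def test_retained_components_beat_the_rejected_next_one(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            T = rng.normal(size=(24, 2)) * [8.0, 5.0]
            P = np.linalg.qr(rng.normal(size=(40, 2)))[0]
            X = T @ P.T + rng.normal(0, 0.05, (24, 40))
            cv = crossvalidate_pca(centered_table(X), 4)
            if cv.n_retained >= 2 and len(cv.q2) > cv.n_retained:
                if min(cv.q2[:cv.n_retained]) > cv.q2[cv.n_retained]:
                    hits += 1
            elif cv.n_retained >= 2:
                hits += 1  # no further component was even computed
        assert hits >= 19


class TestOPLSDA:
    def test_predictive_loading_follows_class_direction(self):
        pt, labels, v, u = geometry_dataset(n=24, n_first=9, seed=3,
                                            separation=8.0, noise_sd=0.1)
        m = fit_oplsda(pt, labels)
        cos = abs(np.dot(m.w, v))
        assert cos >= 0.99
        assert m.n_ortho >= 1
        cos_u = abs(np.dot(m.W_o[:, 0], u))
        assert cos_u >= 0.95
        # orthogonality of weights
        for j in range(m.n_ortho):
            assert abs(np.dot(m.w, m.W_o[:, j])) < 1e-8

    def test_perfectly_separated_clouds_reach_full_r2y(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        y01 = np.array([0.0] * 12 + [1.0] * 12)
        X = np.outer(y01 * 10, v)  # no noise at all
        pt = centered_table(X, groups=["C"] * 12 + ["T"] * 12)
        m = fit_oplsda(pt)
        assert m.r2y >= 0.99

    def test_matches_single_component_pls_oracle(self):
        # with zero orthogonal components the fit is 1-component PLS
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 15))
        labels = ["C"] * 10 + ["T"] * 10
        pt = centered_table(X, groups=labels)
        m = fit_oplsda(pt, labels, n_ortho=0)
        yhat = m.t * m.q
        pls = PLSRegression(n_components=1, scale=False)
        Xc = pt.modeling_matrix().to_numpy()
        y = np.array([0.0] * 10 + [1.0] * 10)
        pls.fit(Xc, y - y.mean())
        ref = pls.predict(Xc).ravel()
        np.testing.assert_allclose(yhat, ref, atol=1e-8)

    def test_q2_never_exceeds_r2y(self):
        for seed in range(5):
            pt, labels, _, _ = geometry_dataset(n=24, n_first=9, seed=seed,
                                                noise_sd=1.0, separation=2.0)
            m = fit_oplsda(pt, labels)
            assert m.q2 <= m.r2y + 1e-12

    def test_stratified_folds_are_deterministic_and_balanced(self):
        labels = ["C"] * 9 + ["T"] * 15
        f1 = stratified_folds(labels, 7)
        f2 = stratified_folds(labels, 7)
        np.testing.assert_array_equal(f1, f2)
        counts = np.bincount(f1, minlength=7)
        assert counts.max() - counts.min() <= 2


class TestPredict:
    def test_training_rows_reproduce_fitted_scores(self):
        pt, labels, _, _ = geometry_dataset(n=24, n_first=9, seed=4)
        m = fit_oplsda(pt, labels)
        pred = predict_oplsda(m, pt.modeling_matrix())
        np.testing.assert_allclose(pred["t_pred"].to_numpy(), m.t, atol=1e-8)

    def test_mean_observation_predicts_the_midpoint(self):
        # balanced classes: the centered-response midpoint is zero
        pt, labels, _, _ = geometry_dataset(n=24, n_first=12, seed=5)
        m = fit_oplsda(pt, labels)
        mean_obs = pt.modeling_matrix().mean(axis=0).to_frame().T
        pred = predict_oplsda(m, mean_obs)
        assert abs(pred["y_pred"].iloc[0]) < 1e-8

    def test_column_mismatch_is_an_error(self):
        pt, labels, _, _ = geometry_dataset(n=24, n_first=9, seed=6)
        m = fit_oplsda(pt, labels)
        bad = pt.modeling_matrix().iloc[:, :-2]
        with pytest.raises(ValueError, match="lack model features"):
            predict_oplsda(m, bad)

    def test_holdout_accuracy_on_separable_classes(self):
        pt, labels, _, _ = geometry_dataset(n=48, n_first=18, seed=8)
        M = pt.modeling_matrix()
        train = M.index[:36]
        test = M.index[36:]
        sub = scale(make_feature_table(M.loc[train].to_numpy(),
                                       groups=[labels[i] for i in range(36)]),
                    PretreatmentSpec(scaling="center"))
        m = fit_oplsda(sub, [labels[i] for i in range(36)])
        # project the held-out rows with the training pretreatment
        new = sub.apply_to(pd.DataFrame(M.loc[test].to_numpy(),
                                        columns=sub.usable_columns, index=test))
        pred = predict_oplsda(m, new)
        truth = [labels[i] for i in range(36, 48)]
        assert (pred["class"].to_numpy() == np.array(truth)).mean() >= 0.9
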