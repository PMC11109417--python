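import numpy as np
import pandas as pd
import pytest

from triomix import (
    ValidationError,
    cross_validate,
    fuse_markers,
    pca,
    plsda,
    roc_auc,
    vip,
)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 8))
        model = pca(X, n_comp=8)
        cov = np.cov(X, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        for a in range(8):
            v = eigvecs[:, a]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, a], v, atol=1e-10)
        total = np.trace(cov)
        np.testing.assert_allclose(
            model.explained_variance_ratio, eigvals / total, atol=1e-10
        )

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 6))
        ours = pca(X, 3)
        theirs = sk.PCA(n_components=3).fit(X)
        np.testing.assert_allclose(
            np.abs(ours.loadings.T), np.abs(theirs.components_), atol=1e-10
        )

    def test_collinear_cloud_one_component(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t])
        model = pca(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        model = pca(X, 4)
        recon = model.scores @ model.loadings.T + model.mean
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.ones((5, 3)), 1)


class TestPLSDA:
    def test_single_feature_equals_ols(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        labels = np.array(["UC"] * 10 + ["CTRL"] * 10)
        y = (labels == "UC").astype(float)
        model = plsda(x[:, None], labels, n_comp=1)
        slope, intercept = np.polyfit(x, y, 1)
        pred = model.predict(x[:, None])
        np.testing.assert_allclose(pred, slope * x + intercept, atol=1e-10)

    def test_perfect_separation_training_auroc_one(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.random((10, 5)), rng.random((10, 5)) + 10])
        labels = ["CTRL"] * 10 + ["UC"] * 10
        model = plsda(X, labels, 2)
        auc, _ = roc_auc(model.predict(X), labels)
        assert auc == 1.0

    def test_no_signal_near_zero_y_loading(self):
        rng = np.random.default_rng(5)
        n = 40
        labels = np.array(["UC", "CTRL"] * (n // 2))
        y = (labels == "UC").astype(float) - 0.5
        X = rng.normal(size=(n, 6))
        # orthogonalize every column against y
        X = X - np.outer(y, y @ X) / (y @ y)
        model = plsda(X, labels, 1)
        assert abs(model.y_loadings[0]) < 1e-10

    def test_scores_orthogonal_weights_unit(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 12))
        labels = ["UC"] * 13 + ["CTRL"] * 12
        model = plsda(X, labels, 3)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)
        np.testing.assert_allclose((model.weights**2).sum(axis=0), 1.0, atol=1e-10)

    def test_matches_sklearn_pls_prediction(self):
        skpls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 8))
        labels = np.array(["UC"] * 15 + ["CTRL"] * 15)
        y = (labels == "UC").astype(float)
        ours = plsda(X, labels, 2)
        theirs = skpls.PLSRegression(n_components=2, scale=False).fit(X, y)
        np.testing.assert_allclose(
            ours.predict(X), theirs.predict(X).ravel(), atol=1e-8
        )


class TestVIP:
    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 17))
        labels = ["UC"] * 16 + ["CTRL"] * 14
        model = plsda(X, labels, 2)
        v = vip(model)
        assert (v**2).sum() == pytest.approx(17, abs=1e-8)

    def test_equal_weights_all_one(self):
        # one component with equal weight on p features: every VIP = 1
        rng = np.random.default_rng(9)
        t = rng.normal(size=40)
        X = np.tile(t[:, None], (1, 5)) + rng.normal(scale=1e-9, size=(40, 5))
        labels = np.where(t > 0, "UC", "CTRL")
        model = plsda(X, labels, 1)
        np.testing.assert_allclose(vip(model), 1.0, atol=1e-4)

    def test_informative_feature_ranks_high(self):
        rng = np.random.default_rng(10)
        labels = np.array(["UC"] * 20 + ["CTRL"] * 20)
        X = rng.normal(size=(40, 30))
        X[:, 3] += (labels == "UC") * 3.0
        model = plsda(X, labels, 2)
        v = vip(model)
        assert np.argmax(v) == 3 and v[3] > 1.0


class TestCrossValidate:
    def test_seed_gives_identical_metrics(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 10))
        labels = ["UC"] * 15 + ["CTRL"] * 15
        m1 = cross_validate(X, labels, 2, k=5, seed=3)
        m2 = cross_validate(X, labels, 2, k=5, seed=3)
        assert (m1.rmse, m1.r2, m1.q2) == (m2.rmse, m2.r2, m2.q2)

    def test_separable_data_high_q2_low_rmse(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.random((20, 5)), rng.random((20, 5)) + 5])
        labels = ["CTRL"] * 20 + ["UC"] * 20
        m = cross_validate(X, labels, 2, k=7, seed=0)
        assert m.q2 > 0.5 and m.rmse < 0.2 and m.r2 <= 1

    def test_shuffled_labels_nonpositive_q2(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 25))
        neg = 0
        for rep in range(20):
            labels = rng.permutation(["UC"] * 20 + ["CTRL"] * 20)
            if cross_validate(X, labels, 2, k=7, seed=rep).q2 <= 0:
                neg += 1
        assert neg >= 18


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),
            ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),
        ],
    )
    def test_hand_cases(self, scores, labels, expected):
        auc, curve = roc_auc(scores, labels)
        assert auc == pytest.approx(expected)
        assert {"fpr", "tpr", "threshold"} <= set(curve.columns)

    def test_matches_sklearn(self):
        skm = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(14)
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        ours, _ = roc_auc(scores, y)
        assert ours == pytest.approx(skm.roc_auc_score(y, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], ["UC", "UC"])


class TestFuseMarkers:
    def _stats(self, q, log2fc):
        return pd.DataFrame(
            {"feature_id": ["f"], "U": [1.0], "p": [q], "q": [q], "log2fc": [log2fc]}
        )

    @pytest.mark.parametrize(
        "vip_val, q, log2fc, expected",
        [
            (1.5, 0.01, 2.0, "UC-marker"),
            (1.5, 0.2, 2.0, "none"),
            (0.9, 0.001, -3.0, "none"),
            (1.5, 0.01, -2.0, "CTRL-marker"),
        ],
    )
    def test_rule_table(self, vip_val, q, log2fc, expected):
        out = fuse_markers(pd.Series([vip_val], index=["f"]), self._stats(q, log2fc))
        assert out.loc[0, "verdict"] == expected

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fuse_markers(pd.Series([1.0], index=["g"]), self._stats(0.01, 1.0))
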