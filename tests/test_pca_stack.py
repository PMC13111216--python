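import numpy as np
import pytest

from mmpcr import fit_correlation_pca, fit_stack, stack_affine_map
from mmpcr.pca_stack import PCAStack, pca_transform

from conftest import make_table

WM_IDS = ["SCC.FA.wm", "GCC.FA.wm", "BCC.FA.wm", "PLIC.FA.wm"]
MIXED_IDS = [
    "FRP.CT.cor", "STG.CT.cor", "PUC.CVR.cor", "LNG.CBF.cor",
    "Amyg.CBF.sub", "PUT.Vol.sub", "CN.MD.sub", "GP.FA.sub",
    "SCC.FA.wm", "PLIC.MD.wm", "ALIC.FW.wm", "GCC.FA.wm",
]


def dense_correlation_eig_oracle(X):
    """Brute-force reference: explicit correlation matrix, dense eigh."""
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestFitCorrelationPCA:
    def test_single_column(self, rng):
        x = rng.standard_normal((10, 1)) * 3 + 5
        layer = fit_correlation_pca(x, pve=0.8)
        assert layer.eigenvalues == pytest.approx([1.0])
        assert layer.k_retained == 1
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(pca_transform(layer, x), z, atol=1e-12)

    def test_perfectly_correlated_pair(self, rng):
        x1 = rng.standard_normal((12, 1))
        X = np.hstack([x1, 2 * x1])
        layer = fit_correlation_pca(X, pve=0.8)
        np.testing.assert_allclose(layer.eigenvalues, [2.0, 0.0], atol=1e-12)
        assert layer.k_retained == 1
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        expected = (z[:, 0] + z[:, 1]) / np.sqrt(2)
        np.testing.assert_allclose(
            pca_transform(layer, X)[:, 0], expected, atol=1e-10
        )

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((6, 4)) @ rng.standard_normal((4, 4))
        layer = fit_correlation_pca(X, pve=1.0)
        ref_evals, ref_evecs = dense_correlation_eig_oracle(X)
        np.testing.assert_allclose(layer.eigenvalues, ref_evals, atol=1e-10)
        for j in range(4):  # loadings agree up to the fixed sign convention
            ours, ref = layer.loadings[:, j], ref_evecs[:, j]
            sign = np.sign(ours @ ref)
            np.testing.assert_allclose(ours, sign * ref, atol=1e-8)

    def test_matches_sklearn_on_standardized_data(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.standard_normal((30, 5)) * [1, 10, 0.1, 3, 7]
        layer = fit_correlation_pca(X, pve=1.0)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = sklearn_pca(n_components=5).fit(Z)
        np.testing.assert_allclose(
            layer.eigenvalues, ref.explained_variance_, atol=1e-10
        )

    def test_eigenvalues_sum_to_trace(self, rng):
        X = rng.standard_normal((9, 6))
        layer = fit_correlation_pca(X, pve=0.9)
        assert layer.eigenvalues.sum() == pytest.approx(6.0, rel=1e-8)

    def test_loadings_orthonormal(self, rng):
        X = rng.standard_normal((15, 7))
        V = fit_correlation_pca(X, pve=0.9).loadings
        np.testing.assert_allclose(V.T @ V, np.eye(7), atol=1e-10)

    def test_constant_column_named_in_error(self, rng):
        X = rng.standard_normal((8, 2))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="f_const"):
            fit_correlation_pca(X, pve=0.9, input_labels=["ok", "f_const"])

    def test_invalid_pve_rejected(self, rng):
        X = rng.standard_normal((8, 2))
        for pve in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="pve"):
                fit_correlation_pca(X, pve=pve)

    def test_rank_deficient_pve_caps_at_positive_eigenvalues(self, rng):
        X = rng.standard_normal((4, 8))  # n-1 = 3 positive eigenvalues at most
        layer = fit_correlation_pca(X, pve=1.0)
        assert layer.k_retained <= 3
        assert (layer.eigenvalues[layer.k_retained:] < 1e-8).all()


class TestTransform:
    def test_training_scores_centered_with_eigenvalue_variance(self, rng):
        X = rng.standard_normal((25, 6))
        layer = fit_correlation_pca(X, pve=0.9)
        scores = pca_transform(layer, X)
        np.testing.assert_allclose(scores.mean(0), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            scores.var(0, ddof=1),
            layer.eigenvalues[: layer.k_retained],
            rtol=1e-8,
        )

    def test_single_row_equals_batch_row(self, rng):
        X = rng.standard_normal((10, 4))
        layer = fit_correlation_pca(X, pve=0.9)
        batch = pca_transform(layer, X)
        np.testing.assert_allclose(pca_transform(layer, X[3]), batch[3:4], atol=1e-12)

    def test_rows_at_the_mean_score_zero(self, rng):
        X = rng.standard_normal((10, 4))
        layer = fit_correlation_pca(layer_X := X, pve=0.9)
        np.testing.assert_allclose(
            pca_transform(layer, np.tile(layer_X.mean(0), (3, 1))), 0.0, atol=1e-12
        )

    def test_column_count_mismatch(self, rng):
        layer = fit_correlation_pca(rng.standard_normal((10, 4)), pve=0.9)
        with pytest.raises(ValueError, match="columns"):
            pca_transform(layer, rng.standard_normal((2, 3)))


class TestStack:
    def test_single_feature_closed_form(self, rng):
        x = rng.standard_normal((10, 1)) * 2 + 7
        table = make_table(x, ["Amyg.CBF.sub"])
        stack = fit_stack(table, grouping="single_group", pve=0.9, two_layer=False)
        mu, sd = x.mean(), x.std(ddof=1)
        A, c = stack_affine_map(stack)
        assert A[0, 0] == pytest.approx(1 / sd)
        assert c[0] == pytest.approx(-mu / sd)
        np.testing.assert_allclose(stack.transform(x)[:, 0], (x[:, 0] - mu) / sd)

    def test_final_dim_is_sum_of_group_retentions(self, default_cohort):
        table, _, _ = default_cohort
        stack = fit_stack(table, grouping="by_region", pve=0.9, two_layer=False)
        assert stack.final_dim == sum(l.k_retained for l in stack.layer1)
        assert [l.group_key for l in stack.layer1] == ["cor", "sub", "wm"]

    @pytest.mark.parametrize("two_layer", [False, True])
    @pytest.mark.parametrize("grouping", ["by_region", "by_metric", "single_group"])
    def test_affine_map_equals_sequential_evaluation(self, rng, grouping, two_layer):
        X = rng.standard_normal((20, 12)) * 2 + 1
        table = make_table(X, MIXED_IDS)
        stack = fit_stack(table, grouping=grouping, pve=0.9, two_layer=two_layer)
        probes = rng.standard_normal((100, 12))
        np.testing.assert_allclose(
            stack.transform(probes),
            stack.transform_sequential(probes),
            atol=1e-10,
        )

    def test_training_scores_reproduced_by_affine_map(self, rng):
        X = rng.standard_normal((20, 12))
        table = make_table(X, MIXED_IDS)
        stack = fit_stack(table, grouping="by_region", pve=0.8, two_layer=True)
        seq = stack.transform_sequential(X)
        aff = stack.transform(X)
        scale = np.abs(seq).max()
        assert np.abs(seq - aff).max() < 1e-10 * max(scale, 1.0)

    def test_permuting_features_permutes_affine_rows(self, rng):
        X = rng.standard_normal((15, 4))
        table = make_table(X, WM_IDS)
        stack = fit_stack(table, grouping="single_group", pve=0.9)
        perm = [2, 0, 3, 1]
        table_p = make_table(X[:, perm], [WM_IDS[j] for j in perm])
        stack_p = fit_stack(table_p, grouping="single_group", pve=0.9)
        A, _ = stack_affine_map(stack)
        A_p, _ = stack_affine_map(stack_p)
        np.testing.assert_allclose(A_p, A[perm], atol=1e-10)
        np.testing.assert_allclose(
            stack.transform(X), stack_p.transform(X[:, perm]), atol=1e-10
        )

    def test_scale_invariance_of_correlation_pca(self, rng):
        X = rng.standard_normal((20, 4)) + 3
        stack = fit_stack(make_table(X, WM_IDS), grouping="single_group", pve=0.9)
        X2 = X.copy()
        X2[:, 1] *= 250.0
        stack2 = fit_stack(make_table(X2, WM_IDS), grouping="single_group", pve=0.9)
        np.testing.assert_allclose(
            stack.layer1[0].eigenvalues, stack2.layer1[0].eigenvalues, atol=1e-8
        )
        assert stack.layer1[0].k_retained == stack2.layer1[0].k_retained
        np.testing.assert_allclose(
            stack.transform(X), stack2.transform(X2), atol=1e-8
        )

    def test_pve_monotonicity(self, default_cohort):
        table, _, _ = default_cohort
        k8 = fit_stack(table, pve=0.8).final_dim
        k9 = fit_stack(table, pve=0.9).final_dim
        assert k9 >= k8

    def test_json_round_trip(self, rng):
        X = rng.standard_normal((20, 12))
        stack = fit_stack(make_table(X, MIXED_IDS), pve=0.9, two_layer=True)
        back = PCAStack.from_json(stack.to_json())
        np.testing.assert_allclose(back.transform(X), stack.transform(X), atol=1e-12)
        assert back.score_labels == stack.score_labels
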