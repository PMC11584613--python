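import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import ftirclass as fc


def eig_oracle(x):
    """Brute-force covariance eigendecomposition (sample normalization)."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order].T


class TestPCA:
    def test_rank_one_data(self):
        m = fc.fit_pca(np.array([[0.0, 0], [1, 1], [2, 2]]), k=1)
        np.testing.assert_allclose(m.components, [[1, 1]] / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(m.explained_variance_ratio, [1.0])

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(9, 5))
        m = fc.fit_pca(x, k=5)
        np.testing.assert_allclose(m.mean + m.transform(x) @ m.components, x,
                                   atol=1e-8)

    def test_matches_eigendecomposition_oracle_on_many_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            d = int(rng.integers(2, 9))
            x = rng.normal(size=(n, d))
            k = min(n - 1, d)
            m = fc.fit_pca(x, k=k)
            vals, vecs = eig_oracle(x)
            np.testing.assert_allclose(m.explained_variance, vals[:k], atol=1e-8)
            for i in range(k):
                dot = abs(m.components[i] @ vecs[i])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(2)
        m = fc.fit_pca(rng.normal(size=(10, 6)), k=4)
        for row in m.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_components_orthonormal(self):
        rng = np.random.default_rng(3)
        m = fc.fit_pca(rng.normal(size=(12, 7)), k=5)
        gram = m.components @ m.components.T
        assert np.abs(gram - np.eye(5)).max() < 1e-8

    def test_k_beyond_rank_bound_errors(self):
        with pytest.raises(ValueError, match="rank bound"):
            fc.fit_pca(np.random.default_rng(0).normal(size=(4, 10)), k=4)


class TestSelectK:
    @pytest.mark.parametrize("ratios,target,expected", [
        ([0.7, 0.2, 0.09, 0.009, 0.001], 0.999, 4),
        ([1.0], 0.999, 1),
        ([0.7, 0.2, 0.09, 0.009, 0.001], 0.5, 1),
    ])
    def test_cumulative_rule(self, ratios, target, expected):
        assert fc.select_k_by_variance(ratios, target) == expected

    def test_rank_one_example_needs_single_component(self):
        m = fc.fit_pca(np.array([[0.0, 0], [1, 1], [2, 2]]), k=2)
        assert fc.select_k_by_variance(m.explained_variance_ratio, 0.999) == 1

    def test_unreachable_target_keeps_all_with_warning(self):
        with pytest.warns(UserWarning, match="not reached"):
            assert fc.select_k_by_variance([0.5, 0.3], 0.999) == 2

    def test_monotone_in_target(self):
        rng = np.random.default_rng(4)
        r = np.sort(rng.dirichlet(np.ones(8)))[::-1]
        ks = [fc.select_k_by_variance(r, t) for t in np.linspace(0.1, 0.999, 30)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_empty_ratios_error(self):
        with pytest.raises(ValueError):
            fc.select_k_by_variance([], 0.9)


class TestDualPCA:
    def test_identical_data_in_both_classes_gives_identical_models(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 4))
        both = np.vstack([x, x])
        y = np.r_[np.zeros(6), np.ones(6)]
        m = fc.fit_dual_pca(both, y, k=3)
        np.testing.assert_allclose(m.pca0.components, m.pca1.components, atol=1e-10)
        np.testing.assert_allclose(m.pca0.mean, m.pca1.mean, atol=1e-12)

    def test_hand_computed_axes(self):
        x = np.array([[0.0, 0], [2, 0], [0, 0], [0, 2]])
        y = np.array([0, 0, 1, 1])
        m = fc.fit_dual_pca(x, y, k=1)
        np.testing.assert_allclose(m.pca0.components, [[1, 0]], atol=1e-12)
        np.testing.assert_allclose(m.pca0.mean, [1, 0], atol=1e-12)
        np.testing.assert_allclose(m.pca1.components, [[0, 1]], atol=1e-12)
        np.testing.assert_allclose(m.pca1.mean, [0, 1], atol=1e-12)

    def test_transform_matches_hand_computation(self):
        x = np.array([[0.0, 0], [2, 0], [0, 0], [0, 2]])
        m = fc.fit_dual_pca(x, np.array([0, 0, 1, 1]), k=1)
        np.testing.assert_allclose(fc.transform_dual(m, [[1.0, 1]]), [[0, 0]],
                                   atol=1e-12)
        np.testing.assert_allclose(fc.transform_dual(m, [[3.0, 0]]), [[2, -1]],
                                   atol=1e-12)

    def test_equals_per_class_pca_blocks_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n0, n1 = rng.integers(3, 9, size=2)
            d = int(rng.integers(3, 7))
            x = rng.normal(size=(n0 + n1, d))
            y = np.r_[np.zeros(n0), np.ones(n1)]
            k = int(min(n0 - 1, n1 - 1, d))
            m = fc.fit_dual_pca(x, y, k)
            p0 = fc.fit_pca(x[y == 0], k=k)
            p1 = fc.fit_pca(x[y == 1], k=k)
            test = rng.normal(size=(4, d))
            expected = np.hstack([p0.transform(test), p1.transform(test)])
            np.testing.assert_allclose(fc.transform_dual(m, test), expected,
                                       atol=1e-10)

    def test_output_width_is_2k(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 6))
        y = np.r_[np.zeros(5), np.ones(5)]
        m = fc.fit_dual_pca(x, y, k=3)
        assert fc.transform_dual(m, rng.normal(size=(4, 6))).shape == (4, 6)
        assert m.out_dim == 6

    def test_small_class_errors_naming_class(self):
        x = np.ones((4, 3))
        with pytest.raises(ValueError, match="class 1"):
            fc.fit_dual_pca(x, np.array([0, 0, 0, 1]), k=1)


class TestLDA:
    def test_closed_form_toy_direction(self):
        z = np.array([[0.0, 0], [1, 0], [0, 1], [3, 0], [4, 0], [3, 1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fc.fit_lda(z, y)
        expected = np.array([2.0, 1.0]) / np.sqrt(5)
        np.testing.assert_allclose(m.direction, expected, atol=1e-6)
        assert m.class_means[1] > m.class_means[0]
        assert m.class_means[0] < m.threshold < m.class_means[1]

    def test_one_dimensional_data(self):
        z = np.array([[0.0], [1], [5], [6]])
        m = fc.fit_lda(z, np.array([0, 0, 1, 1]))
        assert abs(abs(m.direction[0]) - 1.0) < 1e-12

    def test_isotropic_clouds_align_with_mean_difference(self):
        rng = np.random.default_rng(8)
        delta = np.array([3.0, 4.0, 0.0])
        z0 = rng.normal(size=(400, 3))
        z1 = rng.normal(size=(400, 3)) + delta
        m = fc.fit_lda(np.vstack([z0, z1]), np.r_[np.zeros(400), np.ones(400)])
        cos = m.direction @ delta / np.linalg.norm(delta)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5

    def test_label_swap_flips_sign_only(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, size=30)
        m1 = fc.fit_lda(z, y)
        m2 = fc.fit_lda(z, 1 - y)
        np.testing.assert_allclose(m1.direction, -m2.direction, atol=1e-10)

    def test_matches_sklearn_lda_direction(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(60, 5))
        y = np.r_[np.zeros(30), np.ones(30)]
        z[y == 1] += [1, 2, 0, 0, 1]
        ours = fc.fit_lda(z, y).direction
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(z, y).coef_[0]
        ref = ref / np.linalg.norm(ref)
        assert abs(abs(ours @ ref) - 1.0) < 1e-4

    def test_projection_beats_any_single_feature_on_toy(self):
        z = np.array([[0.0, 0], [1, 0], [0, 1], [3, 0], [4, 0], [3, 1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fc.fit_lda(z, y)

        def fisher(v):
            a, b = v[y == 0], v[y == 1]
            within = a.var(ddof=1) + b.var(ddof=1)
            return (a.mean() - b.mean()) ** 2 / within

        proj = fc.transform_lda(m, z)[:, 0]
        assert all(fisher(proj) >= fisher(z[:, j]) for j in range(z.shape[1]))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fc.fit_lda(np.ones((4, 2)), np.zeros(4))

    def test_dimension_mismatch_errors(self):
        z = np.array([[0.0, 1], [1, 0], [2, 2], [3, 3]])
        m = fc.fit_lda(z, np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            fc.transform_lda(m, np.ones((2, 3)))

    def test_unit_vector_along_direction_projects_to_one(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        m = fc.fit_lda(z, y)
        assert fc.transform_lda(m, m.direction[None, :])[0, 0] == pytest.approx(1.0)
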