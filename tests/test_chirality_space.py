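import numpy as np
import pytest

import chirobiophore as cb
from chirobiophore.chirality_space import (DESCRIPTOR_NAMES,
                                           DescriptorMatrix, distance,
                                           gradient_field, hcluster, pca,
                                           standardize)
from chirobiophore.synthetic import mirror, rigid_transform


def matrix_from(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"s{i}" for i in range(len(values))]
    return DescriptorMatrix(ids, values)


class TestStandardize:
    def test_simple_column(self):
        X = np.zeros((3, 6))
        X[:, 0] = [1, 2, 3]
        Z = standardize(matrix_from(X))
        np.testing.assert_allclose(Z.values[:, 0], [-1, 0, 1])
        assert Z.standardized

    def test_constant_column_zeros_with_warning(self):
        X = np.ones((3, 6)) * 5
        with pytest.warns(UserWarning, match="constant column"):
            Z = standardize(matrix_from(X))
        np.testing.assert_array_equal(Z.values, 0.0)

    def test_idempotence(self, rng):
        X = rng.normal(size=(8, 6))
        once = standardize(matrix_from(X))
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize(matrix_from(np.zeros((1, 6))))


class TestDistance:
    def test_identity_and_three_four_five(self):
        a = np.zeros(6)
        b = np.array([3.0, 4.0, 0, 0, 0, 0])
        assert distance(a, a) == 0.0
        assert distance(a, b) == pytest.approx(5.0)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=(2, 6))
            assert distance(a, b) == pytest.approx(distance(b, a))

    def test_whitened_equals_euclidean_on_standardized(self, rng):
        X = rng.normal(size=(10, 6)) * [1, 5, 0.2, 9, 3, 0.7]
        m = matrix_from(X)
        std = standardize(m)
        for i, j in [(0, 1), (2, 7), (4, 9)]:
            dw = distance(X[i], X[j], "whitened", std.column_sds)
            de = distance(std.values[i], std.values[j])
            assert dw == pytest.approx(de, rel=1e-12)

    def test_whitened_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            distance(np.zeros(6), np.ones(6), "whitened", np.zeros(6))


class TestPCA:
    def test_ratios_sum_to_one_and_orthonormal(self, reference_matrix):
        res = pca(standardize(reference_matrix))
        assert res.explained_variance_ratio.sum() == pytest.approx(
            1.0, abs=1e-10)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        L = res.loadings
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-10)

    def test_rank_one_matrix(self, rng):
        base = rng.normal(size=6)
        scale = rng.normal(size=12)
        X = np.outer(scale, base)
        res = pca(standardize(matrix_from(X)))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0,
                                                                abs=1e-10)

    def test_column_permutation_preserves_spectrum(self, rng):
        X = rng.normal(size=(9, 6)) * [1, 4, 2, 8, 0.5, 3]
        perm = [3, 0, 5, 1, 4, 2]
        r1 = pca(standardize(matrix_from(X)))
        r2 = pca(standardize(matrix_from(X[:, perm])))
        np.testing.assert_allclose(r1.explained_variance_ratio,
                                   r2.explained_variance_ratio, atol=1e-10)

    def test_requires_standardized_input(self, reference_matrix):
        with pytest.raises(ValueError):
            pca(reference_matrix)

    def test_oriented_loading_sign_rule(self, reference_matrix):
        L = pca(standardize(reference_matrix)).oriented()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


class TestHCluster:
    def test_identical_rows_merge_first_at_zero(self, rng):
        X = rng.normal(size=(6, 6))
        X[3] = X[1]
        merges = hcluster(standardize(matrix_from(X)))
        i, j, h = merges[0]
        assert {i, j} == {1, 3}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_two_blobs_top_split(self, rng):
        blob1 = rng.normal(size=(5, 6)) * 0.1
        blob2 = rng.normal(size=(5, 6)) * 0.1 + 10.0
        m = matrix_from(np.vstack([blob1, blob2]))
        merges = hcluster(standardize(m))
        # the last merge joins the two blobs: it must be far higher than
        # every within-blob merge
        heights = [h for _, _, h in merges]
        assert heights[-1] > 3 * max(heights[:-1])

    def test_two_rows_single_merge(self, rng):
        X = rng.normal(size=(2, 6))
        std = standardize(matrix_from(X))
        merges = hcluster(std)
        assert len(merges) == 1
        d = distance(std.values[0], std.values[1])
        assert merges[0][2] == pytest.approx(d)


class TestGradientField:
    def test_constant_descriptor_zero_gradient(self, rng):
        X = rng.normal(size=(8, 6))
        X[:, 0] = 5.0
        m = matrix_from(X)
        with pytest.warns(UserWarning):
            std = standardize(m)
        g = gradient_field(std, "LTA", grid=10)
        assert np.max(np.abs(g["grad_x"])) < 1e-10
        assert np.max(np.abs(g["grad_y"])) < 1e-10

    def test_linear_field_recovery(self, rng):
        # descriptor equal to the PC1 coordinate -> gradient along +PC1
        X = rng.normal(size=(30, 6))
        std = standardize(matrix_from(X))
        res = pca(std)
        vals = std.frame.copy()
        vals["LTA"] = res.scores[:, 0]
        m2 = DescriptorMatrix(std.ids, vals.to_numpy(), standardized=True)
        # replacing a column changes the PCA chart, so fix the expected
        # sign from the correlation of the stored values with the new PC1
        res2 = pca(m2)
        sign = np.sign(np.corrcoef(res2.scores[:, 0],
                                   m2.frame["LTA"])[0, 1])
        g = gradient_field(m2, "LTA", grid=15, bandwidth=5.0)
        gx = sign * g["grad_x"][5:-5, 5:-5]
        gy = g["grad_y"][5:-5, 5:-5]
        assert np.all(gx > 0)
        assert np.mean(np.abs(gy)) < 0.5 * np.mean(np.abs(gx))

    def test_infinite_bandwidth_flattens(self, rng):
        X = rng.normal(size=(10, 6))
        std = standardize(matrix_from(X))
        g = gradient_field(std, "DDP", grid=8, bandwidth=1e9)
        assert np.max(np.abs(g["grad_x"])) < 1e-6


class TestAssembleVector:
    def test_deterministic_bit_for_bit(self, decorated_bundle):
        v1 = cb.assemble_vector(decorated_bundle)
        v2 = cb.assemble_vector(decorated_bundle)
        assert np.array_equal(v1.as_array(), v2.as_array())

    def test_rigid_motion_invariance(self, decorated_bundle):
        v0 = cb.assemble_vector(decorated_bundle).as_array()
        moved = cb.infer_bonds(rigid_transform(decorated_bundle, seed=99))
        v1 = cb.assemble_vector(moved).as_array()
        np.testing.assert_allclose(v1, v0, atol=1e-6)

    def test_mirror_negates_lta_and_hpc(self, decorated_bundle):
        framed = cb.frame_structure(decorated_bundle)
        v0 = cb.assemble_vector(framed)
        vm = cb.assemble_vector(mirror(framed, "yz"))
        assert vm.lta == pytest.approx(-v0.lta, abs=1e-9)
        assert vm.hpc == pytest.approx(-v0.hpc, abs=1e-12)
        assert vm.aes == pytest.approx(v0.aes, abs=1e-6)


class TestReferenceMatrix:
    def test_shape_and_ids(self, reference_matrix):
        assert len(reference_matrix) == 9
        assert reference_matrix.frame.shape == (9, 6)
        assert "1C3W" in reference_matrix.ids
        assert list(reference_matrix.frame.columns) == DESCRIPTOR_NAMES

    def test_csv_round_trip(self, reference_matrix, tmp_path):
        p = tmp_path / "m.csv"
        reference_matrix.to_csv(p)
        again = DescriptorMatrix.from_csv(p)
        np.testing.assert_allclose(again.values, reference_matrix.values)
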