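"""Contact-matrix model, I/O, coarsening, balancing, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import sinkhorn_oracle
from ximega.errors import (ConvergenceError, DegenerateInputError, FormatError,
                           ParameterError)
from ximega.matrix import (ContactMatrix, coarsen, kr_balance,
                           pearson_correlation, sqrt_vc_balance)
from ximega.matrix_io import read_matrix, write_matrix


class TestContactMatrix:
    def test_rejects_asymmetric_and_negative(self):
        with pytest.raises(FormatError):
            ContactMatrix(np.array([[0, 1], [2, 0]]))
        with pytest.raises(FormatError):
            ContactMatrix(np.array([[0, -1], [-1, 0]]))

    def test_rejects_tiny(self):
        with pytest.raises(FormatError):
            ContactMatrix(np.array([[3.0]]))


class TestIO:
    def test_triplet_mirroring(self, tmp_path):
        p = tmp_path / "m.triplet"
        p.write_text("0\t1\t5\n")
        m = read_matrix(p, format="triplet", n_bins=2)
        np.testing.assert_array_equal(m.counts, [[0, 5], [5, 0]])

    def test_triplet_duplicates_summed(self, tmp_path):
        p = tmp_path / "m.triplet"
        p.write_text("0\t1\t2\n1\t0\t3\n0\t0\t1\n")
        m = read_matrix(p, format="triplet", n_bins=2)
        assert m.counts[0, 1] == 5 and m.counts[1, 0] == 5 and m.counts[0, 0] == 1

    def test_dense_write_read_byte_identical(self, tmp_path, random_symmetric):
        m = ContactMatrix(np.round(random_symmetric(5).counts))
        p1 = tmp_path / "a.txt"
        p2 = tmp_path / "b.txt"
        write_matrix(m, p1, format="dense")
        write_matrix(read_matrix(p1, format="dense"), p2, format="dense")
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("fmt", ["dense", "triplet", "binned_container"])
    def test_round_trip_all_formats(self, tmp_path, random_symmetric, fmt):
        m = ContactMatrix(np.round(random_symmetric(6).counts),
                          bin_size=50_000, chrom="chr7", allele="alleleA")
        p = tmp_path / "m.dat"
        write_matrix(m, p, format=fmt)
        back = read_matrix(p, format=fmt)
        np.testing.assert_allclose(back.counts, m.counts)
        assert (back.bin_size, back.chrom, back.allele) == (50_000, "chr7", "alleleA")

    def test_asymmetric_dense_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 5\n1 0\n")
        with pytest.raises(FormatError):
            read_matrix(p, format="dense")

    def test_negative_triplet_rejected(self, tmp_path):
        p = tmp_path / "bad.triplet"
        p.write_text("0\t1\t-2\n")
        with pytest.raises(FormatError):
            read_matrix(p, format="triplet")


class TestCoarsen:
    def test_factor_one_identity(self, random_symmetric):
        m = random_symmetric(5)
        np.testing.assert_array_equal(coarsen(m, 1).counts, m.counts)

    def test_block_of_ones(self):
        m = ContactMatrix(np.ones((4, 4)))
        out = coarsen(m, 2)
        np.testing.assert_array_equal(out.counts, np.full((2, 2), 4.0))
        assert out.bin_size == m.bin_size * 2

    def test_partial_block_conserves_totals(self, random_symmetric):
        m = random_symmetric(7)
        out = coarsen(m, 2)
        assert out.n_bins == 4
        # brute-force block sums
        for I in range(4):
            for J in range(4):
                block = m.counts[2 * I:2 * I + 2, 2 * J:2 * J + 2]
                assert out.counts[I, J] == pytest.approx(block.sum())
        assert out.total() == pytest.approx(m.total())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(3, 12), factor=st.integers(1, 5), seed=st.integers(0, 10 ** 6))
    def test_total_conservation_property(self, n, factor, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 20, size=(n, n))
        m = ContactMatrix(a + a.T)
        if -(-n // factor) < 2:
            with pytest.raises(ParameterError):
                coarsen(m, factor)
        else:
            assert coarsen(m, factor).total() == pytest.approx(m.total())


class TestKRBalance:
    def test_two_by_two(self):
        b = kr_balance(ContactMatrix(np.array([[0.0, 20], [20, 0]])),
                       min_row_sum=1)
        rs = np.nansum(b.values, axis=1)
        assert rs[0] == pytest.approx(rs[1])
        assert b.scaling[0] == pytest.approx(b.scaling[1])

    def test_already_balanced_unchanged(self):
        A = np.array([[1.0, 2, 3], [2, 3, 1], [3, 1, 2]]) * 10
        b = kr_balance(ContactMatrix(A), min_row_sum=1)
        x = b.scaling[b.mask]
        assert np.allclose(x, x[0], rtol=1e-4)
        np.testing.assert_allclose(b.values[b.mask][:, b.mask], A, rtol=1e-4)

    def test_matches_sinkhorn_oracle(self, random_symmetric):
        m = random_symmetric(6)
        b = kr_balance(m, tol=1e-10, min_row_sum=1)
        target = b.meta["row_sum_target"]
        ours = b.values / target
        oracle = sinkhorn_oracle(m.counts)
        np.testing.assert_allclose(ours, oracle, rtol=1e-6)

    def test_row_sum_cv_within_tol(self, random_symmetric):
        b = kr_balance(random_symmetric(30), tol=1e-8, min_row_sum=1)
        rs = np.nansum(b.values, axis=1)[b.mask]
        assert rs.std() / rs.mean() <= 1e-6

    def test_scaling_invariant_under_count_rescale(self, random_symmetric):
        m = random_symmetric(8)
        b1 = kr_balance(m, min_row_sum=1)
        b2 = kr_balance(ContactMatrix(m.counts * 7.0), min_row_sum=1)
        r = b1.scaling[b1.mask] / b2.scaling[b2.mask]
        assert np.allclose(r, r[0], rtol=1e-4)

    def test_low_coverage_bins_masked(self):
        A = np.array([[0.0, 50, 40, 0], [50, 0, 60, 0],
                      [40, 60, 0, 1], [0, 0, 1, 0]])
        b = kr_balance(ContactMatrix(A), min_row_sum=10)
        assert not b.mask[3]
        assert np.isnan(b.values[3]).all() and np.isnan(b.values[:, 3]).all()

    def test_fully_masked_raises(self):
        with pytest.raises(DegenerateInputError):
            kr_balance(ContactMatrix(np.array([[0.0, 1], [1, 0]])), min_row_sum=100)

    def test_nonconvergence_raises(self, random_symmetric):
        with pytest.raises(ConvergenceError) as err:
            kr_balance(random_symmetric(20), tol=1e-14, max_iter=1, min_row_sum=1)
        assert err.value.residual is not None


class TestSqrtVC:
    def test_small_example(self):
        b = sqrt_vc_balance(ContactMatrix(np.array([[0.0, 4], [4, 0]])))
        assert b.values[0, 1] == pytest.approx(1.0)

    def test_uniform_off_diagonal_equal(self):
        b = sqrt_vc_balance(ContactMatrix(np.full((4, 4), 3.0)))
        off = b.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_matches_direct_formula(self, random_symmetric):
        m = random_symmetric(5)
        b = sqrt_vc_balance(m)
        rowsum = m.counts.sum(axis=1)
        expected = m.counts / np.sqrt(np.outer(rowsum, rowsum))
        np.testing.assert_allclose(b.values, expected, rtol=1e-12)

    def test_zero_row_masked(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 4
        b = sqrt_vc_balance(ContactMatrix(A))
        assert not b.mask[2]


class TestPearsonCorrelation:
    def test_identical_rows_correlate_one(self, random_symmetric):
        m = random_symmetric(6)
        A = m.counts.copy()
        A[1] = A[0]
        A[:, 1] = A[:, 0]
        A[1, 1] = A[0, 0]
        b = sqrt_vc_balance(ContactMatrix((A + A.T) / 2))
        # make rows 0 and 1 of the balanced values identical directly
        b.values[1] = b.values[0]
        b.values[:, 1] = b.values[:, 0]
        c = pearson_correlation(b)
        assert c.values[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, random_symmetric):
        b = kr_balance(random_symmetric(8), min_row_sum=1)
        c = pearson_correlation(b)
        n = 8
        for i in range(n):
            for j in range(i + 1, n):
                cols = [k for k in range(n) if k not in (i, j)]
                xi = b.values[i, cols]
                xj = b.values[j, cols]
                expected = np.corrcoef(xi, xj)[0, 1]
                assert c.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_unit_diagonal(self, random_symmetric):
        c = pearson_correlation(kr_balance(random_symmetric(10), min_row_sum=1))
        np.testing.assert_allclose(c.values, c.values.T)
        assert np.allclose(np.diag(c.values)[c.mask], 1.0)
        v = c.values[~np.isnan(c.values)]
        assert v.min() >= -1 and v.max() <= 1

    def test_too_few_bins_raises(self):
        b = sqrt_vc_balance(ContactMatrix(np.array([[0.0, 4], [4, 0]])))
        with pytest.raises(DegenerateInputError):
            pearson_correlation(b)


def test_coarsen_rejects_bad_factor(random_symmetric):
    with pytest.raises(ParameterError):
        coarsen(random_symmetric(4), 0)
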