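"""Contact-matrix I/O, KR balancing, O/E, quantile normalization, SCC."""

import numpy as np
import pytest

from hicreg.matrix import (ContactMatrix, MatrixParseError, coarsen, kr_balance,
                           observed_expected, pool, quantile_normalize,
                           read_matrix, scc, write_matrix)
from hicreg.sim import Loop, SimConfig, simulate_contact_map

from conftest import tad_only_config


class TestIO:
    def test_round_trip_identity(self, tmp_path, rng):
        counts = rng.integers(0, 20, size=(12, 12)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix("chr1", 20_000, counts)
        p = tmp_path / "m.txt"
        write_matrix(m, p)
        m2 = read_matrix(p)
        assert m2.chrom == "chr1" and m2.resolution == 20_000
        np.testing.assert_array_equal(m.counts, m2.counts)
        # canonical re-write is byte identical
        p2 = tmp_path / "m2.txt"
        write_matrix(m2, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_empty_body_gives_zero_matrix(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("#chrZ,5000,10\n")
        m = read_matrix(p)
        assert m.n_bins == 10 and m.counts.sum() == 0

    def test_triplet_symmetrized(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("#c,1000,6\n2\t5\t7\n")
        m = read_matrix(p)
        assert m.counts[5, 2] == 7 and m.counts[2, 5] == 7

    @pytest.mark.parametrize("body,msg", [
        ("2\t5\t-3\n", "negative"),
        ("2\t11\t3\n", "out of range"),
        ("2\t5\n", "3 tab-separated"),
        ("a\tb\tc\n", "non-numeric"),
    ])
    def test_malformed_lines_carry_line_number(self, tmp_path, body, msg):
        p = tmp_path / "bad.txt"
        p.write_text("#c,1000,10\n" + body)
        with pytest.raises(MatrixParseError, match="line 2"):
            read_matrix(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0\t1\t2\n")
        with pytest.raises(MatrixParseError, match="line 1"):
            read_matrix(p)


class TestKR:
    def test_two_by_two_analytic(self):
        # balance equations give w = 1/sqrt(2) for [[0,2],[2,0]]
        m = ContactMatrix("c", 1, np.array([[0.0, 2.0], [2.0, 0.0]]))
        w = kr_balance(m, mask_quantile=0.0)
        np.testing.assert_allclose(w, 1 / np.sqrt(2), rtol=1e-8)

    def test_already_balanced_fixed_point(self):
        # doubly stochastic matrix: weights stay equal
        n = 8
        a = np.full((n, n), 1.0 / n)
        m = ContactMatrix("c", 1, a)
        w = kr_balance(m, mask_quantile=0.0)
        np.testing.assert_allclose(w, w[0], rtol=1e-6)
        rs = m.balanced().sum(axis=1)
        np.testing.assert_allclose(rs, 1.0, rtol=1e-6)

    def test_random_positive_row_sums(self, rng):
        a = rng.random((50, 50)) + 0.05
        a = a + a.T
        m = ContactMatrix("c", 1, a)
        kr_balance(m, tol=1e-10)
        rs = np.nansum(m.balanced(), axis=1)
        keep = ~m.masked_bins
        assert np.abs(rs[keep] - 1).max() < 1e-6
        assert m.balance_converged

    def test_idempotence(self, rng):
        a = rng.random((40, 40)) + 0.1
        a = a + a.T
        m = ContactMatrix("c", 1, a)
        kr_balance(m, tol=1e-10, mask_quantile=0.0)
        bal = ContactMatrix("c", 1, np.nan_to_num(m.balanced()))
        w2 = kr_balance(bal, tol=1e-10, mask_quantile=0.0)
        assert np.abs(w2 / w2[0] - 1).max() < 1e-6

    def test_zero_rows_masked(self):
        a = np.ones((6, 6))
        a[3, :] = 0
        a[:, 3] = 0
        m = ContactMatrix("c", 1, a)
        kr_balance(m, mask_quantile=0.0)
        assert m.masked_bins[3]
        assert not m.masked_bins[0]


class TestOE:
    def test_self_expected_profile_gives_unit_oe(self):
        n = 30
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        a = 1.0 / (1.0 + d)
        m = ContactMatrix("c", 1, a)
        m.balance_weights = np.ones(n)
        oe = observed_expected(m)
        vals = oe.values[np.isfinite(oe.values)]
        np.testing.assert_allclose(vals, 1.0, rtol=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.random((25, 25)) + 0.2
        a = a + a.T
        m1 = ContactMatrix("c", 1, a)
        m1.balance_weights = np.ones(25)
        m2 = ContactMatrix("c", 1, 2 * a)
        m2.balance_weights = np.ones(25)
        np.testing.assert_allclose(observed_expected(m1).values,
                                   observed_expected(m2).values)

    def test_per_distance_mean_is_one(self, balanced_tad_matrix):
        m, _ = balanced_tad_matrix
        oe = observed_expected(m)
        for d in (1, 5, 50):
            diag = np.diagonal(oe.values, d)
            assert abs(np.nanmean(diag) - 1.0) < 1e-9

    def test_planted_loop_oe_matches_fold(self):
        # fold-4 loop: O/E at the anchor pair ~ 4, Monte-Carlo over replicates
        loop = Loop(100, 160, 4.0)
        vals = []
        for r in range(20):
            cfg = SimConfig(loops=[loop], seed=77, dispersion=np.inf)
            m, _ = simulate_contact_map(cfg, 0, r)
            m.balance_weights = np.ones(m.n_bins)
            oe = observed_expected(m)
            vals.append(oe.values[100, 160])
        assert abs(np.mean(vals) - 4.0) < 0.5


class TestQuantileNormalize:
    def test_identical_inputs_unchanged(self, rng):
        a = rng.random((15, 15))
        a = a + a.T
        ms = [ContactMatrix("c", 1, a.copy()) for _ in range(3)]
        out = quantile_normalize(ms)
        for o in out:
            np.testing.assert_allclose(o.counts, a, rtol=1e-12)

    def test_two_sample_hand_example(self):
        # stratum values {1,2} and {10,20} -> both {5.5, 11} in rank order
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        a[1, 2] = a[2, 1] = 2
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = 10
        b[1, 2] = b[2, 1] = 20
        qa, qb = quantile_normalize([ContactMatrix("c", 1, a),
                                     ContactMatrix("c", 1, b)])
        assert qa.counts[0, 1] == 5.5 and qa.counts[1, 2] == 11.0
        assert qb.counts[0, 1] == 5.5 and qb.counts[1, 2] == 11.0

    def test_per_stratum_sorted_vectors_agree(self, rng):
        mats = []
        for _ in range(3):
            a = rng.random((20, 20)) * 10
            a = a + a.T
            mats.append(ContactMatrix("c", 1, a))
        out = quantile_normalize(mats)
        for d in range(1, 10):
            sorted_vecs = [np.sort(np.diagonal(o.counts, d)) for o in out]
            for v in sorted_vecs[1:]:
                np.testing.assert_allclose(v, sorted_vecs[0], rtol=1e-9)

    def test_shape_mismatch_rejected(self, rng):
        a = ContactMatrix("c", 1, np.ones((4, 4)))
        b = ContactMatrix("c", 1, np.ones((5, 5)))
        with pytest.raises(ValueError):
            quantile_normalize([a, b])


class TestSCC:
    def test_self_correlation_is_one(self, balanced_tad_matrix):
        m, _ = balanced_tad_matrix
        assert scc(m, m) == pytest.approx(1.0)

    def test_symmetry(self):
        c1, _ = simulate_contact_map(tad_only_config(1), 0, 0)
        c2, _ = simulate_contact_map(tad_only_config(1), 0, 1)
        assert scc(c1, c2) == pytest.approx(scc(c2, c1))

    def test_unrelated_matrices_near_zero(self):
        # decay only, nothing shared beyond it -> |scc| small
        a, _ = simulate_contact_map(SimConfig(seed=5), 0, 0)
        b, _ = simulate_contact_map(SimConfig(seed=6), 0, 0)
        assert abs(scc(a, b)) < 0.1

    def test_replicates_beat_different_truths(self):
        cfg_a = tad_only_config(21)
        cfg_b = SimConfig(tad_segments=[(70 + k * 42, 95 + k * 42, 3.0)
                                        for k in range(18)], seed=22)
        rep1, _ = simulate_contact_map(cfg_a, 0, 0)
        rep2, _ = simulate_contact_map(cfg_a, 0, 1)
        other, _ = simulate_contact_map(cfg_b, 0, 0)
        assert scc(rep1, rep2) > scc(rep1, other)


class TestHelpers:
    def test_coarsen_preserves_total(self, rng):
        a = rng.integers(0, 9, size=(10, 10)).astype(float)
        a = a + a.T
        m = ContactMatrix("c", 1000, a)
        c = coarsen(m, 3)
        assert c.resolution == 3000 and c.n_bins == 4
        assert c.counts.sum() == a.sum()

    def test_pool_sums_counts(self):
        m1 = ContactMatrix("c", 1, np.ones((4, 4)))
        m2 = ContactMatrix("c", 1, 2 * np.ones((4, 4)))
        p = pool([m1, m2])
        np.testing.assert_array_equal(p.counts, 3 * np.ones((4, 4)))
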