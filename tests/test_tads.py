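"""Directionality index, DI-HMM TAD calling, insulation refinement, and
condition-specific boundary testing."""

import numpy as np
import pytest

from hicreg.matrix import ContactMatrix, kr_balance, pool
from hicreg.sim import SimConfig, TadSegment, simulate_contact_map
from hicreg.tads import (Boundary, DIProfile, ISProfile, TAD,
                         boundary_null_distribution, call_tads_hmm, compute_di,
                         compute_is, di_context, refine_tads,
                         specific_boundary_analysis)
from hicreg.tads import test_boundary_specificity as check_boundary_specificity

from conftest import tad_only_config


def di_profile(values, res=20_000, window=10):
    v = np.asarray(values, dtype=float)
    return DIProfile(res, window, v, np.zeros_like(v), np.zeros_like(v))


class TestDI:
    def _matrix_with_sums(self, a_count, b_count, n=30, center=15):
        c = np.zeros((n, n))
        for j in range(center - 10, center):
            c[center, j] = c[j, center] = a_count / 10
        for j in range(center + 1, center + 11):
            c[center, j] = c[j, center] = b_count / 10
        return ContactMatrix("c", 20_000, c)

    def test_balanced_sums_give_zero(self):
        di = compute_di(self._matrix_with_sums(10, 10))
        assert di.di[15] == 0.0

    def test_downstream_only_gives_plus_ten(self):
        # A=0, B=10 -> E=5, DI = +(25/5 + 25/5) = +10
        di = compute_di(self._matrix_with_sums(0, 10))
        assert di.di[15] == pytest.approx(10.0)

    def test_upstream_only_gives_minus_ten(self):
        di = compute_di(self._matrix_with_sums(10, 0))
        assert di.di[15] == pytest.approx(-10.0)

    def test_antisymmetric_under_reflection(self):
        m, _ = simulate_contact_map(tad_only_config(1), 0, 0)
        di = compute_di(m)
        rev = ContactMatrix(m.chrom, m.resolution, m.counts[::-1, ::-1].copy())
        di_rev = compute_di(rev)
        fin = np.isfinite(di.di)
        np.testing.assert_allclose(di_rev.di[::-1][fin], -di.di[fin], atol=1e-9)

    def test_window_clipped_at_ends_masked(self):
        m, _ = simulate_contact_map(SimConfig(seed=0), 0, 0)
        di = compute_di(m, window=10)
        assert np.isnan(di.di[:10]).all() and np.isnan(di.di[-10:]).all()


class TestDIHMM:
    def test_alternating_blocks_recover_junctions(self):
        # +10/-10 blocks of 20 bins: threshold-segmentation oracle puts
        # boundaries at multiples of 40
        v = np.tile([10.0] * 20 + [-10.0] * 20, 5)
        tads, bounds = call_tads_hmm(di_profile(v), seed=0)
        expected = set(range(0, 201, 40))
        called = {b.bin for b in bounds}
        assert all(min(abs(b - e) for e in expected) <= 1 for b in called)
        assert all(min(abs(b - e) for b in called) <= 1 for e in expected if e < 200)
        for a, b in zip(tads, tads[1:]):  # tiling without overlap
            assert a.end_bin <= b.start_bin

    def test_constant_profile_yields_no_tads(self):
        tads, bounds = call_tads_hmm(di_profile(np.zeros(100)), seed=0)
        assert tads == [] and bounds == []

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="unmasked DI bins"):
            call_tads_hmm(di_profile(np.ones(20)), seed=0)

    def test_planted_boundary_recovery(self):
        cfg = tad_only_config(seed=13)
        m = pool([simulate_contact_map(cfg, 0, r)[0] for r in range(2)])
        kr_balance(m)
        di = compute_di(m)
        _, bounds = call_tads_hmm(di, seed=13)
        truth = np.array(sorted({b for t in cfg.tad_segments
                                 for b in (t.start_bin, t.end_bin)}))
        called = np.array(sorted({b.bin for b in bounds}))
        recall = np.mean([np.abs(called - t).min() <= 1 for t in truth])
        assert recall >= 0.8

    def test_boundary_count_invariant_to_scaling(self):
        cfg = tad_only_config(seed=14)
        m, _ = simulate_contact_map(cfg, 0, 0)
        kr_balance(m)
        di1 = compute_di(m)
        m2 = ContactMatrix(m.chrom, m.resolution, m.counts * 5)
        kr_balance(m2)
        di2 = compute_di(m2)
        _, b1 = call_tads_hmm(di1, seed=1)
        _, b2 = call_tads_hmm(di2, seed=1)
        assert {b.bin for b in b1} == {b.bin for b in b2}


class TestInsulation:
    def test_uniform_matrix_no_splits(self):
        n = 80
        m = ContactMatrix("c", 20_000, np.ones((n, n)))
        isp = compute_is(m)
        assert np.nanmax(np.abs(isp.is_norm)) < 1e-9
        tads = [TAD("c", 10, 70)]
        out, extra = refine_tads(tads, isp)
        assert out == tads and extra == []

    def test_planted_sub_boundary_splits_once(self):
        # two adjacent planted blocks inside one coarse domain: the shared
        # edge is an insulation minimum that splits the DI-level TAD
        segs = [TadSegment(100, 140, 3.0), TadSegment(140, 180, 3.0)]
        cfg = SimConfig(tad_segments=segs, seed=3)
        m = pool([simulate_contact_map(cfg, 0, r)[0] for r in range(2)])
        kr_balance(m)
        isp = compute_is(m)
        out, extra = refine_tads([TAD("c", 100, 180)], isp)
        assert len(out) == 2
        assert abs(out[0].end_bin - 140) <= 1

    def test_adjacent_tied_minima_take_leftmost(self):
        y = np.zeros(60)
        y[30] = y[31] = -1.0  # plateau of two equal minima
        isp = ISProfile(20_000, 10, np.ones(60), y)
        out, _ = refine_tads([TAD("c", 10, 50)], isp)
        assert out[0].end_bin == 30


class TestBoundarySpecificity:
    def test_identical_profiles_not_specific(self, balanced_tad_matrix):
        m, cfg = balanced_tad_matrix
        di = compute_di(m)
        b = Boundary(bin=100, source="DI-HMM")
        rng = np.random.default_rng(1)
        t = check_boundary_specificity(b, di, di, one_stage_only=True, rng=rng)
        assert t.rho_obs == pytest.approx(1.0)
        assert not t.specific

    def test_verdict_reproducible_bit_exact(self, balanced_tad_matrix):
        m, _ = balanced_tad_matrix
        di = compute_di(m)
        b = Boundary(bin=100, source="DI-HMM")
        r1 = check_boundary_specificity(b, di, di, True,
                                       rng=np.random.default_rng(42))
        r2 = check_boundary_specificity(b, di, di, True,
                                       rng=np.random.default_rng(42))
        assert (r1.rho_obs, r1.null_q95, r1.empirical_p) == \
               (r2.rho_obs, r2.null_q95, r2.empirical_p)

    def test_shared_boundary_never_specific(self, balanced_tad_matrix):
        m, _ = balanced_tad_matrix
        di = compute_di(m)
        b = Boundary(bin=100, source="DI-HMM")
        t = check_boundary_specificity(b, di, di, one_stage_only=False,
                                      rng=np.random.default_rng(0))
        assert not t.specific

    def test_redrawn_context_flagged(self, balanced_tad_matrix):
        # a boundary whose condition-2 DI context is unrelated noise loses
        # the cross-condition concordance and is flagged
        m, cfg = balanced_tad_matrix
        di1 = compute_di(m)
        di2 = DIProfile(di1.resolution, di1.window_bins, di1.di.copy(),
                        di1.a_up, di1.b_down)
        rng = np.random.default_rng(3)
        lo, hi = 90, 111
        di2.di[lo:hi] = rng.permutation(di2.di[lo:hi])
        t = check_boundary_specificity(Boundary(bin=100, source="DI-HMM"),
                                      di1, di2, one_stage_only=True,
                                      rng=np.random.default_rng(4))
        assert t.specific

    def test_null_two_stage_calibration(self):
        # same truth, fresh noise: flagged fraction within the 5% budget
        fracs, ns = [], []
        for seed in range(3):
            cfg = tad_only_config(seed)
            di, bounds = {}, {}
            for s in (0, 1):
                m = pool([simulate_contact_map(cfg, s, r)[0] for r in range(2)])
                kr_balance(m)
                di[s] = compute_di(m)
                _, bounds[s] = call_tads_hmm(di[s], seed=seed + 11 * s)
            rng = np.random.default_rng(seed + 500)
            tests, frac = specific_boundary_analysis(
                bounds[0], bounds[1], di[0], di[1], n_perm=1000, rng=rng)
            fracs.append(frac)
            ns.append(sum(t.testable for t in tests))
        mc_sd = np.sqrt(0.05 * 0.95 / np.mean(ns))
        assert np.mean(fracs) <= 0.05 + 3 * mc_sd

    def test_context_padding_at_ends(self, balanced_tad_matrix):
        m, _ = balanced_tad_matrix
        di = compute_di(m)
        ctx = di_context(di, 3)
        assert len(ctx) == 21
        assert np.isnan(ctx[:7]).all()  # bins < 0 and clipped window
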