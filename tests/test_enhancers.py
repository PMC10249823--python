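"""H3K27ac signal, ROSE stitching, super-enhancer inflection, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hicreg.enhancers import (StitchedEnhancer, call_super_enhancers,
                              classify_pei_anchors, gene_class_table,
                              read_bedgraph_binned, signal_track,
                              stitch_and_rank)
from hicreg.pei import PEIRecord


def flat(n, value=1.0):
    return np.full(n, value)


class TestSignalTrack:
    def test_equal_tracks_give_zero(self):
        t = signal_track(flat(100, 3.0), flat(100, 3.0))
        np.testing.assert_allclose(t.values, 0.0)

    def test_fourfold_mark_gives_two_with_zero_pseudocount(self):
        mark = flat(100, 1.0)
        mark[10] = 4.0
        inp = flat(100, 1.0)
        # FPKM renormalizes totals; compare against directly computed ratio
        t = signal_track(mark, inp, pseudocount=0.0)
        m_f = mark / (mark.sum() / 1e6)
        i_f = inp / (inp.sum() / 1e6)
        assert t.values[10] == pytest.approx(np.log2(m_f[10] / i_f[10]))

    def test_depth_invariance_bitwise(self):
        rng = np.random.default_rng(0)
        mark = rng.integers(1, 50, 200).astype(float)
        inp = rng.integers(1, 50, 200).astype(float)
        a = signal_track(mark, inp)
        b = signal_track(mark * 2, inp * 2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="different bin sets"):
            signal_track(flat(10), flat(12))


class TestStitching:
    def test_gap_under_rule_merges(self):
        st_ = stitch_and_rank([(0, 1000), (5000, 6000)], flat(50, 5), flat(50, 1))
        assert len(st_) == 1 and st_[0].interval == (0, 6000)

    def test_gap_exactly_12500_merges(self):
        st_ = stitch_and_rank([(0, 1000), (13500, 14500)], flat(50, 5), flat(50, 1))
        assert len(st_) == 1

    def test_gap_12501_does_not_merge(self):
        st_ = stitch_and_rank([(0, 1000), (13501, 14501)], flat(50, 5), flat(50, 1))
        assert len(st_) == 2

    def test_promoter_proximal_constituents_excluded(self):
        st_ = stitch_and_rank([(0, 1000), (5000, 6000)], flat(50, 5), flat(50, 1),
                              tss_positions=[500])
        assert len(st_) == 1 and st_[0].interval == (5000, 6000)

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(np.arange(0, 490_000, 1000), 30, replace=False))
        peaks = [(int(s), int(s) + 800) for s in starts]
        mark = rng.uniform(1, 20, 500)
        inp = flat(500, 1.0)
        once = stitch_and_rank(peaks, mark, inp)
        twice = stitch_and_rank(sorted(r.interval for r in once), mark, inp)
        assert sorted(r.interval for r in once) == sorted(r.interval for r in twice)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=400_000),
                    min_size=1, max_size=20))
    def test_merged_regions_separated_by_more_than_gap(self, starts):
        peaks = [(s, s + 500) for s in sorted(set(starts))]
        track = flat(401, 2.0)
        out = stitch_and_rank(peaks, track, flat(401, 1.0))
        for a, b in zip(out_sorted := sorted(out, key=lambda r: r.start),
                        out_sorted[1:]):
            assert b.start - a.end > 12_500


class TestSuperEnhancers:
    def _regions(self, signals):
        return [StitchedEnhancer(start=100_000 * k, end=100_000 * k + 1000,
                                 constituent_peaks=1, signal=float(s))
                for k, s in enumerate(signals)]

    @staticmethod
    def exhaustive_tangent_oracle(signals):
        """Brute-force scan of the scaled rank curve for the first slope > 1."""
        y = np.sort(np.asarray(signals, dtype=float))
        y = (y - y.min()) / (y.max() - y.min())
        x = np.arange(len(y)) / (len(y) - 1)
        for i in range(len(y) - 1):
            if (y[i + 1] - y[i]) / (x[i + 1] - x[i]) > 1:
                return len(y) - (i + 1)  # count above the inflection
        return 0

    def test_single_outlier_fixture(self):
        signals = [1.0] * 19 + [100.0]
        out = call_super_enhancers(self._regions(signals))
        n_se = sum(r.is_super for r in out)
        assert n_se == 1 == self.exhaustive_tangent_oracle(signals)
        assert [r.signal for r in out if r.is_super] == [100.0]

    def test_perfectly_linear_curve_yields_none(self):
        signals = list(range(20))  # scaled curve is exactly y = x
        out = call_super_enhancers(self._regions(signals))
        assert sum(r.is_super for r in out) == 0 == \
            self.exhaustive_tangent_oracle(signals)

    def test_matches_oracle_on_random_curves(self, rng):
        for _ in range(20):
            signals = rng.lognormal(0, 1.5, size=30)
            out = call_super_enhancers(self._regions(signals))
            assert sum(r.is_super for r in out) == \
                self.exhaustive_tangent_oracle(signals)

    def test_all_equal_signals_warns_and_flags_none(self):
        with pytest.warns(UserWarning, match="all stitched signals equal"):
            out = call_super_enhancers(self._regions([2.0] * 15))
        assert not any(r.is_super for r in out)

    def test_too_few_regions_warns(self):
        with pytest.warns(UserWarning, match="< 10"):
            out = call_super_enhancers(self._regions([1, 5, 9]))
        assert not any(r.is_super for r in out)


class TestClassification:
    def _stitched(self):
        se = StitchedEnhancer(10_000, 30_000, 3, 500.0, is_super=True)
        re_ = StitchedEnhancer(25_000, 26_000, 1, 50.0, is_super=False)
        re2 = StitchedEnhancer(60_000, 62_000, 1, 40.0, is_super=False)
        return [se, re_, re2]

    def _pei(self, distal_bin, gene="g", stage=""):
        return PEIRecord(gene_id=gene, distal_bin=distal_bin, distance=100_000,
                         observed=10.0, expected=2.0, fdr=0.01, stage=stage)

    def test_se_precedence_over_re(self):
        # bin 5 at 5 kb = [25000, 30000): overlaps both SE and RE -> SE
        peis = classify_pei_anchors([self._pei(5)], self._stitched(), 5000)
        assert peis[0].enhancer_class == "SE"

    def test_re_and_none_classes(self):
        peis = classify_pei_anchors([self._pei(12), self._pei(100)],
                                    self._stitched(), 5000)
        assert peis[0].enhancer_class == "RE"
        assert peis[1].enhancer_class == "nonE"

    def test_order_independence(self):
        a = classify_pei_anchors([self._pei(5), self._pei(12)], self._stitched(), 5000)
        b = classify_pei_anchors([self._pei(12), self._pei(5)], self._stitched(), 5000)
        assert {p.distal_bin: p.enhancer_class for p in a} == \
               {p.distal_bin: p.enhancer_class for p in b}

    def test_counts_match_brute_force_overlap(self, rng):
        stitched = self._stitched()
        peis = [self._pei(int(b)) for b in rng.integers(0, 120, size=100)]
        classify_pei_anchors(peis, stitched, 5000)
        for p in peis:
            lo, hi = p.distal_bin * 5000, p.distal_bin * 5000 + 5000
            hit_se = any(r.start < hi and r.end > lo
                         for r in stitched if r.is_super)
            hit_re = any(r.start < hi and r.end > lo
                         for r in stitched if not r.is_super)
            want = "SE" if hit_se else "RE" if hit_re else "nonE"
            assert p.enhancer_class == want

    def test_gene_transition_table(self):
        p1 = [self._pei(100, "gA", "0")]
        p2 = [self._pei(5, "gA", "1")]
        classify_pei_anchors(p1, self._stitched(), 5000)
        classify_pei_anchors(p2, self._stitched(), 5000)
        prof = gene_class_table(p1, p2)[0]
        assert prof.transition == "nonE->SE"


class TestBedGraph:
    def test_round_trip_coverage(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t2000\t5\nchr1\t2000\t2500\t10\nchr2\t0\t1000\t99\n")
        v = read_bedgraph_binned(p, "chr1", 3000)
        assert v[0] == 5 and v[1] == 5
        assert v[2] == pytest.approx(5.0)  # 500 bp at 10 over a 1 kb bin
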