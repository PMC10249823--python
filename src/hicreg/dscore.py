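"""Intra-TAD strength (D-score) and its differential test.

The D-score of a TAD in one replicate is the fraction of that TAD's cis
contacts staying inside the TAD: intra-TAD contacts divided by all
contacts with at least one end in the TAD (diagonal counted once); it
lies in [0, 1] and is invariant to global count scaling. Differential
strength between two conditions follows a two-rule call on the
consensus TAD set: an equal-variance two-sample t-test on per-replicate
D-scores (p < 0.05) combined with the top-5% absolute difference of
stage means, which caps the flagged fraction at 5% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from hicreg.matrix import ContactMatrix
from hicreg.tads import TAD

__all__ = [
    "DScoreRecord",
    "compute_dscore",
    "consensus_tads",
    "test_differential_dscore",
]


def compute_dscore(m: ContactMatrix, tad: TAD) -> float:
    """D-score of one TAD in one matrix; NaN when the TAD has no contacts.

    Uses balanced counts when available, raw otherwise; cis-only by
    construction (per-chromosome matrices). Each unordered bin pair
    contributes once and the diagonal once.
    """
    if tad.end_bin > m.n_bins or tad.start_bin < 0:
        raise ValueError("TAD outside the matrix")
    C = m.balanced() if m.balance_weights is not None else m.counts.astype(float)
    C = np.nan_to_num(C)
    sl = slice(tad.start_bin, tad.end_bin)
    block_sum = C[sl, sl].sum()
    diag_sum = np.diagonal(C[sl, sl]).sum()
    intra = (block_sum + diag_sum) / 2.0
    rows = C[sl, :].sum()
    touching = rows - (block_sum - diag_sum) / 2.0
    if touching <= 0:
        return float("nan")
    return float(intra / touching)


def consensus_tads(tads1: list[TAD], tads2: list[TAD],
                   min_reciprocal: float = 0.8) -> list[TAD]:
    """TADs of condition 1 matched by >= ``min_reciprocal`` reciprocal
    overlap with a condition-2 TAD; unmatched TADs are dropped."""
    out = []
    for t1 in tads1:
        for t2 in tads2:
            lo = max(t1.start_bin, t2.start_bin)
            hi = min(t1.end_bin, t2.end_bin)
            ov = hi - lo
            if ov <= 0:
                continue
            if ov >= min_reciprocal * t1.n_bins and ov >= min_reciprocal * t2.n_bins:
                out.append(TAD(t1.chrom, t1.start_bin, t1.end_bin, stage="consensus"))
                break
    return out


@dataclass
class DScoreRecord:
    tad: TAD
    d_stage1: list[float]
    d_stage2: list[float]
    mean_stage1: float = field(init=False)
    mean_stage2: float = field(init=False)
    delta: float = field(init=False)
    p_value: float = float("nan")
    is_differential: bool = False

    def __post_init__(self):
        self.mean_stage1 = float(np.mean(self.d_stage1))
        self.mean_stage2 = float(np.mean(self.d_stage2))
        self.delta = self.mean_stage2 - self.mean_stage1


def test_differential_dscore(tads: list[TAD],
                             mats_stage1: list[ContactMatrix],
                             mats_stage2: list[ContactMatrix],
                             alpha: float = 0.05,
                             top_delta: float = 0.05,
                             equal_var: bool = True
                             ) -> tuple[list[DScoreRecord], float]:
    """Differential intra-TAD strength over a consensus TAD set.

    Per TAD: per-replicate D-scores in each condition, an equal-variance
    (Student) two-sample t-test, and delta = mean(stage2) - mean(stage1).
    A TAD is differential iff p < ``alpha`` and |delta| is at or above
    the (1 - ``top_delta``) quantile of |delta| over all consensus TADs.
    Degenerate variance: equal means give p = 1; unequal means with zero
    pooled variance give p = 0 (the equal-variance t statistic diverges).
    Returns the records and the flagged fraction.
    """
    records: list[DScoreRecord] = []
    for tad in tads:
        d1 = [compute_dscore(m, tad) for m in mats_stage1]
        d2 = [compute_dscore(m, tad) for m in mats_stage2]
        if any(np.isnan(d1)) or any(np.isnan(d2)):
            continue
        rec = DScoreRecord(tad, d1, d2)
        if np.var(d1) == 0 and np.var(d2) == 0:
            rec.p_value = 1.0 if rec.mean_stage1 == rec.mean_stage2 else 0.0
        else:
            res = stats.ttest_ind(d2, d1, equal_var=equal_var)
            rec.p_value = float(res.pvalue)
        records.append(rec)
    if not records:
        return records, float("nan")
    abs_deltas = np.abs([r.delta for r in records])
    cutoff = float(np.quantile(abs_deltas, 1.0 - top_delta))
    for r in records:
        r.is_differential = bool(r.p_value < alpha and abs(r.delta) >= cutoff and cutoff > 0)
    frac = sum(r.is_differential for r in records) / len(records)
    return records, frac
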