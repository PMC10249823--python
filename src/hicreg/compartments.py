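"""A/B compartment calling at two resolutions, consensus and switch detection.

Coarse (100 kb) compartments come from PC1 of the Pearson-correlation
matrix of the O/E contact matrix, sign-oriented against a genomic
orientation track (gene density or GC content) so that positive PC1
means compartment A. Fine (20 kb) compartments use the A-B index: for
each fine bin, the median log2 O/E contact with coarse-A regions minus
the median with coarse-B regions; positive means A.

Switches between two conditions are called on replicate-consensus
labels only: a bin is eligible when all replicates of both conditions
agree internally, and a switch is an eligible bin whose consensus labels
differ between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from hicreg.matrix import ContactMatrix, OEMatrix, coarsen, kr_balance, observed_expected

__all__ = [
    "CompartmentTrack",
    "SwitchCall",
    "call_pc1",
    "call_ab_index",
    "call_switches",
    "compartment_pipeline",
]

LOG2_FLOOR = -10.0  # numerical floor for log2 O/E of unobserved pairs


@dataclass
class CompartmentTrack:
    """Per-bin compartment score and A/B label for one sample at one resolution."""

    resolution: int
    score: np.ndarray  # PC1 (coarse) or A-B index (fine); NaN on masked bins
    labels: np.ndarray  # 'A' | 'B' | '' (masked)
    sample: str = ""
    low_confidence: bool = field(default=False, compare=False)

    @property
    def n_bins(self) -> int:
        return len(self.score)


@dataclass(frozen=True)
class SwitchCall:
    bin: int
    status_stage1: str
    status_stage2: str

    @property
    def is_switch(self) -> bool:
        return self.status_stage1 != self.status_stage2


def call_pc1(oe: OEMatrix, orientation_track: np.ndarray, sample: str = "",
             min_orientation_r: float = 0.1) -> CompartmentTrack:
    """PC1 compartment call on a coarse-resolution O/E matrix.

    PC1 is the first principal component of the Pearson-correlation
    matrix of O/E; the sign is flipped, if needed, so that Spearman
    correlation with ``orientation_track`` is positive, and positive PC1
    is labeled A. A weak orientation correlation (|rho| below
    ``min_orientation_r``) keeps the labels but flags the track
    low-confidence, as happens on chromosomes where PC1 tracks arm
    structure rather than compartments.
    """
    n = oe.n_bins
    vals = oe.values
    finite_frac = np.isfinite(vals).mean(axis=1)
    keep = finite_frac > 0.5
    score = np.full(n, np.nan)
    labels = np.array([""] * n, dtype=object)
    if keep.sum() < 3:
        return CompartmentTrack(oe.resolution, score, labels, sample, low_confidence=True)
    sub = np.nan_to_num(vals[np.ix_(keep, keep)], nan=1.0)
    row_sd = sub.std(axis=1)
    nondeg = row_sd > 1e-12
    if nondeg.sum() < 3:
        return CompartmentTrack(oe.resolution, score, labels, sample, low_confidence=True)
    keep_idx = np.flatnonzero(keep)[nondeg]
    sub = sub[np.ix_(nondeg, nondeg)]
    corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr)
    X = corr - corr.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    pc1 = X @ vt[0]
    orient = np.asarray(orientation_track, dtype=float)[keep_idx]
    ok = np.isfinite(orient) & np.isfinite(pc1)
    rho = stats.spearmanr(pc1[ok], orient[ok]).statistic if ok.sum() >= 3 else np.nan
    low_conf = (not np.isfinite(rho)) or abs(rho) < min_orientation_r
    if np.isfinite(rho) and rho < 0:
        pc1 = -pc1
    score[keep_idx] = pc1
    labels[keep_idx[pc1 > 0]] = "A"
    labels[keep_idx[pc1 < 0]] = "B"
    return CompartmentTrack(oe.resolution, score, labels, sample, low_confidence=low_conf)


def call_ab_index(oe_fine: OEMatrix, coarse_track: CompartmentTrack,
                  sample: str = "", min_targets: int = 10,
                  min_gap_bins: int = 2) -> CompartmentTrack:
    """A-B index compartment call on a fine-resolution O/E matrix.

    For each fine bin the A (resp. B) score is the median log2 O/E over
    fine bins lying inside coarse A (resp. B) compartments, excluding
    near-diagonal pairs (gap < ``min_gap_bins``); the A-B index is their
    difference. Bins with fewer than ``min_targets`` usable A or B
    targets, or an index of exactly 0, are masked. Unobserved pairs
    (O/E = 0) enter the medians at a fixed log2 floor.
    """
    n = oe_fine.n_bins
    factor = coarse_track.resolution // oe_fine.resolution
    if factor < 1:
        raise ValueError("coarse track must be at coarser or equal resolution")
    fine_labels_100k = np.repeat(np.asarray(coarse_track.labels, dtype=object), factor)[:n]
    a_targets = fine_labels_100k == "A"
    b_targets = fine_labels_100k == "B"
    vals = oe_fine.values
    with np.errstate(divide="ignore"):
        logv = np.where(np.isfinite(vals), np.log2(np.maximum(vals, 2.0 ** LOG2_FLOOR)), np.nan)
    score = np.full(n, np.nan)
    labels = np.array([""] * n, dtype=object)
    gaps = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    near = gaps < min_gap_bins
    logv = np.where(near, np.nan, logv)
    for i in range(n):
        row = logv[i]
        av = row[a_targets & np.isfinite(row)]
        bv = row[b_targets & np.isfinite(row)]
        if len(av) < min_targets or len(bv) < min_targets:
            continue
        ab = float(np.median(av) - np.median(bv))
        score[i] = ab
        if ab > 0:
            labels[i] = "A"
        elif ab < 0:
            labels[i] = "B"
        else:
            score[i] = np.nan  # exact tie: masked, no label
    return CompartmentTrack(oe_fine.resolution, score, labels, sample,
                            low_confidence=coarse_track.low_confidence)


def call_switches(tracks_stage1: list[CompartmentTrack],
                  tracks_stage2: list[CompartmentTrack]
                  ) -> tuple[list[SwitchCall], float]:
    """Replicate-consensus A/B switch calls between two conditions.

    Consensus per condition requires unanimous replicate labels; bins
    lacking consensus in either condition are ineligible. Returns the
    per-eligible-bin calls and the fraction of eligible bins switching.
    A single replicate degenerates to that replicate's labels (warned).
    """
    import warnings

    for tracks, name in ((tracks_stage1, "stage1"), (tracks_stage2, "stage2")):
        if not tracks:
            raise ValueError(f"{name}: no replicate tracks")
        if len(tracks) == 1:
            warnings.warn(f"{name}: single replicate; consensus degenerates to that replicate")
    n = tracks_stage1[0].n_bins

    def consensus(tracks: list[CompartmentTrack]) -> np.ndarray:
        labs = np.stack([np.asarray(t.labels, dtype=object) for t in tracks])
        out = np.array([""] * n, dtype=object)
        unanimous = (labs == labs[0]).all(axis=0) & (labs[0] != "")
        out[unanimous] = labs[0][unanimous]
        return out

    c1, c2 = consensus(tracks_stage1), consensus(tracks_stage2)
    eligible = (c1 != "") & (c2 != "")
    calls = [SwitchCall(bin=int(i), status_stage1=str(c1[i]), status_stage2=str(c2[i]))
             for i in np.flatnonzero(eligible)]
    n_eligible = int(eligible.sum())
    frac = sum(c.is_switch for c in calls) / n_eligible if n_eligible else float("nan")
    return calls, frac


def compartment_pipeline(m_fine: ContactMatrix, orientation_track: np.ndarray,
                         sample: str = "", coarse_res: int = 100_000
                         ) -> tuple[CompartmentTrack, CompartmentTrack]:
    """Coarse PC1 + fine A-B index calls from one fine-resolution raw matrix.

    Coarsens to ``coarse_res``, KR-balances both resolutions, computes
    O/E, and returns (coarse_track, fine_track). ``orientation_track``
    is per-coarse-bin gene density or GC content.
    """
    factor = coarse_res // m_fine.resolution
    m_coarse = coarsen(m_fine, factor)
    kr_balance(m_coarse)
    oe_coarse = observed_expected(m_coarse)
    coarse = call_pc1(oe_coarse, orientation_track, sample=sample)
    if m_fine.balance_weights is None:
        kr_balance(m_fine)
    oe_fine = observed_expected(m_fine)
    fine = call_ab_index(oe_fine, coarse, sample=sample)
    return coarse, fine
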