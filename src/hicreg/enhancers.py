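"""H3K27ac signal, ROSE-style stitching, super-enhancer calling and
PEI distal-anchor classification.

The signal track is log2(mark FPKM / input FPKM) per 1 kb bin with a
pseudocount on both terms, so it is invariant to sequencing depth.
Enhancer peaks within 12.5 kb of each other (inclusive) are stitched
into candidate regions after dropping promoter-proximal constituents
(+/-2 kb of any TSS); stitched regions are ranked by input-subtracted
mark signal, both axes are min-max scaled to [0, 1], and the
super-enhancer cutoff is the first rank where the discrete slope of the
scaled rank-signal curve exceeds 1 — regions above it are SEs, the rest
regular enhancers (REs). A PEI's distal anchor is classified SE if its
bin overlaps any SE by >= 1 bp, else RE if it overlaps a stitched RE,
else non-E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hicreg.pei import PEIRecord

__all__ = [
    "SignalTrack",
    "StitchedEnhancer",
    "GeneEnhancerProfile",
    "read_bedgraph_binned",
    "signal_track",
    "stitch_and_rank",
    "call_super_enhancers",
    "classify_pei_anchors",
    "gene_class_table",
]

STITCH_GAP = 12_500  # bp, inclusive merge rule
PROMOTER_EXCLUSION = 2_000  # bp around TSS
TRACK_BIN = 1000


def read_bedgraph_binned(path, chrom: str, chrom_length: int,
                         bin_size: int = TRACK_BIN) -> np.ndarray:
    """Read a bedGraph and return per-bin summed coverage for one chromosome."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    df = df[df["chrom"] == chrom]
    n = -(-chrom_length // bin_size)
    out = np.zeros(n)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        b0, b1 = int(start) // bin_size, -(-int(end) // bin_size)
        for b in range(b0, min(b1, n)):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            out[b] += value * (hi - lo) / bin_size
    return out


@dataclass
class SignalTrack:
    """log2(mark FPKM / input FPKM) per 1 kb bin."""

    values: np.ndarray
    bin_size: int = TRACK_BIN
    chrom: str = ""


def _fpkm(reads: np.ndarray, bin_size: int) -> np.ndarray:
    total = reads.sum()
    if total <= 0:
        raise ValueError("track has no coverage")
    return reads / (bin_size / 1000.0) / (total / 1e6)


def signal_track(mark: np.ndarray, input_: np.ndarray, pseudocount: float = 0.5,
                 bin_size: int = TRACK_BIN, chrom: str = "") -> SignalTrack:
    """Depth-invariant mark-over-input log ratio per bin.

    Both tracks are FPKM-normalized, a pseudocount is added to numerator
    and denominator, and the log2 ratio is taken; scaling either
    library's depth leaves the track unchanged bit-for-bit.
    """
    if len(mark) != len(input_):
        raise ValueError("mark and input tracks cover different bin sets")
    m = _fpkm(np.asarray(mark, dtype=float), bin_size)
    i = _fpkm(np.asarray(input_, dtype=float), bin_size)
    return SignalTrack(values=np.log2((m + pseudocount) / (i + pseudocount)),
                       bin_size=bin_size, chrom=chrom)


@dataclass
class StitchedEnhancer:
    start: int
    end: int
    constituent_peaks: int
    signal: float  # summed mark-minus-input FPKM over constituents
    rank: int = -1  # ascending by signal
    is_super: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def stitch_and_rank(peaks: list[tuple[int, int]], mark: np.ndarray,
                    input_: np.ndarray, tss_positions: list[int] | None = None,
                    gap: int = STITCH_GAP, bin_size: int = TRACK_BIN
                    ) -> list[StitchedEnhancer]:
    """Single-linkage stitch of enhancer peaks and signal ranking.

    Peaks with inter-peak gap <= ``gap`` bp merge into one region (the
    12.5 kb rule is inclusive at exactly 12,500). Constituents within
    +/-2 kb of a TSS are excluded before stitching. Signal is the
    constituent-summed (mark - input) FPKM; regions are returned sorted
    ascending with ranks assigned.
    """
    original = [(int(s), int(e)) for s, e in peaks]
    peaks = sorted(original)
    if peaks != original:
        warnings.warn("peaks were unsorted; sorted internally")
    if tss_positions:
        kept = []
        for s, e in peaks:
            if any(s < t + PROMOTER_EXCLUSION and e > t - PROMOTER_EXCLUSION
                   for t in tss_positions):
                continue
            kept.append((s, e))
        peaks = kept
    if not peaks:
        return []
    mark_f = _fpkm(np.asarray(mark, dtype=float), bin_size)
    input_f = _fpkm(np.asarray(input_, dtype=float), bin_size)
    diff = mark_f - input_f

    def peak_signal(s: int, e: int) -> float:
        b0, b1 = s // bin_size, -(-e // bin_size)
        total = 0.0
        for b in range(b0, min(b1, len(diff))):
            lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
            total += diff[b] * (hi - lo) / bin_size
        return total

    merged: list[list] = []
    for s, e in peaks:
        sig = peak_signal(s, e)
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += 1
            merged[-1][3] += sig
        else:
            merged.append([s, e, 1, sig])
    out = [StitchedEnhancer(start=s, end=e, constituent_peaks=c, signal=sig)
           for s, e, c, sig in merged]
    out.sort(key=lambda r: (r.signal, r.start))
    for k, r in enumerate(out):
        r.rank = k
    return out


def call_super_enhancers(stitched: list[StitchedEnhancer],
                         min_regions: int = 10) -> list[StitchedEnhancer]:
    """Flag super-enhancers above the rank-signal inflection point.

    Ranks and signals are min-max scaled to [0, 1]; the cutoff is the
    first rank where the discrete tangent slope of the scaled curve
    exceeds 1 (strict, so a perfectly linear curve yields no SEs).
    All-equal signals yield no SEs, with a warning.
    """
    regions = sorted(stitched, key=lambda r: (r.signal, r.start))
    for r in regions:
        r.is_super = False
    n = len(regions)
    if n < min_regions:
        warnings.warn(f"only {n} stitched regions (< {min_regions}); no SEs called")
        return regions
    sig = np.array([r.signal for r in regions], dtype=float)
    if sig.max() == sig.min():
        warnings.warn("all stitched signals equal; no inflection, no SEs")
        return regions
    x = np.arange(n) / (n - 1)
    y = (sig - sig.min()) / (sig.max() - sig.min())
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes > 1.0)
    if above.size == 0:
        return regions
    cutoff = above[0] + 1  # first rank past the inflection
    for r in regions[cutoff:]:
        r.is_super = True
    return regions


def classify_pei_anchors(peis: list[PEIRecord], stitched: list[StitchedEnhancer],
                         resolution: int) -> list[PEIRecord]:
    """Assign each PEI's distal bin an enhancer class (SE > RE > non-E).

    The distal bin interval [bin*res, (bin+1)*res) is intersected with
    the stitched regions; any >= 1 bp overlap with an SE wins, then RE,
    else non-E. Deterministic and independent of record order.
    """
    from intervaltree import IntervalTree

    se_tree, re_tree = IntervalTree(), IntervalTree()
    for r in stitched:
        if r.end > r.start:
            (se_tree if r.is_super else re_tree)[r.start:r.end] = True
    for p in peis:
        lo = p.distal_bin * resolution
        hi = lo + resolution
        if se_tree.overlap(lo, hi):
            p.enhancer_class = "SE"
        elif re_tree.overlap(lo, hi):
            p.enhancer_class = "RE"
        else:
            p.enhancer_class = "nonE"
    return peis


CLASS_PRECEDENCE = ("SE", "RE", "nonE")


@dataclass
class GeneEnhancerProfile:
    gene_id: str
    counts_stage1: dict = field(default_factory=dict)
    counts_stage2: dict = field(default_factory=dict)
    dominant_stage1: str = "none"
    dominant_stage2: str = "none"

    @property
    def transition(self) -> str:
        return f"{self.dominant_stage1}->{self.dominant_stage2}"


def _dominant(counts: dict) -> str:
    for cls in CLASS_PRECEDENCE:
        if counts.get(cls, 0) > 0:
            return cls
    return "none"


def gene_class_table(peis_stage1: list[PEIRecord], peis_stage2: list[PEIRecord]
                     ) -> list[GeneEnhancerProfile]:
    """Per-gene enhancer-class counts by condition and the dominant-class
    transition (the alluvial-plot input)."""
    genes: dict[str, GeneEnhancerProfile] = {}
    for peis, attr in ((peis_stage1, "counts_stage1"), (peis_stage2, "counts_stage2")):
        for p in peis:
            prof = genes.setdefault(p.gene_id, GeneEnhancerProfile(p.gene_id))
            d = getattr(prof, attr)
            d[p.enhancer_class or "nonE"] = d.get(p.enhancer_class or "nonE", 0) + 1
    for prof in genes.values():
        prof.dominant_stage1 = _dominant(prof.counts_stage1)
        prof.dominant_stage2 = _dominant(prof.counts_stage2)
    return sorted(genes.values(), key=lambda g: g.gene_id)
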