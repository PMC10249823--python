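"""Synthetic Hi-C generator with planted regulatory architecture.

Emulates a two-condition ("stage"), multi-replicate cis Hi-C experiment
on a single desk-scale chromosome. The expected contact count between
bins i and j is a power-law distance decay modulated by planted
structure::

    E[c_ij] ~ (max(|i-j|, 1) * res)^(-decay_exponent)
              * tad_fold(i, j, stage)
              * compartment_factor(i, j, stage)
              * loop_fold(i, j, stage)

scaled so the expected total equals ``library_size``, then sampled with
negative-binomial noise (variance = mu + mu^2/dispersion; infinite
dispersion degenerates to Poisson). Stage perturbations are fold
multipliers on planted objects: a loop can be present in one stage only,
a TAD can change intra-fold between stages, a compartment block can flip
label. Every simulated object is recorded in a :class:`SyntheticTruth`
that serializes losslessly to JSON, so downstream callers can be scored
for recovery.

Companion files (gene models, H3K27ac mark/input tracks, peak calls,
expression table) are generated to match the planted loops and enhancer
classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from hicreg.matrix import ContactMatrix

__all__ = [
    "Loop",
    "TadSegment",
    "CompartmentBlock",
    "SimConfig",
    "SyntheticTruth",
    "simulate_contact_map",
    "simulate_companion_tracks",
    "CompanionTracks",
]

COARSE_RES = 100_000  # compartment-truth bookkeeping resolution


@dataclass(frozen=True)
class Loop:
    """A planted point interaction between a promoter bin and a distal bin.

    ``stages`` lists the stages in which the loop is present;
    ``enhancer_class`` controls what the companion tracks plant at the
    distal anchor (a super-enhancer, a regular enhancer, or nothing).
    """

    promoter_bin: int
    distal_bin: int
    fold: float
    stages: tuple[int, ...] = (0, 1)
    enhancer_class: str = "RE"  # SE | RE | nonE

    def active(self, stage: int) -> bool:
        return stage in self.stages


@dataclass(frozen=True)
class TadSegment:
    """A planted self-interacting block, [start_bin, end_bin)."""

    start_bin: int
    end_bin: int
    intra_fold: float
    stage_folds: tuple[tuple[int, float], ...] = ()  # (stage, fold) overrides

    def fold(self, stage: int) -> float:
        for s, f in self.stage_folds:
            if s == stage:
                return f
        return self.intra_fold


@dataclass(frozen=True)
class CompartmentBlock:
    """A planted compartment block with label A or B, [start_bin, end_bin)."""

    start_bin: int
    end_bin: int
    label: str  # A | B
    flip_stages: tuple[int, ...] = ()  # stages in which the label is inverted

    def label_at(self, stage: int) -> str:
        if stage in self.flip_stages:
            return "B" if self.label == "A" else "A"
        return self.label


@dataclass
class SimConfig:
    """Full description of one simulated chromosome.

    Defaults describe the desk-scale condition used throughout: a 20 Mb
    chromosome binned at 20 kb (1000 bins), decay exponent 1, two stages
    with overdispersed replicate noise.
    """

    chrom_length: int = 20_000_000
    resolution: int = 20_000
    decay_exponent: float = 1.0
    tad_segments: list[TadSegment] = field(default_factory=list)
    compartment_blocks: list[CompartmentBlock] = field(default_factory=list)
    compartment_strength: float = 1.0
    loops: list[Loop] = field(default_factory=list)
    n_replicates_per_stage: int = 2
    n_stages: int = 2
    library_size: float = 5_000_000
    dispersion: float = 20.0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.resolution <= 0:
            raise ValueError("chrom_length and resolution must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        self.tad_segments = [t if isinstance(t, TadSegment) else TadSegment(*t)
                             for t in self.tad_segments]
        self.compartment_blocks = [c if isinstance(c, CompartmentBlock) else CompartmentBlock(*c)
                                   for c in self.compartment_blocks]
        self.loops = [l if isinstance(l, Loop) else Loop(*l) for l in self.loops]
        for group, name in ((self.tad_segments, "tad_segments"),
                            (self.compartment_blocks, "compartment_blocks")):
            prev_end = -1
            for seg in sorted(group, key=lambda s: s.start_bin):
                if seg.start_bin < 0 or seg.end_bin > self.n_bins or seg.end_bin <= seg.start_bin:
                    raise ValueError(f"{name}: segment {seg} outside chromosome or empty")
                if seg.start_bin < prev_end:
                    raise ValueError(f"{name}: overlapping segments at bin {seg.start_bin}")
                prev_end = seg.end_bin
        self.tad_segments.sort(key=lambda s: s.start_bin)
        self.compartment_blocks.sort(key=lambda s: s.start_bin)
        for t in self.tad_segments:
            if t.intra_fold < 1 or any(f < 1 for _, f in t.stage_folds):
                raise ValueError("TAD intra_fold values must be >= 1")
        if self.compartment_strength < 1:
            raise ValueError("compartment_strength must be >= 1")
        for l in self.loops:
            if not (0 <= l.promoter_bin < self.n_bins and 0 <= l.distal_bin < self.n_bins):
                raise ValueError(f"loop {l} outside chromosome")
            if l.fold < 1:
                raise ValueError("loop fold must be >= 1")

    @property
    def n_bins(self) -> int:
        # last partial bin, if any, is a real (shorter) bin
        return -(-self.chrom_length // self.resolution)

    def fine_labels(self, stage: int) -> list[str]:
        """Per-sim-bin compartment label at a stage ('' where unlabeled)."""
        labels = [""] * self.n_bins
        for blk in self.compartment_blocks:
            lab = blk.label_at(stage)
            for b in range(blk.start_bin, blk.end_bin):
                labels[b] = lab
        return labels


@dataclass
class SyntheticTruth:
    """Planted architecture of one simulation, serializable to JSON."""

    chrom: str
    resolution: int
    n_bins: int
    compartment_labels: dict  # stage(str) -> per-100kb-bin label list
    compartment_labels_fine: dict  # stage(str) -> per-sim-bin label list
    tad_boundaries: dict  # stage(str) -> sorted bin indices
    loop_anchors: list  # (promoter_bin, distal_bin, [stages], class)
    enhancer_intervals: list  # (start_bp, end_bp, class SE|RE)
    expression_effects: dict  # gene_id -> per-stage fold list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _coarse_labels(fine: list[str], resolution: int) -> list[str]:
    """Majority label per 100 kb bin; '' when no labeled fine bin."""
    per = max(1, COARSE_RES // resolution)
    out = []
    for start in range(0, len(fine), per):
        chunk = fine[start:start + per]
        a = sum(1 for c in chunk if c == "A")
        b = sum(1 for c in chunk if c == "B")
        out.append("A" if a > b else "B" if b > a else "")
    return out


def build_truth(config: SimConfig) -> SyntheticTruth:
    """Assemble the ground-truth record implied by a configuration."""
    comp, comp_fine, bounds = {}, {}, {}
    for stage in range(config.n_stages):
        fine = config.fine_labels(stage)
        comp_fine[str(stage)] = fine
        comp[str(stage)] = _coarse_labels(fine, config.resolution)
        b = set()
        for seg in config.tad_segments:
            if seg.fold(stage) > 1:
                b.add(seg.start_bin)
                b.add(seg.end_bin)
        bounds[str(stage)] = sorted(b)
    enh = []
    for k, loop in enumerate(config.loops):
        if loop.enhancer_class in ("SE", "RE"):
            center = loop.distal_bin * config.resolution + config.resolution // 2
            half = 6000 if loop.enhancer_class == "SE" else 500
            enh.append([max(0, center - half), min(config.chrom_length, center + half),
                        loop.enhancer_class])
    expr = {}
    for k, loop in enumerate(config.loops):
        folds = [2.0 if loop.active(s) else 1.0 for s in range(config.n_stages)]
        expr[f"gene_{k}"] = folds
    return SyntheticTruth(
        chrom=config.chrom, resolution=config.resolution, n_bins=config.n_bins,
        compartment_labels=comp, compartment_labels_fine=comp_fine,
        tad_boundaries=bounds,
        loop_anchors=[[l.promoter_bin, l.distal_bin, list(l.stages), l.enhancer_class]
                      for l in config.loops],
        enhancer_intervals=enh, expression_effects=expr)


def expected_matrix(config: SimConfig, stage: int) -> np.ndarray:
    """Noise-free expected contact matrix for one stage, scaled to library_size."""
    n = config.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    base = (np.maximum(d, 1) * config.resolution) ** (-config.decay_exponent)
    E = base.astype(float)
    for seg in config.tad_segments:
        f = seg.fold(stage)
        if f != 1:
            sl = slice(seg.start_bin, seg.end_bin)
            E[sl, sl] *= f
    if config.compartment_strength != 1 and config.compartment_blocks:
        lab = np.array(config.fine_labels(stage))
        labeled = lab != ""
        same = (lab[:, None] == lab[None, :]) & labeled[:, None] & labeled[None, :]
        E[same] *= config.compartment_strength
    for loop in config.loops:
        if loop.active(stage) and loop.fold != 1:
            i, j = loop.promoter_bin, loop.distal_bin
            E[i, j] *= loop.fold
            if i != j:
                E[j, i] *= loop.fold
    upper_total = np.triu(E).sum()
    E *= config.library_size / upper_total
    return E


def simulate_contact_map(config: SimConfig, stage: int, replicate: int
                         ) -> tuple[ContactMatrix, SyntheticTruth]:
    """Sample one replicate contact map for one stage.

    Sampling is reproducible given (config.seed, stage, replicate).
    Counts are symmetric nonnegative integers whose expected total over
    the upper triangle equals ``library_size``.
    """
    if not (0 <= stage < config.n_stages):
        raise ValueError(f"stage {stage} not in configured stages")
    E = expected_matrix(config, stage)
    n = config.n_bins
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(int(stage), int(replicate))))
    iu, ju = np.triu_indices(n)
    mu = E[iu, ju]
    if np.isinf(config.dispersion):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
        counts = rng.poisson(lam)
    C = np.zeros((n, n))
    C[iu, ju] = counts
    C[ju, iu] = counts
    m = ContactMatrix(chrom=config.chrom, resolution=config.resolution, counts=C)
    return m, build_truth(config)


# ---------------------------------------------------------------------------
# Companion tracks

TRACK_BIN = 1000  # bp, ChIP signal bookkeeping resolution
BG_COVERAGE = 10.0  # reads/kb baseline for mark and input
RE_COVERAGE = 80.0
SE_COVERAGE = 400.0
SE_CONSTITUENTS = 5
SE_SPACING = 2500  # bp between SE constituent peak starts (< 12.5 kb gaps)
PEAK_HALFWIDTH = 500


@dataclass
class CompanionTracks:
    """Gene models, ChIP tracks, peak calls and expression table for a config."""

    genes: list  # (chrom, start, end, gene_id, strand, tss)
    mark: np.ndarray  # reads per 1 kb bin
    input_: np.ndarray
    peaks: list  # (chrom, start, end, signal)
    expression: dict  # gene_id -> list of (stage, replicate, tpm)
    chrom: str
    chrom_length: int

    def write(self, outdir) -> dict:
        """Write BED12 genes, bedGraph tracks, peak BED and expression TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = outdir / "genes.bed12"
        with open(p, "w") as fh:
            for chrom, start, end, gid, strand, _tss in self.genes:
                size = end - start
                fh.write(f"{chrom}\t{start}\t{end}\t{gid}\t0\t{strand}\t{start}\t{end}\t"
                         f"0\t1\t{size},\t0,\n")
        paths["genes"] = p
        for name, track in (("mark", self.mark), ("input", self.input_)):
            p = outdir / f"{name}.bedGraph"
            with open(p, "w") as fh:
                start = 0
                while start < len(track):
                    end = start
                    while end < len(track) and track[end] == track[start]:
                        end += 1
                    hi = min(end * TRACK_BIN, self.chrom_length)
                    fh.write(f"{self.chrom}\t{start * TRACK_BIN}\t{hi}\t{track[start]:g}\n")
                    start = end
            paths[name] = p
        p = outdir / "peaks.bed"
        with open(p, "w") as fh:
            for chrom, start, end, sig in self.peaks:
                fh.write(f"{chrom}\t{start}\t{end}\t{sig:g}\n")
        paths["peaks"] = p
        p = outdir / "expression.tsv"
        with open(p, "w") as fh:
            samples = sorted({(s, r) for rows in self.expression.values() for s, r, _ in rows})
            fh.write("gene_id\t" + "\t".join(f"stage{s}_rep{r}" for s, r in samples) + "\n")
            for gid in sorted(self.expression, key=lambda g: int(g.split("_")[1])):
                vals = {(s, r): t for s, r, t in self.expression[gid]}
                fh.write(gid + "\t" + "\t".join(f"{vals[k]:.3f}" for k in samples) + "\n")
        paths["expression"] = p
        return paths


def simulate_companion_tracks(config: SimConfig,
                              n_background_peaks: int = 20,
                              n_background_genes: int = 20) -> CompanionTracks:
    """Generate gene/ChIP/peak/expression files matching the planted loops.

    Each loop contributes a gene whose TSS sits in the loop's promoter
    bin; its distal anchor carries either a super-enhancer (several
    constituent peaks within 12.5 kb, high signal), a single regular
    enhancer peak, or nothing, per ``enhancer_class``. Background peaks
    and genes fill the rest of the chromosome at low signal.
    """
    truth = build_truth(config)
    for s, e, _cls in truth.enhancer_intervals:
        if s < 0 or e > config.chrom_length:
            raise ValueError("enhancer interval outside chromosome")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(999,)))
    n_track = -(-config.chrom_length // TRACK_BIN)
    mark = np.full(n_track, BG_COVERAGE)
    input_ = np.full(n_track, BG_COVERAGE)
    peaks: list = []
    genes: list = []
    res = config.resolution

    def add_peak(center: int, coverage: float):
        lo = max(0, center - PEAK_HALFWIDTH)
        hi = min(config.chrom_length, center + PEAK_HALFWIDTH)
        b0, b1 = lo // TRACK_BIN, -(-hi // TRACK_BIN)
        mark[b0:b1] = np.maximum(mark[b0:b1], coverage)
        peaks.append((config.chrom, lo, hi, coverage))

    loop_bins = set()
    for k, loop in enumerate(config.loops):
        tss = loop.promoter_bin * res + res // 2
        genes.append((config.chrom, tss, min(tss + 5000, config.chrom_length),
                      f"gene_{k}", "+", tss))
        loop_bins.add(loop.promoter_bin)
        loop_bins.add(loop.distal_bin)
        center = loop.distal_bin * res + res // 2
        if loop.enhancer_class == "SE":
            first = center - (SE_CONSTITUENTS - 1) * SE_SPACING // 2
            for c in range(SE_CONSTITUENTS):
                add_peak(first + c * SE_SPACING, SE_COVERAGE)
        elif loop.enhancer_class == "RE":
            add_peak(center, RE_COVERAGE)
    # background genes/peaks on bins untouched by loops; genes preferentially
    # land in A compartments so gene density can orient PC1, as in real genomes
    free = [b for b in range(config.n_bins) if b not in loop_bins]
    fine = config.fine_labels(0)
    wts = np.array([4.0 if fine[b] == "A" else 1.0 for b in free])
    bg_gene_bins = rng.choice(free, size=min(n_background_genes, len(free)),
                              replace=False, p=wts / wts.sum())
    for k, b in enumerate(sorted(bg_gene_bins)):
        tss = int(b) * res + res // 4
        genes.append((config.chrom, tss, min(tss + 5000, config.chrom_length),
                      f"gene_{len(config.loops) + k}", "+", tss))
    free2 = [b for b in free if b not in set(int(x) for x in bg_gene_bins)]
    bg_peak_bins = rng.choice(free2, size=min(n_background_peaks, len(free2)), replace=False)
    for b in sorted(bg_peak_bins):
        add_peak(int(b) * res + res // 2, RE_COVERAGE * rng.uniform(0.3, 0.8))
    # expression: base 10 TPM, planted per-stage folds, lognormal replicate noise
    expression: dict = {}
    all_gene_ids = [g[3] for g in genes]
    for gid in all_gene_ids:
        folds = truth.expression_effects.get(gid, [1.0] * config.n_stages)
        rows = []
        for s in range(config.n_stages):
            for r in range(config.n_replicates_per_stage):
                tpm = 10.0 * folds[s] * float(rng.lognormal(0.0, 0.1))
                rows.append((s, r, tpm))
        expression[gid] = rows
    genes.sort(key=lambda g: g[1])
    peaks.sort(key=lambda p: (p[1], p[2]))
    return CompanionTracks(genes=genes, mark=mark, input_=input_, peaks=peaks,
                           expression=expression, chrom=config.chrom,
                           chrom_length=config.chrom_length)
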