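"""End-to-end pipeline: simulate -> normalize -> compartments -> TADs ->
D-score -> PEI -> enhancers -> report.

A run is configured by a strict-keyed :class:`RunConfig` (unknown keys
are rejected, every threshold carries its standard default) and is
deterministic given the seed. The report directory holds all
intermediate tables in plain-text formats plus a ``report.json`` with
the headline fractions and, because the inputs are simulated with known
truth, recovery metrics for each component.
"""

from __future__ import annotations


import json
import sys
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np

from hicreg import __version__
from hicreg.compartments import call_switches, compartment_pipeline
from hicreg.dscore import consensus_tads, test_differential_dscore
from hicreg.enhancers import (call_super_enhancers, classify_pei_anchors,
                              gene_class_table, signal_track, stitch_and_rank)
from hicreg.matrix import kr_balance, pool, scc, write_matrix
from hicreg.pei import PromoterAnchor, call_peis, compute_rps
from hicreg.sim import (CompartmentBlock, Loop, SimConfig, TadSegment,
                        build_truth, simulate_companion_tracks, simulate_contact_map)
from hicreg.tads import call_tads_hmm, compute_di, compute_is, refine_tads, \
    specific_boundary_analysis

__all__ = ["RunConfig", "ConfigError", "run", "two_stage_scenario", "scale_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class RunConfig:
    """Declarative pipeline configuration; all thresholds at their
    standard defaults (FDR 0.05, min PEI distance 40 kb, stitch gap
    12.5 kb, 1000 permutations, top-5% delta, t-test alpha 0.05)."""

    seed: int = 0
    outdir: str = "hicreg_run"
    chrom_length: int = 20_000_000
    resolution: int = 20_000
    pei_resolution: int = 5_000
    n_replicates_per_stage: int = 3
    library_size: float = 5_000_000
    dispersion: float = 20.0
    compartment_strength: float = 1.5
    fdr_max: float = 0.05
    min_dist: int = 40_000
    n_perm: int = 1000
    top_delta: float = 0.05
    alpha: float = 0.05
    write_intermediates: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def two_stage_scenario(cfg: RunConfig) -> SimConfig:
    """Standard planted two-condition scenario at desk scale.

    On a 20 Mb / 20 kb chromosome: an alternating A/B checkerboard with
    one block flipping label between conditions; 20 planted TADs of
    which two change intra-fold between conditions; promoter-anchored
    loops of all three enhancer classes, one loop present in condition
    2 only.
    """
    n = cfg.chrom_length // cfg.resolution
    block = 50  # 1 Mb compartment blocks at 20 kb
    blocks = []
    for k, start in enumerate(range(0, n, block)):
        end = min(n, start + block)
        lab = "A" if k % 2 == 0 else "B"
        flips = (1,) if k == 7 else ()  # one planted A/B switch block
        blocks.append(CompartmentBlock(start, end, lab, flips))
    tads = []
    tad_len = 40
    start = 60
    for k in range(20):
        s = start + k * (tad_len + 2)
        if s + tad_len > n - 60:
            break
        stage_folds = ((1, 6.0),) if k in (4, 12) else ()  # planted strength change
        tads.append(TadSegment(s, s + tad_len, 3.0, stage_folds))
    loops = []
    classes = ["SE", "RE", "nonE"]
    for k in range(9):
        p = 70 + k * 100
        dist = 10 + 3 * k  # 200 kb .. 740 kb at 20 kb bins
        if p + dist >= n - 10:
            break
        stages = (1,) if k == 2 else (0, 1)  # one condition-2-only loop
        loops.append(Loop(p, p + dist, 4.0, stages, classes[k % 3]))
    return SimConfig(chrom_length=cfg.chrom_length, resolution=cfg.resolution,
                     decay_exponent=1.0, tad_segments=tads,
                     compartment_blocks=blocks,
                     compartment_strength=cfg.compartment_strength, loops=loops,
                     n_replicates_per_stage=cfg.n_replicates_per_stage,
                     library_size=cfg.library_size, dispersion=cfg.dispersion,
                     seed=cfg.seed)


def scale_config(config: SimConfig, new_resolution: int) -> SimConfig:
    """Re-express a scenario at a finer resolution (bin indices rescaled)."""
    if config.resolution % new_resolution:
        raise ConfigError("new resolution must divide the scenario resolution")
    f = config.resolution // new_resolution
    return SimConfig(
        chrom_length=config.chrom_length, resolution=new_resolution,
        decay_exponent=config.decay_exponent,
        tad_segments=[TadSegment(t.start_bin * f, t.end_bin * f, t.intra_fold,
                                 t.stage_folds) for t in config.tad_segments],
        compartment_blocks=[CompartmentBlock(c.start_bin * f, c.end_bin * f,
                                             c.label, c.flip_stages)
                            for c in config.compartment_blocks],
        compartment_strength=config.compartment_strength,
        # anchors map to the fine bin containing the coarse bin's center,
        # where the companion TSS/enhancer coordinates sit
        loops=[Loop(l.promoter_bin * f + f // 2, l.distal_bin * f + f // 2,
                    l.fold, l.stages, l.enhancer_class) for l in config.loops],
        n_replicates_per_stage=config.n_replicates_per_stage,
        n_stages=config.n_stages, library_size=config.library_size,
        dispersion=config.dispersion, seed=config.seed, chrom=config.chrom)


def _gene_density(tracks, chrom_length: int, res: int = 100_000) -> np.ndarray:
    n = -(-chrom_length // res)
    out = np.zeros(n)
    for _c, start, _e, _g, _s, _t in tracks.genes:
        out[min(start // res, n - 1)] += 1
    return out


def _boundary_metrics(called: list[int], truth: list[int], tol: int = 1) -> dict:
    called_a = np.array(sorted(set(called)))
    truth_a = np.array(sorted(set(truth)))
    if len(truth_a) == 0 or len(called_a) == 0:
        return {"recall": float("nan"), "precision": float("nan")}
    hit_t = sum((np.abs(called_a - t) <= tol).any() for t in truth_a)
    hit_c = sum((np.abs(truth_a - c) <= tol).any() for c in called_a)
    return {"recall": hit_t / len(truth_a), "precision": hit_c / len(called_a)}


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = two_stage_scenario(cfg)
    truth = build_truth(scenario)
    truth.to_json(outdir / "truth.json")
    nrep = cfg.n_replicates_per_stage

    mats = {s: [simulate_contact_map(scenario, s, r)[0] for r in range(nrep)]
            for s in (0, 1)}
    if cfg.write_intermediates:
        for s in (0, 1):
            for r, m in enumerate(mats[s]):
                write_matrix(m, outdir / f"matrix_stage{s}_rep{r}.txt")
    for s in (0, 1):
        for m in mats[s]:
            kr_balance(m)
    scc_rows = []
    for s in (0, 1):
        for a in range(nrep):
            for b in range(a + 1, nrep):
                scc_rows.append((s, a, b, scc(mats[s][a], mats[s][b])))

    # compartments per replicate, switches across conditions; a dense gene
    # complement makes per-100kb gene density a usable PC1 orientation track
    companions = simulate_companion_tracks(scenario, n_background_genes=150,
                                           n_background_peaks=25)
    orientation = _gene_density(companions, cfg.chrom_length)
    fine_tracks = {s: [] for s in (0, 1)}
    for s in (0, 1):
        for r, m in enumerate(mats[s]):
            _coarse, fine = compartment_pipeline(m, orientation,
                                                 sample=f"stage{s}_rep{r}")
            fine_tracks[s].append(fine)
    switches, switch_frac = call_switches(fine_tracks[0], fine_tracks[1])
    if cfg.write_intermediates:
        with open(outdir / "switches.bed", "w") as fh:
            fh.write(f"# hicreg {__version__} seed={cfg.seed}\n")
            for c in switches:
                if c.is_switch:
                    fh.write(f"{scenario.chrom}\t{c.bin * cfg.resolution}\t"
                             f"{(c.bin + 1) * cfg.resolution}\t"
                             f"{c.status_stage1}>{c.status_stage2}\n")

    # TADs on pooled per-condition matrices
    pooled = {s: pool(mats[s]) for s in (0, 1)}
    di, tads, bounds = {}, {}, {}
    for s in (0, 1):
        kr_balance(pooled[s])
        di[s] = compute_di(pooled[s])
        t, b = call_tads_hmm(di[s], chrom=scenario.chrom, stage=str(s),
                             seed=cfg.seed + 17 * s)
        isp = compute_is(pooled[s])
        t, extra = refine_tads(t, isp, di[s], stage=str(s))
        tads[s], bounds[s] = t, b + extra
    rng = np.random.default_rng(cfg.seed + 101)
    tests, shifted_frac = specific_boundary_analysis(
        bounds[0], bounds[1], di[0], di[1], n_perm=cfg.n_perm, rng=rng)
    if cfg.write_intermediates:
        with open(outdir / "boundaries.bed", "w") as fh:
            fh.write(f"# hicreg {__version__} seed={cfg.seed} n_perm={cfg.n_perm}\n")
            for t in tests:
                fh.write(f"{scenario.chrom}\t{t.boundary.bin * cfg.resolution}\t"
                         f"{(t.boundary.bin + 1) * cfg.resolution}\t"
                         f"stage{t.boundary.stage}\t{t.empirical_p:.4g}\t"
                         f"{'specific' if t.specific else 'shared'}\n")
        for s in (0, 1):
            with open(outdir / f"tads_stage{s}.bed", "w") as fh:
                for t in tads[s]:
                    fh.write(f"{scenario.chrom}\t{t.start_bin * cfg.resolution}\t"
                             f"{t.end_bin * cfg.resolution}\n")

    # differential intra-TAD strength on consensus TADs
    cons = consensus_tads(tads[0], tads[1])
    drecs, diff_frac = test_differential_dscore(
        cons, mats[0], mats[1], alpha=cfg.alpha, top_delta=cfg.top_delta)
    if cfg.write_intermediates:
        with open(outdir / "dscore.tsv", "w") as fh:
            fh.write(f"# hicreg {__version__} alpha={cfg.alpha} top_delta={cfg.top_delta}\n")
            fh.write("chrom\tstart\tend\tmean_d_stage1\tmean_d_stage2\tdelta\tp\tdifferential\n")
            for r in drecs:
                fh.write(f"{scenario.chrom}\t{r.tad.start_bin * cfg.resolution}\t"
                         f"{r.tad.end_bin * cfg.resolution}\t{r.mean_stage1:.5f}\t"
                         f"{r.mean_stage2:.5f}\t{r.delta:+.5f}\t{r.p_value:.4g}\t"
                         f"{int(r.is_differential)}\n")

    # PEIs at fine resolution on pooled matrices
    fine_cfg = scale_config(scenario, cfg.pei_resolution)
    pooled_fine = {}
    for s in (0, 1):
        reps = [simulate_contact_map(fine_cfg, s, r)[0] for r in range(nrep)]
        pooled_fine[s] = pool(reps)
        kr_balance(pooled_fine[s])
    promoters = [PromoterAnchor(gid, tss, strand)
                 for _c, _s, _e, gid, strand, tss in companions.genes]
    peis = {s: call_peis(pooled_fine[s], promoters, fdr_max=cfg.fdr_max,
                         min_dist=cfg.min_dist, stage=str(s)) for s in (0, 1)}

    # enhancers
    sig = signal_track(companions.mark, companions.input_, chrom=scenario.chrom)
    stitched = stitch_and_rank([(s, e) for _c, s, e, _v in companions.peaks],
                               companions.mark, companions.input_,
                               tss_positions=[g[5] for g in companions.genes])
    stitched = call_super_enhancers(stitched)
    for s in (0, 1):
        classify_pei_anchors(peis[s], stitched, cfg.pei_resolution)
    profiles = gene_class_table(peis[0], peis[1])
    rps = {s: compute_rps(peis[s]) for s in (0, 1)}
    if cfg.write_intermediates:
        with open(outdir / "peis.tsv", "w") as fh:
            fh.write(f"# hicreg {__version__} fdr_max={cfg.fdr_max} min_dist={cfg.min_dist}\n")
            fh.write("gene_id\tstage\tdistal_start\tdistal_end\tdistance\t"
                     "observed\texpected\tintensity\tfdr\tclass\n")
            for s in (0, 1):
                for p in peis[s]:
                    lo = p.distal_bin * cfg.pei_resolution
                    fh.write(f"{p.gene_id}\t{s}\t{lo}\t{lo + cfg.pei_resolution}\t"
                             f"{p.distance}\t{p.observed:.4f}\t{p.expected:.4f}\t"
                             f"{p.intensity:.4f}\t{p.fdr:.4g}\t{p.enhancer_class}\n")
        with open(outdir / "rps.tsv", "w") as fh:
            fh.write("gene_id\tstage\trps\tn_peis\n")
            for s in (0, 1):
                for r in rps[s]:
                    fh.write(f"{r.gene_id}\t{s}\t{r.rps:.5f}\t{r.n_peis}\n")
        with open(outdir / "enhancers.bed", "w") as fh:
            for r in stitched:
                fh.write(f"{scenario.chrom}\t{r.start}\t{r.end}\t"
                         f"{r.signal:.4f}\t{int(r.is_super)}\n")
        with open(outdir / "gene_classes.tsv", "w") as fh:
            fh.write("gene_id\tstage1_class\tstage2_class\ttransition\n")
            for g in profiles:
                fh.write(f"{g.gene_id}\t{g.dominant_stage1}\t{g.dominant_stage2}\t"
                         f"{g.transition}\n")

    # recovery vs planted truth
    truth_bounds = {s: truth.tad_boundaries[str(s)] for s in (0, 1)}
    bmetrics = {s: _boundary_metrics([b.bin for b in bounds[s]], truth_bounds[s])
                for s in (0, 1)}
    comp_acc = {}
    for s in (0, 1):
        tl = np.array(truth.compartment_labels_fine[str(s)], dtype=object)
        accs = []
        for tr in fine_tracks[s]:
            lab = np.asarray(tr.labels, dtype=object)
            ok = (lab != "") & (tl != "")
            if ok.sum():
                accs.append(float((lab[ok] == tl[ok]).mean()))
        comp_acc[s] = float(np.mean(accs)) if accs else float("nan")
    loop_recall = {}
    f = cfg.resolution // cfg.pei_resolution
    for s in (0, 1):
        active = [(k, d * f + f // 2) for k, (p, d, stages, _cls)
                  in enumerate(truth.loop_anchors)
                  if s in stages and abs(d - p) * cfg.resolution >= cfg.min_dist]
        hits = 0
        called = {(rec.gene_id, rec.distal_bin) for rec in peis[s]}
        for k, db in active:
            if any(g == f"gene_{k}" and abs(b - db) <= 1 for g, b in called):
                hits += 1
        loop_recall[s] = hits / len(active) if active else float("nan")

    all_dist = [p.distance for s in (0, 1) for p in peis[s]]
    cfg_dict = asdict(cfg)
    cfg_dict.pop("outdir")  # path choice must not affect report content
    report = {
        "version": __version__,
        "config": cfg_dict,
        "python": sys.version.split()[0],
        "scc_within_stage": [(s, a, b, float(v)) for s, a, b, v in scc_rows],
        "switch_fraction": float(switch_frac),
        "shifted_boundary_fraction": float(shifted_frac),
        "differential_tad_fraction": float(diff_frac),
        "n_consensus_tads": len(cons),
        "pei_count": {s: len(peis[s]) for s in (0, 1)},
        "pei_median_distance": float(np.median(all_dist)) if all_dist else float("nan"),
        "se_count": sum(r.is_super for r in stitched),
        "re_count": sum(not r.is_super for r in stitched),
        "rps_by_stage": {s: {r.gene_id: r.rps for r in rps[s]} for s in (0, 1)},
        "recovery": {
            "tad_boundaries": bmetrics,
            "compartment_label_accuracy": comp_acc,
            "loop_recall": loop_recall,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
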