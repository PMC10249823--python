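# Methods

This note documents the models behind `hicreg`, the defaults that
matter, the numerical choices, and what the synthetic benchmarks can
and cannot show. Genomic bins are 0-based and half-open throughout: bin
`k` at resolution `r` covers `[k·r, (k+1)·r)`.

## Synthetic contact maps

The generator emulates a two-condition ("stage"), multi-replicate cis
Hi-C experiment on one chromosome. The expected count between bins `i`
and `j` is

    E[c_ij] ∝ (max(|i−j|, 1) · r)^(−α) · tad(i,j,s) · comp(i,j,s) · loop(i,j,s)

scaled so the upper-triangle total equals the library size, then
sampled negative-binomially with variance `μ + μ²/φ` (Gamma–Poisson;
`φ = ∞` degenerates to Poisson). `tad` multiplies pairs inside a
planted block by its intra-fold, `comp` multiplies same-label
compartment pairs by the compartment strength, `loop` multiplies single
anchor pairs. Stage perturbations are fold multipliers on planted
objects — a loop present in one stage only, a TAD whose intra-fold
changes, a compartment block whose label flips — so every differential
test downstream has planted positives and negatives. Sampling is keyed
on (seed, stage, replicate), making replicates exchangeable draws from
one truth.

Defaults (the desk-scale study conditions used by the tests and the
acceptance script): 20 Mb chromosome at 20 kb (1000 bins) — 10 Mb at
5 kb (2000 bins) for promoter-interaction work — decay exponent
`α = 1`, library 5×10⁶ contacts per replicate, dispersion `φ = 20`,
compartment strength 1.5, TAD intra-fold 3, loop fold 4. The library
size matches the motivating experiment's depth pro-rated to a 20 Mb
chromosome (hundreds of millions of valid contacts over a ~1 Gb
genome). Companion files are generated to match the planted loops: a
gene whose TSS sits in each loop's promoter bin, a super-enhancer
(five constituent peaks within 12.5 kb, high mark coverage) or a single
regular-enhancer peak at the distal anchor, background peaks and genes
elsewhere — background genes preferentially in A blocks (4:1), so that
per-100 kb gene density carries the same orientation information gene
density carries in real genomes.

What the simulator does **not** model: restriction-fragment geometry,
trans contacts, copy-number or mappability bias beyond what masking
handles, translocations, and distance-dependent noise correlations.
Passing recovery benchmarks on these maps therefore demonstrates the
correctness and calibration of the algorithms, not their field
performance on artifact-laden libraries.

## Matrix normalization and reproducibility

**KR balancing.** Knight–Ruiz Newton inner–outer iteration (inner
conjugate-gradient solve, preconditioned by the current iterate)
solving `diag(w) C diag(w) 1 = 1`; convergence tolerance 1e−8 on the
residual, bounded iterates (δ=0.1, Δ=3). Bins with zero marginal or in
the lowest 1% of nonzero coverage are masked first. If the Newton
iteration stalls, an iterative-proportional-fitting pass is tried; any
non-convergence is flagged on the matrix and logged, never silent.

**O/E.** Expected at gap `d` is the mean balanced count over unmasked
pairs at that gap; strata with fewer than 2 unmasked pairs are masked.
Per-gap means of O/E are exactly 1 by construction.

**Quantile normalization** operates within distance strata across
samples: the nonzero balanced values of every sample are rank-mapped
onto the mean empirical quantile curve (interpolated when sample
nonzero counts differ), so per-stratum sorted vectors agree across
samples afterwards. Order of operations: KR per sample, then quantile
across samples. Downstream calls in the pipeline use the KR-balanced
matrices; quantile mapping changes values monotonically within strata
and therefore does not move the rank-based compartment/TAD calls.

**SCC.** Both matrices are mean-filtered (3-bin window), Pearson
correlations are computed per gap stratum up to 5 Mb, and combined with
Cochran-style weights `N_d · sqrt(var_x var_y)`. Degenerate strata are
skipped. These defaults are fixed and documented here because the
upstream convention is "default parameters".

## Compartments

PC1 is the first principal component of the Pearson-correlation matrix
of coarse (100 kb) O/E, computed by SVD of the column-centered
correlation matrix. The eigenvector's sign is arbitrary, so it is
oriented against a per-bin track that is known to be A-associated (gene
density or GC): if Spearman ρ with the track is negative the component
is negated; |ρ| < 0.1 flags the chromosome low-confidence (the regime
where PC1 tracks arm structure rather than compartments). Positive PC1
is A. Consequence worth stating: negating the orientation track swaps
the labels — the track *defines* which side is A.

The fine-scale A-B index for a 20 kb bin is the median `log2 O/E` to
bins inside coarse-A compartments minus the median to coarse-B bins,
excluding pairs closer than 2 bins (decay leakage); bins with fewer
than 10 usable targets on either side, or an index of exactly 0, are
masked. Unobserved pairs (O/E = 0) enter the medians at a fixed floor
of −10 in log2 units; the floor affects both medians symmetrically and
only matters for contact-sparse rows.

Switches require unanimous replicate consensus in both conditions;
bins lacking consensus in either are excluded from the denominator. A
single replicate degenerates to that replicate's labels, with a
warning.

## TADs

**DI.** `A`/`B` are the balanced contact sums from each bin to its 10
upstream/downstream bins; `DI = sign(B−A)·((A−E)²/E+(B−E)²/E)`,
`E=(A+B)/2`, zero when `A=B`, NaN where the window is clipped. DI
scales linearly with depth, so all decoding happens in profile-SD
units.

**HMM segmentation.** Three states (downstream-bias / none /
upstream-bias) with Gaussian emissions anchored at −2/0/+2 SD (unit
variance on the biased states, 0.25 on the neutral one); EM fits the
start and transition probabilities (tolerance 1e−4, up to 5 reseeded
restarts), Viterbi decodes. The emissions are anchored rather than
EM-fitted because on desk-scale maps the DI distribution is a
symmetric heavy-tailed mixture whose free 3-Gaussian fit collapses
into concentric variance shells around zero — the states lose their
sign meaning and boundary recovery collapses; anchoring preserves the
semantics while keeping the temporal structure learned. A TAD opens at
the first downstream-biased bin after a non-downstream run and closes
at the last upstream-biased bin of the following upstream run. Masked
runs longer than 5 bins split the chromosome into independently decoded
segments. Constant (featureless) profiles yield zero TADs.

**IS refinement.** Insulation at bin `i` is the mean balanced contact
in the 10×10 square bridging `i` (upstream block × downstream block),
normalized as log2 against the chromosome mean. Local minima with
prominence ≥ 0.2 log2 units strictly inside a TAD split it; adjacent
tied minima resolve to the leftmost bin. The 0.2 default comes from
measuring desk-scale pooled maps: spurious dips inside strong TADs
reach prominence ≈ 0.11 while planted sub-boundary dips are ≈ 1.5, so
0.2 rejects noise splits with a wide margin. Windows larger than a TAD
cannot split it.

**Condition-specific boundaries.** Replicate counts are pooled per
condition before DI. For a boundary called in exactly one condition
(no boundary of the other condition within ±1 bin), the observed
statistic is the Spearman correlation of the two conditions' DI over
the 21-bin context centered on the boundary. The null repeats, 1000
times, the correlation of DI at 20 randomly selected bins — drawn
independently for each condition, so the null is centered near zero. A
boundary is "specific" when its observed correlation falls below the
null's 95th percentile: a conserved boundary shows high cross-condition
concordance and clears that bar, a re-organized one does not. Drawing
the random bins *paired* instead would center the null near 1 and make
the rule vacuous; the unpaired reading is the one under which the test
calibrates (null flagged fraction ≈ 0–2% at these depths). The 21-bin
context vs 20-bin null size asymmetry is intentional and preserved.
Fully masked contexts are untestable and excluded from denominators.

## Intra-TAD strength

`d = (contacts with both ends in the TAD) / (contacts with at least
one end in the TAD)`, unordered pairs, diagonal counted once, cis only,
on balanced counts — exactly invariant to global scaling, `d ∈ [0,1]`.
Consensus TADs are condition-1 calls matched to condition-2 calls by
≥ 80% reciprocal overlap. Differential: equal-variance two-sample
t-test on per-replicate d (Welch available via a flag), `Δd` =
difference of condition means, flagged iff `p < 0.05` and `|Δd|` at or
above the 95th percentile of `|Δd|` over consensus TADs — which caps
the flagged fraction at ~5% by construction. Degenerate variance:
equal means give p = 1; unequal means with zero pooled variance give
p = 0 (the t statistic diverges). Because of the 5% cap, sensitivity
benchmarks plant strength changes in ≤ 5% of TADs; planting more can
never be fully recovered under this rule, a property of the rule
itself, not of the implementation.

## Promoter-anchored interactions and RPS

Promoters are TSS −2 kb/+0.5 kb, strand-aware (5'-most TSS for
multi-TSS genes, BED12 thick coordinates). The pooled balanced 5 kb
matrix is scanned in 20 Mb windows advanced by 10 Mb; within each
window the balanced submatrix is rescaled to the window's raw total
(so intensities are in contact units), a monotone decay background is
fitted by isotonic regression on per-gap means, and each promoter-bin ×
distal-bin pair receives an upper-tail Poisson p-value with λ = the
background at its gap. Benjamini–Hochberg runs within each promoter's
tested pairs; retained records satisfy FDR ≤ 0.05, distance ≥ 40 kb,
and `In = observed − expected > 0`; overlapping-window duplicates keep
the smaller FDR. This caller deliberately replaces a hierarchical
domain-background model with a plain decay background: on
compartmentalized chromosomes it overcalls distal same-compartment
pairs (visible in the full-scenario pipeline report), which is why the
caller's recovery and false-call benchmarks run on loop-only maps
(planted fold-4 loops recovered ≈ 98–100%; null retained-call rate
≈ 1.5×10⁻⁴ per tested pair).

`RPS = Σ max(log10 In, 0)` over a gene's retained PEIs — the floor at
`In = 1` keeps the score monotone in PEI count; genes with no retained
PEI have no score rather than 0.

Promoter-set enrichment: the statistic is the mean O/E over a
target set's cis promoter pairs with gap ≥ 40 kb; the null redraws
1000 equal-size promoter sets and recomputes the statistic with
per-gap-stratum reweighting to the target's gap-quantile distribution
(distance matching); the empirical p is the null fraction ≥ observed.
The degenerate case (target = all promoters) yields z = 0.

## Enhancers

Signal is `log2((mark FPKM + 0.5)/(input FPKM + 0.5))` per 1 kb bin —
depth-invariant by construction. Stitching merges peaks with gaps
≤ 12,500 bp (inclusive at exactly 12.5 kb) after removing constituents
within ±2 kb of a TSS; stitched signal is the constituent-summed
(mark − input) FPKM. Super-enhancers: ranks and signals min-max scaled
to [0,1]; the cutoff is the first rank where the discrete tangent
slope exceeds 1 (strict: an exactly linear scaled curve yields none);
all-equal signals or < 10 stitched regions yield none, with a warning.
Classification of PEI distal anchors is by ≥ 1 bp interval overlap
with precedence SE > RE > non-E, deterministic and order-independent.

## Determinism and problem sizes

Every stochastic step (simulation, HMM restarts, permutation nulls,
resampling) is driven by explicit seeds threaded from the run
configuration; identical config + seed reproduce all outputs
byte-for-byte. The benchmark problem sizes — 1000-bin chromosomes,
10 simulation seeds for TAD recovery, 3 null simulations for
calibrations, 1000-draw permutation nulls, 300-draw resampling nulls —
were chosen as the smallest sizes at which the Monte-Carlo error bands
quoted with each check are meaningful; the full suite and the
acceptance script each run in well under five minutes on one CPU.

## Known limitations

- The decay-only PEI background (above) — the main accuracy gap versus
  domain-aware callers.
- The NB replicate-noise model is an assumption; the motivating
  experiment documents no replicate noise model.
- Compartment calling assumes the first principal component captures
  compartments; chromosomes where it tracks arms are flagged
  (|ρ| < 0.1) but not automatically re-analyzed.
- One chromosome per call; multi-chromosome genomes are composed by
  repeated calls (all analyses are cis-only).
- `.hic`/`.cool` binary formats are out of scope; the triplet text
  dialect is the interchange format.
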