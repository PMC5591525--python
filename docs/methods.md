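# Methods notes

This note records the modeling assumptions, parameter choices and numerical
conventions behind `rbpgroup`, and what the synthetic scenarios do and do
not establish.

## Peak integration

Coordinates are 0-based half-open (BED convention) everywhere; GTF input is
converted on read. Overlap tests are strand-aware when both features carry a
strand and strand-blind when either is `.`.

* **Method intersection.** A peak of the primary caller survives when any
  peak of another caller overlaps it by ≥ 1 bp (`min_overlap_bp`,
  configurable). The primary caller's coordinates and read counts are kept,
  because different callers report incomparable intervals and the primary
  (read-abundance) caller's counts feed the occupancy step.
* **Replica filter.** "Reproducible" means: read count ≥ 4 (a strict
  reading of "more than 3 reads") *and* ≥ 1 bp overlap with a peak that
  itself has ≥ 4 reads in at least one other replicate. Qualifying peaks
  from all replicates are pooled and coalesced; a coalesced peak carries the
  summed read count, which is what a pooled-library counter would report.
  RBPs with a single replicate keep count-filtered peaks — dropping such
  RBPs entirely would silently shrink the column space.
* **Merging and splitting.** Overlapping *or bookended* intervals merge
  (standard merge semantics). Sites longer than 100 bp become 100-bp bins
  at 50-bp steps; when the final step-aligned bin ends short of the site, a
  bin anchored at `end − 100` is appended so every base remains covered and
  all bins have identical length. Bin length uniformity matters because
  bins feed a per-site signal sum.
* **Annotation.** One label per site, by fixed priority (CDS, canonical
  ncRNA, 3′-UTR, 5′-UTR, lncRNA exon, pseudogene, intron, intergenic).
  The GTF reader classifies UTR features lacking a 5′/3′ tag by their
  position relative to the gene's CDS span and strand, and derives introns
  as gene span minus exon cover.

## Occupancy

Θ is a ratio of RPMs, so per-track library size cancels; multiplying any
track's counts by a constant leaves Θ unchanged. Conventions:

* "No RNA-seq signal" means a raw background count of exactly 0 — an
  epsilon threshold would make the retained-site set depend on library
  size.
* The scaling quantile (default 0.95) is computed over **strictly
  positive** ratios with the linear-interpolation (type-7) estimator;
  including zeros would deflate the quantile for sparsely bound RBPs and
  inflate every Θ in that column.
* Ratios above the quantile clip to 1: the top 5 % of sites are treated as
  effectively fully occupied. At most ⌈0.05·n⌉ (+1 for interpolation
  boundary effects) entries per column can clip.
* Sites with fewer than 2 strictly positive entries are removed — a
  single-RBP site carries no co-binding information and only adds KL terms
  that the factorization must waste rank on.

## KL-NMF

Lee–Seung multiplicative updates for the generalized KL divergence, with:

* **Initialization** i.i.d. Uniform(10⁻⁶, 1) for W and H, drawn from a
  seeded PCG64 generator. Identical seed ⇒ bit-identical factors on one
  platform.
* **Safeguards.** Update denominators and the reconstruction WH are floored
  at 10⁻¹², and the factors themselves at 10⁻¹⁶ after each update. Without
  the factor floor, entries associated with exact zeros in V underflow to
  exactly 0 within tens of iterations, after which those entries can never
  recover (multiplicative updates preserve zeros). The floors are orders of
  magnitude below any data scale and do not perturb converged objectives
  measurably.
* **Stopping.** Relative objective decrease < `tol` (default 10⁻⁵) checked
  every 10 iterations, or `max_iter` (default 2000). The objective is
  non-increasing across updates; tests assert this every iteration.
* **Known behaviour.** Multiplicative updates are a local method: on
  noiseless block-structured matrices roughly 1 run in 10 converges to a
  merged-block local optimum with a much higher objective. This is why rank
  diagnostics average many seeded restarts and the reported factorization
  is the lowest-KL of n restarts (default 100; ties break to the smallest
  seed). Consequently the dispersion coefficient at the true rank of a
  noiseless block matrix is typically high but not always exactly 1.

## Rank selection

A factorization induces a hard clustering via argmax over each RBP's
coefficient column (ties to the lowest group index). The consensus matrix
averages the binary same-cluster indicators over runs; per rank, the
largest scheduled run count is computed once and smaller schedule entries
reuse its prefix (runs are exchangeable seeded restarts).

* CPCC uses average linkage on D = 1 − C; with zero variance on either
  side of the correlation (perfect consensus) it returns 1.0 — every
  pairwise relation is maximally stable.
* DC includes a 1/M² normalization so that an all-0/1 consensus gives
  exactly 1 and the maximally uninformative matrix (off-diagonal 0.5)
  gives 1/M; the unnormalized sum would grow with M.
* A candidate rank is a strict local maximum of mean CPCC or mean DC over
  the scanned rank axis (endpoints compare to their single neighbour).
  When the pipeline must choose automatically it takes the candidate with
  the highest mean DC; in interactive use the scan report
  (`rank_scan.tsv`) is meant for inspection, since stability criteria can
  legitimately flag several ranks.

## Group calling and site association

* H columns are scaled by their maximum (preserves zeros; min–max shifting
  would manufacture membership for uniformly weak RBPs). Membership
  threshold 0.2 on the scaled weight; soft clustering is deliberate — an
  RBP above threshold in two groups belongs to both.
* The basis-specificity score of a site's W row w is
  1 + (Σ p log₂ p)/log₂ R with p = w/Σw: 1 for a single-group row, 0 for a
  uniform row, scale-invariant. Sites pass at > 0.8 together with a basis
  coefficient above the 80 % quantile of the group's column (quantile over
  positive entries, over *all* sites in the column — restricting to
  specificity-passing sites would couple the two rules).

## Enrichment statistics

* Fisher tests default to the one-sided "greater" alternative (the
  enrichment direction); the odds ratio is the sample estimate ad/bc,
  infinite when bc = 0 and ad > 0. P-values are validated against exact
  fixed-margin enumeration for every 2×2 table with all margins ≤ 30.
* The permutation support test uses the +1-smoothed estimator
  p = (1 + #{perm ≥ obs})/(1 + n_perm), which can never return 0. Its
  p-values are sub-uniform by construction: the statistic (within-group
  edge count) is integer-valued, so each group's attainable p-values form
  a grid. A Kolmogorov–Smirnov comparison against the continuous uniform
  is therefore only meaningful when the null edge-count distribution has
  fine granularity; the calibration test sizes its null design (universe
  60, group sizes 24–33, edge densities 0.25–0.5) so the statistic's
  standard deviation is ≳ 8 and the discrete atoms are small. Sparser
  networks or pairs-of-RBPs groups give visibly conservative (upward)
  p-values — which is safe but not uniform.
* Motif scanning is sense-strand only on strand-resolved site sequences;
  U and T are interchangeable, IUPAC degeneracies expand to character
  classes, and each sequence counts once regardless of hit multiplicity.
* Half-life classes are genes strictly below the 20th / strictly above the
  80th percentile (linear-interpolation percentiles); splicing classes are
  exons with PSI < 0.2 (alternatively spliced) vs > 0.8 (constitutive),
  and an exon is "hit" when any site overlaps the half-open window
  extending 2 kb up- and downstream in genomic coordinates.

## Synthetic scenarios

`generate_scenario` emits everything the pipeline consumes: per-(RBP,
replicate) peak BEDs with a manifest, a background RNA-seq coverage TSV
with a track manifest, a toy GTF of coding genes, half-life and PSI tables,
an association edge list, and the planted truth as JSON — all byte-stable
for a fixed seed.

Generative model: N sites in evenly spaced slots (jitter keeps neighbours
from merging) on a synthetic chromosome; each site belongs to one of G
groups; each (site, member-RBP) pair draws a log-normal binding strength
(μ = 0, σ = 0.7) held fixed across replicates; site expression is
log-normal (μ = 1.0, σ = 0.8). Expected CLIP reads per true peak are
`20 × strength × expression`, Poisson-sampled (or rounded, in noiseless
mode); background RNA-seq counts are `30 × expression`. Per-RBP dropout
(default 0.1) removes true (site, RBP) pairs entirely; Poisson background
peaks (default rate 0.1 × N per track) land uniformly on the genome with
mean 6 reads and — having no RNA-seq coverage — exercise the
no-background-signal filter. Consecutive sites (5 per gene) share a toy
gene: genes hosting the designated "decay" group's sites draw short
half-lives (log-normal around 35 min vs 150 min), genes hosting the
designated "splicing" group's sites carry a low-PSI exon (PSI < 0.15 vs
> 0.85), and the network contains every within-group pair as a "physical"
edge plus random "co-expression" noise edges. A `promiscuous_rbp` switch
plants one RBP into two groups to exercise soft clustering.

The reference conditions used by `scripts/acceptance.py` and the recovery
tests are 12 RBPs in 3 groups, 1500 sites, 30 % dropout, defaults
elsewhere; the normalization-contrast check uses a noiseless variant
(no dropout, no background, deterministic counts) with 600 sites.

What the scenarios do **not** emulate: crosslink-induced mutations or any
read-level effects, caller-specific peak-shape biases, isoform structure
(expression is site-level, not transcript-level), nucleotide composition
biases, and realistic gene geometry — genes are short and densely packed,
so the ±2 kb splicing window overlaps neighbouring genes and dilutes the
planted PSI contrast (the enrichment remains directionally positive but
modest). Passing tests therefore demonstrate the pipeline's statistical
machinery, not performance on real CLIP libraries.

## Problem sizes and runtime

The test suite and acceptance script run on deliberately modest sizes
(hundreds to ~1500 sites, ≤ 12 RBPs, rank scans over 2–8 with 10–20 runs
per rank), which complete in minutes on a single CPU while leaving the
planted structure comfortably recoverable. All quantities scale: real
datasets with ~10⁵ sites and ~50 RBPs multiply the per-run NMF cost
roughly linearly in N·M·R.

## Known limitations

* The semi-overlap replica rule and the coalesced-peak read count are one
  concrete reading of loosely specified practice; both are configurable.
* Automatic rank choice prefers DC; there is no residual-based or
  stability-selection alternative.
* The permutation test draws subsets uniformly; degree-preserving nulls
  are not implemented.
* Motif enrichment requires externally supplied sequences; no de novo
  motif discovery.
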