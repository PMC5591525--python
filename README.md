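# rbpgroup

Discovery of **co-binding RNA-binding protein (RBP) groups** from CLIP-seq
peak collections.

CLIP-seq experiments map where individual RBPs touch the transcriptome, but
each experiment sees one protein at a time, with peak sets that vary wildly
across protocols (PAR-CLIP, HITS-CLIP, eCLIP), peak callers (Piranha,
PARalyzer, CLIPper, CIMS) and biological replicates. Many regulatory
decisions, though, are made by *combinations* of RBPs competing for or
co-occupying the same RNA elements. `rbpgroup` integrates heterogeneous
per-RBP peak files into a unified set of binding sites, quantifies each
RBP's occupancy at each site, and soft-clusters the RBPs into co-binding
groups — then scores each binding site for how specifically it belongs to
one group and evaluates the groups against orthogonal evidence
(protein-association networks, known motifs, mRNA half-lives, exon
inclusion levels).

## Method

1. **Peak integration.** Per RBP: peaks must be confirmed by a second peak
   caller (coordinates of the primary caller are kept), carry ≥ 4 reads, and
   overlap a similarly supported peak in at least one other replicate.
   Filtered peaks from all RBPs are merged into disjoint binding sites;
   sites longer than 100 bp are split into 100-bp bins with 50-bp overlap.
   Sites are annotated by priority: CDS > canonical ncRNA > 3′-UTR > 5′-UTR >
   lncRNA exon > pseudogene > intron > intergenic.

2. **Occupancy matrix.** Read coverage at a site reflects transcript
   abundance as much as binding. Assuming binding equilibrates much faster
   than transcript turnover, the occupancy Θ — the fraction of transcript
   copies bound at a site — satisfies

        Θ ∝ CLIP RPM / background RNA-seq RPM

   (eCLIP size-matched input serves as background where applicable). Ratios
   are scaled per RBP by the 95 % quantile of positive values and clipped to
   [0, 1]. Sites without RNA-seq signal or bound by fewer than two RBPs are
   discarded, giving the N × M matrix **V**.

3. **KL-NMF soft clustering.** V ≈ WH with non-negative basis W (sites ×
   R) and coefficients H (R × RBPs), fitted by Lee–Seung multiplicative
   updates under the generalized Kullback–Leibler divergence. The rank R is
   chosen from consensus diagnostics over many seeded restarts: the
   cophenetic correlation coefficient (CPCC) and the dispersion coefficient
   DC = (1/M²) Σ 4(C_ij − ½)² of the consensus matrix C; candidate ranks
   are local maxima of either curve. The reported factorization is the
   lowest-KL run among n restarts.

4. **Groups and site associations.** Columns of H are scaled to [0, 1];
   every group with scaled weight > 0.2 claims the RBP (an RBP may sit in
   several groups). A site is associated to a group when its basis row is
   concentrated on that group (entropy-based specificity > 0.8) and its
   basis coefficient exceeds the 80 % quantile of the group's column.

5. **Evaluation.** Within-group association-network edges are tested
   against 10,000 same-size random RBP sets; motif, half-life and
   percent-spliced-in (PSI) enrichments use Fisher's exact test on 2×2
   tables (group sites vs. single-RBP peaks; short- vs. long-half-life
   genes; alternatively spliced vs. constitutive exons within ±2 kb).

A fully seeded synthetic-scenario generator (`rbpgroup.simulate`) plants
co-binding groups with abundance-confounded read counts, per-RBP dropout
and background peaks, plus matching side tables, so the entire pipeline is
testable end to end without any external data.

## Worked example

```bash
rbpgroup simulate --outdir demo/scenario --seed 7 --n-rbps 9 --n-groups 3 --n-sites 400
rbpgroup run \
    --manifest demo/scenario/manifest.tsv \
    --tracks demo/scenario/tracks.tsv \
    --background-coverage demo/scenario/rnaseq_coverage.tsv \
    --network demo/scenario/network.tsv \
    --outdir demo/run --rank 3 --n-best-runs 10 --n-perm 2000 --seed 1
```

prints

```
scenario written to demo/scenario (400 planted sites)
rank 3: 3 non-empty groups, 231 site associations -> demo/run
```

`demo/run/groups.tsv` holds the called memberships — the three planted
groups of three RBPs each are recovered exactly:

```
group	rbp_id	scaled_weight
1	RBP03	1.000000
1	RBP04	1.000000
1	RBP05	1.000000
2	RBP00	1.000000
2	RBP01	1.000000
2	RBP02	1.000000
3	RBP06	1.000000
...
```

`demo/run/associations.tsv` lists the 231 binding sites tied to a single
group with basis-specificity 1.0 (each planted site is bound by exactly one
group), e.g.

```
site_id	chrom	start	end	strand	group	basis_coefficient	specificity
chr1:1343-1400(+)	chr1	1343	1400	+	2	2.67498	1.000000
chr1:1598-1663(+)	chr1	1598	1663	+	1	1.48542	1.000000
```

and `demo/run/enrichment.json` reports the permutation support per evidence
type — here the planted physical edges support every group
(p ≈ 0.04 each with 2000 permutations against a 9-RBP universe), while the
random co-expression edges do not.

All stage outputs (occupancy matrix + quantiles, W, H, rank-scan report,
run metadata) are written beside them as TSV/JSON.

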