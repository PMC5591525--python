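"""Seeded synthetic CLIP-seq scenarios with planted co-binding structure.

A scenario plants G groups of RBPs that share binding sites. Every planted
site belongs to one group; member RBPs receive peaks there whose read counts
are a log-normal per-(site, RBP) binding strength multiplied by a log-normal
site-level expression — so raw counts are confounded by transcript abundance
exactly the way the occupancy normalization is meant to undo. Per-RBP
dropout removes true sites, and Poisson background peaks at random positions
add caller noise. Matching side tables (RNA-seq coverage, toy gene models,
half-lives, exon PSI, a protein-association edge list) carry planted signal
for the designated decay / splicing / network evidence checks.

Everything is emitted in the same plain-text dialects the pipeline consumes,
and the planted truth is returned (and written as JSON) for evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio

__all__ = ["ScenarioConfig", "ScenarioTruth", "generate_scenario"]


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic scenario; defaults give a realistic mid-noise run."""

    n_rbps: int = 12
    n_groups: int = 3
    n_sites: int = 1500
    membership: np.ndarray | None = None  # G x M booleans; default: equal blocks
    genome: list[tuple[str, int]] | None = None  # default: one auto-sized chrom
    site_len_range: tuple[int, int] = (30, 60)
    # log-normal binding strength per (site, member RBP)
    strength_mu: float = 0.0
    strength_sigma: float = 0.7
    # log-normal site-level expression (the abundance confounder)
    expression_mu: float = 1.0
    expression_sigma: float = 0.8
    background_peak_rate: float = 0.1  # expected background peaks per RBP, x n_sites
    dropout_prob: float = 0.1  # P(an RBP misses one of its true sites)
    n_replicas: int = 2
    clip_scale: float = 20.0  # mean reads per true peak at strength=expression=1
    clip_total_mapped: float = 2e6
    rnaseq_scale: float = 30.0
    rnaseq_total_mapped: float = 5e6
    noise_read_mean: float = 6.0
    count_noise: bool = True  # Poisson counts; False gives deterministic rounding
    peak_jitter: int = 5
    sites_per_gene: int = 5
    promiscuous_rbp: bool = False  # plant one RBP into two groups
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_rbps:
            raise ValueError("n_groups cannot exceed n_rbps")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must lie in [0, 1)")
        if min(self.n_rbps, self.n_groups, self.n_sites, self.n_replicas) <= 0:
            raise ValueError("counts must be positive")
        if self.membership is None:
            self.membership = self._default_membership()
        self.membership = np.asarray(self.membership, bool)
        if self.membership.shape != (self.n_groups, self.n_rbps):
            raise ValueError("membership must be G x M")
        if self.genome is None:
            self.genome = [("chr1", max(200_000, self.n_sites * 200))]
        total = sum(length for _, length in self.genome)
        if self.n_sites * 200 > total:
            raise ValueError("genome too small for the requested number of sites")

    def _default_membership(self) -> np.ndarray:
        m = np.zeros((self.n_groups, self.n_rbps), bool)
        bounds = np.linspace(0, self.n_rbps, self.n_groups + 1).astype(int)
        for g in range(self.n_groups):
            m[g, bounds[g] : bounds[g + 1]] = True
        if self.promiscuous_rbp and self.n_groups >= 2:
            m[1, bounds[0]] = True  # first RBP of group 1 also loads group 2
        return m

    @property
    def rbp_ids(self) -> list[str]:
        return [f"RBP{j:02d}" for j in range(self.n_rbps)]


@dataclass
class ScenarioTruth:
    """Planted ground truth matching the emitted files."""

    membership: np.ndarray  # G x M booleans
    rbp_ids: list[str]
    site_intervals: list[tuple[str, int, int, str]]
    site_group: list[int]
    site_expression: list[float]
    gene_of_site: list[str]
    gene_spans: dict[str, tuple[str, int, int, str]]
    short_halflife_genes: set[str]
    as_exons: set[str]
    network_edges: set[tuple[str, str, str]]
    decay_group: int
    splicing_group: int
    paths: dict[str, str] = field(default_factory=dict)

    def rbp_group_labels(self) -> list[int]:
        """Primary (lowest-index) planted group per RBP, for partition scoring."""
        return [int(np.argmax(self.membership[:, j])) for j in range(len(self.rbp_ids))]

    def expression_at(self, chrom: str, start: int, end: int) -> float | None:
        """Planted expression of the site overlapping [start, end), if any."""
        if not hasattr(self, "_site_index"):
            from intervaltree import IntervalTree

            index: dict[str, IntervalTree] = {}
            for (c, s, e, _), expr in zip(self.site_intervals, self.site_expression):
                index.setdefault(c, IntervalTree()).addi(s, e, expr)
            self._site_index = index
        tree = self._site_index.get(chrom)
        if tree is None:
            return None
        best, best_ov = None, 0
        for iv in tree.overlap(start, end):
            ov = min(iv.end, end) - max(iv.begin, start)
            if ov > best_ov:
                best_ov, best = ov, iv.data
        return best

    def to_json(self) -> dict:
        return {
            "rbp_ids": self.rbp_ids,
            "membership": self.membership.astype(int).tolist(),
            "site_group": self.site_group,
            "site_intervals": self.site_intervals,
            "site_expression": self.site_expression,
            "gene_of_site": self.gene_of_site,
            "short_halflife_genes": sorted(self.short_halflife_genes),
            "as_exons": sorted(self.as_exons),
            "network_edges": sorted(self.network_edges),
            "decay_group": self.decay_group,
            "splicing_group": self.splicing_group,
        }


def _place_sites(cfg: ScenarioConfig, rng: np.random.Generator):
    """Non-overlapping site intervals in fixed evenly spaced slots with jitter."""
    chroms = []
    for chrom, length in cfg.genome:
        chroms.append((chrom, length))
    total = sum(l for _, l in chroms)
    per_chrom = [max(1, round(cfg.n_sites * l / total)) for _, l in chroms]
    while sum(per_chrom) > cfg.n_sites:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < cfg.n_sites:
        per_chrom[int(np.argmax([l for _, l in chroms]))] += 1

    lo, hi = cfg.site_len_range
    sites = []
    for (chrom, length), n in zip(chroms, per_chrom):
        slot = length // n
        for k in range(n):
            site_len = int(rng.integers(lo, hi + 1))
            margin = slot - site_len - 2 * (cfg.peak_jitter + 1)
            offset = int(rng.integers(0, max(1, margin)))
            start = k * slot + cfg.peak_jitter + 1 + offset
            sites.append((chrom, start, start + site_len, "+"))
    return sites


def _count(rng: np.random.Generator, lam: float, noise: bool) -> int:
    return int(rng.poisson(lam)) if noise else int(round(lam))


def generate_scenario(cfg: ScenarioConfig, outdir: str | Path) -> ScenarioTruth:
    """Write one complete synthetic scenario under ``outdir``.

    Emits per-(RBP, replicate) peak BEDs with a manifest, an RNA-seq
    coverage TSV with a track manifest, a toy GTF, half-life and PSI tables,
    a protein-association edge list and the planted truth as JSON.
    Byte-identical for identical configs (the seed covers every draw).
    """
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    G, M, N = cfg.n_groups, cfg.n_rbps, cfg.n_sites
    rbp_ids = cfg.rbp_ids

    sites = _place_sites(cfg, rng)
    site_group = list(rng.permutation(np.arange(N) % G).astype(int))
    expression = np.exp(rng.normal(cfg.expression_mu, cfg.expression_sigma, N))

    # per-(site, RBP) binding strengths for true member pairs, fixed across replicates
    member = cfg.membership  # G x M
    true_pair = np.zeros((N, M), bool)
    for i in range(N):
        true_pair[i] = member[site_group[i]]
    strength = np.where(
        true_pair, np.exp(rng.normal(cfg.strength_mu, cfg.strength_sigma, (N, M))), 0.0
    )
    dropped = true_pair & (rng.random((N, M)) < cfg.dropout_prob)

    # ---- peak BED per (RBP, replicate), with jittered true peaks + background
    manifest_rows = []
    genome_ends = dict(cfg.genome)
    for j, rbp in enumerate(rbp_ids):
        for rep in range(cfg.n_replicas):
            rows = []
            for i in range(N):
                if not true_pair[i, j] or dropped[i, j]:
                    continue
                chrom, s, e, strand = sites[i]
                js = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
                je = int(rng.integers(-cfg.peak_jitter, cfg.peak_jitter + 1))
                lam = cfg.clip_scale * strength[i, j] * expression[i]
                count = _count(rng, lam, cfg.count_noise)
                rows.append((chrom, max(0, s + js), max(s + js + 10, e + je), count, strand))
            n_noise = int(rng.poisson(cfg.background_peak_rate * N)) if cfg.background_peak_rate else 0
            for _ in range(n_noise):
                chrom, clen = cfg.genome[int(rng.integers(len(cfg.genome)))]
                start = int(rng.integers(0, clen - 80))
                length = int(rng.integers(20, 61))
                count = _count(rng, cfg.noise_read_mean, True)
                rows.append((chrom, start, start + length, count, "+"))
            rows.sort()
            path = outdir / "peaks" / f"{rbp}_piranha_rep{rep + 1}.bed"
            with open(path, "w") as fh:
                seen = set()
                for chrom, s, e, count, strand in rows:
                    if (chrom, s, e) in seen:
                        continue
                    seen.add((chrom, s, e))
                    fh.write(f"{chrom}\t{s}\t{min(e, genome_ends[chrom])}\t{rbp}\t{count}\t{strand}\n")
            manifest_rows.append((str(path.relative_to(outdir)), rbp, "piranha", f"rep{rep + 1}"))

    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("file\trbp_id\tmethod\treplicate\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")

    # ---- RNA-seq background coverage over (padded) planted sites
    with open(outdir / "rnaseq_coverage.tsv", "w") as fh:
        for i, (chrom, s, e, strand) in enumerate(sites):
            count = _count(rng, cfg.rnaseq_scale * expression[i], cfg.count_noise)
            fh.write(f"{chrom}\t{max(0, s - 20)}\t{e + 20}\t{strand}\t{count}\n")

    with open(outdir / "tracks.tsv", "w") as fh:
        fh.write("track_id\tkind\ttotal_mapped\n")
        for rbp in rbp_ids:
            fh.write(f"{rbp}\tclip\t{cfg.clip_total_mapped:.0f}\n")
        fh.write(f"rnaseq\trnaseq\t{cfg.rnaseq_total_mapped:.0f}\n")

    # ---- toy gene models: consecutive sites share a coding gene
    gene_of_site: list[str] = []
    gene_spans: dict[str, tuple[str, int, int, str]] = {}
    order = sorted(range(N), key=lambda i: (sites[i][0], sites[i][1]))
    for rank, i in enumerate(order):
        gid = f"GENE{rank // cfg.sites_per_gene:04d}"
        chrom, s, e, strand = sites[i]
        if gid in gene_spans and gene_spans[gid][0] == chrom:
            gc, gs, ge, gstr = gene_spans[gid]
            gene_spans[gid] = (gc, min(gs, s - 100), max(ge, e + 100), gstr)
        else:
            gene_spans[gid] = (chrom, max(0, s - 100), e + 100, strand)
    rank_of = {i: r for r, i in enumerate(order)}
    gene_of_site = [f"GENE{rank_of[i] // cfg.sites_per_gene:04d}" for i in range(N)]

    with open(outdir / "annotation.gtf", "w") as fh:
        for gid, (chrom, gs, ge, strand) in sorted(gene_spans.items()):
            attrs = f'gene_id "{gid}"; gene_type "protein_coding";'
            fh.write(f'{chrom}\ttoy\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}\n')
            fh.write(f'{chrom}\ttoy\texon\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}\n')
            fh.write(f'{chrom}\ttoy\tCDS\t{gs + 1}\t{ge}\t.\t{strand}\t.\t{attrs}\n')

    decay_group = 0
    splicing_group = 1 % G

    # ---- half-lives: genes hosting decay-group sites draw from the short mode
    decay_genes = {gene_of_site[i] for i in range(N) if site_group[i] == decay_group}
    short_genes: set[str] = set()
    with open(outdir / "halflife.tsv", "w") as fh:
        fh.write("gene_id\thalf_life_min\n")
        for gid in sorted(gene_spans):
            if gid in decay_genes:
                hl = float(np.exp(rng.normal(np.log(35.0), 0.3)))
                short_genes.add(gid)
            else:
                hl = float(np.exp(rng.normal(np.log(150.0), 0.5)))
            fh.write(f"{gid}\t{hl:.3f}\n")

    # ---- PSI: one exon per gene; low PSI when the gene hosts splicing-group sites
    as_exons: set[str] = set()
    with open(outdir / "psi.tsv", "w") as fh:
        for gid, (chrom, gs, ge, strand) in sorted(gene_spans.items()):
            mid = (gs + ge) // 2
            exon = (chrom, mid - 60, mid + 60, strand)
            hosts_splicing = any(
                gene_of_site[i] == gid and site_group[i] == splicing_group for i in range(N)
            )
            if hosts_splicing:
                psi = float(rng.uniform(0.0, 0.15))
                as_exons.add(f"{chrom}:{exon[1]}-{exon[2]}")
            else:
                psi = float(rng.uniform(0.85, 1.0))
            fh.write(f"{chrom}\t{exon[1]}\t{exon[2]}\t{strand}\t{psi:.4f}\n")

    # ---- association network: all within-group pairs (physical) + noise edges
    edges: set[tuple[str, str, str]] = set()
    for g in range(G):
        ids = [rbp_ids[j] for j in range(M) if member[g, j]]
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                edges.add((ids[x], ids[y], "physical"))
    n_noise_edges = M  # sparse co-expression noise
    for _ in range(n_noise_edges):
        a, b = rng.choice(M, 2, replace=False)
        pair = sorted((rbp_ids[int(a)], rbp_ids[int(b)]))
        edges.add((pair[0], pair[1], "co-expression"))
    with open(outdir / "network.tsv", "w") as fh:
        for a, b, ev in sorted(edges):
            fh.write(f"{a}\t{b}\t{ev}\n")

    with open(outdir / "motifs.txt", "w") as fh:
        fh.write("UGUGU\nAAUAAA\nUGUA\n")

    truth = ScenarioTruth(
        membership=member.copy(),
        rbp_ids=rbp_ids,
        site_intervals=sites,
        site_group=[int(g) for g in site_group],
        site_expression=[float(x) for x in expression],
        gene_of_site=gene_of_site,
        gene_spans=gene_spans,
        short_halflife_genes=short_genes,
        as_exons=as_exons,
        network_edges=edges,
        decay_group=decay_group,
        splicing_group=splicing_group,
        paths={
            "manifest": str(outdir / "manifest.tsv"),
            "tracks": str(outdir / "tracks.tsv"),
            "rnaseq_coverage": str(outdir / "rnaseq_coverage.tsv"),
            "annotation": str(outdir / "annotation.gtf"),
            "halflife": str(outdir / "halflife.tsv"),
            "psi": str(outdir / "psi.tsv"),
            "network": str(outdir / "network.tsv"),
            "motifs": str(outdir / "motifs.txt"),
        },
    )
    rio.write_json(outdir / "truth.json", truth.to_json())
    return truth
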