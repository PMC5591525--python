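"""End-to-end orchestration: peak files -> occupancy matrix -> groups -> stats.

Stage order follows the method: per-RBP method intersection, replica
filtering, merging into unified sites, 100-bp splitting, annotation,
occupancy normalization, co-bound filtering, NMF (optional rank scan, then
best-of-n factorization), group calling, site association and enrichment.
Each stage writes its intermediates so runs are inspectable and resumable.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import enrichment as enr
from . import io as rio
from .groups import associate_sites, call_members, scale_coefficients
from .intervals import (
    GenomicInterval,
    MergedSite,
    PeakSet,
    annotate_site,
    assign_site_ids,
    filter_replicas,
    intersect_methods,
    merge_sites,
    split_long_sites,
)
from .occupancy import OccupancyMatrix, SignalTable, build_occupancy, filter_cobound
from .rank_selection import best_run, rank_scan

log = logging.getLogger("rbpgroup")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_filtered_peaks"]


@dataclass
class PipelineConfig:
    manifest: str
    tracks: str
    background_coverage: str
    outdir: str
    annotation: str | None = None
    halflife: str | None = None
    psi: str | None = None
    network: str | None = None
    primary_method: str = "piranha"
    min_reads: int = 4
    min_replicas: int = 2
    bin_len: int = 100
    step: int = 50
    quantile: float = 0.95
    min_cobound: int = 2
    rank: int | None = None
    rank_range: tuple[int, int] = (5, 20)
    runs_schedule: tuple[int, ...] = (10, 30, 50, 80, 100)
    do_rank_scan: bool = False
    n_best_runs: int = 100
    max_iter: int = 2000
    tol: float = 1e-5
    membership_threshold: float = 0.2
    spec_threshold: float = 0.8
    coeff_quantile: float = 0.80
    n_perm: int = 10000
    seed: int = 0

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    sites: list[MergedSite]
    V: OccupancyMatrix
    rank: int
    W: np.ndarray
    H: np.ndarray
    groups: list
    associations: list
    candidate_ranks: list[int] = field(default_factory=list)
    enrichment: dict = field(default_factory=dict)
    outdir: Path | None = None


def load_filtered_peaks(cfg: PipelineConfig) -> dict[str, PeakSet]:
    """Read the manifest, intersect methods and filter replicas per RBP."""
    base = Path(cfg.manifest).parent
    manifest = rio.read_manifest(cfg.manifest)
    per_rbp: dict[str, PeakSet] = {}
    for rbp_id, sub in manifest.groupby("rbp_id", sort=True):
        replicas = []
        for rep, tracks in sub.groupby("replicate", sort=True):
            sets = {
                row.method: rio.read_peak_bed(
                    base / row.file, rbp_id, row.method, rep
                )
                for row in tracks.itertuples()
            }
            if cfg.primary_method in sets and len(sets) > 1:
                primary = sets[cfg.primary_method]
                merged_other = [
                    p for m, ps in sets.items() if m != cfg.primary_method for p in ps.peaks
                ]
                other = PeakSet(rbp_id, "other", rep, _dedupe(merged_other))
                replicas.append(intersect_methods(primary, other))
            else:
                method = cfg.primary_method if cfg.primary_method in sets else sorted(sets)[0]
                replicas.append(sets[method])
        filtered = filter_replicas(replicas, cfg.min_reads, cfg.min_replicas)
        log.info(
            "%s: %d replicate tracks -> %d filtered peaks", rbp_id, len(replicas), len(filtered)
        )
        per_rbp[rbp_id] = filtered
    return per_rbp


def _dedupe(peaks):
    seen, out = set(), []
    for p in peaks:
        key = (p.interval.chrom, p.interval.start, p.interval.end, p.interval.strand)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def clip_counts_for_sites(
    sites: Sequence[MergedSite], per_rbp: dict[str, PeakSet]
) -> pd.DataFrame:
    """Sum each RBP's filtered peak read counts over every merged site."""
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end, s.site_id
        )
    rbp_ids = sorted(per_rbp)
    counts = pd.DataFrame(
        0.0, index=[s.site_id for s in sites], columns=rbp_ids
    )
    for rbp, ps in per_rbp.items():
        for p in ps.peaks:
            tree = trees.get(p.interval.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(p.interval.start, p.interval.end):
                counts.loc[iv.data, rbp] += p.read_count
    return counts


def background_counts_for_sites(
    sites: Sequence[MergedSite], coverage: pd.DataFrame
) -> pd.DataFrame:
    """Assign each site the count of the best-overlapping coverage interval.

    Coverage rows are disjoint padded windows; a site not overlapped by any
    window gets zero (no transcript signal).
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _strand, count in coverage.itertuples(index=False, name=None):
        trees.setdefault(chrom, IntervalTree()).addi(start, end, count)
    out = np.zeros(len(sites))
    for k, s in enumerate(sites):
        tree = trees.get(s.interval.chrom)
        if tree is None:
            continue
        best, best_ov = 0.0, 0
        for iv in tree.overlap(s.interval.start, s.interval.end):
            ov = min(iv.end, s.interval.end) - max(iv.begin, s.interval.start)
            if ov > best_ov:
                best_ov, best = ov, iv.data
        out[k] = best
    return pd.DataFrame({"rnaseq": out}, index=[s.site_id for s in sites])


def build_matrix(cfg: PipelineConfig, per_rbp: dict[str, PeakSet]):
    """Merge, split, annotate sites and build the filtered occupancy matrix."""
    sites = merge_sites(list(per_rbp.values()))
    log.info("merged %d filtered peak sets into %d sites", len(per_rbp), len(sites))
    sites = split_long_sites(sites, cfg.bin_len, cfg.step)
    sites = assign_site_ids(sites)
    if cfg.annotation:
        model = rio.read_annotation_gtf(cfg.annotation)
        for s in sites:
            s.annotation = annotate_site(s, model)

    tracks = pd.read_csv(cfg.tracks, sep="\t", dtype={"track_id": str})
    clip_tracks = tracks[tracks["kind"] == "clip"]
    bg_tracks = tracks[tracks["kind"].isin(["rnaseq", "eclip_input"])]
    clip_totals = dict(zip(clip_tracks["track_id"], clip_tracks["total_mapped"].astype(float)))
    bg_id = bg_tracks["track_id"].iloc[0]
    bg_total = float(bg_tracks["total_mapped"].iloc[0])

    clip_counts = clip_counts_for_sites(sites, per_rbp)
    clip_counts = clip_counts[[c for c in clip_counts.columns if c in clip_totals]]
    clip = SignalTable(clip_counts, clip_totals, {t: "clip" for t in clip_totals})

    coverage = rio.read_coverage_tsv(cfg.background_coverage)
    bg_counts = background_counts_for_sites(sites, coverage)
    bg_counts.columns = [bg_id]
    background = SignalTable(bg_counts, {bg_id: bg_total}, {bg_id: "rnaseq"})

    V = build_occupancy(clip, background, quantile=cfg.quantile)
    log.info("occupancy: %d sites with background signal", V.shape[0])
    V = filter_cobound(V, cfg.min_cobound)
    log.info("co-bound filter: %d sites retained", V.shape[0])
    return sites, V


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write every stage output to ``outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_json(outdir / "config.json", cfg.to_json())

    per_rbp = load_filtered_peaks(cfg)
    sites, V = build_matrix(cfg, per_rbp)
    site_by_id = {s.site_id: s for s in sites}
    rio.write_sites_bed([site_by_id[i] for i in V.site_ids], outdir / "sites.bed")
    rio.write_matrix_tsv(outdir / "occupancy.tsv", V.V, V.site_ids, V.rbp_ids)
    rio.write_json(
        outdir / "occupancy_q95.json", dict(zip(V.rbp_ids, map(float, V.q95)))
    )

    candidate_ranks: list[int] = []
    rank = cfg.rank
    if cfg.do_rank_scan or rank is None:
        lo, hi = cfg.rank_range
        stats, candidate_ranks = rank_scan(
            V.V,
            range(lo, hi + 1),
            list(cfg.runs_schedule),
            base_seed=cfg.seed,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
        report = pd.DataFrame(
            [
                {"rank": s.rank, "n_runs": s.n_runs, "cpcc": s.cpcc, "dc": s.dc}
                for s in stats
            ]
        )
        agg = report.groupby("rank").agg(
            cpcc_mean=("cpcc", "mean"), cpcc_min=("cpcc", "min"), cpcc_max=("cpcc", "max"),
            dc_mean=("dc", "mean"), dc_min=("dc", "min"), dc_max=("dc", "max"),
        )
        agg["flagged"] = [r in candidate_ranks for r in agg.index]
        agg.to_csv(outdir / "rank_scan.tsv", sep="\t")
        if rank is None:
            # among flagged candidates, prefer the most stable one by mean DC
            pool = candidate_ranks or list(agg.index)
            rank = int(max(pool, key=lambda r: agg.loc[r, "dc_mean"]))
        log.info("rank scan candidates: %s; using rank %d", candidate_ranks, rank)

    run = best_run(
        V.V, rank, n_runs=cfg.n_best_runs, base_seed=cfg.seed,
        max_iter=cfg.max_iter, tol=cfg.tol,
    )
    group_ids = [f"group{r + 1}" for r in range(rank)]
    rio.write_matrix_tsv(outdir / "basis_W.tsv", run.W, V.site_ids, group_ids)
    rio.write_matrix_tsv(outdir / "coefficients_H.tsv", run.H, group_ids, V.rbp_ids)
    rio.write_json(
        outdir / "nmf_run.json",
        {"rank": run.rank, "seed": run.seed, "kl_error": run.kl_error,
         "n_iter": run.n_iter, "converged": run.converged},
    )

    H_scaled = scale_coefficients(run.H)
    groups = call_members(H_scaled, cfg.membership_threshold, V.rbp_ids)
    with open(outdir / "groups.tsv", "w") as fh:
        fh.write("group\trbp_id\tscaled_weight\n")
        for g in groups:
            for rbp, w in g.members:
                fh.write(f"{g.group_index}\t{rbp}\t{w:.6f}\n")

    associations = associate_sites(
        run.W, cfg.spec_threshold, cfg.coeff_quantile, V.site_ids
    )
    with open(outdir / "associations.tsv", "w") as fh:
        fh.write("site_id\tchrom\tstart\tend\tstrand\tgroup\tbasis_coefficient\tspecificity\n")
        for a in associations:
            s = site_by_id[a.site_id]
            fh.write(
                f"{a.site_id}\t{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{s.interval.strand}\t{a.group_index}\t{a.basis_coefficient:.6g}"
                f"\t{a.specificity:.6f}\n"
            )

    enrichment = _run_enrichment(cfg, groups, associations, site_by_id, V)
    if enrichment:
        rio.write_json(outdir / "enrichment.json", enrichment)

    log.info(
        "pipeline done: %d sites, rank %d, %d associations", V.shape[0], rank, len(associations)
    )
    return PipelineResult(
        sites=sites, V=V, rank=rank, W=run.W, H=run.H, groups=groups,
        associations=associations, candidate_ranks=candidate_ranks,
        enrichment=enrichment, outdir=outdir,
    )


def _run_enrichment(cfg, groups, associations, site_by_id, V) -> dict:
    out: dict = {}
    assoc_sites = {g.group_index: [] for g in groups}
    for a in associations:
        assoc_sites.setdefault(a.group_index, []).append(site_by_id[a.site_id])

    if cfg.network:
        network = enr.AssociationNetwork(rio.read_network_tsv(cfg.network))
        support = {}
        for g in groups:
            if len(g.members) < 2:
                continue
            support[g.group_index] = enr.permutation_group_support(
                g.rbp_ids, V.rbp_ids, network, n_perm=cfg.n_perm, seed=cfg.seed + g.group_index
            )
        out["network_support"] = support

    if cfg.annotation and cfg.halflife:
        model = rio.read_annotation_gtf(cfg.annotation)
        halflife = rio.read_halflife_tsv(cfg.halflife)
        hl = {}
        for g in groups:
            sites = assoc_sites.get(g.group_index, [])
            if not sites:
                continue
            hit_genes = set()
            for s in sites:
                hit_genes |= model.overlapping_genes(s.interval)
            hits = {gene: gene in hit_genes for gene in halflife}
            res = enr.halflife_enrichment(hits, halflife)
            hl[g.group_index] = {
                "p_value": res.p_value, "odds_ratio": res.odds_ratio,
                "log2_ratio": res.log2_ratio,
            }
        out["halflife"] = hl

    if cfg.psi:
        exons = rio.read_psi_tsv(cfg.psi)
        sp = {}
        for g in groups:
            sites = assoc_sites.get(g.group_index, [])
            if not sites:
                continue
            res = enr.splicing_enrichment(sites, exons)
            sp[g.group_index] = {
                "p_value": res.p_value, "odds_ratio": res.odds_ratio,
                "log2_ratio": res.log2_ratio,
            }
        out["splicing"] = sp
    return out
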