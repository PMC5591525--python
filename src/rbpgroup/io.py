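"""Readers and writers for the plain-text formats the pipeline consumes.

Peak files are BED6+ (0-based half-open); the per-peak read count is taken
from the BED score column by default. A manifest TSV maps each peak file to
its (rbp_id, method, replicate) track. Signal tables, half-life, PSI,
network and motif inputs are simple TSVs.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import (
    AnnotationModel,
    CANONICAL_NCRNA_TYPES,
    GenomicInterval,
    MergedSite,
    Peak,
    PeakSet,
)

__all__ = [
    "read_peak_bed",
    "write_sites_bed",
    "read_manifest",
    "read_annotation_gtf",
    "read_coverage_tsv",
    "read_halflife_tsv",
    "read_psi_tsv",
    "read_network_tsv",
    "read_motif_list",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def read_peak_bed(
    path: str | Path,
    rbp_id: str,
    method: str = "unknown",
    replicate: str = "rep1",
    count_column: int = 4,
) -> PeakSet:
    """Read one peak BED file into a :class:`PeakSet`.

    ``count_column`` is the 0-based column index holding the read count
    (default 4, the BED score column).
    """
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "."
            count = int(float(f[count_column])) if len(f) > count_column else 0
            peaks.append(
                Peak(GenomicInterval(f[0], int(f[1]), int(f[2]), strand), count)
            )
    return PeakSet(rbp_id, method, replicate, peaks)


def write_sites_bed(sites: Sequence[MergedSite], path: str | Path) -> None:
    """Write merged sites as BED6 with the annotation category in the name."""
    with open(path, "w") as fh:
        for s in sites:
            name = s.annotation.replace(" ", "_")
            if s.parent_id:
                name += f";parent={s.parent_id}"
            fh.write(
                f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                f"\t{name}\t{len(s.source_rbps)}\t{s.interval.strand}\n"
            )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a peak-file manifest TSV: columns file, rbp_id, method, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"file", "rbp_id", "method", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# annotation

_NCRNA_ALIASES = {t.lower() for t in CANONICAL_NCRNA_TYPES} | {"7sk_rna", "yrna"}


def _classify_gene_type(gene_type: str) -> str | None:
    gt = gene_type.lower()
    if gt in _NCRNA_ALIASES or gt.replace("mt_", "") in _NCRNA_ALIASES:
        return "canonical ncRNA"
    if "pseudogene" in gt:
        return "pseudogene"
    if gt in {"lncrna", "lincrna", "antisense", "processed_transcript"}:
        return "lncRNA"
    if gt == "protein_coding":
        return "coding"
    return None


def _attr(attributes: str, key: str) -> str:
    # GENCODE GTF attribute dialect: key "value"; ...
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return ""


def read_annotation_gtf(path: str | Path) -> AnnotationModel:
    """Flatten a GENCODE-style GTF into an :class:`AnnotationModel`.

    Feature mapping: CDS features of coding genes -> CDS; UTR features are
    split into 5'/3' by position relative to the gene's CDS span and strand;
    exons of lncRNA-like genes -> lncRNA exon; any feature of a pseudogene ->
    pseudogene; canonical ncRNA gene types (miRNA, snRNA, snoRNA, tRNA, rRNA,
    Y RNA, 7SK) -> canonical ncRNA; gene-span bases not covered by exons ->
    intron (coding and lncRNA genes). GTF 1-based closed coordinates are
    converted to 0-based half-open on read.
    """
    model = AnnotationModel()
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            gene_id = _attr(attrs, "gene_id")
            gene_type = _attr(attrs, "gene_type") or _attr(attrs, "gene_biotype")
            g = genes.setdefault(
                gene_id,
                {"type": gene_type, "span": None, "exons": [], "cds": [], "utr": []},
            )
            if gene_type and not g["type"]:
                g["type"] = gene_type
            if feature == "gene":
                g["span"] = iv
            elif feature == "exon":
                g["exons"].append(iv)
            elif feature == "CDS":
                g["cds"].append(iv)
            elif feature in ("UTR", "five_prime_utr", "three_prime_utr"):
                g["utr"].append((feature, iv))

    for gene_id, g in genes.items():
        cls = _classify_gene_type(g["type"] or "")
        span = g["span"]
        if span is None and g["exons"]:
            ex = g["exons"]
            span = GenomicInterval(
                ex[0].chrom, min(e.start for e in ex), max(e.end for e in ex), ex[0].strand
            )
        if cls == "canonical ncRNA":
            for iv in g["exons"] or ([span] if span else []):
                model.add_feature("canonical ncRNA", iv, gene_id)
            continue
        if cls == "pseudogene":
            for iv in g["exons"] or ([span] if span else []):
                model.add_feature("pseudogene", iv, gene_id)
            continue
        if cls == "lncRNA":
            for iv in g["exons"]:
                model.add_feature("lncRNA exon", iv, gene_id)
        elif cls == "coding":
            for iv in g["cds"]:
                model.add_feature("CDS", iv, gene_id)
            cds_lo = min((c.start for c in g["cds"]), default=None)
            cds_hi = max((c.end for c in g["cds"]), default=None)
            for feature, iv in g["utr"]:
                if feature == "five_prime_utr":
                    model.add_feature("5'-UTR", iv, gene_id)
                elif feature == "three_prime_utr":
                    model.add_feature("3'-UTR", iv, gene_id)
                elif cds_lo is not None:
                    upstream = iv.end <= cds_lo
                    five_prime = upstream if iv.strand == "+" else not upstream
                    model.add_feature("5'-UTR" if five_prime else "3'-UTR", iv, gene_id)
        # introns: gene span minus exon cover (coding and lncRNA genes)
        if cls in ("coding", "lncRNA") and span is not None and g["exons"]:
            blocks = sorted((e.start, e.end) for e in g["exons"])
            merged = [list(blocks[0])]
            for s, e in blocks[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            prev = span.start
            for s, e in merged + [[span.end, span.end]]:
                if s > prev:
                    model.add_feature(
                        "intron", GenomicInterval(span.chrom, prev, s, span.strand), gene_id
                    )
                prev = max(prev, e)
    return model


# ---------------------------------------------------------------------------
# signal and side tables

def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    """Read a coverage TSV (chrom, start, end, strand, count) for one track."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "strand", "count"],
        dtype={"chrom": str, "start": int, "end": int, "strand": str, "count": float},
        comment="#",
    )
    if (df["count"] < 0).any():
        raise ValueError("negative coverage counts")
    return df


def read_halflife_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))


def read_psi_tsv(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "strand", "psi"],
        dtype={"chrom": str, "start": int, "end": int, "strand": str, "psi": float},
        comment="#",
    )
    return [
        (GenomicInterval(r.chrom, r.start, r.end, r.strand), r.psi)
        for r in df.itertuples()
    ]


def read_network_tsv(path: str | Path) -> set[tuple[str, str, str]]:
    """Read protein-association edges: rbp_a, rbp_b, evidence_type."""
    edges = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, b, ev = line.rstrip("\n").split("\t")[:3]
            if a == b:
                continue
            edges.add((min(a, b), max(a, b), ev))
    return edges


def read_motif_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_matrix_tsv(
    path: str | Path, matrix, row_ids: Sequence[str], col_ids: Sequence[str]
) -> None:
    pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
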