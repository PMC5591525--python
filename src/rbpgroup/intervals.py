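"""Genomic peak intervals: comparison, filtering, merging, splitting, annotation.

Coordinates are 0-based half-open (BED dialect) throughout. A *peak* is one
caller's call for one RBP in one replicate; a *site* is a merged interval
unified across RBPs, methods and replicates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "MergedSite",
    "AnnotationModel",
    "ANNOTATION_PRIORITY",
    "CANONICAL_NCRNA_TYPES",
    "jaccard_similarity",
    "intersect_methods",
    "filter_replicas",
    "merge_sites",
    "split_long_sites",
    "annotate_site",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """Overlap by at least ``min_bp`` bases, strand-aware unless either is '.'."""
        if self.chrom != other.chrom:
            return False
        if "." not in (self.strand, other.strand) and self.strand != other.strand:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    read_count: int = 0
    score: float | None = None

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")


@dataclass
class PeakSet:
    """All peaks from one (RBP, peak-calling method, replicate) track."""

    rbp_id: str
    method: str
    replicate: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        seen: set[tuple] = set()
        for p in self.peaks:
            key = (p.interval.chrom, p.interval.start, p.interval.end, p.interval.strand)
            if key in seen:
                raise ValueError(f"duplicate peak {key} in {self.rbp_id}/{self.method}/{self.replicate}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


@dataclass
class MergedSite:
    """A unified binding-site interval with contributing RBPs and annotation."""

    interval: GenomicInterval
    source_rbps: frozenset[str] = frozenset()
    annotation: str = "others"
    parent_id: str | None = None
    site_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.interval)


# Priority order used when a site overlaps several feature classes.
ANNOTATION_PRIORITY = (
    "CDS",
    "canonical ncRNA",
    "3'-UTR",
    "5'-UTR",
    "lncRNA exon",
    "pseudogene",
    "intron",
    "intergenic",
    "others",
)

CANONICAL_NCRNA_TYPES = frozenset(
    {"miRNA", "snRNA", "snoRNA", "tRNA", "rRNA", "Y_RNA", "7SK"}
)


class AnnotationModel:
    """Feature intervals per annotation class, queried by overlap.

    Classes follow :data:`ANNOTATION_PRIORITY` (minus the fallbacks
    ``intergenic``/``others`` which are computed, not stored).
    """

    FEATURE_CLASSES = ANNOTATION_PRIORITY[:7]

    def __init__(self) -> None:
        # class -> chrom -> IntervalTree of (start, end, (strand, gene_id))
        self._trees: dict[str, dict[str, IntervalTree]] = {
            c: {} for c in self.FEATURE_CLASSES
        }

    def add_feature(
        self, feature_class: str, interval: GenomicInterval, gene_id: str = ""
    ) -> None:
        if feature_class not in self._trees:
            raise ValueError(f"unknown feature class {feature_class!r}")
        tree = self._trees[feature_class].setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, (interval.strand, gene_id))

    def overlapping_classes(self, interval: GenomicInterval) -> set[str]:
        hits = set()
        for cls, by_chrom in self._trees.items():
            tree = by_chrom.get(interval.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(interval.start, interval.end):
                strand = iv.data[0]
                if "." in (strand, interval.strand) or strand == interval.strand:
                    hits.add(cls)
                    break
        return hits

    def overlapping_genes(self, interval: GenomicInterval) -> set[str]:
        genes = set()
        for by_chrom in self._trees.values():
            tree = by_chrom.get(interval.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(interval.start, interval.end):
                strand, gene_id = iv.data
                if gene_id and ("." in (strand, interval.strand) or strand == interval.strand):
                    genes.add(gene_id)
        return genes


# ---------------------------------------------------------------------------
# interval set arithmetic helpers

def _union_blocks(intervals: Iterable[GenomicInterval]) -> dict[tuple[str, str], list[list[int]]]:
    """Merge intervals into disjoint blocks per (chrom, strand) key."""
    by_key: dict[tuple[str, str], list[list[int]]] = {}
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.strand, i.start, i.end)):
        key = (iv.chrom, iv.strand)
        blocks = by_key.setdefault(key, [])
        if blocks and iv.start <= blocks[-1][1]:  # overlap or bookended
            blocks[-1][1] = max(blocks[-1][1], iv.end)
        else:
            blocks.append([iv.start, iv.end])
    return by_key


def _total_bases(blocks: dict[tuple[str, str], list[list[int]]]) -> int:
    return sum(e - s for bl in blocks.values() for s, e in bl)


def _intersect_bases(a: dict, b: dict) -> int:
    total = 0
    for key, blocks_a in a.items():
        blocks_b = b.get(key)
        if not blocks_b:
            continue
        i = j = 0
        while i < len(blocks_a) and j < len(blocks_b):
            s = max(blocks_a[i][0], blocks_b[j][0])
            e = min(blocks_a[i][1], blocks_b[j][1])
            if e > s:
                total += e - s
            if blocks_a[i][1] < blocks_b[j][1]:
                i += 1
            else:
                j += 1
    return total


def jaccard_similarity(a: PeakSet, b: PeakSet) -> float:
    """Base-level Jaccard index between the interval unions of two peak sets.

    Intersection and union are counted in bases after collapsing each set to
    its per-base union, so nested or duplicated peaks do not inflate either
    term.

    Raises
    ------
    ValueError
        If both sets are empty (the index is undefined).
    """
    if not a.peaks and not b.peaks:
        raise ValueError("Jaccard similarity undefined: both peak sets are empty")
    ua = _union_blocks(a.intervals())
    ub = _union_blocks(b.intervals())
    inter = _intersect_bases(ua, ub)
    union = _total_bases(ua) + _total_bases(ub) - inter
    return inter / union


def intersect_methods(primary: PeakSet, other: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """Keep peaks of ``primary`` confirmed by at least one peak of ``other``.

    Cross-method confirmation: a peak survives when a second caller found a
    peak overlapping it by >= ``min_overlap_bp`` bases. Surviving peaks keep
    the primary caller's coordinates and read counts.
    """
    if primary.rbp_id != other.rbp_id:
        raise ValueError(
            f"method intersection requires matching rbp_id: {primary.rbp_id!r} vs {other.rbp_id!r}"
        )
    others = other.intervals()
    kept = [
        p for p in primary.peaks
        if any(p.interval.overlaps(o, min_overlap_bp) for o in others)
    ]
    return PeakSet(primary.rbp_id, primary.method, primary.replicate, kept)


def filter_replicas(
    replicas: Sequence[PeakSet], min_reads: int = 4, min_replicas: int = 2
) -> PeakSet:
    """Keep peaks with >= ``min_reads`` reads reproduced across replicates.

    A peak qualifies when it carries at least ``min_reads`` reads and overlaps
    (>= 1 bp) a similarly supported peak in at least ``min_replicas - 1``
    other replicates. With a single replicate only the read-count filter
    applies. The returned set is the union of qualifying peaks with
    overlapping or bookended coordinates coalesced; a coalesced peak carries
    the summed read count of its members.
    """
    if not replicas:
        raise ValueError("empty replica list")
    rbp_ids = {r.rbp_id for r in replicas}
    if len(rbp_ids) > 1:
        raise ValueError(f"replicas span multiple RBPs: {sorted(rbp_ids)}")
    rbp_id = replicas[0].rbp_id

    supported = [
        [p for p in r.peaks if p.read_count >= min_reads] for r in replicas
    ]
    if len(replicas) == 1:
        kept = supported[0]
    else:
        kept = []
        for i, peaks in enumerate(supported):
            for p in peaks:
                n_confirming = sum(
                    1
                    for j, other in enumerate(supported)
                    if j != i and any(p.interval.overlaps(q.interval) for q in other)
                )
                if n_confirming >= min_replicas - 1:
                    kept.append(p)

    # coalesce the union across replicates, summing read support
    kept.sort(key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start))
    out: list[Peak] = []
    for p in kept:
        if out and out[-1].interval.chrom == p.interval.chrom \
                and out[-1].interval.strand == p.interval.strand \
                and p.interval.start <= out[-1].interval.end:
            prev = out.pop()
            merged = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, p.interval.end),
                prev.interval.strand,
            )
            out.append(Peak(merged, prev.read_count + p.read_count))
        else:
            out.append(p)
    return PeakSet(rbp_id, "filtered", "pooled", out)


def merge_sites(all_rbp_peaks: Sequence[PeakSet]) -> list[MergedSite]:
    """Coalesce every RBP's filtered peaks into one unified set of sites.

    Overlapping or bookended intervals (per chromosome and strand) merge into
    a single site whose ``source_rbps`` is the union of contributing RBPs.
    """
    tagged: list[tuple[GenomicInterval, str]] = []
    for ps in all_rbp_peaks:
        for p in ps.peaks:
            tagged.append((p.interval, ps.rbp_id))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].strand, t[0].start, t[0].end))

    sites: list[MergedSite] = []
    cur: list | None = None  # [chrom, strand, start, end, set(rbps)]
    for iv, rbp in tagged:
        if cur is not None and iv.chrom == cur[0] and iv.strand == cur[1] and iv.start <= cur[3]:
            cur[3] = max(cur[3], iv.end)
            cur[4].add(rbp)
        else:
            if cur is not None:
                sites.append(
                    MergedSite(GenomicInterval(cur[0], cur[2], cur[3], cur[1]), frozenset(cur[4]))
                )
            cur = [iv.chrom, iv.strand, iv.start, iv.end, {rbp}]
    if cur is not None:
        sites.append(
            MergedSite(GenomicInterval(cur[0], cur[2], cur[3], cur[1]), frozenset(cur[4]))
        )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end))
    return sites


def split_long_sites(
    sites: Sequence[MergedSite], bin_len: int = 100, step: int = 50
) -> list[MergedSite]:
    """Split sites longer than ``bin_len`` into overlapping fixed-length bins.

    Bins start at offsets 0, step, 2*step, ... while a full bin fits; if the
    final bin does not reach the site end, an extra bin anchored at
    ``[end - bin_len, end)`` is appended so every base stays covered. Split
    bins record the parent site in ``parent_id``.
    """
    if not (bin_len > step > 0):
        raise ValueError(f"require bin_len > step > 0, got {bin_len}, {step}")
    out: list[MergedSite] = []
    for idx, site in enumerate(sites):
        iv = site.interval
        if len(iv) <= bin_len:
            out.append(site)
            continue
        parent = site.site_id or f"site_{idx}:{iv.chrom}:{iv.start}-{iv.end}"
        starts = list(range(iv.start, iv.end - bin_len + 1, step))
        if starts[-1] + bin_len < iv.end:
            starts.append(iv.end - bin_len)
        for s in starts:
            out.append(
                MergedSite(
                    GenomicInterval(iv.chrom, s, s + bin_len, iv.strand),
                    site.source_rbps,
                    site.annotation,
                    parent_id=parent,
                )
            )
    return out


def annotate_site(site: MergedSite, model: AnnotationModel) -> str:
    """Assign the highest-priority feature class overlapping the site.

    Priority: CDS > canonical ncRNA > 3'-UTR > 5'-UTR > lncRNA exon >
    pseudogene > intron > intergenic. ``intergenic`` means no stored feature
    overlaps at all.
    """
    hits = model.overlapping_classes(site.interval)
    for cls in AnnotationModel.FEATURE_CLASSES:
        if cls in hits:
            return cls
    return "intergenic"


def assign_site_ids(sites: Sequence[MergedSite]) -> list[MergedSite]:
    """Give every site a stable coordinate-based identifier."""
    for s in sites:
        s.site_id = f"{s.interval.chrom}:{s.interval.start}-{s.interval.end}({s.interval.strand})"
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        warnings.warn("duplicate site coordinates after merge/split; ids disambiguated")
        seen: dict[str, int] = {}
        for s in sites:
            n = seen.get(s.site_id, 0)
            seen[s.site_id] = n + 1
            if n:
                s.site_id = f"{s.site_id}#{n}"
    return list(sites)
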