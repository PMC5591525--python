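"""Downstream evaluation statistics for called RBP groups.

Four families of evidence:

* protein-association support — are within-group network edges more numerous
  than in random RBP sets of the same size (permutation p-value)?
* known-motif enrichment — does a literature motif occur in a larger
  fraction of group-associated sites than of a single RBP's peaks (Fisher)?
* RNA half-life — do group sites preferentially hit short-half-life genes?
* alternative splicing — do group sites flank low-PSI (cassette) exons more
  often than constitutive exons?
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, MergedSite

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "AssociationNetwork",
    "fisher_exact",
    "permutation_group_support",
    "known_motif_fraction",
    "motif_enrichment_group_vs_rbp",
    "halflife_enrichment",
    "splicing_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) for set 1 and (c, d) for set 2 (present/absent)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float
    p_value: float
    log2_ratio: float = float("nan")


class AssociationNetwork:
    """Undirected protein-association edges tagged with an evidence type."""

    EVIDENCE_TYPES = (
        "physical",
        "co-expression",
        "pathway",
        "domain",
        "genetic",
        "co-localization",
    )

    def __init__(self, edges: set[tuple[str, str, str]] | None = None) -> None:
        self._edges: set[tuple[str, str, str]] = set()
        for a, b, ev in edges or ():
            self.add_edge(a, b, ev)

    def add_edge(self, a: str, b: str, evidence: str) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        self._edges.add((min(a, b), max(a, b), evidence))

    def evidence_types(self) -> list[str]:
        return sorted({ev for *_, ev in self._edges})

    def edges_of_type(self, evidence: str) -> set[tuple[str, str]]:
        return {(a, b) for a, b, ev in self._edges if ev == evidence}

    def __len__(self) -> int:
        return len(self._edges)


def fisher_exact(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table.

    The odds ratio is the sample estimate ad/bc (infinity when bc = 0 with
    ad > 0, NaN when both products vanish).
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = table.as_array()
    p = float(stats.fisher_exact(arr, alternative=alternative).pvalue)
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    return EnrichmentResult(table, odds, min(p, 1.0))


def permutation_group_support(
    group_members: list[str],
    universe: list[str],
    network: AssociationNetwork,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation p-value of within-group edge counts per evidence type.

    The statistic is the number of network edges with both endpoints in the
    group. The null draws ``n_perm`` uniform random subsets of ``universe``
    of the same size; p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    members = sorted(set(group_members))
    if len(members) < 2:
        raise ValueError("group must contain at least 2 members")
    uni = sorted(set(universe))
    missing = set(members) - set(uni)
    if missing:
        raise ValueError(f"group members outside universe: {sorted(missing)}")
    index = {r: i for i, r in enumerate(uni)}
    n, k = len(uni), len(members)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, k), dtype=np.intp)
    for t in range(n_perm):
        perms[t] = rng.choice(n, size=k, replace=False)

    out: dict[str, float] = {}
    member_idx = np.array([index[r] for r in members])
    for ev in network.evidence_types():
        A = np.zeros((n, n), dtype=np.int32)
        for a, b in network.edges_of_type(ev):
            if a in index and b in index:
                A[index[a], index[b]] = A[index[b], index[a]] = 1
        observed = int(A[np.ix_(member_idx, member_idx)].sum() // 2)
        sub = A[perms[:, :, None], perms[:, None, :]]
        null = sub.sum(axis=(1, 2)) // 2
        out[ev] = float((1 + int((null >= observed).sum())) / (1 + n_perm))
    return out


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _iupac_pattern(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(_IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC letter {exc.args[0]!r} in motif {motif!r}") from exc


def known_motif_fraction(
    sequences: list[str], motif: str
) -> tuple[int, float]:
    """Count sequences containing >= 1 occurrence of an IUPAC motif.

    Sense strand only; RNA and DNA alphabets are treated as equivalent
    (U == T). Duplicate sequences count separately. Returns
    (count_with_motif, fraction_of_sequences).
    """
    if not sequences:
        raise ValueError("empty sequence list")
    pat = _iupac_pattern(motif)
    hits = sum(1 for s in sequences if pat.search(s.upper().replace("U", "T")))
    return hits, hits / len(sequences)


def motif_enrichment_group_vs_rbp(
    group_sites_with_motif: int,
    group_sites_total: int,
    rbp_peaks_with_motif: int,
    rbp_peaks_total: int,
) -> EnrichmentResult:
    """Fisher enrichment of a motif in group sites vs one RBP's peaks.

    Table rows are (with motif, without motif) for the group's associated
    sites and the individual RBP's peaks; tested one-sided for the group
    fraction exceeding the RBP fraction.
    """
    if group_sites_with_motif > group_sites_total or rbp_peaks_with_motif > rbp_peaks_total:
        raise ValueError("with-motif counts exceed totals")
    table = ContingencyTable2x2(
        group_sites_with_motif,
        group_sites_total - group_sites_with_motif,
        rbp_peaks_with_motif,
        rbp_peaks_total - rbp_peaks_with_motif,
    )
    res = fisher_exact(table, "greater")
    gf = group_sites_with_motif / group_sites_total if group_sites_total else float("nan")
    rf = rbp_peaks_with_motif / rbp_peaks_total if rbp_peaks_total else float("nan")
    res.log2_ratio = _safe_log2_ratio(gf, rf)
    return res


def _safe_log2_ratio(num: float, den: float) -> float:
    if num > 0 and den > 0:
        return math.log2(num / den)
    if num == 0 and den == 0:
        warnings.warn("both fractions zero; log2 ratio undefined")
        return float("nan")
    return float("inf") if den == 0 else float("-inf") if num == 0 else float("nan")


def halflife_enrichment(
    site_gene_hits: dict[str, bool],
    halflife: dict[str, float],
    pct_low: float = 0.20,
    pct_high: float = 0.80,
) -> EnrichmentResult:
    """Enrichment of binding in short- vs long-half-life genes.

    Genes above the ``pct_high`` percentile of half-life are the long class,
    genes below the ``pct_low`` percentile the short class. The log2 ratio
    compares the fraction of each class carrying >= 1 binding site
    (short over long); the Fisher test is one-sided for short-class
    enrichment.
    """
    genes = sorted(halflife)
    values = np.array([halflife[g] for g in genes])
    lo = np.percentile(values, pct_low * 100)
    hi = np.percentile(values, pct_high * 100)
    short = [g for g in genes if halflife[g] < lo]
    long_ = [g for g in genes if halflife[g] > hi]
    if not short or not long_:
        raise ValueError("empty half-life class; check percentile cutoffs")
    s_hit = sum(bool(site_gene_hits.get(g)) for g in short)
    l_hit = sum(bool(site_gene_hits.get(g)) for g in long_)
    table = ContingencyTable2x2(s_hit, len(short) - s_hit, l_hit, len(long_) - l_hit)
    res = fisher_exact(table, "greater")
    res.log2_ratio = _safe_log2_ratio(s_hit / len(short), l_hit / len(long_))
    return res


def splicing_enrichment(
    sites: list[MergedSite],
    exons: list[tuple[GenomicInterval, float]],
    window_bp: int = 2000,
    as_max: float = 0.2,
    const_min: float = 0.8,
) -> EnrichmentResult:
    """Enrichment of binding near alternatively spliced vs constitutive exons.

    Exons with PSI < ``as_max`` are the alternatively spliced (AS) class,
    PSI > ``const_min`` the constitutive class; others are ignored. An exon
    is hit when any site overlaps the window extending ``window_bp`` bases
    up- and downstream of the exon (genomic coordinates, half-open). The
    log2 ratio is AS over constitutive hit fractions; Fisher is one-sided
    for AS enrichment.
    """
    for _, psi in exons:
        if not 0 <= psi <= 1:
            raise ValueError(f"PSI {psi} outside [0, 1]")

    def hit(exon: GenomicInterval) -> bool:
        win = GenomicInterval(
            exon.chrom, max(0, exon.start - window_bp), exon.end + window_bp, exon.strand
        )
        return any(s.interval.overlaps(win) for s in sites)

    as_exons = [e for e, psi in exons if psi < as_max]
    const_exons = [e for e, psi in exons if psi > const_min]
    if not as_exons or not const_exons:
        raise ValueError("empty exon class; check PSI cutoffs")
    a_hit = sum(hit(e) for e in as_exons)
    c_hit = sum(hit(e) for e in const_exons)
    table = ContingencyTable2x2(
        a_hit, len(as_exons) - a_hit, c_hit, len(const_exons) - c_hit
    )
    res = fisher_exact(table, "greater")
    if a_hit == 0 and c_hit == 0:
        warnings.warn("no exon in either class is hit; log2 ratio undefined")
        res.log2_ratio = float("nan")
    else:
        res.log2_ratio = _safe_log2_ratio(a_hit / len(as_exons), c_hit / len(const_exons))
    return res
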