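"""Independent brute-force oracles used to check the package's operations.

Everything here is deliberately naive — per-base boolean arrays, exact
integer enumeration, explicit agglomeration loops — and shares no code with
the implementations under test.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# per-base interval arithmetic (single chromosome of known length)

def base_mask(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return mask


def jaccard_from_masks(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union)


def blocks_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of covered bases (the expected merge result)."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            out.append((start, i))
    if in_run:
        out.append((start, len(mask)))
    return out


def split_bins(start: int, end: int, bin_len: int, step: int) -> list[tuple[int, int]]:
    """Reference splitting rule, written independently: full bins at step
    offsets, plus an end-anchored bin if the tail is uncovered."""
    length = end - start
    if length <= bin_len:
        return [(start, end)]
    bins = []
    off = 0
    while off + bin_len <= length:
        bins.append((start + off, start + off + bin_len))
        off += step
    if bins[-1][1] < end:
        bins.append((end - bin_len, end))
    return bins


# ---------------------------------------------------------------------------
# Fisher's exact test by exact enumeration over fixed margins

def fisher_pvalues_by_margins(r1: int, r2: int, c1: int) -> dict[int, dict[str, float]]:
    """Exact one- and two-sided p-values for every table with margins
    (r1, r2, c1), computed with integer arithmetic.

    Returns {a: {"greater": p, "less": p, "two-sided": p}} for every
    feasible a (first cell).
    """
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {a: math.comb(r1, a) * math.comb(r2, c1 - a) for a in range(lo, hi + 1)}
    total = sum(weights.values())
    out = {}
    for a in range(lo, hi + 1):
        w = weights[a]
        greater = Fraction(sum(weights[k] for k in weights if k >= a), total)
        less = Fraction(sum(weights[k] for k in weights if k <= a), total)
        two = Fraction(sum(wk for wk in weights.values() if wk <= w), total)
        out[a] = {
            "greater": float(greater),
            "less": float(less),
            "two-sided": float(min(two, Fraction(1))),
        }
    return out


# ---------------------------------------------------------------------------
# cophenetic correlation from first principles

def cophenetic_matrix_average_linkage(D: np.ndarray) -> np.ndarray:
    """Cophenetic distances under average (UPGMA) linkage, by explicit
    agglomeration: repeatedly merge the closest pair of clusters; the merge
    height is the cophenetic distance of every cross pair."""
    D = np.asarray(D, float)
    M = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(M)]
    T = np.zeros((M, M))

    def cluster_dist(x: list[int], y: list[int]) -> float:
        return float(np.mean([D[i, j] for i in x for j in y]))

    while len(clusters) > 1:
        best = None
        for p in range(len(clusters)):
            for q in range(p + 1, len(clusters)):
                d = cluster_dist(clusters[p], clusters[q])
                if best is None or d < best[0]:
                    best = (d, p, q)
        d, p, q = best
        for i in clusters[p]:
            for j in clusters[q]:
                T[i, j] = T[j, i] = d
        clusters[p] = clusters[p] + clusters[q]
        del clusters[q]
    return T


def pearson_upper_triangle(A: np.ndarray, B: np.ndarray) -> float:
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))


# ---------------------------------------------------------------------------
# misc

def consensus_loop(connectivities: list[np.ndarray]) -> np.ndarray:
    M = connectivities[0].shape[0]
    out = np.zeros((M, M))
    for C in connectivities:
        for i in range(M):
            for j in range(M):
                out[i, j] += C[i, j]
    return out / len(connectivities)


def entropy_specificity(weights) -> float:
    """Scalar-by-scalar kim score: 1 + (1/log2 R) * sum p log2 p."""
    w = [float(x) for x in weights]
    s = sum(w)
    acc = 0.0
    for x in w:
        p = x / s
        if p > 0:
            acc += p * math.log2(p)
    return 1.0 + acc / math.log2(len(w))


def sort_percentile_classes(values: dict[str, float], low: float, high: float):
    """Short/long classes by strict comparison against interpolated
    percentiles, recomputed here with a plain sort."""
    keys = sorted(values)
    xs = sorted(values[k] for k in keys)

    def pct(q: float) -> float:
        pos = q * (len(xs) - 1)
        lo = int(math.floor(pos))
        hi = int(math.ceil(pos))
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    lo_cut, hi_cut = pct(low), pct(high)
    short = {k for k in keys if values[k] < lo_cut}
    long_ = {k for k in keys if values[k] > hi_cut}
    return short, long_
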