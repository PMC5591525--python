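"""Consensus-clustering diagnostics for choosing the NMF rank.

Each factorization induces a hard clustering of the RBPs (argmax over the
coefficient rows). Averaging the binary same-cluster connectivity matrices
over many seeded runs yields a consensus matrix C whose entries measure how
reproducibly two RBPs co-cluster. Two stability summaries are computed per
rank: the cophenetic correlation coefficient (CPCC) of the dissimilarity
D = 1 - C against its average-linkage dendrogram, and the dispersion
coefficient (DC), which measures how far C sits from the uninformative value
0.5. Candidate ranks are local maxima of either summary over the rank axis.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .nmf import NMFRun, factorize

__all__ = [
    "ConsensusStats",
    "connectivity_matrix",
    "consensus_matrix",
    "cophenetic_cc",
    "dispersion",
    "rank_scan",
    "best_run",
]

_SEED_MOD = 2**31


@dataclass
class ConsensusStats:
    """Consensus diagnostics for one rank at one run count."""

    rank: int
    n_runs: int
    C: np.ndarray
    cpcc: float
    dc: float
    seeds: list[int] = field(default_factory=list)


def connectivity_matrix(H: np.ndarray) -> np.ndarray:
    """Binary same-cluster matrix from one coefficient matrix.

    RBP j is assigned to cluster argmax_r H[r, j] (ties break to the
    smallest index); entry (i, j) is 1 iff i and j share the assignment.
    """
    H = np.asarray(H, float)
    labels = np.argmax(H, axis=0)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(runs: list[NMFRun]) -> np.ndarray:
    """Elementwise mean of the runs' connectivity matrices."""
    if not runs:
        raise ValueError("no runs")
    shapes = {r.H.shape for r in runs}
    if len(shapes) > 1:
        raise ValueError(f"runs disagree on (rank, M): {sorted(shapes)}")
    return np.mean([connectivity_matrix(r.H) for r in runs], axis=0)


def cophenetic_cc(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity D = 1 - C.

    Pearson correlation between the upper triangle of D and the cophenetic
    distances of its average-linkage dendrogram. Degenerate inputs with zero
    variance on either side (e.g. a perfect consensus) return 1.0: every
    pairwise relation is equally stable, which is maximal agreement.
    """
    C = np.asarray(C, float)
    M = C.shape[0]
    if C.shape != (M, M) or M < 3:
        raise ValueError("consensus matrix must be square with M >= 3")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    Z = linkage(d, method="average")
    t = cophenet(Z)
    if np.ptp(d) == 0 or np.ptp(t) == 0:
        return 1.0
    return float(np.corrcoef(d, t)[0, 1])


def dispersion(C: np.ndarray) -> float:
    """Dispersion of the consensus matrix away from 0.5, normalized to [0, 1].

    DC = (1/M^2) * sum_ij 4 (C_ij - 1/2)^2; equals 1 exactly when every entry
    is 0 or 1 (all runs agree) and 1/M when all off-diagonal entries are 0.5.
    """
    C = np.asarray(C, float)
    M = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / (M * M))


def _run_seeds(base_seed: int, rank: int, n: int) -> list[int]:
    return [(base_seed + rank * 100_003 + k) % _SEED_MOD for k in range(n)]


def rank_scan(
    V: np.ndarray,
    ranks: range | list[int] = range(5, 21),
    runs_schedule: list[int] = (10, 30, 50, 80, 100),
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> tuple[list[ConsensusStats], list[int]]:
    """Scan ranks, computing consensus stability at each run-schedule size.

    For each rank the largest scheduled number of factorizations is run once
    (distinct seeds derived from ``base_seed``) and the consensus matrix for
    a schedule entry n uses the first n runs. Per-rank CPCC and DC are the
    means across schedule entries. Returns all per-(rank, n_runs) stats and
    the candidate ranks: local maxima of mean CPCC or mean DC, where a local
    maximum is strictly greater than both rank neighbors (endpoints compare
    to their single neighbor).
    """
    V = np.asarray(V, float)
    N, M = V.shape
    ranks = [r for r in ranks]
    feasible = [r for r in ranks if r <= min(N, M)]
    if len(feasible) < len(ranks):
        warnings.warn(
            f"rank range truncated to <= min(N, M) = {min(N, M)}", stacklevel=2
        )
    if not feasible:
        raise ValueError("no feasible ranks")
    schedule = sorted(runs_schedule)

    stats: list[ConsensusStats] = []
    mean_cpcc, mean_dc = [], []
    for r in feasible:
        seeds = _run_seeds(base_seed, r, schedule[-1])
        runs = [factorize(V, r, s, max_iter=max_iter, tol=tol) for s in seeds]
        per_rank = []
        for n in schedule:
            C = consensus_matrix(runs[:n])
            per_rank.append(
                ConsensusStats(r, n, C, cophenetic_cc(C), dispersion(C), seeds[:n])
            )
        stats.extend(per_rank)
        mean_cpcc.append(float(np.mean([s.cpcc for s in per_rank])))
        mean_dc.append(float(np.mean([s.dc for s in per_rank])))

    candidates = sorted(
        set(_local_maxima(feasible, mean_cpcc)) | set(_local_maxima(feasible, mean_dc))
    )
    return stats, candidates


def _local_maxima(ranks: list[int], values: list[float]) -> list[int]:
    out = []
    for i, r in enumerate(ranks):
        left_ok = i == 0 or values[i] > values[i - 1]
        right_ok = i == len(ranks) - 1 or values[i] > values[i + 1]
        if left_ok and right_ok:
            out.append(r)
    return out


def best_run(
    V: np.ndarray,
    R: int,
    n_runs: int = 100,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> NMFRun:
    """Return the lowest-KL factorization among ``n_runs`` seeded restarts.

    Seeds are ``base_seed .. base_seed + n_runs - 1``; ties break to the
    smallest seed.
    """
    best: NMFRun | None = None
    for k in range(n_runs):
        run = factorize(V, R, (base_seed + k) % _SEED_MOD, max_iter=max_iter, tol=tol)
        if best is None or run.kl_error < best.kl_error:
            best = run
    assert best is not None
    return best
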