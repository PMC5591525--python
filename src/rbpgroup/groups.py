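"""RBP group membership from H and site-to-group association from W.

The factorization is a soft clustering: after scaling each RBP's column of
the coefficient matrix to [0, 1], every group whose scaled weight exceeds a
threshold claims that RBP, so one protein can sit in several groups. On the
basis side, a site is tied to a group only when its basis row is concentrated
on that group (entropy-based specificity score) and its basis coefficient is
large within the group's column — which rules out promiscuous high-abundance
sites bound weakly by many RBPs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .occupancy import positive_quantile

__all__ = [
    "RBPGroup",
    "SiteAssociation",
    "scale_coefficients",
    "call_members",
    "kim_specificity",
    "associate_sites",
]


@dataclass
class RBPGroup:
    group_index: int  # 1-based
    members: list[tuple[str, float]] = field(default_factory=list)

    @property
    def rbp_ids(self) -> list[str]:
        return [m[0] for m in self.members]


@dataclass
class SiteAssociation:
    site_id: str
    group_index: int  # 1-based
    basis_coefficient: float
    specificity: float


def scale_coefficients(H: np.ndarray) -> np.ndarray:
    """Scale each column of H to [0, 1] by dividing by its maximum.

    All-zero columns are left untouched (with a warning) rather than
    producing NaNs.
    """
    H = np.asarray(H, float)
    col_max = H.max(axis=0)
    zero = col_max == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero coefficient columns", stacklevel=2)
    safe = np.where(zero, 1.0, col_max)
    return H / safe


def call_members(
    H_scaled: np.ndarray,
    threshold: float = 0.2,
    rbp_ids: list[str] | None = None,
) -> list[RBPGroup]:
    """Assign RBP j to every group r with scaled weight > ``threshold``.

    Groups with no member above threshold are retained empty so group
    indices stay aligned with the basis columns.
    """
    if not 0 < threshold < 1:
        raise ValueError("membership threshold must lie in (0, 1)")
    H_scaled = np.asarray(H_scaled, float)
    R, M = H_scaled.shape
    if rbp_ids is None:
        rbp_ids = [f"RBP{j}" for j in range(M)]
    groups = [RBPGroup(r + 1) for r in range(R)]
    for j in range(M):
        rows = np.nonzero(H_scaled[:, j] > threshold)[0]
        if rows.size == 0:
            warnings.warn(f"RBP {rbp_ids[j]!r} falls below threshold in every group")
        for r in rows:
            groups[r].members.append((rbp_ids[j], float(H_scaled[r, j])))
    return groups


def kim_specificity(w_row: np.ndarray) -> float:
    """Entropy-based basis-specificity of one site's basis row.

    With p = w / sum(w), the score is 1 + (1/log2 R) * sum_r p_r log2 p_r:
    1 when the row loads a single group, 0 when it is uniform across all R
    groups. Scale-invariant by construction.
    """
    w = np.asarray(w_row, float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("specificity needs a 1-D row over R >= 2 groups")
    if (w < 0).any():
        raise ValueError("basis row must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero basis row has undefined specificity")
    p = w / total
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log2(nz)))
    return 1.0 - entropy / np.log2(w.size)


def associate_sites(
    W: np.ndarray,
    spec_threshold: float = 0.8,
    coeff_quantile: float = 0.80,
    site_ids: list[str] | None = None,
) -> list[SiteAssociation]:
    """Associate sites to groups by specificity and basis-coefficient rules.

    Site i is associated to group r iff its basis-specificity exceeds
    ``spec_threshold`` and W[i, r] exceeds the ``coeff_quantile`` quantile of
    column r (computed over the column's strictly positive entries).
    """
    W = np.asarray(W, float)
    N, R = W.shape
    if site_ids is None:
        site_ids = [f"site{i}" for i in range(N)]
    cutoffs = np.array([positive_quantile(W[:, r], coeff_quantile) for r in range(R)])
    out: list[SiteAssociation] = []
    for i in range(N):
        row = W[i]
        if row.sum() == 0:
            continue
        spec = kim_specificity(row)
        if spec <= spec_threshold:
            continue
        for r in np.nonzero(row > cutoffs)[0]:
            out.append(SiteAssociation(site_ids[i], int(r) + 1, float(row[r]), spec))
    return out
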