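"""Occupancy profile matrix: CLIP signal normalized by background RNA-seq.

CLIP read coverage at a site tracks transcript abundance as much as binding.
Under a fast binding equilibrium the fraction of transcript copies bound at a
site (the occupancy Theta) is proportional to CLIP RPM divided by background
RNA-seq RPM (or eCLIP size-matched input RPM). Scaling each RBP's ratios by
their 95% quantile maps them onto [0, 1], treating the most heavily bound
sites as effectively fully occupied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import MergedSite

__all__ = ["SignalTable", "OccupancyMatrix", "compute_rpm", "build_occupancy", "filter_cobound"]


@dataclass
class SignalTable:
    """Raw counts per (site, track) plus per-track library sizes.

    ``counts`` is a site x track DataFrame of raw read counts; ``total_mapped``
    maps track_id -> total mapped reads; ``kind`` maps track_id to one of
    {"clip", "rnaseq", "eclip_input"}.
    """

    counts: pd.DataFrame
    total_mapped: dict[str, float]
    kind: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("signal counts must be non-negative")
        for t in self.counts.columns:
            if self.total_mapped.get(t, 0) <= 0:
                raise ValueError(f"track {t!r} needs total mapped reads > 0")

    def rpm(self) -> pd.DataFrame:
        totals = np.array([self.total_mapped[t] for t in self.counts.columns], float)
        return self.counts * (1e6 / totals)


@dataclass
class OccupancyMatrix:
    """N sites x M RBPs matrix of occupancies in [0, 1]."""

    V: np.ndarray
    site_ids: list[str]
    rbp_ids: list[str]
    q95: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, float)
        if self.V.shape != (len(self.site_ids), len(self.rbp_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.V < 0).any() or (self.V > 1).any():
            raise ValueError("occupancies must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.V.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.V, index=self.site_ids, columns=self.rbp_ids)


def compute_rpm(count: float, total_mapped: float) -> float:
    """Reads per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count * 1e6 / total_mapped


def positive_quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile over strictly positive values only."""
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("no strictly positive values for quantile")
    return float(np.quantile(pos, q))


def build_occupancy(
    clip: SignalTable,
    background: SignalTable,
    sites: Sequence[MergedSite] | Sequence[str] | None = None,
    quantile: float = 0.95,
) -> OccupancyMatrix:
    """Build the occupancy matrix Theta from CLIP and background signal.

    Per site i and RBP track j: ratio_ij = clip_rpm_ij / background_rpm_i.
    Sites with zero raw background count are discarded (no transcript
    evidence means the ratio is meaningless). Each column is scaled by the
    ``quantile`` quantile of its strictly positive ratios and clipped at 1.

    ``background`` must have exactly one track covering all sites.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    if background.counts.shape[1] != 1:
        raise ValueError("background table must contain exactly one track")
    if sites is not None:
        ids = [s.site_id if isinstance(s, MergedSite) else s for s in sites]
        missing = set(ids) - set(background.counts.index)
        if missing:
            raise ValueError(f"{len(missing)} sites missing from background table")
        clip_counts = clip.counts.reindex(ids).fillna(0.0)
        bg_counts = background.counts.loc[ids]
    else:
        ids = list(clip.counts.index)
        bg_counts = background.counts.reindex(ids)
        if bg_counts.isna().any().any():
            raise ValueError("background table missing sites present in CLIP table")
        clip_counts = clip.counts

    bg_raw = bg_counts.values[:, 0].astype(float)
    keep = bg_raw > 0  # "no RNA-seq signal" = raw count of zero
    ids = [i for i, k in zip(ids, keep) if k]

    clip_rpm = SignalTable(clip_counts.loc[ids], clip.total_mapped, clip.kind).rpm().values
    bg_total = background.total_mapped[background.counts.columns[0]]
    bg_rpm = bg_raw[keep] * 1e6 / bg_total

    ratio = clip_rpm / bg_rpm[:, None]
    rbp_ids = list(clip.counts.columns)
    q = np.empty(len(rbp_ids))
    for j, rbp in enumerate(rbp_ids):
        col = ratio[:, j]
        if not (col > 0).any():
            raise ValueError(f"RBP {rbp!r} has no positive CLIP/background ratios")
        q[j] = positive_quantile(col, quantile)
    theta = np.minimum(1.0, ratio / q)
    return OccupancyMatrix(theta, ids, rbp_ids, q)


def filter_cobound(V: OccupancyMatrix, min_rbps: int = 2) -> OccupancyMatrix:
    """Retain sites bound by at least ``min_rbps`` RBPs (positive entries).

    Single-RBP rows carry no co-binding information and are dropped before
    factorization.
    """
    keep = (V.V > 0).sum(axis=1) >= min_rbps
    if not keep.any():
        raise ValueError(f"no sites with >= {min_rbps} bound RBPs remain")
    return OccupancyMatrix(
        V.V[keep], [s for s, k in zip(V.site_ids, keep) if k], V.rbp_ids, V.q95
    )
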