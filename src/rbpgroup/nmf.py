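"""Kullback-Leibler non-negative matrix factorization, V ~ W @ H.

Multiplicative updates (Lee & Seung) for the generalized KL divergence

    F(W, H) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ],

which is the natural objective for non-negative count-like data and the loss
under which the occupancy matrix is decomposed into binding-site basis
vectors (W, sites x rank) and RBP coefficients (H, rank x RBPs).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NMFRun", "kl_divergence", "factorize"]

_EPS = 1e-12  # denominator floor in the multiplicative updates
_FLOOR = 1e-16  # positivity floor on the factors (prevents exact underflow)
_INIT_LOW = 1e-6  # lower bound of the uniform random initialization


@dataclass
class NMFRun:
    """One seeded factorization: basis W (N x R), coefficients H (R x M)."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    seed: int
    kl_error: float
    n_iter: int
    converged: bool
    trajectory: list[float] | None = None  # per-iteration objective, if recorded


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence between V and W @ H.

    Uses the convention 0*log 0 = 0; returns +inf when (WH)_ij = 0 at an
    entry where V_ij > 0.
    """
    V = np.asarray(V, float)
    if (V < 0).any() or (np.asarray(W) < 0).any() or (np.asarray(H) < 0).any():
        raise ValueError("V, W, H must be non-negative")
    WH = W @ H
    pos = V > 0
    if np.any(WH[pos] == 0):
        return float("inf")
    out = np.sum(WH) - np.sum(V)
    out += np.sum(V[pos] * np.log(V[pos] / WH[pos]))
    return float(out)


def factorize(
    V: np.ndarray,
    R: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-5,
    check_every: int = 10,
    record_objective: bool = False,
) -> NMFRun:
    """Factorize ``V`` into rank-``R`` non-negative factors by KL updates.

    Starts from i.i.d. Uniform(1e-6, 1) factors drawn with ``seed``; iterates

        H <- H * (W.T @ (V / WH)) / (W.T @ 1)
        W <- W * ((V / WH) @ H.T) / (1 @ H.T)

    with denominators floored at 1e-12, and stops when the relative decrease
    of the objective over ``check_every`` iterations falls below ``tol`` (or
    at ``max_iter``). Identical seed gives identical factors.
    """
    V = np.asarray(V, float)
    if (V < 0).any():
        raise ValueError("V must be non-negative")
    N, M = V.shape
    if R > min(N, M):
        raise ValueError(f"rank {R} exceeds min(N, M) = {min(N, M)}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(_INIT_LOW, 1.0, size=(N, R))
    H = rng.uniform(_INIT_LOW, 1.0, size=(R, M))

    if record_objective:
        check_every = 1
    prev = kl_divergence(V, W, H)
    trajectory = [prev] if record_objective else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        np.maximum(H, _FLOOR, out=H)  # keep factors strictly positive in float
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        np.maximum(W, _FLOOR, out=W)
        if it % check_every == 0 or it == max_iter:
            cur = kl_divergence(V, W, H)
            if not np.isfinite(cur):
                raise FloatingPointError("non-finite KL objective")
            if trajectory is not None:
                trajectory.append(cur)
            denom = abs(prev) if prev != 0 else 1.0
            if prev - cur < tol * denom:
                converged = True
                prev = cur
                break
            prev = cur
    return NMFRun(
        W=W, H=H, rank=R, seed=seed, kl_error=float(prev), n_iter=it,
        converged=converged, trajectory=trajectory,
    )
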