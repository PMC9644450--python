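"""Euclidean projection onto the probability simplex (sparsemax) and helpers.

sparsemax(z) = argmin_{p in simplex} ||p - z||^2.  Unlike softmax, the
solution can place exact zeros on low-scoring coordinates; the threshold
separating the support from the zeros is determined from the scores
themselves.  This module provides the forward map, the threshold/support
decomposition, the Jacobian-vector product needed to backpropagate through
the projection, a masked variant for padded inputs, and a brute-force
KKT enumeration oracle used for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SparsemaxSolution",
    "sparsemax",
    "sparsemax_threshold",
    "sparsemax_jvp",
    "masked_sparsemax",
    "masked_sparsemax_batch",
    "masked_softmax_batch",
    "simplex_project_oracle",
]


@dataclass(frozen=True)
class SparsemaxSolution:
    """Projection result: simplex weights, adaptive threshold, support set."""

    weights: np.ndarray
    tau: float
    support: np.ndarray = field(repr=False)


def _validate(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.ndim != 1:
        raise ValueError(f"expected a 1-D score vector, got ndim={z.ndim}")
    if z.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("scores must be finite")
    return z


def sparsemax_threshold(z: np.ndarray) -> SparsemaxSolution:
    """Full solution of the simplex projection via sort-and-scan.

    The threshold tau satisfies sum_j max(z_j - tau, 0) = 1; the support is
    the largest k such that 1 + k * z_(k) > sum_{i<=k} z_(i) over the
    descending order statistics z_(1) >= ... >= z_(K).  O(K log K).
    """
    z = _validate(z)
    z_sorted = np.sort(z)[::-1]
    cssv = np.cumsum(z_sorted)
    ks = np.arange(1, z.size + 1)
    k = int(ks[1.0 + ks * z_sorted > cssv][-1])
    tau = (cssv[k - 1] - 1.0) / k
    weights = np.maximum(z - tau, 0.0)
    support = np.flatnonzero(z > tau)
    return SparsemaxSolution(weights=weights, tau=float(tau), support=support)


def sparsemax(z: np.ndarray) -> np.ndarray:
    """Project a finite score vector onto the probability simplex."""
    return sparsemax_threshold(z).weights


def sparsemax_jvp(z: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Jacobian-vector product J(z) @ v of the sparsemax map.

    On the support S the Jacobian acts by centering: (Jv)_j = v_j - mean_S(v);
    off the support the output is zero.  At boundary points (z_j == tau) the
    subgradient corresponding to the retained support is used.
    """
    z = _validate(z)
    v = np.asarray(v, dtype=np.float64)
    if v.shape != z.shape:
        raise ValueError(f"shape mismatch: z {z.shape} vs v {v.shape}")
    support = sparsemax_threshold(z).support
    out = np.zeros_like(z)
    out[support] = v[support] - v[support].mean()
    return out


def masked_sparsemax(z: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Sparsemax restricted to the coordinates where ``mask`` is true.

    Masked-out slots get exact zero weight; on the valid slots the result
    equals sparsemax of the corresponding subvector.
    """
    z = _validate(z)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != z.shape:
        raise ValueError(f"shape mismatch: z {z.shape} vs mask {mask.shape}")
    if not mask.any():
        raise ValueError("empty bag: mask has no valid entries")
    out = np.zeros_like(z)
    out[mask] = sparsemax(z[mask])
    return out


def masked_sparsemax_batch(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise masked sparsemax for a (batch, K) score matrix.

    Vectorized over rows: masked slots are treated as -inf scores, which is
    equivalent to projecting the valid subvector (they can never enter the
    support and do not shift the threshold).
    """
    scores = np.asarray(scores, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if scores.shape != mask.shape or scores.ndim != 2:
        raise ValueError("scores and mask must be equal-shape 2-D arrays")
    if not mask.any(axis=1).all():
        raise ValueError("empty bag: a mask row has no valid entries")
    z = np.where(mask, scores, -np.inf)
    z_sorted = np.sort(z, axis=1)[:, ::-1]
    cssv = np.cumsum(np.where(np.isfinite(z_sorted), z_sorted, 0.0), axis=1)
    ks = np.arange(1, scores.shape[1] + 1)[None, :]
    feasible = np.where(np.isfinite(z_sorted), 1.0 + ks * z_sorted > cssv, False)
    k = feasible.sum(axis=1)  # >= 1 since each row has a valid entry
    tau = (np.take_along_axis(cssv, k[:, None] - 1, axis=1)[:, 0] - 1.0) / k
    return np.where(mask, np.maximum(scores - tau[:, None], 0.0), 0.0)


def masked_softmax_batch(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax over the valid slots; zeros elsewhere (dense baseline)."""
    scores = np.asarray(scores, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if scores.shape != mask.shape or scores.ndim != 2:
        raise ValueError("scores and mask must be equal-shape 2-D arrays")
    if not mask.any(axis=1).all():
        raise ValueError("empty bag: a mask row has no valid entries")
    shifted = scores - np.max(np.where(mask, scores, -np.inf), axis=1, keepdims=True)
    expd = np.where(mask, np.exp(shifted), 0.0)
    return expd / expd.sum(axis=1, keepdims=True)


def simplex_project_oracle(z: np.ndarray, max_k: int = 12) -> np.ndarray:
    """Brute-force simplex projection by support enumeration (verification only).

    Tries every nonempty candidate support S, solves for the threshold
    tau = (sum_S z - 1)/|S|, and accepts when the KKT conditions hold:
    z_j - tau > 0 on S and z_j - tau <= 0 off S.  Exponential in K.
    """
    z = _validate(z)
    K = z.size
    if K > max_k:
        raise ValueError(f"oracle refuses K={K} > {max_k} (combinatorial blow-up)")
    supports = (
        (np.arange(1, 2**K)[:, None] >> np.arange(K)[None, :]) & 1
    ).astype(bool)  # all 2^K - 1 nonempty candidate supports
    taus = (supports @ z - 1.0) / supports.sum(axis=1)
    slack = z[None, :] - taus[:, None]
    feasible = np.all(np.where(supports, slack > 0, slack <= 1e-15), axis=1)
    assert feasible.any(), "KKT enumeration found no feasible support"
    cand = np.where(supports[feasible], slack[feasible], 0.0)
    obj = np.sum((cand - z[None, :]) ** 2, axis=1)
    return cand[np.argmin(obj)]
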