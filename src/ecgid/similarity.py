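"""Distance and similarity kernels between equal-length heartbeat waveforms.

Euclidean and Mahalanobis distances shrink toward 0 for similar beats;
cosine similarity grows toward 1. ``to_percent`` maps a distance onto a
bounded 0-100 similarity scale so heterogeneous metrics can be reported on
one axis.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .errors import ArgumentError, NumericalError

METRICS = ("euclidean", "mahalanobis", "cosine")


def _check_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 1:
        raise ArgumentError(
            f"waveforms must be equal-length 1-D arrays, got {p.shape} vs {q.shape}"
        )
    return p, q


def euclidean(p, q) -> float:
    """Euclidean distance sqrt(sum_i (q_i - p_i)^2)."""
    p, q = _check_pair(p, q)
    return float(np.sqrt(np.sum((q - p) ** 2)))


def mahalanobis(p, q, C) -> float:
    """Mahalanobis distance sqrt((p-q) C^-1 (p-q)^T).

    Reduces to the Euclidean distance when C is the identity. Raises
    :class:`NumericalError` (naming the condition number) when C is not
    symmetric positive-definite.
    """
    p, q = _check_pair(p, q)
    C = np.asarray(C, dtype=np.float64)
    if C.shape != (p.size, p.size):
        raise ArgumentError(f"covariance must be {p.size}x{p.size}, got {C.shape}")
    diff = p - q
    try:
        cho = linalg.cho_factor(C, check_finite=False)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise NumericalError(
            f"covariance is not positive-definite (condition number {cond:.3e})"
        ) from exc
    d2 = float(diff @ linalg.cho_solve(cho, diff, check_finite=False))
    # clip tiny negative round-off before the sqrt
    return float(np.sqrt(max(d2, 0.0)))


def cosine(p, q) -> float:
    """Cosine similarity p.q / (|p||q|), in [-1, 1]; 1 means identical shape."""
    p, q = _check_pair(p, q)
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0.0 or nq == 0.0:
        raise ArgumentError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(p, q) / (np_ * nq), -1.0, 1.0))


def to_percent(d: float, scale: float) -> float:
    """Map a distance d >= 0 to a similarity percentage in (0, 100].

    Uses the bounded inverse form 100*scale/(scale+d): 100 at d=0, 50 at
    d=scale, strictly decreasing in d. ``scale`` is typically the median
    intra-set distance.
    """
    if d < 0:
        raise ArgumentError(f"distance must be non-negative, got {d}")
    if not scale > 0:
        raise ArgumentError(f"scale must be positive, got {scale}")
    return float(100.0 * scale / (scale + d))


def cosine_to_percent(c: float) -> float:
    """Affine map of a cosine similarity [-1, 1] onto [0, 100]."""
    if not -1.0 <= c <= 1.0:
        raise ArgumentError(f"cosine similarity must lie in [-1, 1], got {c}")
    return float(50.0 * (c + 1.0))


def estimate_covariance(cycles, ridge: float = 1e-6) -> np.ndarray:
    """Sample covariance of a stack of cycles with diagonal loading.

    Parameters
    ----------
    cycles : (n_cycles, n_samples) array-like
    ridge : fractional diagonal loading, added as ridge*trace/dim*I so the
        matrix is always invertible even with fewer cycles than samples.
    """
    X = np.asarray(cycles, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ArgumentError("need a 2-D stack of at least two cycles")
    C = np.cov(X, rowvar=False)
    dim = C.shape[0]
    C = C + ridge * (np.trace(C) / dim) * np.eye(dim)
    return C


def median_distance_scale(cycles, reference) -> float:
    """Median Euclidean distance of a cycle stack to a reference waveform.

    The conventional ``scale`` argument for :func:`to_percent`.
    """
    X = np.asarray(cycles, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    d = np.sqrt(np.sum((X - ref[None, :]) ** 2, axis=1))
    med = float(np.median(d))
    return med if med > 0 else 1.0
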