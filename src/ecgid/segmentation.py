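"""Fiducial beat segmentation and length matching.

Each beat is cut in a fixed window around its R peak — 0.3 s of the P-wave
side and 0.4 s of the T-wave side — and can be resampled to the length of a
reference (ideal) cycle so waveforms are compared point for point.
Windows are half-open [start, end) on a 0-based sample grid; beats whose
window would cross a record edge are dropped.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import ArgumentError
from .records import Cycle, EcgRecord, RPeakSet

log = logging.getLogger(__name__)

DEFAULT_PRE_S = 0.3
DEFAULT_POST_S = 0.4


def cycle_length(fs: float, pre: float = DEFAULT_PRE_S, post: float = DEFAULT_POST_S) -> int:
    """Window length in samples: round(pre*fs) + round(post*fs)."""
    return int(round(pre * fs)) + int(round(post * fs))


def segment_cycles(
    record: EcgRecord,
    peaks: RPeakSet,
    pre: float = DEFAULT_PRE_S,
    post: float = DEFAULT_POST_S,
) -> list[Cycle]:
    """One :class:`Cycle` per R peak whose full window fits in the record.

    Out-of-bounds beats (too close to either record edge) are dropped and
    the count is logged. An empty peak set yields an empty list.
    """
    if pre <= 0 or post <= 0:
        raise ArgumentError("pre and post must be positive")
    if len(peaks) == 0:
        log.warning("segment_cycles: empty R-peak set for %s", record.subject_id)
        return []
    fs = record.fs
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    cycles: list[Cycle] = []
    dropped = 0
    for r in peaks.indices:
        start, end = int(r) - n_pre, int(r) + n_post
        if start < 0 or end > record.samples.size:
            dropped += 1
            continue
        cycles.append(
            Cycle(
                samples=record.samples[start:end].copy(),
                fs=fs,
                r_index=n_pre,
                subject_id=record.subject_id,
                condition=record.condition,
            )
        )
    if dropped:
        log.info("segment_cycles: dropped %d edge beat(s) of %d", dropped, len(peaks))
    return cycles


def match_length(cycle: Cycle, target_length: int) -> Cycle:
    """Resample a beat to ``target_length`` samples by linear interpolation.

    The first and last samples are preserved exactly; the R index and the
    effective sampling rate are rescaled proportionally. Identity when the
    length already matches.
    """
    if target_length < 2:
        raise ArgumentError(f"target_length must be >= 2, got {target_length}")
    n = len(cycle)
    if n == target_length:
        return cycle
    ratio = (target_length - 1) / (n - 1) if n > 1 else 1.0
    old_grid = np.arange(n, dtype=np.float64)
    new_grid = np.linspace(0.0, n - 1, target_length)
    resampled = np.interp(new_grid, old_grid, cycle.samples)
    return Cycle(
        samples=resampled,
        fs=cycle.fs * ratio,
        r_index=min(target_length - 1, int(round(cycle.r_index * ratio))),
        subject_id=cycle.subject_id,
        condition=cycle.condition,
    )


def cycles_matrix(cycles: list[Cycle]) -> np.ndarray:
    """Stack equal-length cycles into an (n_cycles, n_samples) matrix."""
    if not cycles:
        raise ArgumentError("no cycles to stack")
    lengths = {len(c) for c in cycles}
    if len(lengths) != 1:
        raise ArgumentError(f"cycles have mixed lengths {sorted(lengths)}")
    return np.vstack([c.samples for c in cycles])
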