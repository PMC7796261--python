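"""Adaptive threshold-filter normalization of heartbeat sets.

The core procedure: for each subject, the static-state beat closest
(Euclidean) to the generated ideal cycle becomes the subject's *sample
cycle* (maximum-similarity-rate selection). Every recognition beat is then
scored by its Euclidean distance S to that sample cycle, and a beat passes
the filter when

    S < k + Th * step

where k is the minimum of S over the set, Th is an integer threshold on the
grid {0, 1, ..., ceil((l-k)/step)} between k and the maximum l, and the grid
``step`` is 1 (raw distance units) when the spread l-k is at least 1, else
one percent of the spread. Beats tied at the minimum S are always kept, so
the filtered set is never empty. Raising Th admits more beats; lowering it
keeps only the beats most similar to the subject's own template, discarding
motion-artifact-corrupted cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .ideal_cycle import IdealCycle
from .records import Cycle
from .similarity import euclidean


@dataclass
class SampleCycle:
    """A subject's normalization template: the static beat nearest the ideal."""

    samples: np.ndarray
    subject_id: str | None
    distance_to_ideal: float
    source_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclass
class SimilarityProfile:
    """Euclidean distances S of a beat set to a sample cycle, with bounds.

    ``k``/``l`` are the min/max of S; ``step`` is the integer-grid unit for
    thresholds (1.0 in raw distance units, or spread/100 when the spread is
    sub-unit); ``grid_max`` is the largest useful Th.
    """

    values: np.ndarray
    k: float = field(init=False)
    l: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ArgumentError("similarity profile needs at least one cycle")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ArgumentError("distances must be finite and non-negative")
        self.k = float(np.min(self.values))
        self.l = float(np.max(self.values))

    @property
    def step(self) -> float:
        spread = self.l - self.k
        if spread >= 1.0:
            return 1.0
        return spread / 100.0  # 1-percent grid for sub-unit spreads

    @property
    def grid_max(self) -> int:
        if self.step == 0.0:
            return 0
        return int(math.ceil((self.l - self.k) / self.step))


@dataclass
class NormalizedSet:
    """Beats that passed the threshold filter."""

    cycles: list[Cycle]
    indices: np.ndarray
    threshold: int
    pass_rate: float

    def __len__(self) -> int:
        return len(self.cycles)


def _check_lengths(cycles: Sequence[Cycle], n: int, what: str) -> None:
    for i, c in enumerate(cycles):
        if len(c) != n:
            raise ArgumentError(
                f"cycle {i} has length {len(c)}, expected {n} (length-match to the {what} first)"
            )


def select_sample_cycle(static_cycles: Sequence[Cycle], ideal: IdealCycle) -> SampleCycle:
    """Pick the static beat with minimum Euclidean distance to the ideal.

    Ties are broken toward the lowest index. All beats must already be
    length-matched to the ideal cycle.
    """
    if len(static_cycles) == 0:
        raise ArgumentError("need at least one static cycle")
    _check_lengths(static_cycles, ideal.length, "ideal cycle")
    d = np.array([euclidean(c.samples, ideal.samples) for c in static_cycles])
    best = int(np.argmin(d))  # argmin returns the first minimum
    return SampleCycle(
        samples=static_cycles[best].samples.copy(),
        subject_id=static_cycles[best].subject_id,
        distance_to_ideal=float(d[best]),
        source_index=best,
    )


def similarity_profile(cycles: Sequence[Cycle], sample: SampleCycle) -> SimilarityProfile:
    """Euclidean distance of every beat to the sample cycle."""
    if len(cycles) == 0:
        raise ArgumentError("need at least one cycle to profile")
    _check_lengths(cycles, sample.samples.size, "sample cycle")
    return SimilarityProfile(
        values=np.array([euclidean(c.samples, sample.samples) for c in cycles])
    )


def filter_cycles(
    profile: SimilarityProfile, cycles: Sequence[Cycle], Th: int
) -> NormalizedSet:
    """Keep the beats with S < k + Th*step (minimum-S beats always kept).

    The kept count is non-decreasing in Th; for Th > (l-k)/step every beat
    passes.
    """
    if Th < 0:
        raise ArgumentError(f"threshold must be >= 0, got {Th}")
    if int(Th) != Th:
        raise ArgumentError(f"threshold must lie on the integer grid, got {Th}")
    if len(cycles) != profile.values.size:
        raise ArgumentError("profile and cycle list disagree in length")
    S = profile.values
    mask = (S < profile.k + Th * profile.step) | (S == profile.k)
    idx = np.flatnonzero(mask)
    return NormalizedSet(
        cycles=[cycles[i] for i in idx],
        indices=idx,
        threshold=int(Th),
        pass_rate=float(idx.size / S.size),
    )


def choose_threshold(profile: SimilarityProfile, min_pass: float) -> int:
    """Smallest grid threshold whose pass rate reaches ``min_pass``.

    Always terminates: one past the grid maximum keeps every beat.
    """
    if not 0.0 < min_pass <= 1.0:
        raise ArgumentError(f"min_pass must be in (0, 1], got {min_pass}")
    S = profile.values
    for th in range(profile.grid_max + 2):
        n_kept = int(np.sum((S < profile.k + th * profile.step) | (S == profile.k)))
        if n_kept / S.size >= min_pass:
            return th
    return profile.grid_max + 1  # unreachable; keep-all bound


def normalize_cycles(
    recognition_cycles: Sequence[Cycle],
    sample: SampleCycle,
    Th: int | None = None,
    min_pass: float | None = None,
) -> tuple[NormalizedSet, SimilarityProfile]:
    """Profile + filter in one call; exactly one of Th / min_pass given."""
    if (Th is None) == (min_pass is None):
        raise ArgumentError("give exactly one of Th or min_pass")
    profile = similarity_profile(recognition_cycles, sample)
    if Th is None:
        Th = choose_threshold(profile, min_pass)
    return filter_cycles(profile, recognition_cycles, Th), profile
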