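"""Core in-memory containers for single-lead ECG data.

Voltages are millivolts throughout; time is seconds; sample indices are
0-based. ``EcgRecord.annotations`` carries ground-truth or detected R-peak
sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ArgumentError

#: canonical wave order of one cardiac cycle
WAVES = ("P", "Q", "R", "S", "T")

#: minimum physiologically plausible spacing between R peaks (seconds)
REFRACTORY_S = 0.2


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class EcgRecord:
    """A single-lead ECG trace.

    Parameters
    ----------
    samples : array of mV values
    fs : sampling rate in Hz
    subject_id, condition : optional provenance labels
    annotations : optional strictly increasing R-peak sample indices
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    condition: str | None = None
    annotations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.samples.ndim != 1:
            raise ArgumentError("samples must be a 1-D array")
        if not self.fs > 0:
            raise ArgumentError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ArgumentError("samples must be finite")
        if self.annotations is not None:
            ann = np.asarray(self.annotations, dtype=np.int64)
            if ann.size and (
                np.any(np.diff(ann) <= 0)
                or ann[0] < 0
                or ann[-1] >= self.samples.size
            ):
                raise ArgumentError(
                    "annotations must be strictly increasing within [0, length)"
                )
            self.annotations = ann

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "EcgRecord":
        """Copy of this record with new samples; labels/fs/annotations kept."""
        return replace(self, samples=_as_float_array(samples))


@dataclass
class RPeakSet:
    """Detected or annotated R-peak locations (sample indices) at rate fs."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if not self.fs > 0:
            raise ArgumentError(f"fs must be positive, got {self.fs}")
        if self.indices.size > 1:
            gaps = np.diff(self.indices)
            if np.any(gaps <= 0):
                raise ArgumentError("R-peak indices must be strictly increasing")
            if np.any(gaps < REFRACTORY_S * self.fs):
                raise ArgumentError(
                    f"R-peak gaps must be >= {REFRACTORY_S}s (refractory period)"
                )

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def rr_intervals(self) -> np.ndarray:
        """RR intervals in seconds."""
        return np.diff(self.indices) / self.fs


@dataclass
class Cycle:
    """One fixed-window heartbeat cut around an R peak.

    ``r_index`` is the sample offset of the R peak inside the window.
    ``peaks`` optionally maps wave name ("P".."T") to a sample index inside
    the window.
    """

    samples: np.ndarray
    fs: float
    r_index: int
    subject_id: str | None = None
    condition: str | None = None
    peaks: Mapping[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ArgumentError("cycle samples must be a non-empty 1-D array")
        if not (0 <= self.r_index < self.samples.size):
            raise ArgumentError("r_index must lie inside the cycle window")

    def __len__(self) -> int:
        return int(self.samples.size)
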