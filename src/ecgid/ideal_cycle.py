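"""Construction of the ideal one-cycle ECG from averaged peak information.

An "ideal" cycle is a noise-free single heartbeat built from the average
voltage and sample location of the five fiducial peaks (P, Q, R, S, T) of a
set of annotated beats. Neighbouring peaks are bridged by first- or
second-order interpolation: the linear bridge

    y(n) = y1 + w*(n - x1),            w = (y2 - y1)/(x2 - x1)

for the steep QRS limbs, and the normalized quadratic bridge

    y(n) = y1 + (y2 - y1) * ((n - x1)/(x2 - x1))^2

for the rounded P/T waves. Both forms pass exactly through the two
endpoints, so the generated waveform reproduces every vertex to machine
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError, DataError
from .records import WAVES, Cycle

log = logging.getLogger(__name__)

#: bridge segments of one cycle, in temporal order
SEGMENTS = ("onset_p", "p_q", "q_r", "r_s", "s_t", "t_offset")

#: default interpolation order per segment: quadratic for the rounded
#: P/T waves and the onset/offset shoulders, linear for the straight QRS limbs
DEFAULT_ORDER_MAP: dict[str, int] = {
    "onset_p": 2,
    "p_q": 2,
    "q_r": 1,
    "r_s": 1,
    "s_t": 2,
    "t_offset": 2,
}


@dataclass
class PeakStats:
    """Per-wave average voltage (mV) and sample location of P,Q,R,S,T peaks.

    ``voltages`` and ``locations`` are length-5 arrays in wave order
    P, Q, R, S, T. Locations must be strictly increasing and the R voltage
    must dominate all others.
    """

    voltages: np.ndarray
    locations: np.ndarray
    n_cycles_averaged: int = 1

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=np.float64)
        self.locations = np.asarray(self.locations, dtype=np.float64)
        if self.voltages.shape != (5,) or self.locations.shape != (5,):
            raise ArgumentError("voltages and locations must each have 5 entries")
        if np.any(np.diff(self.locations) <= 0):
            raise ArgumentError(
                "peak locations must be strictly ordered P < Q < R < S < T"
            )
        r_idx = WAVES.index("R")
        if not np.all(self.voltages[r_idx] > np.delete(self.voltages, r_idx)):
            raise ArgumentError("R voltage must strictly dominate P, Q, S, T")
        if self.n_cycles_averaged < 1:
            raise ArgumentError("n_cycles_averaged must be >= 1")

    def voltage(self, wave: str) -> float:
        return float(self.voltages[WAVES.index(wave)])

    def location(self, wave: str) -> float:
        return float(self.locations[WAVES.index(wave)])


@dataclass
class IdealCycle:
    """A generated noise-free single-beat waveform.

    ``peak_indices`` are the integer sample positions of the five vertices;
    the waveform passes exactly through the (location, voltage) pairs.
    """

    samples: np.ndarray
    peak_indices: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.samples.size)

    @property
    def r_index(self) -> int:
        return int(self.peak_indices[WAVES.index("R")])


def annotate_peaks(cycle: Cycle) -> dict[str, int]:
    """Locate the five fiducial peaks inside a fixed-window beat.

    Uses the known R position and physiological search windows relative to
    it: Q is the minimum just before R, S the minimum just after, P the
    maximum in the atrial window before the QRS and T the maximum in the
    repolarization window after it.
    """
    s, fs, r = cycle.samples, cycle.fs, cycle.r_index
    n = s.size

    def win(lo_s: float, hi_s: float) -> tuple[int, int]:
        lo = max(0, r + int(round(lo_s * fs)))
        hi = min(n, r + int(round(hi_s * fs)))
        if hi <= lo:
            raise DataError("cycle window too short to annotate peaks")
        return lo, hi

    peaks: dict[str, int] = {"R": r}
    lo, hi = win(-0.06, 0.0)
    peaks["Q"] = lo + int(np.argmin(s[lo:hi]))
    lo, hi = win(0.001, 0.07)
    peaks["S"] = lo + int(np.argmin(s[lo:hi]))
    lo, hi = win(-0.26, -0.07)
    peaks["P"] = lo + int(np.argmax(s[lo:hi]))
    lo, hi = win(0.10, 0.39)
    peaks["T"] = lo + int(np.argmax(s[lo:hi]))
    if not (peaks["P"] < peaks["Q"] < peaks["R"] < peaks["S"] < peaks["T"]):
        raise DataError(f"annotated peaks are not ordered: {peaks}")
    return peaks


def compute_peak_stats(cycles: Sequence[Cycle]) -> PeakStats:
    """Arithmetic per-wave mean of voltage and location over annotated beats.

    Every cycle must carry a full ``peaks`` annotation (all five waves);
    a missing wave raises :class:`DataError` naming it.
    """
    if len(cycles) == 0:
        raise ArgumentError("need at least one annotated cycle")
    volts = np.empty((len(cycles), 5))
    locs = np.empty((len(cycles), 5))
    for i, cyc in enumerate(cycles):
        if cyc.peaks is None:
            raise DataError(f"cycle {i} has no peak annotations")
        for j, wave in enumerate(WAVES):
            if wave not in cyc.peaks:
                raise DataError(f"cycle {i} is missing the {wave} peak annotation")
            idx = int(cyc.peaks[wave])
            locs[i, j] = idx
            volts[i, j] = cyc.samples[idx]
    return PeakStats(
        voltages=volts.mean(axis=0),
        locations=locs.mean(axis=0),
        n_cycles_averaged=len(cycles),
    )


def interpolate_segment(
    x1: float, y1: float, x2: float, y2: float, order: int, n
) -> np.ndarray:
    """Bridge two vertices over the sample grid ``n``.

    order=1 gives the straight line through the endpoints; order=2 the
    normalized quadratic y1 + (y2-y1)*t^2 with t = (n-x1)/(x2-x1). Both
    return exactly y1 at n=x1 and y2 at n=x2.
    """
    if x2 <= x1:
        raise ArgumentError(f"degenerate segment: x2 ({x2}) must exceed x1 ({x1})")
    if order not in (1, 2):
        raise ArgumentError(f"order must be 1 or 2, got {order}")
    n = np.asarray(n, dtype=np.float64)
    t = (n - x1) / (x2 - x1)
    return y1 + (y2 - y1) * (t if order == 1 else t**2)


def generate_ideal_cycle(
    stats: PeakStats,
    target_length: int,
    order_map: Mapping[str, int] | None = None,
) -> IdealCycle:
    """Assemble the full ideal cycle of ``target_length`` samples.

    Vertex locations are rounded to the integer sample grid; bridges are laid
    down onset->P->Q->R->S->T->offset, with the onset/offset shoulders
    interpolating from/to the 0 mV baseline (the convention after baseline
    removal). If the vertex span does not fit the window as annotated, the
    span is re-centred.
    """
    orders = dict(DEFAULT_ORDER_MAP)
    if order_map:
        unknown = set(order_map) - set(SEGMENTS)
        if unknown:
            raise ArgumentError(f"unknown segments in order_map: {sorted(unknown)}")
        orders.update(order_map)

    locs = np.rint(stats.locations).astype(np.int64)
    span = int(locs[-1] - locs[0])
    if target_length < span + 1:
        raise ArgumentError(
            f"target_length {target_length} is shorter than the vertex span {span + 1}"
        )
    if locs[0] < 0 or locs[-1] >= target_length:
        locs = locs - locs[0] + (target_length - 1 - span) // 2
        log.debug("vertex span re-centred to %s", locs.tolist())

    volts = stats.voltages
    out = np.zeros(target_length, dtype=np.float64)

    # (x1, y1, x2, y2, order) for each bridge; skip zero-length shoulders
    knots_x = np.concatenate(([0], locs, [target_length - 1]))
    knots_y = np.concatenate(([0.0], volts, [0.0]))
    for seg, xa, ya, xb, yb in zip(
        SEGMENTS, knots_x[:-1], knots_y[:-1], knots_x[1:], knots_y[1:]
    ):
        if xb == xa:
            if seg in ("onset_p", "t_offset"):  # vertex sits on the window edge
                out[xa] = ya if seg == "t_offset" else yb
                continue
            raise ArgumentError(f"degenerate {seg} segment at sample {xa}")
        grid = np.arange(xa, xb + 1)
        out[xa : xb + 1] = interpolate_segment(xa, ya, xb, yb, orders[seg], grid)

    out[locs] = volts  # vertices exact by construction; enforce bit-exactness
    return IdealCycle(samples=out, peak_indices=locs)
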