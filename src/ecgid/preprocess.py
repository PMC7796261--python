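"""Denoising and R-peak detection for raw single-lead ECG.

Stage order follows acquisition practice: zero-phase Butterworth bandpass,
Pan-Tompkins R-wave detection, moving-average smoothing that spares the QRS
complex (it carries the subject-specific morphology), then piecewise linear
baseline estimation anchored in the TP segment of each beat and subtracted
so the isoelectric line sits at 0 mV.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ArgumentError, InsufficientDataError
from .records import REFRACTORY_S, EcgRecord, RPeakSet

log = logging.getLogger(__name__)

DEFAULT_BAND = (0.5, 40.0)
DEFAULT_ORDER = 4
DEFAULT_SMOOTH_WINDOW_S = 0.025
DEFAULT_QRS_HALFWIDTH_S = 0.060
#: fraction of the RR interval (from the R peak) where the baseline knot sits;
#: ~2/3 through the beat lands in the quiet TP segment
BASELINE_KNOT_FRACTION = 0.66
SNAP_TOLERANCE_S = 0.025


def bandpass(
    record: EcgRecord,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EcgRecord:
    """Zero-phase Butterworth bandpass; removes drift below ``low`` and
    high-frequency noise above ``high`` without phase distortion."""
    nyq = record.fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ArgumentError(
            f"cutoffs must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={record.fs}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.fs, output="sos")
    return record.with_samples(sps.sosfiltfilt(sos, record.samples))


def _pan_tompkins_stages(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """QRS-band filter, five-point derivative, squaring, 150 ms integration."""
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * fs / 8.0
    deriv = np.convolve(filt, kernel, mode="same")
    squared = deriv**2
    mwi = uniform_filter1d(squared, size=max(1, int(round(0.150 * fs))), mode="nearest")
    return filt, mwi


def detect_r_peaks(record: EcgRecord) -> RPeakSet:
    """Pan-Tompkins QRS detection with adaptive dual thresholds.

    Stages: 5-15 Hz bandpass, derivative, squaring, 150 ms moving-window
    integration; candidate peaks classified against running signal/noise
    levels (threshold = noise + 0.25*(signal - noise)) with a 0.2 s
    refractory period, T-wave discrimination inside 360 ms, and a
    half-threshold search-back when a beat is missed for 1.66x the running
    RR average. Accepted peaks are snapped to the local maximum of the
    input signal within +/-25 ms. Deterministic.
    """
    fs = record.fs
    x = record.samples
    if x.size < 2 * fs:
        raise InsufficientDataError(
            f"need >= 2 s of samples for R detection, got {x.size / fs:.2f} s"
        )
    filt, mwi = _pan_tompkins_stages(x, fs)
    refr = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refr)
    if cand.size == 0 or np.max(mwi) <= 0:
        return RPeakSet(indices=np.array([], dtype=np.int64), fs=fs)

    learn = mwi[: int(2 * fs)]
    spki = 0.7 * float(np.max(learn))
    npki = 0.5 * float(np.mean(learn))

    def slope_near(i: int) -> float:
        lo, hi = max(0, i - refr // 2), min(x.size, i + refr // 2)
        return float(np.max(np.abs(np.diff(filt[lo:hi])))) if hi - lo > 1 else 0.0

    accepted: list[int] = []
    rr_hist: list[float] = []

    def accept(i: int, peak: float, searchback: bool) -> None:
        nonlocal spki
        if accepted:
            rr_hist.append(i - accepted[-1])
            if len(rr_hist) > 8:
                rr_hist.pop(0)
        accepted.append(i)
        spki = (0.25 if searchback else 0.125) * peak + (
            0.75 if searchback else 0.875
        ) * spki

    for c in cand:
        peak = mwi[c]
        thr1 = npki + 0.25 * (spki - npki)
        rr_avg = float(np.mean(rr_hist)) if rr_hist else None

        if accepted and rr_avg is not None and (c - accepted[-1]) > 1.66 * rr_avg:
            # missed-beat search-back at half threshold
            lo, hi = accepted[-1] + refr, c - refr // 2
            if hi > lo:
                seg = np.arange(lo, hi)
                inner = seg[sps.argrelmax(mwi[lo:hi], order=1)[0]] if hi - lo > 2 else seg
                inner = inner[mwi[inner] > 0.5 * thr1]
                if inner.size:
                    best = int(inner[np.argmax(mwi[inner])])
                    accept(best, mwi[best], searchback=True)

        if peak > thr1:
            is_twave = False
            if accepted and (c - accepted[-1]) < 0.36 * fs:
                # T waves have gentler slope than the preceding QRS
                is_twave = slope_near(c) < 0.5 * slope_near(accepted[-1])
            if is_twave or (accepted and (c - accepted[-1]) < refr):
                npki = 0.125 * peak + 0.875 * npki
            else:
                accept(int(c), peak, searchback=False)
        else:
            npki = 0.125 * peak + 0.875 * npki

    if not accepted:
        return RPeakSet(indices=np.array([], dtype=np.int64), fs=fs)

    # the MWI peak lags the R wave by up to half the integration window:
    # locate the QRS-band maximum in a trailing window, then snap to the
    # local maximum of the input signal within +/-25 ms
    snap = int(round(SNAP_TOLERANCE_S * fs))
    lag = int(round(0.150 * fs))
    snapped = []
    for i in accepted:
        lo, hi = max(0, i - lag), min(x.size, i + snap + 1)
        j = lo + int(np.argmax(filt[lo:hi]))
        lo2, hi2 = max(0, j - snap), min(x.size, j + snap + 1)
        snapped.append(lo2 + int(np.argmax(x[lo2:hi2])))

    # dedupe after snapping, keeping the larger-amplitude peak of close pairs
    snapped = sorted(set(snapped))
    final: list[int] = []
    for i in snapped:
        if final and i - final[-1] < refr:
            if x[i] > x[final[-1]]:
                final[-1] = i
        else:
            final.append(i)
    return RPeakSet(indices=np.asarray(final, dtype=np.int64), fs=fs)


def smooth_outside_qrs(
    record: EcgRecord,
    peaks: RPeakSet,
    window: float = DEFAULT_SMOOTH_WINDOW_S,
    qrs_halfwidth: float = DEFAULT_QRS_HALFWIDTH_S,
) -> EcgRecord:
    """Centred moving average everywhere except inside QRS windows.

    Samples within ``qrs_halfwidth`` seconds of an R peak are returned
    bit-identical to the input: the QRS complex is the discriminative part
    of the beat and must not be blurred.
    """
    if window <= 0 or qrs_halfwidth <= 0:
        raise ArgumentError("window and qrs_halfwidth must be positive")
    fs = record.fs
    size = max(1, int(round(window * fs)))
    smoothed = uniform_filter1d(record.samples, size=size, mode="nearest")
    if len(peaks) == 0:
        warnings.warn("empty R-peak set: smoothing the whole record", stacklevel=2)
        return record.with_samples(smoothed)
    hw = int(round(qrs_halfwidth * fs))
    out = smoothed.copy()
    for r in peaks.indices:
        lo, hi = max(0, r - hw), min(out.size, r + hw + 1)
        out[lo:hi] = record.samples[lo:hi]
    return record.with_samples(out)


def remove_baseline(record: EcgRecord, peaks: RPeakSet) -> EcgRecord:
    """Piecewise-linear baseline removal anchored in the TP segment.

    One knot is placed 66% of the way through each RR interval (the
    isoelectric TP segment); its level is the median of the samples within
    +/-25 ms. The knot-to-knot first-order (linear) trend is subtracted,
    held flat beyond the first/last knot, calibrating the baseline to 0 mV.
    """
    if len(peaks) < 2:
        raise InsufficientDataError("need at least two R peaks for baseline removal")
    fs = record.fs
    x = record.samples
    idx = peaks.indices
    half = max(1, int(round(0.025 * fs)))
    knots_x = []
    knots_y = []
    for a, b in zip(idx[:-1], idx[1:]):
        k = int(round(a + BASELINE_KNOT_FRACTION * (b - a)))
        lo, hi = max(0, k - half), min(x.size, k + half + 1)
        knots_x.append(k)
        knots_y.append(float(np.median(x[lo:hi])))
    baseline = np.interp(np.arange(x.size), knots_x, knots_y)
    return record.with_samples(x - baseline)


def preprocess_record(
    record: EcgRecord,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW_S,
    qrs_halfwidth: float = DEFAULT_QRS_HALFWIDTH_S,
) -> tuple[EcgRecord, RPeakSet]:
    """Full denoising chain: bandpass -> R detect -> QRS-sparing smoothing ->
    baseline removal. Returns the cleaned record and the detected peaks."""
    filtered = bandpass(record, low, high, order)
    rpeaks = detect_r_peaks(filtered)
    smoothed = smooth_outside_qrs(filtered, rpeaks, smooth_window, qrs_halfwidth)
    if len(rpeaks) < 2:
        log.warning(
            "record %s: %d R peak(s) found; skipping baseline removal",
            record.subject_id, len(rpeaks),
        )
        return smoothed, rpeaks
    cleaned = remove_baseline(smoothed, rpeaks)
    return cleaned, rpeaks


def match_annotations(
    detected: RPeakSet, truth: np.ndarray, tolerance_s: float = 0.05
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected peaks to ground truth.

    Returns (true positives, false positives, false negatives) at the given
    time tolerance; the standard beat-detector scoring.
    """
    tol = tolerance_s * detected.fs
    truth = np.asarray(truth, dtype=np.int64)
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    for d in detected.indices:
        if truth.size == 0:
            break
        j = int(np.argmin(np.abs(truth - d) + np.where(used, 10 * tol + 1, 0)))
        if not used[j] and abs(int(truth[j]) - int(d)) <= tol:
            used[j] = True
            tp += 1
    fp = len(detected) - tp
    fn = truth.size - tp
    return tp, fp, fn
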