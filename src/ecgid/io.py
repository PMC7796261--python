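"""CSV I/O for records, peaks, cycles, peak statistics and ideal cycles.

Dialect: comma-separated, UTF-8, header row, time in seconds, voltage in
mV. Record-level metadata (sampling rate, labels) travels in a single
leading comment line ``# key=value,...`` so a file is self-describing;
a record CSV without its sampling rate is rejected at parse time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .ideal_cycle import IdealCycle, PeakStats
from .records import WAVES, Cycle, EcgRecord, RPeakSet

_META_PREFIX = "# "


def _write_meta(fh, meta: dict) -> None:
    parts = [f"{k}={v}" for k, v in meta.items() if v is not None and v != ""]
    fh.write(_META_PREFIX + ",".join(parts) + "\n")


def _read_meta(path: Path) -> tuple[dict, int]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith(_META_PREFIX):
        return {}, 0
    meta = {}
    for part in first[len(_META_PREFIX):].strip().split(","):
        if "=" in part:
            k, v = part.split("=", 1)
            meta[k] = v
    return meta, 1


def write_record_csv(record: EcgRecord, path: str | Path) -> None:
    """Two-column (time_s, mv) CSV with a metadata comment line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(
            fh,
            {
                "fs_hz": f"{float(record.fs):.17g}",
                "subject_id": record.subject_id,
                "condition": record.condition,
            },
        )
        fh.write("time_s,mv\n")
        t = record.times
        for ti, v in zip(t, record.samples):
            fh.write(f"{ti:.9g},{float(v):.17g}\n")


def read_record_csv(path: str | Path, annotations: np.ndarray | None = None) -> EcgRecord:
    """Read a record CSV; raises :class:`ParseError` if fs metadata is absent."""
    path = Path(path)
    meta, skip = _read_meta(path)
    if "fs_hz" not in meta:
        raise ParseError(f"{path}:1: missing fs_hz metadata line ('# fs_hz=...')")
    try:
        fs = float(meta["fs_hz"])
    except ValueError as exc:
        raise ParseError(f"{path}:1: unparseable fs_hz {meta['fs_hz']!r}") from exc
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:
        raise ParseError(f"{path}: malformed CSV body: {exc}") from exc
    if "mv" not in df.columns:
        raise ParseError(f"{path}:2: expected 'time_s,mv' header, got {list(df.columns)}")
    return EcgRecord(
        samples=df["mv"].to_numpy(dtype=np.float64),
        fs=fs,
        subject_id=meta.get("subject_id"),
        condition=meta.get("condition"),
        annotations=annotations,
    )


def write_peaks_csv(peaks: RPeakSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, {"fs_hz": f"{float(peaks.fs):.17g}"})
        fh.write("sample_index\n")
        for i in peaks.indices:
            fh.write(f"{int(i)}\n")


def read_peaks_csv(path: str | Path) -> RPeakSet:
    path = Path(path)
    meta, skip = _read_meta(path)
    if "fs_hz" not in meta:
        raise ParseError(f"{path}:1: missing fs_hz metadata line")
    df = pd.read_csv(path, skiprows=skip)
    return RPeakSet(
        indices=df["sample_index"].to_numpy(dtype=np.int64), fs=float(meta["fs_hz"])
    )


def write_cycles_csv(cycles: list[Cycle], path: str | Path) -> None:
    """Matrix CSV (one row per beat) plus a ``<stem>_meta.csv`` sidecar."""
    path = Path(path)
    mat = np.vstack([c.samples for c in cycles])
    pd.DataFrame(mat).to_csv(path, index=False)
    meta = pd.DataFrame(
        {
            "cycle_id": range(len(cycles)),
            "subject_id": [c.subject_id or "" for c in cycles],
            "condition": [c.condition or "" for c in cycles],
            "r_index": [c.r_index for c in cycles],
            "fs_hz": [c.fs for c in cycles],
        }
    )
    meta.to_csv(path.with_name(path.stem + "_meta.csv"), index=False)


def read_cycles_csv(path: str | Path) -> list[Cycle]:
    path = Path(path)
    mat = pd.read_csv(path).to_numpy(dtype=np.float64)
    meta_path = path.with_name(path.stem + "_meta.csv")
    if not meta_path.exists():
        raise ParseError(f"missing sidecar metadata file {meta_path}")
    meta = pd.read_csv(meta_path, keep_default_na=False)
    if len(meta) != mat.shape[0]:
        raise ParseError(
            f"{meta_path}: {len(meta)} metadata rows for {mat.shape[0]} cycles"
        )
    return [
        Cycle(
            samples=mat[i],
            fs=float(row.fs_hz),
            r_index=int(row.r_index),
            subject_id=str(row.subject_id) or None,
            condition=str(row.condition) or None,
        )
        for i, row in enumerate(meta.itertuples())
    ]


def write_peak_stats_csv(stats: PeakStats, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, {"n_cycles_averaged": stats.n_cycles_averaged})
        fh.write("wave,mean_voltage_mv,mean_location_sample\n")
        for w, v, loc in zip(WAVES, stats.voltages, stats.locations):
            fh.write(f"{w},{float(v):.17g},{float(loc):.17g}\n")


def read_peak_stats_csv(path: str | Path) -> PeakStats:
    path = Path(path)
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    df = df.set_index("wave").loc[list(WAVES)]
    return PeakStats(
        voltages=df["mean_voltage_mv"].to_numpy(dtype=np.float64),
        locations=df["mean_location_sample"].to_numpy(dtype=np.float64),
        n_cycles_averaged=int(meta.get("n_cycles_averaged", 1)),
    )


def write_ideal_cycle_csv(cycle: IdealCycle, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, {"peak_indices": ";".join(map(str, cycle.peak_indices))})
        fh.write("sample_index,mv\n")
        for i, v in enumerate(cycle.samples):
            fh.write(f"{i},{float(v):.17g}\n")
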