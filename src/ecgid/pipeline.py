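"""End-to-end identification pipeline and its configuration.

``run_pipeline`` executes preprocess -> segment -> length-match ->
adaptive-filter normalization -> classification on a cohort of records
(registration = static enrollment recordings, recognition = probe
recordings from complex conditions) and returns a JSON-serializable report
that embeds the fully resolved configuration, per-stage beat counts and
accuracies with and without normalization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import adaptive_filter as af
from . import identification as ident
from . import preprocess as pp
from . import segmentation as seg
from .errors import ArgumentError, ConfigError
from .ideal_cycle import annotate_peaks, compute_peak_stats, generate_ideal_cycle
from .records import Cycle, EcgRecord
from . import similarity
from .similarity import METRICS

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, validated at construction."""

    fs: float = 500.0
    bandpass_low: float = 0.5
    bandpass_high: float = 40.0
    bandpass_order: int = 4
    smooth_window: float = 0.025
    qrs_halfwidth: float = 0.060
    segment_pre: float = 0.3
    segment_post: float = 0.4
    metric: str = "euclidean"
    threshold: int | None = None
    min_pass: float | None = 0.7
    cycle_counts: tuple[int, ...] = (1, 2, 3, 4, 5)
    classifier: str = "nearest_template"
    lstm: ident.LstmConfig = field(default_factory=ident.LstmConfig)
    compare_unnormalized: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high < self.fs / 2:
            raise ConfigError("bandpass cutoffs must satisfy 0 < low < high < fs/2")
        if self.smooth_window <= 0 or self.qrs_halfwidth <= 0:
            raise ConfigError("smoothing window and QRS halfwidth must be positive")
        if self.segment_pre <= 0 or self.segment_post <= 0:
            raise ConfigError("segmentation windows must be positive")
        if self.metric not in METRICS:
            raise ConfigError(f"metric must be one of {METRICS}")
        if (self.threshold is None) == (self.min_pass is None):
            raise ConfigError("set exactly one of threshold / min_pass")
        if self.min_pass is not None and not 0.0 < self.min_pass <= 1.0:
            raise ConfigError("min_pass must be in (0, 1]")
        if self.classifier not in ("nearest_template", "lstm"):
            raise ConfigError("classifier must be 'nearest_template' or 'lstm'")
        if any(c < 1 for c in self.cycle_counts):
            raise ConfigError("cycle_counts must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        lstm_raw = raw.pop("lstm", None)
        cfg = {k: v for k, v in raw.items()}
        if "cycle_counts" in cfg:
            cfg["cycle_counts"] = tuple(cfg["cycle_counts"])
        if lstm_raw:
            cfg["lstm"] = ident.LstmConfig(**lstm_raw)
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle_counts"] = list(self.cycle_counts)
        return d


def _process_record(record: EcgRecord, config: PipelineConfig) -> list[Cycle]:
    cleaned, rpeaks = pp.preprocess_record(
        record,
        low=config.bandpass_low,
        high=config.bandpass_high,
        order=config.bandpass_order,
        smooth_window=config.smooth_window,
        qrs_halfwidth=config.qrs_halfwidth,
    )
    return seg.segment_cycles(cleaned, rpeaks, config.segment_pre, config.segment_post)


def run_pipeline(
    config: PipelineConfig,
    cohort: dict[str, dict[str, Sequence[EcgRecord]]],
) -> dict:
    """Execute the full identification pipeline on a cohort.

    ``cohort`` maps subject_id -> {"registration": [...records...],
    "recognition": [...records...]}. Every subject needs registration data.
    Returns the evaluation report as a plain dict (JSON-serializable).
    """
    for subject, data in cohort.items():
        if not data.get("registration"):
            raise ConfigError(f"subject {subject!r} has no registration data")

    target_len = seg.cycle_length(config.fs, config.segment_pre, config.segment_post)
    stages: dict = {"registration_cycles": {}, "recognition_cycles": {}}

    reg_cycles: dict[str, list[Cycle]] = {}
    rec_cycles: dict[str, list[Cycle]] = {}
    for subject in sorted(cohort):
        reg = []
        for record in cohort[subject]["registration"]:
            reg.extend(_process_record(record, config))
        rec = []
        for record in cohort[subject].get("recognition", []):
            rec.extend(_process_record(record, config))
        reg_cycles[subject] = [seg.match_length(c, target_len) for c in reg]
        rec_cycles[subject] = [seg.match_length(c, target_len) for c in rec]
        stages["registration_cycles"][subject] = len(reg)
        stages["recognition_cycles"][subject] = len(rec)
        if not reg:
            raise ConfigError(f"subject {subject!r}: no beats found in registration data")

    # ideal cycle from all registration beats (across-subject average)
    annotated = []
    for subject in sorted(reg_cycles):
        for c in reg_cycles[subject]:
            try:
                annotated.append(
                    Cycle(
                        samples=c.samples, fs=c.fs, r_index=c.r_index,
                        subject_id=c.subject_id, peaks=annotate_peaks(c),
                    )
                )
            except Exception:  # unannotatable beat: skip, the average is robust
                continue
    if not annotated:
        raise ConfigError("no registration beat could be peak-annotated")
    stats = compute_peak_stats(annotated)
    ideal = generate_ideal_cycle(stats, target_len)

    normalized: dict[str, list[Cycle]] = {}
    norm_report: dict[str, dict] = {}
    for subject in sorted(cohort):
        sample = af.select_sample_cycle(reg_cycles[subject], ideal)
        cycles = rec_cycles[subject]
        if not cycles:
            normalized[subject] = []
            continue
        kept, profile = af.normalize_cycles(
            cycles, sample, Th=config.threshold, min_pass=config.min_pass
        )
        normalized[subject] = kept.cycles
        norm_report[subject] = {
            "n_in": len(cycles),
            "n_kept": len(kept),
            "threshold": kept.threshold,
            "pass_rate": kept.pass_rate,
            "k": profile.k,
            "l": profile.l,
            "mean_S_in": float(np.mean(profile.values)),
            "mean_S_kept": float(np.mean(profile.values[kept.indices])),
        }
        # similarity on the 0-100 scale, scale = median intra-set distance
        med = float(np.median(profile.values)) or 1.0
        norm_report[subject]["similarity_pct_in"] = float(
            np.mean([similarity.to_percent(d, med) for d in profile.values])
        )
        norm_report[subject]["similarity_pct_kept"] = float(
            np.mean([similarity.to_percent(d, med) for d in profile.values[kept.indices]])
        )
    stages["normalization"] = norm_report

    all_reg = [c for subject in sorted(reg_cycles) for c in reg_cycles[subject]]
    if config.classifier == "lstm":
        model = ident.train(config.lstm, all_reg)
    else:
        model = ident.train_nearest_template(all_reg)

    def score(cycle_sets: dict[str, list[Cycle]]) -> dict[str, float]:
        out = {}
        for m in config.cycle_counts:
            usable = {s: c for s, c in cycle_sets.items() if len(c) >= m}
            if not usable:
                continue
            counts = ident.evaluate(model, usable, n_cycles=m)
            out[str(m)] = ident.accuracy(counts)
        return out

    report = {
        "config": config.to_dict(),
        "stages": stages,
        "ideal_cycle_peaks": ideal.peak_indices.tolist(),
        "accuracy_normalized": score(normalized),
        "classifier": config.classifier,
    }
    if config.compare_unnormalized:
        report["accuracy_unnormalized"] = score(rec_cycles)
    return report


def report_to_json(report: dict) -> str:
    """Canonical (sorted, fixed-format) JSON so identical runs are
    byte-identical."""
    return json.dumps(report, sort_keys=True, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def build_synthetic_cohort(
    n_subjects: int,
    seed: int,
    fs: float = 500.0,
    registration_duration: float = 60.0,
    recognition_duration: float = 60.0,
    recognition_condition: str = "driving",
) -> dict[str, dict[str, list[EcgRecord]]]:
    """Convenience constructor: sit-condition registration plus one
    complex-condition recognition record per subject, all seeded."""
    from . import synthetic as syn

    templates = syn.make_cohort(n_subjects, seed)
    cohort: dict[str, dict[str, list[EcgRecord]]] = {}
    for i, tpl in enumerate(templates):
        reg = syn.synthesize_record(
            tpl, syn.noise_profile_for("sit"), registration_duration, fs,
            seed=seed * 100003 + 2 * i,
        )
        rec = syn.synthesize_record(
            tpl, syn.noise_profile_for(recognition_condition), recognition_duration,
            fs, seed=seed * 100003 + 2 * i + 1,
        )
        cohort[tpl.subject_id] = {"registration": [reg], "recognition": [rec]}
    return cohort
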