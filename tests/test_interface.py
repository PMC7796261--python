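"""CSV I/O roundtrips, pipeline configuration, report determinism, CLI."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import ecgid
from ecgid import cli as ecg_cli
from ecgid import io as ecg_io
from ecgid import pipeline as pl


class TestRecordCsv:
    def test_roundtrip_exact(self, tmp_path, clean_record):
        path = tmp_path / "rec.csv"
        ecg_io.write_record_csv(clean_record, path)
        back = ecg_io.read_record_csv(path)
        assert np.allclose(back.samples, clean_record.samples, atol=1e-6)
        assert back.fs == clean_record.fs
        assert back.subject_id == clean_record.subject_id
        assert back.condition == clean_record.condition

    def test_missing_fs_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,mv\n0.0,1.0\n")
        with pytest.raises(ecgid.ParseError, match="fs_hz"):
            ecg_io.read_record_csv(path)

    def test_peaks_roundtrip_exact(self, tmp_path, clean_record):
        peaks = ecgid.RPeakSet(indices=clean_record.annotations, fs=clean_record.fs)
        path = tmp_path / "peaks.csv"
        ecg_io.write_peaks_csv(peaks, path)
        back = ecg_io.read_peaks_csv(path)
        assert np.array_equal(back.indices, peaks.indices)
        assert back.fs == peaks.fs

    def test_cycles_roundtrip(self, tmp_path, clean_cycles):
        path = tmp_path / "cycles.csv"
        ecg_io.write_cycles_csv(clean_cycles, path)
        back = ecg_io.read_cycles_csv(path)
        assert len(back) == len(clean_cycles)
        for a, b in zip(back, clean_cycles):
            assert np.allclose(a.samples, b.samples)
            assert a.r_index == b.r_index
            assert a.subject_id == b.subject_id

    def test_peak_stats_roundtrip(self, tmp_path, annotated_cycles):
        stats = ecgid.compute_peak_stats(annotated_cycles)
        path = tmp_path / "stats.csv"
        ecg_io.write_peak_stats_csv(stats, path)
        back = ecg_io.read_peak_stats_csv(path)
        assert np.allclose(back.voltages, stats.voltages)
        assert np.allclose(back.locations, stats.locations)
        assert back.n_cycles_averaged == stats.n_cycles_averaged


class TestPipelineConfig:
    def test_validation_errors(self):
        with pytest.raises(ecgid.ConfigError):
            pl.PipelineConfig(bandpass_low=50.0, bandpass_high=40.0)
        with pytest.raises(ecgid.ConfigError):
            pl.PipelineConfig(threshold=2, min_pass=0.5)
        with pytest.raises(ecgid.ConfigError):
            pl.PipelineConfig(metric="dtw")

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            yaml.safe_dump(
                {"fs": 400.0, "min_pass": 0.8, "cycle_counts": [1, 2],
                 "lstm": {"hidden_base": 16, "seed": 5}}
            )
        )
        cfg = pl.PipelineConfig.from_yaml(path)
        assert cfg.fs == 400.0
        assert cfg.cycle_counts == (1, 2)
        assert cfg.lstm.hidden_base == 16


class TestRunPipeline:
    def test_zero_noise_two_subjects_perfect(self):
        templates = ecgid.make_cohort(2, seed=8)
        cohort = {}
        for i, tpl in enumerate(templates):
            reg = ecgid.synthesize_record(
                tpl, ecgid.silent_profile(), 30.0, 500.0, seed=80 + i
            )
            rec = ecgid.synthesize_record(
                tpl, ecgid.silent_profile(), 20.0, 500.0, seed=90 + i
            )
            cohort[tpl.subject_id] = {"registration": [reg], "recognition": [rec]}
        cfg = pl.PipelineConfig(min_pass=0.9, cycle_counts=(1, 2))
        report = pl.run_pipeline(cfg, cohort)
        assert all(v == 1.0 for v in report["accuracy_normalized"].values())

    def test_missing_registration_names_subject(self):
        with pytest.raises(ecgid.ConfigError, match="S9"):
            pl.run_pipeline(
                pl.PipelineConfig(), {"S9": {"registration": [], "recognition": []}}
            )

    def test_report_embeds_config(self):
        cohort = pl.build_synthetic_cohort(2, seed=3, registration_duration=15,
                                           recognition_duration=15)
        cfg = pl.PipelineConfig(min_pass=0.7, cycle_counts=(1,))
        report = pl.run_pipeline(cfg, cohort)
        assert report["config"] == cfg.to_dict()

    def test_rerun_is_byte_identical(self):
        def run():
            cohort = pl.build_synthetic_cohort(
                3, seed=17, registration_duration=15, recognition_duration=15
            )
            cfg = pl.PipelineConfig(min_pass=0.7, cycle_counts=(1, 2))
            return pl.report_to_json(pl.run_pipeline(cfg, cohort))

        assert run() == run()


class TestModelArchive:
    def test_lstm_save_load_predictions_equal(self, tmp_path, clean_cycles):
        cohort = ecgid.make_cohort(2, seed=5)
        from test_identification import beat_cycles

        cycles = beat_cycles(cohort[0], 8, noise=0.02, seed=1) + beat_cycles(
            cohort[1], 8, noise=0.02, seed=2
        )
        model = ecgid.train(
            ecgid.LstmConfig(hidden_base=16, dense_widths=(16,), n_samples=40,
                             frame_size=8, seed=2),
            cycles,
        )
        path = tmp_path / "model.npz"
        ecg_cli.save_model(model, path)
        back = ecg_cli.load_model(path)
        from ecgid.identification import predict_proba

        assert np.allclose(predict_proba(back, cycles), predict_proba(model, cycles))

    def test_nearest_template_save_load(self, tmp_path):
        cohort = ecgid.make_cohort(2, seed=6)
        from test_identification import beat_cycles

        cycles = beat_cycles(cohort[0], 5, seed=1) + beat_cycles(cohort[1], 5, seed=2)
        model = ecgid.train_nearest_template(cycles)
        path = tmp_path / "model.npz"
        ecg_cli.save_model(model, path)
        back = ecg_cli.load_model(path)
        assert back.labels == model.labels
        assert np.allclose(back.templates, model.templates)


class TestCli:
    def test_synth_preprocess_segment_chain(self, tmp_path):
        runner = CliRunner()
        out_dir = tmp_path / "cohort"
        r = runner.invoke(
            ecg_cli.main,
            ["synth", "--subjects", "1", "--duration", "20", "--seed", "4",
             "--out", str(out_dir)],
        )
        assert r.exit_code == 0, r.output
        rec_csv = next(out_dir.glob("S000_*.csv"))
        r = runner.invoke(
            ecg_cli.main,
            ["preprocess", str(rec_csv), "--out", str(tmp_path / "clean.csv"),
             "--peaks-out", str(tmp_path / "peaks.csv")],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            ecg_cli.main,
            ["segment", str(tmp_path / "clean.csv"), str(tmp_path / "peaks.csv"),
             "--out", str(tmp_path / "cycles.csv")],
        )
        assert r.exit_code == 0, r.output
        cycles = ecg_io.read_cycles_csv(tmp_path / "cycles.csv")
        assert len(cycles) > 10

    def test_normalize_enroll_identify_chain(self, tmp_path):
        from test_identification import beat_cycles

        t1, t2 = ecgid.make_cohort(2, seed=9)
        cycles = beat_cycles(t1, 10, noise=0.02, seed=1) + beat_cycles(
            t2, 10, noise=0.02, seed=2
        )
        ecg_io.write_cycles_csv(cycles, tmp_path / "cycles.csv")
        ecg_io.write_cycles_csv(cycles[:1], tmp_path / "sample.csv")
        runner = CliRunner()
        r = runner.invoke(
            ecg_cli.main,
            ["normalize", str(tmp_path / "cycles.csv"), str(tmp_path / "sample.csv"),
             "--min-pass", "0.5", "--out", str(tmp_path / "kept.csv")],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "kept.csv").read_text().startswith("cycle_id,S,kept")
        r = runner.invoke(
            ecg_cli.main,
            ["enroll", str(tmp_path / "cycles.csv"),
             "--out", str(tmp_path / "model.npz")],
        )
        assert r.exit_code == 0, r.output
        ecg_io.write_cycles_csv(
            [c for c in cycles if c.subject_id == "S001"], tmp_path / "probe.csv"
        )
        r = runner.invoke(
            ecg_cli.main,
            ["identify", str(tmp_path / "model.npz"), str(tmp_path / "probe.csv")],
        )
        assert r.exit_code == 0, r.output
        assert "predicted: S001" in r.output

    def test_evaluate_writes_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "report.json"
        r = runner.invoke(
            ecg_cli.main,
            ["evaluate", "--subjects", "2", "--duration", "15", "--seed", "1",
             "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        import json

        report = json.loads(out.read_text())
        assert "accuracy_normalized" in report
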