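"""Classifier training, 1:N identification, and the confusion tally."""

import numpy as np
import pytest

import ecgid
from ecgid import identification as ident
from ecgid.lstm import LstmNetwork, frame_sequence

SMALL_LSTM = dict(hidden_base=24, dense_widths=(32, 16), n_samples=40, frame_size=8)


def beat_cycles(template, n, fs=500.0, noise=0.0, seed=0, label=None):
    """n noisy copies of a subject's beat as Cycle objects."""
    from ecgid.synthetic import template_beat

    rng = np.random.default_rng(seed)
    beat = template_beat(template, fs)
    return [
        ecgid.Cycle(
            samples=beat + noise * rng.standard_normal(beat.size),
            fs=fs,
            r_index=int(0.3 * fs),
            subject_id=label or template.subject_id,
        )
        for _ in range(n)
    ]


@pytest.fixture(scope="module")
def two_subject_cycles():
    t1, t2 = ecgid.make_cohort(2, seed=5)
    return beat_cycles(t1, 12, noise=0.02, seed=1) + beat_cycles(
        t2, 12, noise=0.02, seed=2
    )


class TestAccuracy:
    def test_arithmetic(self):
        counts = ecgid.ConfusionCounts(tp=9, tn=90, fp=1, fn=0)
        assert ecgid.accuracy(counts) == pytest.approx(0.99)

    def test_perfect_when_no_errors(self):
        assert ecgid.accuracy(ecgid.ConfusionCounts(tp=5, tn=20, fp=0, fn=0)) == 1.0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 100, size=4)
            if tp + tn + fp + fn == 0:
                continue
            counts = ecgid.ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            assert ecgid.accuracy(counts) == pytest.approx(
                (tp + tn) / (tp + tn + fp + fn)
            )

    def test_empty_tally_rejected(self):
        with pytest.raises(ecgid.ArgumentError):
            ecgid.accuracy(ecgid.ConfusionCounts())

    def test_monotone_in_error_counts(self):
        base = ecgid.accuracy(ecgid.ConfusionCounts(tp=10, tn=10, fp=5, fn=5))
        fewer_fp = ecgid.accuracy(ecgid.ConfusionCounts(tp=10, tn=10, fp=2, fn=5))
        assert fewer_fp >= base


class TestTally:
    def test_total_is_decisions_times_classes(self):
        labels = ["a", "b", "c"]
        counts = ecgid.tally_decisions(
            ["a", "b", "c", "a"], ["a", "c", "c", "b"], labels
        )
        assert counts.total == 4 * 3
        assert counts.tp == 2 and counts.fp == 2 and counts.fn == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ecgid.ArgumentError):
            ecgid.tally_decisions(["x"], ["a"], ["a", "b"])


class TestTrain:
    def test_single_subject_rejected(self, two_subject_cycles):
        only_one = [c for c in two_subject_cycles if c.subject_id == "S000"]
        with pytest.raises(ecgid.ArgumentError, match="degenerate"):
            ecgid.train(ecgid.LstmConfig(**SMALL_LSTM), only_one)
        with pytest.raises(ecgid.ArgumentError, match="degenerate"):
            ecgid.train_nearest_template(only_one)

    def test_loss_decreases_on_separable_data(self, two_subject_cycles):
        model = ecgid.train(ecgid.LstmConfig(seed=0, **SMALL_LSTM), two_subject_cycles)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_seeded_determinism(self, two_subject_cycles):
        cfg = ecgid.LstmConfig(seed=3, **SMALL_LSTM)
        m1 = ecgid.train(cfg, two_subject_cycles)
        m2 = ecgid.train(ecgid.LstmConfig(seed=3, **SMALL_LSTM), two_subject_cycles)
        p1 = ident.predict_proba(m1, two_subject_cycles)
        p2 = ident.predict_proba(m2, two_subject_cycles)
        assert np.array_equal(p1, p2)

    def test_heldout_static_accuracy(self):
        """Parameter recovery: enrollment-scale clean beat sets (a 60 s
        static recording yields ~50+ beats) identify held-out beats of the
        same subjects nearly perfectly (mean over 5 seeds)."""
        accs = []
        for seed in range(1, 6):
            cohort = ecgid.make_cohort(5, seed=seed)
            train_c, test = [], {}
            for tpl in cohort:
                beats = beat_cycles(tpl, 50, noise=0.03, seed=seed)
                train_c += beats[:40]
                test[tpl.subject_id] = beats[40:]
            model = ecgid.train(
                ecgid.LstmConfig.reduced(seed=seed), train_c
            )
            hits = total = 0
            for sid, beats in test.items():
                for b in beats:
                    lab, _ = ecgid.identify(model, [b])
                    hits += lab == sid
                    total += 1
            accs.append(hits / total)
        assert np.mean(accs) >= 0.95


class TestIdentify:
    def test_training_beats_identify_their_subject(self, two_subject_cycles):
        model = ecgid.train_nearest_template(two_subject_cycles)
        own = [c for c in two_subject_cycles if c.subject_id == "S001"]
        label, scores = ecgid.identify(model, own)
        assert label == "S001"

    def test_scores_sum_to_one_per_cycle(self, two_subject_cycles):
        for maker in (
            lambda: ecgid.train_nearest_template(two_subject_cycles),
            lambda: ecgid.train(ecgid.LstmConfig(seed=1, **SMALL_LSTM), two_subject_cycles),
        ):
            model = maker()
            probs = ident.predict_proba(model, two_subject_cycles[:5])
            assert np.allclose(probs.sum(axis=1), 1.0)

    def test_empty_set_rejected(self, two_subject_cycles):
        model = ecgid.train_nearest_template(two_subject_cycles)
        with pytest.raises(ecgid.ArgumentError):
            ecgid.identify(model, [])

    def test_filtered_corrupted_set_agrees_with_clean_prediction(self):
        """After adaptive filtering, a partially corrupted probe set should
        give the same decision as the clean probe set in nearly all trials."""
        agree = trials = 0
        for seed in range(8):
            cohort = ecgid.make_cohort(4, seed=100 + seed)
            train_c = []
            for tpl in cohort:
                train_c += beat_cycles(tpl, 10, noise=0.02, seed=seed)
            model = ecgid.train_nearest_template(train_c)
            tpl = cohort[seed % 4]
            clean = beat_cycles(tpl, 12, noise=0.02, seed=50 + seed)
            rng = np.random.default_rng(seed)
            corrupted = list(clean)
            for i in rng.choice(12, size=3, replace=False):
                c = corrupted[i]
                corrupted[i] = ecgid.Cycle(
                    samples=c.samples + rng.normal(0, 1.0, c.samples.size),
                    fs=c.fs, r_index=c.r_index, subject_id=c.subject_id,
                )
            sample = ecgid.SampleCycle(
                samples=clean[0].samples, subject_id=tpl.subject_id,
                distance_to_ideal=0.0,
            )
            kept, _ = ecgid.normalize_cycles(corrupted, sample, min_pass=0.6)
            clean_label, _ = ecgid.identify(model, clean)
            kept_label, _ = ecgid.identify(model, kept)
            agree += clean_label == kept_label
            trials += 1
        assert agree / trials >= 0.9


class TestLstmNetwork:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = LstmNetwork(
            input_dim=3, lstm_widths=(4, 3), dense_widths=(5,), n_classes=3,
            dropout=0.0, seed=0,
        )
        X = rng.standard_normal((2, 4, 3))
        y = np.array([0, 2])
        onehot = np.zeros((2, 3))
        onehot[np.arange(2), y] = 1.0
        probs = net.forward(X, train=False)
        grads = net.backward(probs, onehot)

        def loss():
            p = net.forward(X, train=False)
            return float(-np.mean(np.log(p[np.arange(2), y])))

        worst = 0.0
        for k in net.params:
            flat = net.params[k].ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[idx]
                eps = 1e-6
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[idx]
                worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
        assert worst < 1e-4

    def test_frame_sequence_pads_tail(self):
        X = np.arange(10.0).reshape(1, 10)
        F = frame_sequence(X, 4)
        assert F.shape == (1, 3, 4)
        assert F[0, 2, 2] == 0.0  # zero-padded tail
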