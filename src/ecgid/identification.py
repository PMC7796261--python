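"""Subject identification from normalized heartbeat sets.

Two interchangeable classifiers share one interface:

* an LSTM sequence model (three recurrent layers of widths n, n/2, n/3 over
  framed beat waveforms, two ReLU dense layers with 0.5 dropout, softmax
  output, RMSprop at learning rate 0.001 for 10 epochs), and
* a deterministic nearest-template baseline (minimum mean Euclidean
  distance to each subject's enrolled mean beat), used as a cross-check and
  wherever training cost matters.

Multi-beat decisions average per-beat softmax scores and take the argmax
(1:N identification). Scoring uses a one-vs-rest confusion tally: each
decision contributes one scored entry per enrolled class — a correct
decision gives 1 TP and n-1 TN, a wrong one gives 1 FP (the predicted
class), 1 FN (the true class) and n-2 TN — and accuracy is
(TP+TN)/(TP+FN+FP+TN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .adaptive_filter import NormalizedSet
from .errors import ArgumentError
from .lstm import LstmNetwork, frame_sequence
from .records import Cycle

DOWNSAMPLE_CAP = 350


@dataclass
class LstmConfig:
    """Hyperparameters of the LSTM identifier.

    ``n_samples`` is the per-beat waveform length after down-sampling
    (capped at 350 to keep desk-scale); recurrent widths default to
    n, n/2, n/3 of the hidden base, which itself defaults to ``n_samples``.
    ``frame_size`` groups consecutive samples into one recurrent step so
    the BPTT depth stays short.
    """

    n_samples: int = 70
    frame_size: int = 7
    n_layers: int = 3
    hidden_base: int | None = None
    dense_widths: tuple[int, ...] = (400, 200)
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 2
    optimizer: str = "rmsprop"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_layers <= 3:
            raise ArgumentError("n_layers must be 1, 2 or 3")
        if self.n_samples > DOWNSAMPLE_CAP:
            raise ArgumentError(f"n_samples capped at {DOWNSAMPLE_CAP}")
        if not 0.0 <= self.dropout < 1.0:
            raise ArgumentError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ArgumentError("epochs must be >= 1")
        if self.optimizer != "rmsprop":
            raise ArgumentError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def reduced(cls, seed: int = 0) -> "LstmConfig":
        """Down-sized widths (hidden base 48, dense 64/32) for quick
        desk-scale experiments; optimizer settings unchanged."""
        return cls(hidden_base=48, dense_widths=(64, 32), seed=seed)

    @property
    def lstm_widths(self) -> tuple[int, ...]:
        n = self.hidden_base if self.hidden_base is not None else self.n_samples
        return tuple(max(2, n // d) for d in (1, 2, 3))[: self.n_layers]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN tallies from 1:N identification decisions."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ArgumentError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN) / (TP+FN+FP+TN)."""
    if counts.total == 0:
        raise ArgumentError("cannot score an empty confusion tally")
    return (counts.tp + counts.tn) / counts.total


def tally_decisions(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> ConfusionCounts:
    """One-vs-rest confusion tally over identification decisions.

    Every decision is scored against each of the N enrolled classes, so
    the total equals decisions x N.
    """
    if len(y_true) != len(y_pred):
        raise ArgumentError("y_true and y_pred must align")
    labels = list(labels)
    counts = ConfusionCounts()
    for t, p in zip(y_true, y_pred):
        if t not in labels or p not in labels:
            raise ArgumentError(f"label outside the enrolled set: {t!r}/{p!r}")
        if t == p:
            counts.tp += 1
            counts.tn += len(labels) - 1
        else:
            counts.fp += 1
            counts.fn += 1
            counts.tn += len(labels) - 2
    return counts


@dataclass
class IdentityModel:
    """A trained identifier: enrolled labels plus classifier state."""

    kind: str  # "lstm" | "nearest_template"
    labels: list[str]
    n_samples: int
    frame_size: int = 1
    scale: float = 1.0
    network: LstmNetwork | None = field(default=None, repr=False)
    templates: np.ndarray | None = field(default=None, repr=False)
    loss_history: list[float] = field(default_factory=list)


def _resample_rows(X: np.ndarray, n_out: int) -> np.ndarray:
    if X.shape[1] == n_out:
        return X
    old = np.arange(X.shape[1], dtype=np.float64)
    new = np.linspace(0.0, X.shape[1] - 1, n_out)
    return np.vstack([np.interp(new, old, row) for row in X])


def _prepare(cycles: Sequence[Cycle]) -> tuple[np.ndarray, list[str]]:
    if len(cycles) == 0:
        raise ArgumentError("no cycles supplied")
    labels = []
    for c in cycles:
        if c.subject_id is None:
            raise ArgumentError("every training cycle needs a subject_id")
        labels.append(c.subject_id)
    X = np.vstack([c.samples for c in cycles])
    return X, labels


def train(config: LstmConfig, cycles: Sequence[Cycle]) -> IdentityModel:
    """Train the LSTM identifier on labeled enrollment beats.

    Deterministic under ``config.seed``. Raises on single-subject
    (degenerate) enrollment.
    """
    X, labels = _prepare(cycles)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ArgumentError("degenerate enrollment: need at least two subjects")
    y = np.array([classes.index(s) for s in labels])
    X = _resample_rows(X, config.n_samples)
    scale = float(X.std()) or 1.0
    frames = frame_sequence(X / scale, config.frame_size)
    net = LstmNetwork(
        input_dim=config.frame_size,
        lstm_widths=config.lstm_widths,
        dense_widths=config.dense_widths,
        n_classes=len(classes),
        dropout=config.dropout,
        seed=config.seed,
    )
    history = net.fit(
        frames, y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
    )
    return IdentityModel(
        kind="lstm",
        labels=classes,
        n_samples=config.n_samples,
        frame_size=config.frame_size,
        scale=scale,
        network=net,
        loss_history=history,
    )


def train_nearest_template(cycles: Sequence[Cycle], n_samples: int = 70) -> IdentityModel:
    """Enroll the deterministic nearest-template baseline.

    Stores each subject's mean beat (after down-sampling); identification
    softmaxes the negated Euclidean distances so scores are comparable to
    the LSTM's.
    """
    X, labels = _prepare(cycles)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ArgumentError("degenerate enrollment: need at least two subjects")
    X = _resample_rows(X, n_samples)
    templates = np.vstack(
        [X[[i for i, s in enumerate(labels) if s == cls]].mean(axis=0) for cls in classes]
    )
    return IdentityModel(
        kind="nearest_template",
        labels=classes,
        n_samples=n_samples,
        templates=templates,
    )


def predict_proba(model: IdentityModel, cycles: Sequence[Cycle]) -> np.ndarray:
    """Per-beat class probabilities, rows summing to 1."""
    if len(cycles) == 0:
        raise ArgumentError("no cycles to score")
    X = _resample_rows(np.vstack([c.samples for c in cycles]), model.n_samples)
    if model.kind == "lstm":
        assert model.network is not None
        return model.network.predict_proba(
            frame_sequence(X / model.scale, model.frame_size)
        )
    assert model.templates is not None
    d = np.sqrt(((X[:, None, :] - model.templates[None, :, :]) ** 2).sum(axis=2))
    tau = np.mean(d, axis=1, keepdims=True)
    tau[tau == 0] = 1.0
    z = -d / tau
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def identify(
    model: IdentityModel, normalized: NormalizedSet | Sequence[Cycle]
) -> tuple[str, np.ndarray]:
    """Predict the subject for a beat set: mean softmax score, argmax label.

    Ties break toward the lowest label order. Returns (label, mean scores).
    """
    cycles = normalized.cycles if isinstance(normalized, NormalizedSet) else list(normalized)
    if len(cycles) == 0:
        raise ArgumentError("cannot identify from an empty cycle set")
    scores = predict_proba(model, cycles).mean(axis=0)
    return model.labels[int(np.argmax(scores))], scores


def evaluate(
    model: IdentityModel,
    cycles_by_subject: dict[str, Sequence[Cycle]],
    n_cycles: int = 1,
) -> ConfusionCounts:
    """Score 1:N identification over non-overlapping groups of beats.

    Each subject's recognition beats are split into consecutive groups of
    ``n_cycles`` (the remainder is dropped) and each group yields one
    decision.
    """
    if n_cycles < 1:
        raise ArgumentError("n_cycles must be >= 1")
    y_true: list[str] = []
    y_pred: list[str] = []
    for subject, cycles in sorted(cycles_by_subject.items()):
        cycles = list(cycles)
        for s in range(0, len(cycles) - n_cycles + 1, n_cycles):
            label, _ = identify(model, cycles[s : s + n_cycles])
            y_true.append(subject)
            y_pred.append(label)
    return tally_decisions(y_true, y_pred, model.labels)
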