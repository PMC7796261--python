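"""A compact, fully deterministic stacked-LSTM classifier in numpy.

Architecture: a stack of LSTM layers read a framed waveform left to right;
the final hidden state feeds two ReLU dense layers with inverted dropout
and a softmax output. Training is full backpropagation through time with
RMSprop. Everything (weight init, shuffling, dropout)
is driven by one seeded Generator, so identical data + seed gives
bit-identical models and predictions.

Sized for enrollment-scale problems (hundreds of beats, tens of classes);
this is not a GPU training stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def frame_sequence(X: np.ndarray, frame_size: int) -> np.ndarray:
    """Reshape (B, n) waveforms into (B, T, frame_size) step frames.

    Framing shortens the recurrence (T = ceil(n/frame_size) steps) without
    discarding samples; the tail frame is zero-padded.
    """
    if frame_size < 1:
        raise ArgumentError("frame_size must be >= 1")
    B, n = X.shape
    T = -(-n // frame_size)
    padded = np.zeros((B, T * frame_size), dtype=np.float64)
    padded[:, :n] = X
    return padded.reshape(B, T, frame_size)


@dataclass
class LstmNetwork:
    """Stacked LSTM + dense head with softmax output."""

    input_dim: int
    lstm_widths: tuple[int, ...]
    dense_widths: tuple[int, ...]
    n_classes: int
    dropout: float = 0.5
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ArgumentError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ArgumentError("need at least two classes")
        self.rng = np.random.default_rng(self.seed)
        if not self.params:
            self._init_params()

    def _glorot(self, fan_in: int, fan_out: int, shape) -> np.ndarray:
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        return self.rng.standard_normal(shape) * scale

    def _init_params(self) -> None:
        p = self.params
        fan = self.input_dim
        for li, H in enumerate(self.lstm_widths):
            p[f"W{li}"] = self._glorot(fan + H, 4 * H, (fan + H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias: remember by default
            p[f"b{li}"] = b
            fan = H
        for di, D in enumerate(self.dense_widths):
            p[f"Wd{di}"] = self._glorot(fan, D, (fan, D))
            p[f"bd{di}"] = np.zeros(D)
            fan = D
        p["Wo"] = self._glorot(fan, self.n_classes, (fan, self.n_classes))
        p["bo"] = np.zeros(self.n_classes)

    # ---------------------------------------------------------------- forward

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Probabilities (B, n_classes) for framed input (B, T, F)."""
        B, T, F = X.shape
        if F != self.input_dim:
            raise ArgumentError(f"expected frame size {self.input_dim}, got {F}")
        p = self.params
        cache: dict = {"layers": [], "B": B, "T": T}
        inp = X
        for li, H in enumerate(self.lstm_widths):
            W, b = p[f"W{li}"], p[f"b{li}"]
            h = np.zeros((B, T, H))
            c = np.zeros((B, T, H))
            gates = np.zeros((B, T, 4 * H))
            h_t = np.zeros((B, H))
            c_t = np.zeros((B, H))
            for t in range(T):
                z = np.concatenate([inp[:, t, :], h_t], axis=1) @ W + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_t = f * c_t + i * g
                h_t = o * np.tanh(c_t)
                h[:, t], c[:, t] = h_t, c_t
                gates[:, t] = np.concatenate([i, f, g, o], axis=1)
            cache["layers"].append({"inp": inp, "h": h, "c": c, "gates": gates, "H": H})
            inp = h
        a = inp[:, -1, :]
        cache["dense"] = []
        for di in range(len(self.dense_widths)):
            z = a @ p[f"Wd{di}"] + p[f"bd{di}"]
            relu = np.maximum(z, 0.0)
            if train and self.dropout > 0.0:
                mask = (self.rng.random(relu.shape) >= self.dropout) / (1.0 - self.dropout)
            else:
                mask = np.ones_like(relu)
            out = relu * mask
            cache["dense"].append({"a_in": a, "z": z, "mask": mask})
            a = out
        logits = a @ p["Wo"] + p["bo"]
        probs = _softmax(logits)
        cache["head_in"] = a
        self._cache = cache
        return probs

    # --------------------------------------------------------------- backward

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray) -> dict:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        p = self.params
        cache = self._cache
        B = cache["B"]
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = (probs - y_onehot) / B
        grads["Wo"] = cache["head_in"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        da = dlogits @ p["Wo"].T
        for di in reversed(range(len(self.dense_widths))):
            dc = cache["dense"][di]
            dz = da * dc["mask"] * (dc["z"] > 0)
            grads[f"Wd{di}"] = dc["a_in"].T @ dz
            grads[f"bd{di}"] = dz.sum(axis=0)
            da = dz @ p[f"Wd{di}"].T

        T = cache["T"]
        # seed the top layer with the head gradient at the last timestep
        dh_seq = None
        for li in reversed(range(len(self.lstm_widths))):
            lc = cache["layers"][li]
            H = lc["H"]
            W = p[f"W{li}"]
            inp, h, c, gates = lc["inp"], lc["h"], lc["c"], lc["gates"]
            F = inp.shape[2]
            if dh_seq is None:
                dh_seq = np.zeros_like(h)
                dh_seq[:, -1, :] = da
            dinp = np.zeros_like(inp)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            dW = grads[f"W{li}"]
            db = grads[f"b{li}"]
            for t in reversed(range(T)):
                i = gates[:, t, :H]
                f = gates[:, t, H : 2 * H]
                g = gates[:, t, 2 * H : 3 * H]
                o = gates[:, t, 3 * H :]
                tc = np.tanh(c[:, t])
                dh = dh_seq[:, t] + dh_next
                do = dh * tc
                dcell = dc_next + dh * o * (1.0 - tc**2)
                c_prev = c[:, t - 1] if t > 0 else np.zeros((B, H))
                h_prev = h[:, t - 1] if t > 0 else np.zeros((B, H))
                di_ = dcell * g
                df = dcell * c_prev
                dg = dcell * i
                dc_next = dcell * f
                dz = np.concatenate(
                    [
                        di_ * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                xh = np.concatenate([inp[:, t, :], h_prev], axis=1)
                dW += xh.T @ dz
                db += dz.sum(axis=0)
                dxh = dz @ W.T
                dinp[:, t] = dxh[:, :F]
                dh_next = dxh[:, F:]
            dh_seq = dinp  # becomes the per-timestep gradient for the layer below
        return grads

    # ---------------------------------------------------------------- training

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 10,
        batch_size: int = 16,
        lr: float = 0.001,
        rho: float = 0.9,
        eps: float = 1e-8,
    ) -> list[float]:
        """RMSprop training; returns the per-epoch mean loss history."""
        if epochs < 1:
            raise ArgumentError("epochs must be >= 1")
        B = X.shape[0]
        onehot = np.zeros((B, self.n_classes))
        onehot[np.arange(B), y] = 1.0
        caches = {k: np.zeros_like(v) for k, v in self.params.items()}
        history: list[float] = []
        for _ in range(epochs):
            order = self.rng.permutation(B)
            losses = []
            for s in range(0, B, batch_size):
                sel = order[s : s + batch_size]
                probs = self.forward(X[sel], train=True)
                losses.append(
                    float(-np.mean(np.log(np.clip(probs[np.arange(sel.size), y[sel]], 1e-12, None))))
                )
                grads = self.backward(probs, onehot[sel])
                for k, g in grads.items():
                    caches[k] = rho * caches[k] + (1.0 - rho) * g**2
                    self.params[k] -= lr * g / (np.sqrt(caches[k]) + eps)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, train=False)
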