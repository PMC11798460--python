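"""Sequence classifiers and their majority-vote fusion.

Two member models consume per-region sliding windows of preprocessed
features:

* **Bi-GRU** — a gated recurrent unit run forward and backward over the
  window; the two final hidden states are concatenated and fed to a dense
  head. Gates per step (σ = logistic, ⊙ = elementwise product, [·,·] =
  concatenation of previous hidden state and current input):

      F_t = σ(W_F·[h_{t−1}, x_t] + b_F)         (update gate)
      r_t = σ(W_r·[h_{t−1}, x_t] + b_r)         (reset gate)
      h̃_t = tanh(W_c·[r_t ⊙ h_{t−1}, x_t] + b_c)
      h_t = (1 − F_t) ⊙ h_{t−1} + F_t ⊙ h̃_t

* **1-D CNN** — valid (unpadded) temporal convolutions with bias and an
  activation, optional non-overlapping max-pooling per layer, flattened into
  a dense head.

Fusion is a hard majority vote over member labels; two-member ties fall back
to the highest summed class probability (soft vote), then to the lowest
class index, with a flag marking that the fallback fired.

Training is seeded mini-batch gradient descent (Adam) on mean cross-entropy
(classification) or mean squared error (regression head); determinism is
run-to-run on one machine, not across platforms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

logger = logging.getLogger(__name__)

_ACTIVATIONS = {"relu": ad.relu, "tanh": ad.tanh, "sigmoid": ad.sigmoid, "identity": ad.identity}


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GRU primitives
# ---------------------------------------------------------------------------


def gru_step(x_t: np.ndarray | Tensor, h_prev: np.ndarray | Tensor, params: dict) -> Tensor:
    """One GRU step; `params` maps W_F,b_F,W_r,b_r,W_c,b_c to Tensors.

    Weight matrices map the concatenation [h_prev, x_t] (hidden ⊕ input) to
    the hidden dimension.
    """
    x_t = x_t if isinstance(x_t, Tensor) else Tensor(np.atleast_2d(x_t))
    h_prev = h_prev if isinstance(h_prev, Tensor) else Tensor(np.atleast_2d(h_prev))
    if x_t.shape[0] != h_prev.shape[0]:
        raise ModelError("batch size mismatch between x_t and h_prev")
    hx = ad.concat([h_prev, x_t], axis=1)
    F_t = ad.sigmoid(hx @ params["W_F"] + params["b_F"])
    r_t = ad.sigmoid(hx @ params["W_r"] + params["b_r"])
    rhx = ad.concat([r_t * h_prev, x_t], axis=1)
    h_tilde = ad.tanh(rhx @ params["W_c"] + params["b_c"])
    one = Tensor(np.ones_like(F_t.data))
    return (one - F_t) * h_prev + F_t * h_tilde


def _init_gru_direction(rng: np.random.Generator, n_in: int, hidden: int) -> dict:
    def mat(rows, cols):
        s = 1.0 / np.sqrt(rows)
        return Tensor(rng.uniform(-s, s, size=(rows, cols)), requires_grad=True)

    d = {}
    for gate in ("F", "r", "c"):
        d[f"W_{gate}"] = mat(hidden + n_in, hidden)
        d[f"b_{gate}"] = Tensor(np.zeros(hidden), requires_grad=True)
    return d


def bigru_encode(sequence: np.ndarray, forward: dict, backward: dict, hidden: int) -> Tensor:
    """Encode a batch of sequences (batch × time × features) to length 2H.

    Returns [→h_T ⊕ ←h_1]: the forward pass's final state concatenated with
    the backward pass's final state.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim == 2:
        seq = seq[None, :, :]
    B, T, _ = seq.shape
    if T < 1:
        raise ModelError("empty sequence")
    h_f = Tensor(np.zeros((B, hidden)))
    for t in range(T):
        h_f = gru_step(Tensor(seq[:, t, :]), h_f, forward)
    h_b = Tensor(np.zeros((B, hidden)))
    for t in range(T - 1, -1, -1):
        h_b = gru_step(Tensor(seq[:, t, :]), h_b, backward)
    return ad.concat([h_f, h_b], axis=1)


# ---------------------------------------------------------------------------
# CNN primitives
# ---------------------------------------------------------------------------


@dataclass
class ConvLayerSpec:
    filters: int = 8
    width: int = 2
    activation: str = "relu"
    pool: int | None = None  # non-overlapping max-pool window


def conv_layer(positions: list[Tensor], W: Tensor, b: Tensor, width: int,
               activation: str, pool: int | None) -> list[Tensor]:
    """Valid 1-D convolution over a sequence held as per-step tensors.

    ``positions[t]`` is the (batch × channels) slice at step t; the filter
    bank W maps width·channels → filters. Output position t is
    act(πᵀ·window_t + B), optionally max-pooled over non-overlapping windows.
    """
    T = len(positions)
    if width > T:
        raise ModelError(f"sequence of length {T} too short for kernel width {width}")
    act = _ACTIVATIONS[activation]
    outs = []
    for t in range(T - width + 1):
        window = ad.concat(positions[t : t + width], axis=1)
        outs.append(act(window @ W + b))
    if pool is not None and pool > 1:
        pooled = []
        for start in range(0, len(outs) - pool + 1, pool):
            m = outs[start]
            for j in range(start + 1, start + pool):
                m = ad.maximum(m, outs[j])
            pooled.append(m)
        if not pooled:  # shorter than one pool window: pool everything
            m = outs[0]
            for o in outs[1:]:
                m = ad.maximum(m, o)
            pooled = [m]
        outs = pooled
    return outs


def cnn_forward(sequence: np.ndarray, layers: list[tuple[Tensor, Tensor, ConvLayerSpec]]) -> Tensor:
    """Run conv/pool layers over a (batch × time × features) array and
    flatten the surviving positions into one feature vector per sample."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim == 2:
        seq = seq[None, :, :]
    positions = [Tensor(seq[:, t, :]) for t in range(seq.shape[1])]
    for W, b, spec in layers:
        positions = conv_layer(positions, W, b, spec.width, spec.activation, spec.pool)
    return ad.concat(positions, axis=1) if len(positions) > 1 else positions[0]


# ---------------------------------------------------------------------------
# Member models
# ---------------------------------------------------------------------------


class SequenceModel:
    """Shared surface of the two members: forward to logits, predict, save."""

    params: list[Tensor]
    n_out: int

    def forward(self, X: np.ndarray) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return ad.softmax_probs(self.forward(X).data)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        """Regression head output (n_out == 1)."""
        return self.forward(X).data[:, 0]

    def save(self, path) -> None:
        path = Path(path)
        manifest = {"class": type(self).__name__, "config": self._config(),
                    "arrays": [list(p.shape) for p in self.params]}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
        np.savez(path.with_suffix(".npz"), *[p.data for p in self.params])

    def load_arrays(self, path) -> None:
        with np.load(Path(path).with_suffix(".npz")) as arrays:
            for p, key in zip(self.params, arrays.files):
                p.data = arrays[key]

    def _config(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError


class BiGRUClassifier(SequenceModel):
    def __init__(self, n_features: int, hidden: int = 16, n_out: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_features, self.hidden, self.n_out = n_features, hidden, n_out
        self.forward_params = _init_gru_direction(rng, n_features, hidden)
        self.backward_params = _init_gru_direction(rng, n_features, hidden)
        s = 1.0 / np.sqrt(2 * hidden)
        self.W_out = Tensor(rng.uniform(-s, s, size=(2 * hidden, n_out)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_out), requires_grad=True)
        self.params = (
            [self.forward_params[k] for k in sorted(self.forward_params)]
            + [self.backward_params[k] for k in sorted(self.backward_params)]
            + [self.W_out, self.b_out]
        )

    def forward(self, X: np.ndarray) -> Tensor:
        enc = bigru_encode(X, self.forward_params, self.backward_params, self.hidden)
        return enc @ self.W_out + self.b_out

    def _config(self) -> dict:
        return {"n_features": self.n_features, "hidden": self.hidden, "n_out": self.n_out}


class CNNClassifier(SequenceModel):
    def __init__(self, n_features: int, window: int, layer_specs: list[ConvLayerSpec] | None = None,
                 dense: int = 16, n_out: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        if layer_specs is None:
            layer_specs = default_cnn_layers(window)
        self.n_features, self.window, self.n_out, self.dense = n_features, window, n_out, dense
        self.layer_specs = layer_specs
        self.layers: list[tuple[Tensor, Tensor, ConvLayerSpec]] = []
        c_in, length = n_features, window
        for spec in layer_specs:
            if spec.width > length:
                raise ModelError(
                    f"kernel width {spec.width} needs sequence length >= {spec.width}, have {length}"
                )
            s = 1.0 / np.sqrt(spec.width * c_in)
            W = Tensor(rng.uniform(-s, s, size=(spec.width * c_in, spec.filters)), requires_grad=True)
            b = Tensor(np.zeros(spec.filters), requires_grad=True)
            self.layers.append((W, b, spec))
            length = length - spec.width + 1
            if spec.pool and spec.pool > 1:
                length = max(1, length // spec.pool)
            c_in = spec.filters
        flat = length * c_in
        s = 1.0 / np.sqrt(flat)
        self.W_dense = Tensor(rng.uniform(-s, s, size=(flat, dense)), requires_grad=True)
        self.b_dense = Tensor(np.zeros(dense), requires_grad=True)
        s = 1.0 / np.sqrt(dense)
        self.W_out = Tensor(rng.uniform(-s, s, size=(dense, n_out)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_out), requires_grad=True)
        self.params = [w for layer in self.layers for w in layer[:2]] + [
            self.W_dense, self.b_dense, self.W_out, self.b_out
        ]

    def forward(self, X: np.ndarray) -> Tensor:
        flat = cnn_forward(X, self.layers)
        hidden = ad.relu(flat @ self.W_dense + self.b_dense)
        return hidden @ self.W_out + self.b_out

    def _config(self) -> dict:
        return {
            "n_features": self.n_features,
            "window": self.window,
            "n_out": self.n_out,
            "dense": self.dense,
            "layers": [vars(s) for s in self.layer_specs],
        }


def default_cnn_layers(window: int) -> list[ConvLayerSpec]:
    """Two width-2 conv layers with a final pool, shrunk for short windows."""
    if window >= 4:
        return [ConvLayerSpec(8, 2, "relu", None), ConvLayerSpec(8, 2, "relu", 2)]
    if window >= 2:
        return [ConvLayerSpec(8, 2, "relu", None)]
    return [ConvLayerSpec(8, 1, "relu", None)]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 60
    lr: float = 0.01
    batch_size: int = 64
    seed: int = 0
    loss: str = "cross_entropy"  # or "mse"
    patience: int | None = None  # early stop on non-improving epoch loss

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ModelError("epochs and batch size must be positive")
        if self.lr < 0:
            raise ModelError("learning rate must be nonnegative")
        if self.loss not in ("cross_entropy", "mse"):
            raise ModelError(f"unknown loss {self.loss!r}")


def train_member(model: SequenceModel, X: np.ndarray, y: np.ndarray,
                 config: TrainConfig | None = None) -> list[float]:
    """Seeded mini-batch Adam on the configured loss; returns the per-epoch
    mean loss trace. Aborts on a NaN loss."""
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = y.astype(int) if config.loss == "cross_entropy" else y.astype(float)
    rng = np.random.default_rng(config.seed)
    opt = ad.Adam(model.params, lr=config.lr)
    trace: list[float] = []
    best, stale = np.inf, 0
    n = len(X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(X[idx])
            if config.loss == "cross_entropy":
                loss = ad.softmax_cross_entropy(logits, labels[idx])
            else:
                loss = ad.mse_loss(logits, labels[idx].reshape(len(idx), -1))
            value = float(loss.data)
            if not np.isfinite(value):
                raise ModelError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += value * len(idx)
        trace.append(epoch_loss / n)
        if config.patience is not None:
            if trace[-1] < best - 1e-6:
                best, stale = trace[-1], 0
            else:
                stale += 1
                if stale > config.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    return trace


# ---------------------------------------------------------------------------
# Voting fusion
# ---------------------------------------------------------------------------


@dataclass
class EnsemblePrediction:
    member_labels: list[int]
    member_probs: list[list[float]]
    tally: dict[int, int]
    label: int
    tie: bool = False


def vote(member_predictions: list[tuple[int, np.ndarray]]) -> EnsemblePrediction:
    """Hard majority vote with a soft-probability tie fallback.

    Each member casts one vote for its predicted label; the label with the
    most votes wins. A tie falls back to the highest summed class
    probability, then to the lowest class index; the tie flag records that a
    fallback fired.
    """
    if len(member_predictions) < 2:
        raise ModelError("vote needs at least 2 members")
    n_classes = {len(np.asarray(p)) for _, p in member_predictions}
    if len(n_classes) != 1:
        raise ModelError("members disagree on the class set")
    k = n_classes.pop()
    labels = [int(lbl) for lbl, _ in member_predictions]
    probs = [np.asarray(p, dtype=float) for _, p in member_predictions]
    for lbl, p in zip(labels, probs):
        if not (0 <= lbl < k):
            raise ModelError(f"label {lbl} outside the class set")
        if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
            raise ModelError("member probabilities must be a distribution")
    tally = np.zeros(k, dtype=int)
    for lbl in labels:
        tally[lbl] += 1
    top = tally.max()
    winners = np.flatnonzero(tally == top)
    if len(winners) == 1:
        final, tie = int(winners[0]), False
    else:
        sums = np.sum(probs, axis=0)[winners]
        best = winners[np.flatnonzero(sums == sums.max())]
        final, tie = int(best.min()), True
    return EnsemblePrediction(
        member_labels=labels,
        member_probs=[p.tolist() for p in probs],
        tally={c: int(tally[c]) for c in range(k)},
        label=final,
        tie=tie,
    )


def ensemble_predict(models: list[SequenceModel], X: np.ndarray) -> list[EnsemblePrediction]:
    """Vote the members over a batch of sequences (or one sequence)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    member_probs = [m.predict_proba(X) for m in models]
    out = []
    for i in range(X.shape[0]):
        preds = [(int(p[i].argmax()), p[i]) for p in member_probs]
        out.append(vote(preds))
    return out


def ensemble_regress(models: list[SequenceModel], X: np.ndarray) -> np.ndarray:
    """Member-mean fusion of regression heads."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    return np.mean([m.predict_value(X) for m in models], axis=0)
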