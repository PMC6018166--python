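"""Gated recurrent units for inter-slice feature learning.

The cell follows the standard bias-free GRU recurrence: with input x_i and
previous hidden state h_{i-1},

    z_i = sigmoid(W_xz x_i + W_hz h_{i-1})          (update gate)
    r_i = sigmoid(W_xr x_i + W_hr h_{i-1})          (reset gate)
    h~_i = tanh(W_xh x_i + W_hh (h_{i-1} * r_i))    (candidate state)
    h_i = (1 - z_i) * h~_i + z_i * h_{i-1}          (linear interpolation)

``gru_step``/``run_gru``/``run_bgru`` are the plain-numpy reference
implementations of this recurrence and return full step traces for
verification.  ``SequenceClassifier`` assembles the trainable model: two
stacked bidirectional GRU layers whose per-step outputs (forward and
time-aligned backward states, concatenated) feed two fully connected layers
and a softmax, trained with Adam on subject-level labels while the
convolutional feature extractors stay frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cnn import softmax


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GRUParams:
    """Weight matrices of one GRU cell (input weights HxF, recurrent HxH)."""

    W_xz: np.ndarray
    W_hz: np.ndarray
    W_xr: np.ndarray
    W_hr: np.ndarray
    W_xh: np.ndarray
    W_hh: np.ndarray

    def __post_init__(self):
        mats = [self.W_xz, self.W_hz, self.W_xr, self.W_hr, self.W_xh, self.W_hh]
        for i, m in enumerate(mats):
            mats[i] = np.asarray(m, dtype=np.float64)
            if not np.isfinite(mats[i]).all():
                raise ValueError("GRU weights must be finite")
        self.W_xz, self.W_hz, self.W_xr, self.W_hr, self.W_xh, self.W_hh = mats
        h, f = self.W_xz.shape
        for name in ("W_xr", "W_xh"):
            if getattr(self, name).shape != (h, f):
                raise ValueError(f"{name} must have shape ({h}, {f})")
        for name in ("W_hz", "W_hr", "W_hh"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape ({h}, {h})")

    @property
    def input_dim(self) -> int:
        return self.W_xz.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W_xz.shape[0]

    @classmethod
    def random(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator, scale: float | None = None) -> "GRUParams":
        s_in = scale if scale is not None else math.sqrt(6.0 / (input_dim + hidden_dim))
        s_h = scale if scale is not None else math.sqrt(6.0 / (2 * hidden_dim))
        u = rng.uniform
        return cls(
            W_xz=u(-s_in, s_in, (hidden_dim, input_dim)),
            W_hz=u(-s_h, s_h, (hidden_dim, hidden_dim)),
            W_xr=u(-s_in, s_in, (hidden_dim, input_dim)),
            W_hr=u(-s_h, s_h, (hidden_dim, hidden_dim)),
            W_xh=u(-s_in, s_in, (hidden_dim, input_dim)),
            W_hh=u(-s_h, s_h, (hidden_dim, hidden_dim)),
        )


@dataclass
class GRUStepTrace:
    """All intermediate quantities of one recurrent update."""

    x_i: np.ndarray
    h_prev: np.ndarray
    z_i: np.ndarray
    r_i: np.ndarray
    h_cand: np.ndarray
    h_i: np.ndarray


def gru_step(p: GRUParams, x_i: np.ndarray, h_prev: np.ndarray) -> GRUStepTrace:
    """One bias-free GRU update; returns the full trace of intermediates."""
    x_i = np.asarray(x_i, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_i.shape != (p.input_dim,):
        raise ValueError(f"x_i must have shape ({p.input_dim},), got {x_i.shape}")
    if h_prev.shape != (p.hidden_dim,):
        raise ValueError(f"h_prev must have shape ({p.hidden_dim},), got {h_prev.shape}")
    z = _sigmoid(p.W_xz @ x_i + p.W_hz @ h_prev)
    r = _sigmoid(p.W_xr @ x_i + p.W_hr @ h_prev)
    h_cand = np.tanh(p.W_xh @ x_i + p.W_hh @ (h_prev * r))
    h = (1.0 - z) * h_cand + z * h_prev
    return GRUStepTrace(x_i=x_i, h_prev=h_prev, z_i=z, r_i=r, h_cand=h_cand, h_i=h)


def run_gru(p: GRUParams, seq: np.ndarray, h_0: np.ndarray | None = None) -> np.ndarray:
    """Run the recurrence left-to-right over ``seq`` (n, F) -> states (n, H)."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("seq must be a nonempty (n, F) array")
    if seq.shape[1] != p.input_dim:
        raise ValueError(f"sequence feature dim {seq.shape[1]} != params input_dim {p.input_dim}")
    h = np.zeros(p.hidden_dim) if h_0 is None else np.asarray(h_0, dtype=np.float64)
    states = np.empty((seq.shape[0], p.hidden_dim))
    for i, x in enumerate(seq):
        h = gru_step(p, x, h).h_i
        states[i] = h
    return states


def run_bgru(p_fwd: GRUParams, p_bwd: GRUParams, seq: np.ndarray) -> np.ndarray:
    """Bidirectional pass: per step, concat(h_i forward, time-aligned backward state).

    The backward states are computed by running the backward cell over the
    reversed sequence and re-reversing, so step i pairs the forward state
    over steps 1..i with the backward state over steps n..i.  Output is
    (n, 2H).
    """
    if p_fwd.input_dim != p_bwd.input_dim:
        raise ValueError("forward and backward cells must share input_dim")
    fwd = run_gru(p_fwd, seq)
    bwd = run_gru(p_bwd, np.asarray(seq)[::-1])[::-1]
    return np.concatenate([fwd, bwd], axis=1)


def select_group_slices(group_size: int, m: int = 4) -> list[int]:
    """Indices of ``m`` equally spaced slices within a group of ``group_size``.

    For m >= 2 the j-th index is round(j * (L - 1) / (m - 1)) with halves
    rounded up; m = 1 picks the middle slice floor(L / 2).
    """
    if not (1 <= m <= group_size):
        raise ValueError(f"require 1 <= m <= group_size, got m={m}, group_size={group_size}")
    if m == 1:
        return [group_size // 2]
    if m == group_size:
        return list(range(group_size))
    return [int(math.floor(j * (group_size - 1) / (m - 1) + 0.5)) for j in range(m)]


# ---------------------------------------------------------------------------
# trainable stacked bidirectional model
# ---------------------------------------------------------------------------


class GRUCellModule(nn.Module):
    """Autodiff twin of :func:`gru_step`; weights stored transposed for x @ W."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator, bias: bool = False):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        s_in = math.sqrt(6.0 / (input_dim + hidden_dim))
        s_h = math.sqrt(6.0 / (2 * hidden_dim))

        def w(shape, s):
            return nn.Tensor(rng.uniform(-s, s, shape), requires_grad=True)

        self.Wxz = w((input_dim, hidden_dim), s_in)
        self.Whz = w((hidden_dim, hidden_dim), s_h)
        self.Wxr = w((input_dim, hidden_dim), s_in)
        self.Whr = w((hidden_dim, hidden_dim), s_h)
        self.Wxh = w((input_dim, hidden_dim), s_in)
        self.Whh = w((hidden_dim, hidden_dim), s_h)
        self.bias = bias
        if bias:
            self.bz = nn.Tensor(np.zeros(hidden_dim), requires_grad=True)
            self.br = nn.Tensor(np.zeros(hidden_dim), requires_grad=True)
            self.bh = nn.Tensor(np.zeros(hidden_dim), requires_grad=True)

    def step(self, x: nn.Tensor, h: nn.Tensor) -> nn.Tensor:
        az = x @ self.Wxz + h @ self.Whz
        ar = x @ self.Wxr + h @ self.Whr
        if self.bias:
            az = az + self.bz
            ar = ar + self.br
        z = az.sigmoid()
        r = ar.sigmoid()
        ah = x @ self.Wxh + (h * r) @ self.Whh
        if self.bias:
            ah = ah + self.bh
        h_cand = ah.tanh()
        return (1.0 - z) * h_cand + z * h

    def run(self, steps: list[nn.Tensor]) -> list[nn.Tensor]:
        n_batch = steps[0].shape[0]
        h = nn.Tensor(np.zeros((n_batch, self.hidden_dim)))
        out = []
        for x in steps:
            h = self.step(x, h)
            out.append(h)
        return out

    def to_params(self) -> GRUParams:
        """Export the weights in the reference (HxF / HxH) layout."""
        return GRUParams(
            W_xz=self.Wxz.data.T, W_hz=self.Whz.data.T,
            W_xr=self.Wxr.data.T, W_hr=self.Whr.data.T,
            W_xh=self.Wxh.data.T, W_hh=self.Whh.data.T,
        )


class BGRULayer(nn.Module):
    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator, bias: bool = False):
        self.fwd = GRUCellModule(input_dim, hidden_dim, rng, bias)
        self.bwd = GRUCellModule(input_dim, hidden_dim, rng, bias)

    def run(self, steps: list[nn.Tensor]) -> list[nn.Tensor]:
        f = self.fwd.run(steps)
        b = self.bwd.run(steps[::-1])[::-1]
        return [nn.concat([fi, bi], axis=1) for fi, bi in zip(f, b)]


class SequenceClassifier(nn.Module):
    """Two stacked BGRU layers, two dense layers and a softmax head.

    Consumes fixed-length feature sequences of shape (n, F); the per-step
    outputs of the second BGRU layer are concatenated into one vector
    (n * 2H) before the dense head.
    """

    def __init__(
        self,
        input_dim: int,
        seq_len: int,
        hidden_dim: int = 256,
        fc_sizes: tuple[int, int] = (512, 256),
        n_classes: int = 2,
        dropout_rate: float = 0.2,
        bias: bool = False,
        seed: int = 0,
    ):
        if hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.seq_len = seq_len
        self.hidden_dim = hidden_dim
        self.dropout_rate = dropout_rate
        self.layer1 = BGRULayer(input_dim, hidden_dim, rng, bias)
        self.layer2 = BGRULayer(2 * hidden_dim, hidden_dim, rng, bias)
        self.fc1 = nn.Dense(seq_len * 2 * hidden_dim, fc_sizes[0], rng)
        self.fc2 = nn.Dense(fc_sizes[0], fc_sizes[1], rng)
        self.head = nn.Dense(fc_sizes[1], n_classes, rng)

    def logits(self, sequences: np.ndarray, training: bool = False, rng=None) -> nn.Tensor:
        x = np.asarray(sequences, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.seq_len or x.shape[2] != self.input_dim:
            raise ValueError(f"expected sequences of shape (N, {self.seq_len}, {self.input_dim}), got {x.shape}")
        t = nn.Tensor(x)
        steps = [t[:, i, :] for i in range(self.seq_len)]
        steps = [nn.dropout(s, self.dropout_rate, rng, training) for s in steps]
        steps = self.layer1.run(steps)
        steps = self.layer2.run(steps)
        steps = [nn.dropout(s, self.dropout_rate, rng, training) for s in steps]
        flat = nn.concat(steps, axis=1)
        h = self.fc1(flat).relu()
        h = self.fc2(h).relu()
        return self.head(h)

    def predict_proba(self, sequences: np.ndarray, batch_size: int = 128) -> np.ndarray:
        x = np.asarray(sequences, dtype=np.float64)
        outs = [softmax(self.logits(x[i : i + batch_size]).data) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)


def build_sequence_classifier(
    hidden_dim: int,
    n_classes: int,
    input_dim: int,
    seq_len: int,
    fc_sizes: tuple[int, int] = (512, 256),
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> SequenceClassifier:
    return SequenceClassifier(
        input_dim=input_dim,
        seq_len=seq_len,
        hidden_dim=hidden_dim,
        fc_sizes=fc_sizes,
        n_classes=n_classes,
        dropout_rate=dropout_rate,
        seed=seed,
    )


@dataclass
class SequenceTrainConfig:
    """Adam settings for the sequence classifier."""

    learning_rate: float = 1e-3
    batch_size: int = 40
    epochs: int = 60
    patience: int = 10
    dropout_rate: float = 0.2
    hidden_dim: int = 256
    fc_sizes: tuple[int, int] = (512, 256)
    seed: int = 0


@dataclass
class TrainedSequenceModel:
    model: SequenceClassifier
    val_accuracy: float
    val_losses: list[float] = field(default_factory=list)


def train_sequence_model(
    train_sequences: np.ndarray,
    train_labels: np.ndarray,
    val_sequences: np.ndarray,
    val_labels: np.ndarray,
    cfg: SequenceTrainConfig,
) -> TrainedSequenceModel:
    """Train the stacked-BGRU subject classifier for one view with Adam.

    The convolutional feature extractors are frozen upstream: this function
    only ever sees fixed feature sequences.  Training stops once validation
    error has not improved for ``cfg.patience`` epochs; best weights are
    restored.
    """
    x = np.asarray(train_sequences, dtype=np.float64)
    if x.ndim != 3 or len(x) == 0:
        raise ValueError("train_sequences must be a nonempty (N, n, F) array")
    y = np.asarray(train_labels, dtype=int)
    xv = np.asarray(val_sequences, dtype=np.float64)
    yv = np.asarray(val_labels, dtype=int)
    model = SequenceClassifier(
        input_dim=x.shape[2],
        seq_len=x.shape[1],
        hidden_dim=cfg.hidden_dim,
        fc_sizes=cfg.fc_sizes,
        n_classes=int(y.max()) + 1,
        dropout_rate=cfg.dropout_rate,
        seed=cfg.seed,
    )
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    best_acc, best_state, since_best = -1.0, None, 0
    val_losses: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            loss = nn.softmax_cross_entropy(model.logits(x[idx], training=True, rng=rng), y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_logits = model.logits(xv)
        val_losses.append(float(nn.softmax_cross_entropy(val_logits, yv).data))
        val_acc = float((softmax(val_logits.data).argmax(axis=1) == yv).mean())
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainedSequenceModel(model=model, val_accuracy=best_acc, val_losses=val_losses)
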