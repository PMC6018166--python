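"""Per-group 2D convolutional networks for intra-slice feature learning.

Each slice group gets its own network; all groups share one architecture so
that slices can be reduced to a common size and features have a common
dimension.  The reference architecture stacks five 3x3 convolutions (16, 16,
32, 32, 64 filters; the first with stride 2), two 2x2/2 max-pooling layers,
two fully connected layers (512, 256 units) and a softmax pair, all with
"valid" (unpadded) windows, taking a 1x150x150 slice to the layer sizes
74, 72, 36, 34, 32, 16, 14, 12544, 512, 256, 2.

Slices inherit their subject's class label; the slice-level validation
accuracy of each group network is recorded and later used to prune weak
groups.  After pre-training, the activations of the second fully connected
layer serve as the per-slice feature vector for the recurrent stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn


class ArchitectureError(ValueError):
    """Raised when layer arithmetic produces a non-positive spatial size."""


class SingleClassError(ValueError):
    """Raised when training data contains fewer than two classes."""


@dataclass
class ConvLayerSpec:
    kind: str  # conv | maxpool | flatten | dense | softmax
    n_filters: int = 0  # conv filters or dense/softmax units
    kernel: int = 0
    stride: int = 1
    activation: str = "relu"

    def __post_init__(self):
        if self.kind not in ("conv", "maxpool", "flatten", "dense", "softmax"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class CNNArchitecture:
    layers: list[ConvLayerSpec]
    input_shape: tuple[int, int, int] = (1, 150, 150)


def table2_architecture(n_classes: int = 2, activation: str = "relu") -> CNNArchitecture:
    """The reference slice-network architecture for 150x150 inputs."""
    a = activation
    return CNNArchitecture(
        layers=[
            ConvLayerSpec("conv", 16, 3, 2, a),
            ConvLayerSpec("conv", 16, 3, 1, a),
            ConvLayerSpec("maxpool", kernel=2, stride=2),
            ConvLayerSpec("conv", 32, 3, 1, a),
            ConvLayerSpec("conv", 32, 3, 1, a),
            ConvLayerSpec("maxpool", kernel=2, stride=2),
            ConvLayerSpec("conv", 64, 3, 1, a),
            ConvLayerSpec("flatten"),
            ConvLayerSpec("dense", 512, activation=a),
            ConvLayerSpec("dense", 256, activation=a),
            ConvLayerSpec("softmax", n_classes),
        ],
        input_shape=(1, 150, 150),
    )


def scaled_architecture(
    input_hw: int = 48,
    widths: tuple[int, ...] = (8, 8, 16, 16, 32),
    fc: tuple[int, int] = (64, 32),
    n_classes: int = 2,
    activation: str = "relu",
) -> CNNArchitecture:
    """The same topology with thinner layers for small desk-scale slices."""
    a = activation
    return CNNArchitecture(
        layers=[
            ConvLayerSpec("conv", widths[0], 3, 2, a),
            ConvLayerSpec("conv", widths[1], 3, 1, a),
            ConvLayerSpec("maxpool", kernel=2, stride=2),
            ConvLayerSpec("conv", widths[2], 3, 1, a),
            ConvLayerSpec("conv", widths[3], 3, 1, a),
            ConvLayerSpec("maxpool", kernel=2, stride=2),
            ConvLayerSpec("conv", widths[4], 3, 1, a),
            ConvLayerSpec("flatten"),
            ConvLayerSpec("dense", fc[0], activation=a),
            ConvLayerSpec("dense", fc[1], activation=a),
            ConvLayerSpec("softmax", n_classes),
        ],
        input_shape=(1, input_hw, input_hw),
    )


def compute_output_shapes(arch: CNNArchitecture) -> list[tuple[int, ...]]:
    """Propagate the input shape through every layer (valid windows).

    Spatial arithmetic per conv/pool layer: out = floor((in - k) / s) + 1.
    """
    c, h, w = arch.input_shape
    shapes: list[tuple[int, ...]] = []
    flat: int | None = None
    for layer in arch.layers:
        if layer.kind in ("conv", "maxpool"):
            if flat is not None:
                raise ArchitectureError("spatial layer after flatten")
            k, s = layer.kernel, layer.stride
            h2 = (h - k) // s + 1
            w2 = (w - k) // s + 1
            if h2 <= 0 or w2 <= 0:
                raise ArchitectureError(f"{layer.kind} {k}x{k}/{s} collapses a {h}x{w} input")
            h, w = h2, w2
            if layer.kind == "conv":
                c = layer.n_filters
            shapes.append((c, h, w))
        elif layer.kind == "flatten":
            flat = c * h * w
            shapes.append((flat,))
        else:  # dense | softmax
            if flat is None:
                raise ArchitectureError("dense layer before flatten")
            flat = layer.n_filters
            shapes.append((flat,))
    return shapes


def count_parameters(arch: CNNArchitecture) -> int:
    """Trainable parameter count (weights + biases) of the architecture."""
    c_in = arch.input_shape[0]
    shapes = compute_output_shapes(arch)
    total = 0
    prev_flat = None
    for layer, shape in zip(arch.layers, shapes):
        if layer.kind == "conv":
            total += layer.n_filters * c_in * layer.kernel * layer.kernel + layer.n_filters
            c_in = layer.n_filters
        elif layer.kind == "flatten":
            prev_flat = shape[0]
        elif layer.kind in ("dense", "softmax"):
            total += prev_flat * layer.n_filters + layer.n_filters
            prev_flat = layer.n_filters
    return total


def softmax(logits: np.ndarray) -> np.ndarray:
    """Normalized exponential over the last axis; rows sum to one."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class GroupCNN(nn.Module):
    """A slice classifier instantiated from a :class:`CNNArchitecture`.

    ``feature_layer`` selects which fully connected layer provides the
    per-slice embedding: "fc2" (default, the last hidden layer) or "fc1".
    """

    def __init__(self, arch: CNNArchitecture, seed: int = 0, dropout_rate: float = 0.5, feature_layer: str = "fc2"):
        compute_output_shapes(arch)  # validate arithmetic before building
        if feature_layer not in ("fc1", "fc2"):
            raise ValueError("feature_layer must be 'fc1' or 'fc2'")
        self.arch = arch
        self.dropout_rate = dropout_rate
        self.feature_layer = feature_layer
        rng = np.random.default_rng(seed)
        c, h, w = arch.input_shape
        self.ops: list[tuple[str, object]] = []
        flat = None
        for layer in arch.layers:
            if layer.kind == "conv":
                self.ops.append(("conv", nn.Conv2d(c, layer.n_filters, layer.kernel, layer.stride, rng)))
                self.ops.append(("act", layer.activation))
                c = layer.n_filters
                h = (h - layer.kernel) // layer.stride + 1
                w = (w - layer.kernel) // layer.stride + 1
            elif layer.kind == "maxpool":
                if (layer.kernel, layer.stride) != (2, 2):
                    raise ArchitectureError("trainable model supports 2x2/2 max pooling")
                self.ops.append(("pool", nn.MaxPool2()))
                h, w = h // 2, w // 2
            elif layer.kind == "flatten":
                flat = c * h * w
                self.ops.append(("flatten", flat))
            elif layer.kind == "dense":
                self.ops.append(("dropout", None))
                self.ops.append(("dense", nn.Dense(flat, layer.n_filters, rng)))
                self.ops.append(("act", layer.activation))
                flat = layer.n_filters
            else:  # softmax head: linear logits; normalisation lives in the loss
                self.ops.append(("dense", nn.Dense(flat, layer.n_filters, rng)))
        self.feature_dim = self._dense_units(arch)[{"fc1": 0, "fc2": 1}[feature_layer]]
        self._modules = [op for _, op in self.ops if isinstance(op, nn.Module)]

    @staticmethod
    def _dense_units(arch: CNNArchitecture) -> list[int]:
        return [layer.n_filters for layer in arch.layers if layer.kind == "dense"]

    def parameters(self):
        params = []
        for m in self._modules:
            params.extend(m.parameters())
        return params

    def _forward(self, x: nn.Tensor, training: bool, rng, tap: str | None):
        dense_index = 0
        tapped = None
        for kind, op in self.ops:
            if kind in ("conv", "pool", "dense"):
                x = op(x)
                if kind == "dense":
                    dense_index += 1
            elif kind == "act":
                x = x.relu() if op == "relu" else x.tanh()
                if tap is not None and dense_index == {"fc1": 1, "fc2": 2}[tap]:
                    tapped = x
            elif kind == "flatten":
                x = x.reshape(x.shape[0], op)
            elif kind == "dropout":
                x = nn.dropout(x, self.dropout_rate, rng, training)
        return x, tapped

    def logits(self, x: np.ndarray, training: bool = False, rng=None) -> nn.Tensor:
        t = nn.Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)
        out, _ = self._forward(t, training, rng, tap=None)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        outs = [softmax(self.logits(x[i : i + batch_size]).data) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Embedding of each slice from the selected fully connected layer."""
        x = np.asarray(x, dtype=np.float64)
        outs = []
        for i in range(0, len(x), batch_size):
            t = nn.Tensor(x[i : i + batch_size])
            _, tapped = self._forward(t, False, None, tap=self.feature_layer)
            outs.append(tapped.data)
        return np.concatenate(outs, axis=0)


@dataclass
class TrainConfig:
    """Optimisation settings for the slice networks (SGD with momentum)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 1e-6
    batch_size: int = 40
    epochs: int = 100
    dropout_rate: float = 0.5
    patience: int = 10
    seed: int = 0
    activation: str = "relu"
    feature_layer: str = "fc2"

    def __post_init__(self):
        for name in ("learning_rate", "momentum", "weight_decay", "batch_size", "epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedGroupCNN:
    model: GroupCNN
    val_accuracy: float
    train_losses: list[float] = field(default_factory=list)


def extract_features(model: GroupCNN, slices: np.ndarray) -> np.ndarray:
    """Per-slice feature vectors (dropout disabled, deterministic)."""
    slices = np.asarray(slices, dtype=np.float64)
    if slices.ndim == 2:
        slices = slices[None]
    if slices.ndim == 3:
        slices = slices[:, None]
    expected = model.arch.input_shape[1:]
    if slices.shape[2:] != expected:
        raise ValueError(f"slice shape {slices.shape[2:]} does not match model input {expected}")
    return model.features(slices)


def train_group_cnn(
    train_slices: np.ndarray,
    train_labels: np.ndarray,
    val_slices: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig,
    arch: CNNArchitecture | None = None,
) -> TrainedGroupCNN:
    """Pre-train one group network and record its slice-level validation accuracy.

    Training minimises the softmax cross-entropy with SGD (momentum,
    weight decay) and stops early once the validation error has not
    improved for ``cfg.patience`` epochs; the best-validation weights are
    restored.
    """
    train_labels = np.asarray(train_labels, dtype=int)
    val_labels = np.asarray(val_labels, dtype=int)
    if len(np.unique(train_labels)) < 2:
        raise SingleClassError("training slices contain a single class")
    x = np.asarray(train_slices, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]
    xv = np.asarray(val_slices, dtype=np.float64)
    if xv.ndim == 3:
        xv = xv[:, None]
    if arch is None:
        arch = table2_architecture(n_classes=int(train_labels.max()) + 1, activation=cfg.activation)
    elif cfg.activation != "relu":
        arch = replace(arch, layers=[replace(l, activation=cfg.activation) for l in arch.layers])

    model = GroupCNN(arch, seed=cfg.seed, dropout_rate=cfg.dropout_rate, feature_layer=cfg.feature_layer)
    opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed + 1)

    best_acc, best_state, since_best = -1.0, None, 0
    losses: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits, _ = model._forward(nn.Tensor(x[idx]), True, rng, tap=None)
            loss = nn.softmax_cross_entropy(logits, train_labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / len(x))
        val_acc = float((model.predict_proba(xv).argmax(axis=1) == val_labels).mean())
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainedGroupCNN(model=model, val_accuracy=best_acc, train_losses=losses)
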