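"""Build, train and apply the binary CNN mapping matrices to Pr[AI].

Architecture: an input batch-normalisation layer (the 8-bit count
matrices are fed in unnormalised), followed by ``k`` blocks of
batch normalisation -> 2D convolution (16 filters, 4x4 kernel, 2x2
stride, SAME padding) -> leaky ReLU, then a flatten and a single
sigmoid output unit.  There are no pooling layers; the stride does the
downsampling.  Labels follow the convention AI = 1, {neutral, sweep,
DFE} = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from introscan._nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Flatten,
    LeakyReLU,
    Sequential,
    bce_with_logits,
    sigmoid,
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters."""

    m: int = 256
    k: int = 7
    filters: int = 16
    kernel: tuple[int, int] = (4, 4)
    stride: tuple[int, int] = (2, 2)
    leaky_alpha: float = 0.2

    def __post_init__(self):
        if self.k < 0 or self.m < 1:
            raise ValueError("invalid model config")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters (defaults as used for the results)."""

    epochs: int = 3
    batch_size: int = 64
    learning_rate: float = 1e-3
    split_fraction: float = 0.9

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must be in (0, 1)")


@dataclass
class TrainedClassifier:
    """A (possibly trained) CNN with its configuration and history."""

    config: ModelConfig
    input_shape: tuple[int, int]
    network: Sequential
    history: dict[str, list[float]] = field(default_factory=dict)
    label_convention: str = "AI=1"

    def predict(self, matrices: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return predict(self, matrices, batch_size=batch_size)

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.network.state_dict())
        meta = {
            "config": self.config.__dict__ | {"kernel": list(self.config.kernel),
                                              "stride": list(self.config.stride)},
            "input_shape": list(self.input_shape),
            "history": self.history,
            "label_convention": self.label_convention,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        cfg_d = meta["config"]
        cfg_d["kernel"] = tuple(cfg_d["kernel"])
        cfg_d["stride"] = tuple(cfg_d["stride"])
        cfg = ModelConfig(**cfg_d)
        clf = build_model(cfg, tuple(meta["input_shape"]), seed=0)
        with np.load(path / "weights.npz") as state:
            clf.network.load_state_dict(state)
        clf.history = meta["history"]
        clf.label_convention = meta["label_convention"]
        return clf


def build_model(
    cfg: ModelConfig, input_shape: tuple[int, int], seed: int = 0
) -> TrainedClassifier:
    """Construct the untrained classifier for (n, m) input matrices.

    Raises
    ------
    ValueError
        If ``k`` is too deep for the input: both dimensions must be at
        least ``2**k`` so every block output keeps size >= 2.
    """
    n, m = input_shape
    if m != cfg.m:
        raise ValueError(f"input has {m} bins but config expects {cfg.m}")
    if cfg.k > 0 and min(n, m) < 2 ** cfg.k:
        raise ValueError(
            f"k={cfg.k} blocks too deep for input {input_shape}; "
            f"need min(n, m) >= {2 ** cfg.k}"
        )
    rng = np.random.default_rng(seed)
    layers = [BatchNorm(1)]
    h, w, c = n, m, 1
    for _ in range(cfg.k):
        layers.append(BatchNorm(c))
        conv = Conv2D(c, cfg.filters, kernel=cfg.kernel, stride=cfg.stride, rng=rng)
        layers.append(conv)
        layers.append(LeakyReLU(cfg.leaky_alpha))
        h, w = conv.out_shape(h, w)
        c = cfg.filters
    layers.append(Flatten())
    layers.append(Dense(h * w * c, 1, rng=rng))
    return TrainedClassifier(config=cfg, input_shape=(n, m), network=Sequential(layers))


def split_train_val(
    data: tuple, fraction: float = 0.9, seed: int = 0, labels=None
) -> tuple[tuple, tuple]:
    """Class-stratified, reproducible split of aligned arrays.

    ``data`` is a tuple of equal-length sequences; stratification uses
    ``labels`` (default: ``data[1]``).  Returns ``(train, val)`` tuples
    with the same structure as ``data``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(data[1] if labels is None else labels)
    rng = np.random.default_rng(seed)
    train_idx = []
    val_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        cut = int(round(fraction * len(idx)))
        train_idx.append(idx[:cut])
        val_idx.append(idx[cut:])
    train_idx = np.sort(np.concatenate(train_idx))
    val_idx = np.sort(np.concatenate(val_idx))

    def take(part, idx):
        return tuple(
            a[idx] if isinstance(a, np.ndarray) else [a[i] for i in idx] for a in part
        )

    return take(data, train_idx), take(data, val_idx)


def _as_input(matrices: np.ndarray) -> np.ndarray:
    x = np.asarray(matrices)
    if x.ndim == 3:
        x = x[..., None]
    return x


def train(
    classifier: TrainedClassifier,
    train_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    validation_data: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedClassifier:
    """Train with Adam on cross-entropy; inputs are consumed as 8-bit
    integer matrices and normalised inside the network.

    Records per-epoch ``loss``/``accuracy`` (and ``val_accuracy`` when
    validation data is given) in ``classifier.history``.
    """
    X, y = train_set
    X = _as_input(X)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[1:3] != classifier.input_shape:
        raise ValueError(
            f"matrix shape {X.shape[1:3]} does not match model input "
            f"{classifier.input_shape}"
        )
    rng = np.random.default_rng(seed)
    net = classifier.network
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history = {"loss": [], "accuracy": []}
    if validation_data is not None:
        history["val_accuracy"] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X[idx].astype(np.float32)
            yb = y[idx]
            z = net.forward(xb, train=True)
            loss, dz = bce_with_logits(z, yb)
            net.backward(dz)
            opt.step()
            losses.append(loss * len(idx))
            correct += int(((sigmoid(z.ravel()) > 0.5) == (yb > 0.5)).sum())
        history["loss"].append(sum(losses) / len(X))
        history["accuracy"].append(correct / len(X))
        _recalibrate_norm_stats(net, X, cfg.batch_size)
        if validation_data is not None:
            pv = predict(classifier, validation_data[0])
            acc = float(np.mean((pv > 0.5) == (np.asarray(validation_data[1]) > 0.5)))
            history["val_accuracy"].append(acc)
    classifier.history = history
    return classifier


def _recalibrate_norm_stats(net, X: np.ndarray, batch_size: int) -> None:
    """Replace EMA normalisation statistics with exact averages over the
    training set.  With few batches the exponential moving averages are
    nowhere near converged, which would wreck inference-mode output."""
    from introscan._nn import BatchNorm

    bn_layers = [l for l in net.layers if isinstance(l, BatchNorm)]
    for layer in bn_layers:
        layer.calibrating = True
        layer._calib_n = 0
        layer.moving_mean[...] = 0
        layer.moving_var[...] = 0
    for start in range(0, len(X), batch_size):
        net.forward(X[start : start + batch_size].astype(np.float32), train=True)
    for layer in bn_layers:
        layer.calibrating = False


def predict(
    classifier: TrainedClassifier, matrices: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Pr[AI] for each matrix; deterministic given the trained weights."""
    X = _as_input(matrices)
    if X.shape[1:3] != classifier.input_shape:
        raise ValueError(
            f"matrix shape {X.shape[1:3]} does not match model input "
            f"{classifier.input_shape}"
        )
    out = []
    for start in range(0, len(X), batch_size):
        z = classifier.network.forward(
            X[start : start + batch_size].astype(np.float32), train=False
        )
        out.append(sigmoid(z.ravel()))
    return np.concatenate(out) if out else np.empty(0)
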