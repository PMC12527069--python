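"""Heartbeat classifiers: 1D-CNN, stacked LSTM, and the hybrid 1D-CNN-LSTM.

Three architectures classify fixed-length beat segments into the five AAMI
classes:

* :class:`CNNClassifier` — two convolutional blocks
  (Conv(1->256, k=8, s=5, p=1) and Conv(256->128, k=7, s=4, p=1), each with
  ReLU, dropout and max-pool 2), a flatten, a 128-unit dense layer and a
  softmax over the 5 classes;
* :class:`LSTMClassifier` — the raw segment as a length-T sequence of
  scalars through three stacked LSTM layers (64, 32, 16 units) with 0.4
  dropout between them, then a dense softmax head on the final hidden
  state;
* :class:`HybridCNNLSTM` — the CNN front end's final feature map
  re-interpreted as a (time x channels) sequence feeding a single LSTM
  layer, then a dense softmax head.  This hand-off keeps >1 time step so
  the recurrent stage can model the temporal order of the extracted
  features.

Usage follows the model/results convention: construct the model from data,
call ``fit`` to obtain a :class:`TrainingResults` carrying the trained
weights, the per-epoch history and evaluation helpers::

    model = HybridCNNLSTM(train_ds, valid_ds)
    res = model.fit(TrainConfig(epochs=10, seed=0))
    print(res.summary())
    report = res.evaluate(test_ds)

Training uses weighted cross-entropy (inverse-class-frequency weights by
default) to counter the dominance of normal beats, Kaiming-normal
initialization, and seeded shuffling so a given seed reproduces a run
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._exceptions import ConfigurationError, NumericalError, ValidationError
from .io import AAMI_CLASSES, BeatDataset
from .nn import (
    Conv1d, Dense, Dropout, Flatten, LSTM, MaxPool1d, ReLU, Sequential,
    ToSequence, kaiming_init, make_optimizer, softmax, softmax_wce_with_grad,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlock:
    """One convolutional block: Conv -> ReLU -> Dropout -> MaxPool."""
    filters: int
    kernel_size: int
    stride: int = 1
    padding: int = 1
    dropout_rate: float = 0.1
    pool_size: int = 2

    def __post_init__(self):
        if min(self.filters, self.kernel_size, self.stride, self.pool_size) < 1:
            raise ValidationError("conv block dimensions must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")


#: Standard two-block CNN front end (256 filters k=8 s=5, then 128 k=7 s=4).
DEFAULT_CONV_BLOCKS = (
    ConvBlock(filters=256, kernel_size=8, stride=5, padding=1,
              dropout_rate=0.15, pool_size=2),
    ConvBlock(filters=128, kernel_size=7, stride=4, padding=1,
              dropout_rate=0.10, pool_size=2),
)


@dataclass(frozen=True)
class CNNConfig:
    blocks: tuple[ConvBlock, ...] = DEFAULT_CONV_BLOCKS
    dense_units: int = 128
    n_classes: int = 5
    input_len: int = 280

    def __post_init__(self):
        if self.input_len < 1 or self.dense_units < 1 or self.n_classes < 1:
            raise ValidationError("CNNConfig counts must be >= 1")


@dataclass(frozen=True)
class LSTMConfig:
    layer_sizes: tuple[int, ...] = (64, 32, 16)
    inter_layer_dropout: float = 0.4
    n_classes: int = 5
    input_len: int = 280

    def __post_init__(self):
        if not self.layer_sizes or min(self.layer_sizes) < 1:
            raise ValidationError("layer_sizes must be nonempty positive counts")
        if not (0.0 <= self.inter_layer_dropout < 1.0):
            raise ValidationError("inter_layer_dropout must be in [0, 1)")


@dataclass(frozen=True)
class HybridConfig:
    blocks: tuple[ConvBlock, ...] = DEFAULT_CONV_BLOCKS
    lstm_hidden: int = 64
    n_classes: int = 5
    input_len: int = 280

    def __post_init__(self):
        if self.lstm_hidden < 1:
            raise ValidationError("lstm_hidden must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop parameters.

    Defaults follow the hybrid model's regimen (AdamW, lr 1e-3); the CNN
    and LSTM classifiers override the optimizer and learning rate with
    their own published settings via ``default_train_config``.
    """
    epochs: int = 30
    batch_size: int = 20
    learning_rate: float = 1e-3
    optimizer_name: str = "adamw"
    class_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")


def inverse_frequency_weights(labels: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Class weights proportional to inverse frequency, mean-normalized.

    Classes absent from ``labels`` get weight 0 (they cannot occur in the
    loss anyway).
    """
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=n_classes)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


# ---------------------------------------------------------------------------
# Architecture builders
# ---------------------------------------------------------------------------

def _conv_front_end(blocks, input_len: int) -> tuple[list, tuple]:
    layers: list = []
    shape = (1, input_len)
    in_ch = 1
    for bi, blk in enumerate(blocks):
        conv = Conv1d(in_ch, blk.filters, blk.kernel_size, blk.stride, blk.padding)
        for layer in (conv, ReLU(), Dropout(blk.dropout_rate),
                      MaxPool1d(blk.pool_size)):
            try:
                shape = layer.out_shape(shape)
            except ConfigurationError as exc:
                raise ConfigurationError(
                    f"block {bi + 1} ({type(layer).__name__}): {exc}") from exc
            layers.append(layer)
        in_ch = blk.filters
    return layers, shape


def build_cnn(cfg: CNNConfig) -> Sequential:
    """Two conv blocks -> flatten -> dense -> class logits.

    ``predict_proba`` applies the softmax, so the network's own output rows
    are logits; the probability simplex property is enforced downstream.
    """
    layers, shape = _conv_front_end(cfg.blocks, cfg.input_len)
    layers.append(Flatten())
    flat = int(np.prod(shape))
    layers += [Dense(flat, cfg.dense_units), ReLU(),
               Dense(cfg.dense_units, cfg.n_classes)]
    return Sequential(layers, input_shape=(1, cfg.input_len))


def build_lstm(cfg: LSTMConfig) -> Sequential:
    layers: list = []
    in_size = 1
    n = len(cfg.layer_sizes)
    for li, hidden in enumerate(cfg.layer_sizes):
        last = li == n - 1
        layers.append(LSTM(in_size, hidden, return_sequences=not last))
        if not last and cfg.inter_layer_dropout > 0:
            layers.append(Dropout(cfg.inter_layer_dropout))
        in_size = hidden
    layers.append(Dense(in_size, cfg.n_classes))
    return Sequential(layers, input_shape=(cfg.input_len, 1))


def build_hybrid(cfg: HybridConfig) -> Sequential:
    """Conv feature extractor -> (time x channels) sequence -> LSTM -> logits."""
    layers, shape = _conv_front_end(cfg.blocks, cfg.input_len)
    channels, length = shape
    if length < 1:
        raise ConfigurationError(
            "hybrid hand-off: the conv feature map has no time steps left")
    layers += [ToSequence(), LSTM(channels, cfg.lstm_hidden),
               Dense(cfg.lstm_hidden, cfg.n_classes)]
    return Sequential(layers, input_shape=(1, cfg.input_len))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.argmax(logits, axis=1) == labels))


def _batched_forward(net, X, batch: int = 256) -> np.ndarray:
    outs = [net.forward(X[i:i + batch], training=False)
            for i in range(0, X.shape[0], batch)]
    return np.vstack(outs)


def train_model(
    net: Sequential,
    train_X: np.ndarray, train_y: np.ndarray,
    valid_X: np.ndarray, valid_y: np.ndarray,
    cfg: TrainConfig,
) -> tuple[Sequential, dict]:
    """Seeded mini-batch training; returns the final net and its history.

    The history dict holds per-epoch ``train_loss``, ``train_acc``,
    ``val_loss``, ``val_acc`` and ``best_epoch`` (0-based index of the
    best validation accuracy).  Weights are initialized Kaiming-normal
    from ``cfg.seed`` before the first update.
    """
    if train_X.shape[0] == 0 or valid_X.shape[0] == 0:
        raise ValidationError("training and validation sets must be nonempty")
    if not (np.all(np.isfinite(train_X)) and np.all(np.isfinite(valid_X))):
        raise ValidationError("training data must be finite")

    weights = None
    if cfg.class_weights is not None:
        weights = np.asarray(cfg.class_weights, dtype=float)

    kaiming_init(net, cfg.seed)
    net.seed_dropout(cfg.seed + 1)
    rng = np.random.default_rng(cfg.seed + 2)
    opt = make_optimizer(cfg.optimizer_name, cfg.learning_rate)

    n = train_X.shape[0]
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    from .nn.loss import weighted_cross_entropy  # scoring route

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(train_X[idx], training=True)
            loss, grad = softmax_wce_with_grad(logits, train_y[idx], weights)
            if not np.isfinite(loss):
                raise NumericalError(
                    f"non-finite loss at epoch {epoch}, batch start {start} "
                    f"(lr={cfg.learning_rate}, batch_size={cfg.batch_size})")
            net.backward(grad)
            opt.step(net.parameters(), net.gradients())

        tr_logits = _batched_forward(net, train_X)
        va_logits = _batched_forward(net, valid_X)
        history["train_loss"].append(
            weighted_cross_entropy(softmax(tr_logits, axis=1), train_y, weights))
        history["train_acc"].append(_accuracy(tr_logits, train_y))
        history["val_loss"].append(
            weighted_cross_entropy(softmax(va_logits, axis=1), valid_y, weights))
        history["val_acc"].append(_accuracy(va_logits, valid_y))
        logger.info("epoch %d/%d  loss %.4f  acc %.4f  val_acc %.4f",
                    epoch + 1, cfg.epochs, history["train_loss"][-1],
                    history["train_acc"][-1], history["val_acc"][-1])

    history["best_epoch"] = int(np.argmax(history["val_acc"]))
    return net, history


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class BeatClassifier:
    """Common base: a classifier model bound to train/validation data."""

    #: subclasses set the architecture config type and builder
    name = "base"

    def __init__(self, train: BeatDataset, valid: BeatDataset, config=None):
        if len(train) == 0 or len(valid) == 0:
            raise ValidationError("train and valid datasets must be nonempty")
        if train.segment_len != valid.segment_len:
            raise ValidationError("train/valid segment lengths differ")
        self.train_data = train
        self.valid_data = valid
        self.config = self._default_config(train.segment_len) if config is None \
            else config

    # -- hooks ------------------------------------------------------------
    def _default_config(self, input_len: int):
        raise NotImplementedError

    def _build(self) -> Sequential:
        raise NotImplementedError

    def _to_input(self, segments: np.ndarray) -> np.ndarray:
        """Reshape (n, L) segments into the network's input tensor."""
        raise NotImplementedError

    def default_train_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(seed=seed)

    # -- fitting ----------------------------------------------------------
    def fit(self, train_config: TrainConfig | None = None) -> "TrainingResults":
        cfg = train_config or self.default_train_config()
        if cfg.class_weights is None:
            cfg = TrainConfig(**{**asdict(cfg), "class_weights":
                                 tuple(inverse_frequency_weights(self.train_data.labels))})
        net = self._build()
        net, history = train_model(
            net,
            self._to_input(self.train_data.segments), self.train_data.labels,
            self._to_input(self.valid_data.segments), self.valid_data.labels,
            cfg,
        )
        return TrainingResults(self, net, history, cfg)

    @property
    def n_parameters(self) -> int:
        return self._build().n_parameters


class CNNClassifier(BeatClassifier):
    name = "cnn"

    def _default_config(self, input_len):
        return CNNConfig(input_len=input_len)

    def _build(self):
        return build_cnn(self.config)

    def _to_input(self, segments):
        return segments[:, None, :]

    def default_train_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(epochs=30, batch_size=20, learning_rate=1.5e-4,
                           optimizer_name="adam", seed=seed)


class LSTMClassifier(BeatClassifier):
    name = "lstm"

    def _default_config(self, input_len):
        return LSTMConfig(input_len=input_len)

    def _build(self):
        return build_lstm(self.config)

    def _to_input(self, segments):
        return segments[:, :, None]

    def default_train_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(epochs=30, batch_size=20, learning_rate=2e-4,
                           optimizer_name="adam", seed=seed)


class HybridCNNLSTM(BeatClassifier):
    name = "hybrid"

    def _default_config(self, input_len):
        return HybridConfig(input_len=input_len)

    def _build(self):
        return build_hybrid(self.config)

    def _to_input(self, segments):
        return segments[:, None, :]

    def default_train_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(epochs=30, batch_size=20, learning_rate=1e-3,
                           optimizer_name="adamw", seed=seed)


class TrainingResults:
    """Outcome of one training run: weights, history, and evaluation."""

    def __init__(self, model: BeatClassifier, net: Sequential, history: dict,
                 train_config: TrainConfig):
        self.model = model
        self.net = net
        self.history = history
        self.train_config = train_config

    @property
    def best_epoch(self) -> int:
        return self.history["best_epoch"]

    @property
    def final_val_accuracy(self) -> float:
        return self.history["val_acc"][-1]

    # -- prediction -------------------------------------------------------
    def predict_proba(self, data) -> np.ndarray:
        segments = data.segments if isinstance(data, BeatDataset) else np.asarray(data)
        logits = _batched_forward(self.net, self.model._to_input(segments))
        return softmax(logits, axis=1)

    def predict(self, data) -> np.ndarray:
        return np.argmax(self.predict_proba(data), axis=1)

    def evaluate(self, test: BeatDataset):
        """Confusion matrix and metric suite on a held-out dataset."""
        from .evaluate import evaluate_predictions
        return evaluate_predictions(test.labels, self.predict(test))

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        h = self.history
        cfg = self.train_config
        lines = [
            f"{type(self.model).__name__} training results",
            "=" * 44,
            f"epochs           {cfg.epochs:>10d}",
            f"batch size       {cfg.batch_size:>10d}",
            f"optimizer        {cfg.optimizer_name:>10s}",
            f"learning rate    {cfg.learning_rate:>10.2g}",
            f"seed             {cfg.seed:>10d}",
            f"parameters       {self.net.n_parameters:>10d}",
            "-" * 44,
            f"final train acc  {h['train_acc'][-1]:>10.4f}",
            f"final val acc    {h['val_acc'][-1]:>10.4f}",
            f"best val acc     {max(h['val_acc']):>10.4f} (epoch {h['best_epoch'] + 1})",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path_prefix) -> None:
        """Weights as ``<prefix>.npz`` plus a JSON sidecar (config, history)."""
        prefix = Path(path_prefix)
        np.savez_compressed(prefix.with_suffix(".npz"), **self.net.parameters())
        sidecar = {
            "model": self.model.name,
            "train_config": asdict(self.train_config),
            "history": self.history,
            "classes": list(AAMI_CLASSES),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def load_weights(self, path_prefix) -> None:
        with np.load(Path(path_prefix).with_suffix(".npz")) as z:
            self.net.set_parameters({k: z[k] for k in z.files})
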