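"""The hybrid CNN / Bi-LSTM binder classifier.

Architecture of the full model: the stacked per-residue encodings
(EIIP / INM / AAAF) pass through an embedding front-end (lookup table for
the integer INM channel, learned linear maps for the continuous channels,
summed position-wise), then through two parallel branches — a 1-D valid
convolution at a branch-specific kernel size (defaults 10 and 8, ReLU),
max pooling (window 2), batch normalisation, dropout (rate 0.5) and a
bidirectional LSTM summarised by its final hidden states.  The branch
summaries are concatenated and fed to a ReLU dense layer and a final
1-unit dense layer with sigmoid output: the predicted probability that the
peptide binds.  A peptide is called a binder when that probability is
*strictly* greater than the decision threshold (default 0.5).

Five ablation variants of the architecture (single CNN, single Bi-LSTM,
CNN→Bi-LSTM in series, two parallel CNNs, two parallel Bi-LSTMs) are
available through :func:`build_variant` for architecture comparisons.

Training minimises binary cross-entropy with Adam and is bit-for-bit
reproducible under a fixed seed (NumPy throughout — no threading
nondeterminism).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .encoders import CHANNELS, DEFAULT_L_MAX, EncodingMatrix, encode_batch
from .exceptions import (
    ConfigurationError,
    DivergenceError,
    ShapeError,
    TrainingError,
)
from .peptide_io import LabeledDataset

VARIANTS = (
    "cnn_only",
    "bilstm_only",
    "cnn_then_bilstm_series",
    "cnn_parallel",
    "bilstm_parallel",
    "full",
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    Defaults follow the published architecture where stated (branch kernel
    sizes 10 and 8, pooling window 2, dropout 0.5) and this package's own
    choices elsewhere (widths, optimiser settings, early stopping).
    """

    l_max: int = DEFAULT_L_MAX
    channels: tuple[str, ...] = CHANNELS
    embedding_dim: int = 32
    branch_kernels: tuple[int, int] = (10, 8)
    pool_size: int = 2
    dropout_rate: float = 0.5
    conv_filters: int = 64
    lstm_units: int = 64
    dense_units: int = 64
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    patience: int = 10
    pad_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(
                f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        for k in self.branch_kernels:
            if k > self.l_max:
                raise ConfigurationError(
                    f"branch kernel {k} exceeds input length {self.l_max}")
        positive = {
            "l_max": self.l_max, "embedding_dim": self.embedding_dim,
            "pool_size": self.pool_size, "conv_filters": self.conv_filters,
            "lstm_units": self.lstm_units, "dense_units": self.dense_units,
            "batch_size": self.batch_size,
        }
        for name, value in positive.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.epochs < 0:
            raise ConfigurationError(f"epochs must be >= 0, got {self.epochs}")
        if not self.channels:
            raise ConfigurationError("at least one encoding channel is required")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "branch_kernels", tuple(self.branch_kernels))


def sigmoid(x):
    """``Sigmoid(x) = (1 + e^{-x})^{-1}`` (numerically stable)."""
    return nn.stable_sigmoid(x)


def _pooled_length(config: ModelConfig, kernel: int) -> int:
    conv_len = config.l_max - kernel + 1
    pooled = conv_len // config.pool_size
    if pooled < 1:
        raise ConfigurationError(
            f"kernel {kernel} with pool {config.pool_size} leaves no positions "
            f"at input length {config.l_max}")
    return pooled


def _conv_branch(config: ModelConfig, kernel: int, rng: np.random.Generator,
                 recurrent: bool) -> tuple[nn.Sequential, int]:
    """conv → ReLU → pool → batch-norm → dropout, then Bi-LSTM or flatten."""
    pooled = _pooled_length(config, kernel)
    layers: list[nn.Layer] = [
        nn.Conv1D(config.embedding_dim, config.conv_filters, kernel, rng),
        nn.ReLU(),
        nn.MaxPool1D(config.pool_size),
        nn.BatchNorm(config.conv_filters),
        nn.Dropout(config.dropout_rate),
    ]
    if recurrent:
        layers.append(nn.BiLSTM(config.conv_filters, config.lstm_units, rng))
        width = 2 * config.lstm_units
    else:
        layers.append(nn.Flatten())
        width = pooled * config.conv_filters
    return nn.Sequential(layers), width


def _head(config: ModelConfig, in_width: int, rng: np.random.Generator
          ) -> list[nn.Layer]:
    return [
        nn.Dense(in_width, config.dense_units, rng, activation="relu"),
        nn.Dense(config.dense_units, 1, rng, activation="linear"),
    ]


class Model(nn.Sequential):
    """Embedding front-end plus trunk; maps (B, L, C) encodings to logits."""

    def __init__(self, config: ModelConfig, layers: Sequence[nn.Layer],
                 variant: str):
        super().__init__(layers)
        self.config = config
        self.variant = variant

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)[:, 0]


def build_model(config: ModelConfig) -> Model:
    """The full dual-branch architecture (equivalent to variant ``full``)."""
    return build_variant("full", config)


def build_variant(kind: str, config: ModelConfig) -> Model:
    """Build one of the six architecture variants (``full`` = the model)."""
    if kind not in VARIANTS:
        raise ValueError(f"unknown variant {kind!r}; choose from {VARIANTS}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    front = nn.ChannelEmbedding(config.channels, config.embedding_dim, rng)
    k0, k1 = config.branch_kernels

    if kind == "full":
        branch_a, w_a = _conv_branch(config, k0, rng, recurrent=True)
        branch_b, w_b = _conv_branch(config, k1, rng, recurrent=True)
        trunk = [nn.Parallel([branch_a, branch_b])]
        width = w_a + w_b
    elif kind == "cnn_then_bilstm_series":
        branch, width = _conv_branch(config, k0, rng, recurrent=True)
        trunk = [branch]
    elif kind == "cnn_only":
        branch, width = _conv_branch(config, k0, rng, recurrent=False)
        trunk = [branch]
    elif kind == "cnn_parallel":
        branch_a, w_a = _conv_branch(config, k0, rng, recurrent=False)
        branch_b, w_b = _conv_branch(config, k1, rng, recurrent=False)
        trunk = [nn.Parallel([branch_a, branch_b])]
        width = w_a + w_b
    elif kind == "bilstm_only":
        trunk = [nn.BiLSTM(config.embedding_dim, config.lstm_units, rng)]
        width = 2 * config.lstm_units
    else:  # bilstm_parallel
        branch_a = nn.BiLSTM(config.embedding_dim, config.lstm_units, rng)
        branch_b = nn.BiLSTM(config.embedding_dim, config.lstm_units, rng)
        trunk = [nn.Parallel([branch_a, branch_b])]
        width = 4 * config.lstm_units

    layers = [front, *trunk, *_head(config, width, rng)]
    return Model(config, layers, kind)


@dataclass
class TrainedModel:
    """A fitted classifier: config, weights handle, and training history."""

    config: ModelConfig
    model: Model
    history: list[dict] = field(default_factory=list)

    @property
    def variant(self) -> str:
        return self.model.variant

    def predict_proba(
        self, matrices: np.ndarray | Sequence[EncodingMatrix]
    ) -> np.ndarray:
        """Binding probabilities in [0,1], one per input, order preserved."""
        x = _as_batch(matrices)
        if x.shape[1:] != (self.config.l_max, len(self.config.channels)):
            raise ShapeError(
                f"expected (*, {self.config.l_max}, {len(self.config.channels)}) "
                f"input, got {x.shape}")
        return sigmoid(self.model.logits(x, training=False))


def _as_batch(matrices) -> np.ndarray:
    if isinstance(matrices, np.ndarray):
        x = matrices
    else:
        x = np.stack([m.data if isinstance(m, EncodingMatrix) else np.asarray(m)
                      for m in matrices])
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ShapeError(f"expected a (N, L, C) batch, got shape {x.shape}")
    return np.asarray(x, dtype=float)


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary calls: 1 iff probability is strictly greater than threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    p = np.asarray(probabilities, dtype=float)
    return (p > threshold).astype(int)


def _stratified_validation_split(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class tail split so both classes appear in validation."""
    val_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        cls_idx = rng.permutation(cls_idx)
        n_val = max(1, int(round(fraction * cls_idx.size)))
        val_idx.extend(cls_idx[:n_val])
    val = np.sort(np.asarray(val_idx, dtype=int))
    mask = np.ones(y.size, dtype=bool)
    mask[val] = False
    return np.flatnonzero(mask), val


def train(model: Model, dataset: LabeledDataset,
          config: ModelConfig | None = None) -> TrainedModel:
    """Fit the classifier by minimising binary cross-entropy with Adam.

    Holds out a stratified ``validation_fraction`` of the data to drive
    early stopping (patience in epochs, best weights restored); set
    ``validation_fraction=0`` to train on everything for exactly ``epochs``
    epochs.  Fully deterministic under ``config.seed``.
    """
    config = config or model.config
    x = encode_batch(dataset.records, config.channels, config.l_max,
                     config.pad_value)
    y = dataset.labels.astype(float)
    if len(np.unique(dataset.labels)) < 2:
        raise TrainingError("training requires samples of both classes")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    model.set_rng(rng)
    use_val = config.validation_fraction > 0 and min(
        (y == 0).sum(), (y == 1).sum()) >= 2
    if use_val:
        train_idx, val_idx = _stratified_validation_split(
            dataset.labels, config.validation_fraction, rng)
        x_val, y_val = x[val_idx], y[val_idx]
        x_tr, y_tr = x[train_idx], y[train_idx]
    else:
        x_tr, y_tr = x, y

    optimizer = nn.Adam(model, lr=config.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            optimizer.zero_grad()
            logits = model.logits(x_tr[batch], training=True)
            loss, dlogits = nn.bce_with_logits(logits, y_tr[batch])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch + 1}")
            model.backward(dlogits[:, None])
            optimizer.step()
            epoch_loss += loss * len(batch)
        record = {"epoch": epoch + 1, "train_loss": epoch_loss / len(order)}
        if use_val:
            val_logits = model.logits(x_val, training=False)
            val_loss, _ = nn.bce_with_logits(val_logits, y_val)
            record["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = [a.copy() for a in model.state_arrays()]
                stale = 0
            else:
                stale += 1
        history.append(record)
        if use_val and stale >= config.patience:
            break

    if use_val and best_state is not None:
        model.load_state_arrays(best_state)
    return TrainedModel(config=config, model=model, history=history)


def fit(dataset: LabeledDataset, config: ModelConfig | None = None,
        variant: str = "full") -> TrainedModel:
    """Convenience: build the (variant) architecture and train it."""
    config = config or ModelConfig()
    return train(build_variant(variant, config), dataset, config)


# ---------------------------------------------------------------------------
# checkpoints

def save_model(trained: TrainedModel, directory: str | Path) -> Path:
    """Save config (JSON), weights (npz) and history (JSON) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "variant": trained.variant,
        "config": asdict(trained.config),
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    (directory / "history.json").write_text(json.dumps(trained.history, indent=2))
    np.savez(directory / "weights.npz",
             *[np.asarray(a) for a in trained.model.state_arrays()])
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    """Rebuild the architecture from config.json and restore the weights."""
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    config = ModelConfig(**meta["config"])
    model = build_variant(meta["variant"], config)
    with np.load(directory / "weights.npz") as data:
        arrays = [data[k] for k in sorted(data.files,
                                          key=lambda s: int(s.split("_")[1]))]
    model.load_state_arrays(arrays)
    history_path = directory / "history.json"
    history = json.loads(history_path.read_text()) if history_path.exists() else []
    return TrainedModel(config=config, model=model, history=history)
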