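"""The SFCN backbone, its heads, parameter accounting, and training regimes.

The Simple Fully Convolutional Network stacks repeated blocks of
(3x3x3 convolution, batch normalization, ReLU, 2x max pooling), then an
appended block of (1x1x1 convolution, batch normalization, global average
pooling).  The pooled channel means form the feature vector (length equal
to the last filter count; 64 in the reference configuration), which feeds
a dropout layer and a fully connected head with one output (chronological
age regression) or two outputs (binary classification logits).

Training uses plain stochastic gradient descent with L2 weight decay and a
step learning-rate schedule; "early stopping" is best-epoch checkpoint
selection on the validation metric (AUC for classification, MAE for
regression) over the full epoch budget.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ShapeError, UsageError, ValidationError
from .nn import (
    BatchNorm3d,
    Conv3d,
    Dropout,
    GlobalAvgPool,
    Linear,
    MaxPool3d,
    ReLU,
    mae,
    softmax_cross_entropy,
)

REFERENCE_FILTERS = (32, 64, 128, 256, 256, 64)
DESK_FILTERS = (8, 16, 16, 8)

HEAD_CLASSIFICATION = "classification_2"
HEAD_REGRESSION = "regression_1"


@dataclass
class SFCNConfig:
    """Architecture of the SFCN.

    ``filters`` lists channel counts; the last entry is the appended 1x1x1
    block, all earlier entries are repeated conv/BN/ReLU/max-pool blocks.
    """

    filters: tuple[int, ...] = REFERENCE_FILTERS
    input_shape: tuple[int, int, int] = (167, 212, 160)
    head: str = HEAD_CLASSIFICATION
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        self.filters = tuple(int(f) for f in self.filters)
        self.input_shape = tuple(int(s) for s in self.input_shape)
        if len(self.filters) < 2:
            raise ConfigurationError("filters: need at least 2 entries")
        if any(f <= 0 for f in self.filters):
            raise ConfigurationError(f"filters: all must be positive, got {self.filters}")
        if self.head not in (HEAD_CLASSIFICATION, HEAD_REGRESSION):
            raise ConfigurationError(f"head: unknown head type {self.head!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate: must be in [0, 1), got {self.dropout_rate}")

    @property
    def n_repeated_blocks(self) -> int:
        return len(self.filters) - 1

    @property
    def feature_length(self) -> int:
        return self.filters[-1]

    @property
    def head_width(self) -> int:
        return 2 if self.head == HEAD_CLASSIFICATION else 1

    def feature_map_shape(self, input_shape: tuple[int, int, int] | None = None
                          ) -> tuple[int, int, int]:
        """Spatial shape entering the appended block, by shape inference.

        Each repeated block halves every axis by floor division; raises if
        any axis collapses below one voxel.
        """
        shape = tuple(input_shape or self.input_shape)
        for i in range(self.n_repeated_blocks):
            shape = tuple(s // 2 for s in shape)
            if min(shape) < 1:
                raise ShapeError(
                    f"input {tuple(input_shape or self.input_shape)} too small: "
                    f"axis collapsed to {shape} after pooling stage {i + 1}")
        return shape


@dataclass
class TrainConfig:
    """SGD hyperparameters mirroring the fixed set used for every model."""

    weight_decay: float = 1e-4
    initial_lr: float = 0.1
    lr_decay_every: int = 30
    lr_decay_factor: float = 0.1
    batch_size: int = 6
    epochs: int = 150
    update_bn_stats: bool = True   # False: keep (calibrated) running statistics
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_decay < 0 or self.initial_lr <= 0:
            raise ConfigurationError("rates must be positive")
        if self.epochs < 1:
            raise ConfigurationError(f"epochs: must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size: must be >= 1")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for a 0-based epoch index (step decay)."""
    return cfg.initial_lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


@dataclass
class FeatureVector:
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32).reshape(-1)


class SFCN:
    """A built SFCN with explicit forward/backward over its layer list."""

    def __init__(self, config: SFCNConfig, seed: int = 0) -> None:
        config.feature_map_shape()  # validate input size up front
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5FC2]))
        self.backbone: list = []
        c_in = 1
        for i, c_out in enumerate(config.filters[:-1]):
            self.backbone += [
                Conv3d(c_in, c_out, kernel=3, rng=rng, name=f"block{i + 1}.conv"),
                BatchNorm3d(c_out, name=f"block{i + 1}.bn"),
                ReLU(),
                MaxPool3d(),
            ]
            c_in = c_out
        last = config.filters[-1]
        self.backbone += [
            Conv3d(c_in, last, kernel=1, pad=0, rng=rng, name="appended.conv"),
            BatchNorm3d(last, name="appended.bn"),
            GlobalAvgPool(),
        ]
        self.backbone[0].compute_dx = False  # gradient w.r.t. the image is unused
        self.dropout = Dropout(config.dropout_rate, rng=np.random.default_rng(
            np.random.SeedSequence([seed, 0xD209])))
        self.head = Linear(last, config.head_width, rng=rng, name="head")

    # -- inference ---------------------------------------------------------
    @property
    def head_type(self) -> str:
        return self.config.head

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Global-average-pooled channel means, shape (N, feature_length)."""
        h = np.asarray(x, dtype=np.float32)
        if h.ndim == 4:
            h = h[:, None]
        for layer in self.backbone:
            h = layer.forward(h, train=train)
        return h

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.features(x, train=train)
        h = self.dropout.forward(h, train=train)
        return self.head.forward(h, train=train)

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Evaluation-mode outputs: age (N,) or class-1 logit margin (N,)."""
        outs = []
        x = np.asarray(x, dtype=np.float32)
        for i in range(0, len(x), batch_size):
            out = self.forward(x[i:i + batch_size], train=False)
            if self.config.head == HEAD_REGRESSION:
                outs.append(out[:, 0])
            else:
                outs.append(out[:, 1] - out[:, 0])
        return np.concatenate(outs) if outs else np.empty(0, dtype=np.float32)

    # -- training plumbing -------------------------------------------------
    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(dout)
        d = self.dropout.backward(d)
        for layer in reversed(self.backbone):
            d = layer.backward(d)

    def parameters(self) -> list:
        params = []
        for layer in self.backbone:
            params.extend(layer.parameters())
        params.extend(self.head.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def get_state(self) -> dict:
        state = {"params": [p.value.copy() for p in self.parameters()],
                 "bn": [l.state() for l in self.backbone if isinstance(l, BatchNorm3d)]}
        return state

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.parameters(), state["params"]):
            p.value = v.copy()
        bns = [l for l in self.backbone if isinstance(l, BatchNorm3d)]
        for layer, s in zip(bns, state["bn"]):
            layer.load_state(s)

    def copy(self) -> "SFCN":
        return copy.deepcopy(self)

    def replace_head(self, head_type: str, rng: np.random.Generator | None = None) -> None:
        """Swap the fully connected head (e.g. regression -> 2-class)."""
        cfg = copy.deepcopy(self.config)
        cfg.head = head_type
        self.config = cfg
        self.head = Linear(cfg.feature_length, cfg.head_width,
                           rng=rng or np.random.default_rng(0), name="head")


def build_sfcn(config: SFCNConfig, seed: int = 0) -> SFCN:
    return SFCN(config, seed=seed)


def count_trainable_parameters(model) -> int:
    """Trainable scalars: conv/FC weights and biases plus batch-norm affine
    scale and shift.  Batch-norm running statistics are excluded."""
    if hasattr(model, "parameters"):
        return int(sum(p.size for p in model.parameters()))
    # sklearn-style linear models: weights + intercept
    return int(np.asarray(model.coef_).size + np.asarray(model.intercept_).size)


def extract_features(model: SFCN, volume: np.ndarray,
                     subject_id: str = "") -> FeatureVector:
    """64-D (at reference width) feature vector for one preprocessed volume."""
    v = np.asarray(volume, dtype=np.float32)
    if v.ndim == 3:
        v = v[None]
    feats = model.features(v, train=False)
    return FeatureVector(values=feats[0], subject_id=subject_id)


def calibrate_batchnorm(model: SFCN, x: np.ndarray, batch_size: int = 8) -> SFCN:
    """Re-estimate batch-norm running statistics on a new domain.

    Runs forward passes in training mode (no weight updates) with each
    batch weighted equally, so the running mean/variance converge to the
    statistics of ``x``.  Used when a pretrained backbone is transferred to
    data whose intensity statistics differ from the pretraining cohort;
    without it, statistics drift during low-learning-rate finetuning can
    outpace weight adaptation.
    """
    bns = [l for l in model.backbone if isinstance(l, BatchNorm3d)]
    saved = [l.momentum for l in bns]
    x = np.asarray(x, dtype=np.float32)
    n_batches = max(1, int(np.ceil(len(x) / batch_size)))
    for i in range(n_batches):
        for l in bns:
            l.momentum = 1.0 / (i + 1)  # cumulative average over batches
        model.features(x[i * batch_size:(i + 1) * batch_size], train=True)
    for l, m in zip(bns, saved):
        l.momentum = m
    return model


def _validation_metric(model: SFCN, x_val, y_val, batch_size: int) -> float:
    from .stats import auc  # local import to avoid a cycle at import time

    pred = model.predict(x_val, batch_size=batch_size)
    if model.config.head == HEAD_CLASSIFICATION:
        return auc(pred, y_val)
    return float(np.abs(pred - np.asarray(y_val)).mean())


def train_model(model: SFCN, x_train, y_train, x_val, y_val,
                cfg: TrainConfig) -> tuple[SFCN, pd.DataFrame]:
    """SGD training with best-epoch checkpoint selection.

    Classification heads minimize cross-entropy and select the epoch with the
    highest validation AUC; regression heads minimize MAE and select the
    lowest validation MAE.  Ties resolve to the earliest epoch.  Returns the
    model restored to the selected checkpoint and a per-epoch metric trace.
    """
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    classification = model.config.head == HEAD_CLASSIFICATION
    if classification:
        y_train = np.asarray(y_train, dtype=np.int64)
        y_val = np.asarray(y_val, dtype=np.int64)
        if len(np.unique(y_train)) < 2:
            raise ValidationError("classification training set has a single class")
    else:
        y_train = np.asarray(y_train, dtype=np.float32)
        y_val = np.asarray(y_val, dtype=np.float32)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValidationError("training and validation sets must be nonempty")

    if not classification and not np.any(model.head.bias.value):
        # a freshly initialized regression head starts at the training-mean
        # target so the L1 loss optimizes deviations, not the global offset
        model.head.bias.value[:] = float(y_train.mean())

    ss = np.random.SeedSequence([cfg.seed, 0x7124])
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    model.dropout.reseed(ss.spawn(1)[0])

    bns = [l for l in model.backbone if isinstance(l, BatchNorm3d)]
    saved_momenta = [l.momentum for l in bns]
    if not cfg.update_bn_stats:
        for l in bns:
            l.momentum = 0.0  # running statistics stay at their current values

    params = model.parameters()
    best_state, best_metric, best_epoch = None, None, -1
    rows = []
    n = len(x_train)
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            out = model.forward(x_train[idx], train=True)
            if classification:
                loss, dout = softmax_cross_entropy(out, y_train[idx])
            else:
                loss, dout = mae(out, y_train[idx])
            model.backward(dout)
            for p in params:
                p.value -= lr * (p.grad + cfg.weight_decay * p.value)
            epoch_loss += loss * len(idx)
        metric = _validation_metric(model, x_val, y_val, cfg.batch_size)
        rows.append({"epoch": epoch, "lr": lr, "train_loss": epoch_loss / n,
                     "val_metric": metric})
        better = (best_metric is None
                  or (classification and metric > best_metric)
                  or (not classification and metric < best_metric))
        if better:
            best_state, best_metric, best_epoch = model.get_state(), metric, epoch
    model.set_state(best_state)
    for l, m in zip(bns, saved_momenta):
        l.momentum = m
    trace = pd.DataFrame(rows)
    trace.attrs["best_epoch"] = best_epoch
    trace.attrs["best_metric"] = best_metric
    return model, trace


def pretrain_brainage(model_cfg: SFCNConfig, records, volumes,
                      train_cfg: TrainConfig, val_fraction: float = 0.2
                      ) -> tuple[SFCN, pd.DataFrame]:
    """Train an SFCN-regression model to predict chronological age.

    This stage stands in for a large published brain-age model: it is trained
    on a synthetic healthy cohort and then plays the pretrained-model role in
    every downstream brain-age approach.  ``records`` must be CN-only
    (a warning is raised otherwise); an internal 80:20 train/validation split
    selects the best-MAE epoch.
    """
    records = list(records)
    if any(getattr(r, "group", "CN") != "CN" for r in records):
        warnings.warn("pretraining cohort contains non-CN subjects; "
                      "brain-age pretraining expects healthy participants only")
    if model_cfg.head != HEAD_REGRESSION:
        raise UsageError("brain-age pretraining requires a regression head")
    ids = [r.subject_id for r in records]
    ages = np.array([r.age for r in records], dtype=np.float32)
    x = np.stack([np.asarray(volumes[i], dtype=np.float32) for i in ids])
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0xA6E]))
    order = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    model = build_sfcn(model_cfg, seed=train_cfg.seed)
    return train_model(model, x[train_idx], ages[train_idx],
                       x[val_idx], ages[val_idx], train_cfg)
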