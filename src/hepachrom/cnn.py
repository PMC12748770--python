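"""Convolutional concentration regressor.

Architecture (channels-last, same padding, stride-1 convolutions):

    Input (S, S, 3)
    Conv 32 x 3x3 + ReLU -> MaxPool 2x2
    Conv 64 x 3x3 + ReLU -> MaxPool 2x2
    Conv 128 x 3x3 + ReLU -> MaxPool 2x2
    Conv 128 x 3x3 + ReLU -> MaxPool 2x2
    Flatten -> Dense 512 + ReLU -> Dense 1 (linear)

At the default S = 128 the spatial trace is 128 -> 64 -> 32 -> 16 -> 8, so
the flattened feature length is 8*8*128 = 8192. Training uses Adam
(lr 0.001) on mean squared error in native assay units; the returned
regressor carries the weights from the epoch with the lowest validation
loss. Predicted concentrations are clipped at 0 (physical concentrations
cannot be negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import CategoryScheme, assign_category
from .nn import Adam, Conv2D, Dense, Flatten, MaxPool2D, ReLU, Sequential, mse_loss
from .phantom import PhantomImage, labels_of, stack_pixels

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedRegressor",
    "build_model",
    "train",
    "predict",
    "predict_category",
    "save_regressor",
    "load_regressor",
]

CONV_FILTERS = (32, 64, 128, 128)


@dataclass(frozen=True)
class ModelConfig:
    """Network shape. Only the input size is meant to vary (reduced-scale
    runs may use 64x64 or 32x32 inputs); the conv stack is fixed."""

    input_size: int = 128
    conv_filters: Tuple[int, ...] = CONV_FILTERS
    kernel: int = 3
    dense_units: int = 512

    def __post_init__(self) -> None:
        if self.conv_filters != CONV_FILTERS:
            raise ValueError(f"conv_filters must be {CONV_FILTERS}")
        if self.input_size % 2 ** len(self.conv_filters) != 0:
            raise ValueError(
                f"input_size must be divisible by {2 ** len(self.conv_filters)}"
            )

    @property
    def spatial_trace(self) -> Tuple[int, ...]:
        trace = [self.input_size]
        for _ in self.conv_filters:
            trace.append(trace[-1] // 2)
        return tuple(trace)

    @property
    def flatten_length(self) -> int:
        s = self.spatial_trace[-1]
        return s * s * self.conv_filters[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam, MSE, best-validation checkpointing)."""

    learning_rate: float = 1e-3
    max_epochs: int = 40
    batch_size: int = 32
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 1 <= self.max_epochs <= 100:
            raise ValueError("max_epochs must be in [1, 100]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class TrainedRegressor:
    """A trained network plus its provenance."""

    model: Sequential
    config: ModelConfig
    train_config: TrainConfig
    history: pd.DataFrame
    assay: str
    checkpoint_epoch: int

    def predict(self, images) -> np.ndarray:
        return predict(self, images)


def build_model(config: ModelConfig, seed: int = 0) -> Sequential:
    """Assemble the untrained network with seeded He-normal init."""
    rng = np.random.default_rng(seed)
    layers: List = []
    c_in = 3
    for c_out in config.conv_filters:
        layers.append(Conv2D(c_in, c_out, k=config.kernel, rng=rng))
        layers.append(ReLU())
        layers.append(MaxPool2D())
        c_in = c_out
    layers.append(Flatten())
    layers.append(Dense(config.flatten_length, config.dense_units, rng=rng))
    layers.append(ReLU())
    layers.append(Dense(config.dense_units, 1, rng=rng))
    return Sequential(layers)


def _as_arrays(images) -> Tuple[np.ndarray, np.ndarray | None]:
    if isinstance(images, np.ndarray):
        return images.astype(np.float64, copy=False), None
    imgs = list(images)
    if imgs and isinstance(imgs[0], PhantomImage):
        return stack_pixels(imgs), labels_of(imgs)
    return np.asarray(imgs, dtype=np.float64), None


def train(
    train_set: Sequence[PhantomImage],
    cfg: TrainConfig,
    model_config: ModelConfig | None = None,
    validation_set: Sequence[PhantomImage] | None = None,
) -> TrainedRegressor:
    """Train the regressor; returns the best-validation-epoch weights.

    If no explicit validation set is given, ``validation_fraction`` of the
    training images is carved off by the config seed (the held-out test set
    is never touched during training).
    """
    imgs = list(train_set)
    if not imgs:
        raise ValueError("training set is empty")
    assay = imgs[0].assay
    y_all = labels_of(imgs)
    if not np.all(np.isfinite(y_all)):
        raise ValueError("non-finite concentration labels")

    rng = np.random.default_rng(cfg.seed)
    if validation_set is None:
        perm = rng.permutation(len(imgs))
        n_val = max(1, int(round(cfg.validation_fraction * len(imgs))))
        if n_val >= len(imgs):
            raise ValueError("validation carve-out leaves no training images")
        val_imgs = [imgs[i] for i in perm[:n_val]]
        tr_imgs = [imgs[i] for i in perm[n_val:]]
    else:
        val_imgs = list(validation_set)
        if not val_imgs:
            raise ValueError("validation set is empty")
        tr_imgs = imgs

    x_tr, y_tr = stack_pixels(tr_imgs), labels_of(tr_imgs)
    x_val, y_val = stack_pixels(val_imgs), labels_of(val_imgs)

    size = x_tr.shape[1]
    if model_config is None:
        model_config = ModelConfig(input_size=size)
    if model_config.input_size != size:
        raise ValueError(
            f"images are {size}x{size} but model expects "
            f"{model_config.input_size}x{model_config.input_size}"
        )

    model = build_model(model_config, seed=cfg.seed)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)

    best_val = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    rows = []
    n = len(tr_imgs)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model.forward(x_tr[idx])
            loss, grad = mse_loss(pred, y_tr[idx])
            model.backward(grad)
            optimizer.step(model.grads())
            losses.append(loss)
        val_pred = _forward_batched(model, x_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch

    model.set_weights(best_weights)
    return TrainedRegressor(
        model=model,
        config=model_config,
        train_config=cfg,
        history=pd.DataFrame(rows),
        assay=assay,
        checkpoint_epoch=best_epoch,
    )


def _forward_batched(model: Sequential, x: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [model.forward(x[i : i + batch]).reshape(-1) for i in range(0, len(x), batch)]
    return np.concatenate(outs) if outs else np.empty(0)


def predict(regressor: TrainedRegressor, images) -> np.ndarray:
    """Predicted concentrations, one per image, clipped at 0."""
    x, _ = _as_arrays(images)
    single = x.ndim == 3
    if single:
        x = x[None]
    s = regressor.config.input_size
    if x.shape[1:] != (s, s, 3):
        raise ValueError(f"expected images of shape ({s}, {s}, 3), got {x.shape[1:]}")
    out = np.clip(_forward_batched(regressor.model, x), 0.0, None)
    return out[0] if single else out


def predict_category(
    regressor: TrainedRegressor, image, scheme: CategoryScheme
) -> str:
    """Clinical category of a single image's predicted concentration."""
    c = float(predict(regressor, image))
    return assign_category(c, scheme)


def save_regressor(regressor: TrainedRegressor, out_dir: str | Path) -> Path:
    """Persist weights (.npz), history (CSV) and JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": w for i, w in enumerate(regressor.model.get_weights())}
    np.savez(out / "weights.npz", **weights)
    regressor.history.to_csv(out / "history.csv", index=False)
    meta = {
        "assay": regressor.assay,
        "input_size": regressor.config.input_size,
        "checkpoint_epoch": regressor.checkpoint_epoch,
        "train_config": {
            "learning_rate": regressor.train_config.learning_rate,
            "max_epochs": regressor.train_config.max_epochs,
            "batch_size": regressor.train_config.batch_size,
            "seed": regressor.train_config.seed,
            "validation_fraction": regressor.train_config.validation_fraction,
        },
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    return out


def load_regressor(model_dir: str | Path) -> TrainedRegressor:
    root = Path(model_dir)
    meta = json.loads((root / "metadata.json").read_text())
    config = ModelConfig(input_size=int(meta["input_size"]))
    tcfg = TrainConfig(**meta["train_config"])
    model = build_model(config, seed=tcfg.seed)
    with np.load(root / "weights.npz") as data:
        model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    history = pd.read_csv(root / "history.csv")
    return TrainedRegressor(
        model=model,
        config=config,
        train_config=tcfg,
        history=history,
        assay=str(meta["assay"]),
        checkpoint_epoch=int(meta["checkpoint_epoch"]),
    )
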