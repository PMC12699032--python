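"""Compact convolutional regression harness: normalized ultrasound samples
-> 4 joint activations.

The backbone is a small strided CNN (pluggable) whose features flatten to a
1024-dimensional vector, preserving the regression head shape used at full
scale (1024 -> 100 -> 4).  Training uses AdamW with an RMSE loss and a
learning-rate schedule that ramps up over the first two epochs and then
decays linearly to 1% of the peak by the final epoch.  A held-out 10% of the
training frames serves as the validation set for best-epoch selection.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .nn import AdamW, Conv2d, Dense, Flatten, ReLU, Sequential, rmse_loss

#: Channel widths of the default tiny backbone (stride-2 3x3 convs, 128 -> 4).
TINY_CNN_WIDTHS = (16, 32, 64, 64, 64)

WARMUP_START_FACTOR = 0.01  # lr ramps from this fraction of peak ("from 0")


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    backbone: str = "tiny_cnn"
    head_hidden: int = 100
    n_outputs: int = 4
    lr: float = 1e-4              # 3e-5 is the multi-source counterpart at full scale
    weight_decay: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.99)
    epochs: int = 10              # desk scale; 50 at full scale
    warmup_epochs: int = 2
    lr_floor_factor: float = 0.01
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < self.warmup_epochs:
            raise ValueError("epochs must be >= warmup_epochs")
        if self.n_outputs != 4:
            raise ValueError("the regression head emits 4 activations")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def hash(self) -> str:
        h = hashlib.sha256()
        for seq in (self.train_loss, self.val_loss, self.lr):
            h.update(np.asarray(seq, dtype=np.float64).tobytes())
        return h.hexdigest()


def lr_schedule(epoch: int, config: ModelConfig) -> float:
    """Learning rate used during 1-based ``epoch``.

    Geometric ramp from ``WARMUP_START_FACTOR * lr`` to the peak ``lr`` at
    the end of the warmup (epoch ``warmup_epochs``), then linear decay to
    ``lr_floor_factor * lr`` at the final epoch.  Both endpoints are exact.
    """
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch must be in [1, {config.epochs}]")
    if epoch <= config.warmup_epochs:
        frac = epoch / config.warmup_epochs
        return config.lr * WARMUP_START_FACTOR ** (1.0 - frac)
    span = config.epochs - config.warmup_epochs
    p = (epoch - config.warmup_epochs) / span
    return config.lr * (1.0 - (1.0 - config.lr_floor_factor) * p)


def build_model(config: ModelConfig) -> Sequential:
    """Deterministically initialized model accepting [C x 128 x 128] input."""
    rng = np.random.default_rng(config.seed)
    if config.backbone != "tiny_cnn":
        raise ValueError(f"unknown backbone {config.backbone!r}")
    layers: list = []
    c_in = config.in_channels
    for width in TINY_CNN_WIDTHS:
        layers += [Conv2d(c_in, width, kernel=3, stride=2, pad=1, rng=rng), ReLU()]
        c_in = width
    layers.append(Flatten())
    feat = TINY_CNN_WIDTHS[-1] * 4 * 4  # 128 / 2^5 = 4 -> 1024-dim feature
    layers += [Dense(feat, config.head_hidden, rng=rng), ReLU(),
               Dense(config.head_hidden, config.n_outputs, rng=rng)]
    model = Sequential(layers)
    model.in_channels = config.in_channels
    return model


def save_model(model: Sequential, config: ModelConfig, path) -> None:
    """Persist weights + config as a compressed npz checkpoint."""
    import dataclasses
    import json

    payload = {f"param_{i}": p for i, p in enumerate(model.params)}
    payload["config_json"] = np.frombuffer(
        json.dumps(dataclasses.asdict(config)).encode(), dtype=np.uint8)
    np.savez_compressed(path, **payload)


def load_model(path) -> tuple[Sequential, ModelConfig]:
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"].tobytes()).decode())
        for key in ("betas",):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        model = build_model(config)
        state = [data[f"param_{i}"] for i in range(len(model.params))]
    model.load_state(state)
    return model, config


def _check_input(model: Sequential, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    expected = getattr(model, "in_channels", x.shape[1])
    if x.ndim != 4 or x.shape[1] != expected:
        raise ValueError(
            f"samples must be [N x {expected} x H x W], got {x.shape}"
        )
    return x


def predict(model: Sequential, samples: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Activation matrix [N x 4]; batch-order independent."""
    x = _check_input(model, samples)
    outs = [model.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    out = np.concatenate(outs, axis=0)
    if not np.isfinite(out).all():
        raise FloatingPointError("non-finite predictions")
    return out


def train(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator | None = None,
    augment_fn=None,
) -> tuple[Sequential, TrainHistory]:
    """Train in place; returns the model restored to its best epoch + history.

    ``augment_fn(batch, rng, idx) -> batch`` optionally perturbs training
    batches only (``idx`` gives each batch row's index into ``x``, e.g. to
    redraw per-sample reference channels); validation and prediction paths
    never augment.  The validation set is the last ``val_fraction`` of a
    seeded shuffle of the training frames.
    """
    x = _check_input(model, x)
    y = np.asarray(y, dtype=np.float32)
    if len(x) == 0:
        raise ValueError("empty training set")
    if y.shape != (len(x), config.n_outputs):
        raise ValueError(f"targets must be [N x {config.n_outputs}]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    perm = rng.permutation(len(x))
    n_val = max(int(round(config.val_fraction * len(x))), 1) if len(x) > 4 else 0
    val_idx, tr_idx = perm[len(perm) - n_val:], perm[:len(perm) - n_val]
    if len(tr_idx) == 0:
        raise ValueError("empty training split after validation carve-out")

    opt = AdamW(model.params, lr=config.lr, betas=config.betas,
                weight_decay=config.weight_decay)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state()
    for epoch in range(1, config.epochs + 1):
        opt.lr = lr_schedule(epoch, config)
        order = rng.permutation(tr_idx)
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x[idx], y[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng, idx)
            pred = model.forward(xb, train=True)
            loss, dpred = rmse_loss(pred, yb)
            model.backward(dpred)
            opt.step(model.grads)
            losses.append(loss)
        if n_val:
            val_pred = predict(model, x[val_idx])
            val_loss, _ = rmse_loss(val_pred, y[val_idx])
        else:
            val_loss = float(np.mean(losses))
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(val_loss))
        history.lr.append(opt.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            history.best_epoch = epoch
    model.load_state(best_state)
    return model, history
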