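"""Training loop for the input-artery segmentation network.

Optimization follows the recipe used for the clinical model: RMSprop, a
reduce-on-plateau learning-rate schedule (patience 10 epochs, decay factor
0.5) monitoring the validation loss, and early stopping with a patience of
50 epochs up to a maximum of 1000.  The clinical initial learning rate of
1e-6 suits long runs on large images; short desk-scale smoke runs on small
phantoms use a larger rate.  All randomness (shuffling, augmentation) is
driven by a single seeded generator, so training is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import augment
from .metrics import combined_loss, combined_loss_grad_wrt_logits, evaluate
from .unet import UNet, UNetConfig, _sigmoid


@dataclass
class TrainConfig:
    learning_rate: float = 1e-6
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    early_stop_patience: int = 50
    max_epochs: int = 1000
    augment_prob: float = 0.5
    translate_frac: float = 0.05
    scale_frac: float = 0.05
    rotate_deg: float = 10.0
    hflip: bool = True
    augment_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.augment_prob <= 1.0):
            raise ValueError("augment_prob must be in [0, 1]")
        if self.plateau_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patience values must be positive")


class RMSProp:
    """Root-mean-square propagation with an adjustable learning rate."""

    def __init__(self, params: list[np.ndarray], lr: float, alpha: float = 0.99,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.cache = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, c in zip(self.params, grads, self.cache):
            c *= self.alpha
            c += (1.0 - self.alpha) * g * g
            p -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(p.dtype)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving.

    An epoch counts as "bad" when the monitored value is not strictly below
    the best seen so far; after ``patience`` consecutive bad epochs the
    optimizer's rate is multiplied by ``factor`` and the counter resets.
    """

    def __init__(self, optimizer: RMSProp, patience: int = 10, factor: float = 0.5) -> None:
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> None:
        if value < self.best:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.epochs.append(dict(kwargs))

    def __len__(self) -> int:
        return len(self.epochs)


def train(
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    val_pairs: list[tuple[np.ndarray, np.ndarray]],
    unet_config: UNetConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[UNet, TrainHistory]:
    """Train a UNet on (MinIP image, binary mask) pairs.

    Returns the model restored to its best-on-validation-loss weights along
    with the per-epoch history (train loss, validation loss, validation
    Dice, learning rate).
    """
    cfg = train_config or TrainConfig()
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must both be nonempty")
    model = UNet(unet_config, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = RMSProp(model.parameters, cfg.learning_rate, cfg.rmsprop_alpha, cfg.rmsprop_eps)
    sched = ReduceLROnPlateau(opt, cfg.plateau_patience, cfg.plateau_factor)
    history = TrainHistory()

    best_val = np.inf
    best_state = model.state_dict()
    best_state = {k: v.copy() for k, v in best_state.items()}
    bad = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_pairs))
        losses = []
        for idx in order:
            img, msk = train_pairs[idx]
            if cfg.augment_enabled:
                img, msk = augment(
                    img, msk, rng, prob=cfg.augment_prob,
                    translate_frac=cfg.translate_frac, scale_frac=cfg.scale_frac,
                    rotate_deg=cfg.rotate_deg, hflip=cfg.hflip,
                )
            logits = model.forward(img)
            p = _sigmoid(logits)
            loss = combined_loss(p, msk)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            model.backward(combined_loss_grad_wrt_logits(p, msk))
            opt.step(model.gradients)

        val_loss, val_dice = _validate(model, val_pairs)
        history.append(
            epoch=epoch, train_loss=float(np.mean(losses)),
            val_loss=val_loss, val_dice=val_dice, lr=opt.lr,
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            bad = 0
        else:
            bad += 1
            if bad >= cfg.early_stop_patience:
                break
        sched.step(val_loss)

    model.load_state_dict(best_state)
    return model, history


def _validate(model: UNet, pairs: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    losses, dices = [], []
    thr = model.config.binarize_threshold
    for img, msk in pairs:
        p = model.predict_proba(img)
        losses.append(combined_loss(p, msk))
        dices.append(evaluate((p >= thr).astype(np.uint8), msk).dice)
    return float(np.mean(losses)), float(np.mean(dices))


def save_model(model: UNet, path) -> None:
    """Persist weights plus architecture config as an .npz checkpoint."""
    cfg = model.config
    np.savez(
        path,
        __in_channels=cfg.in_channels, __base_channels=cfg.base_channels,
        __max_channels=cfg.max_channels, __threshold=cfg.binarize_threshold,
        **model.state_dict(),
    )


def load_model(path) -> UNet:
    data = np.load(path)
    cfg = UNetConfig(
        in_channels=int(data["__in_channels"]),
        base_channels=int(data["__base_channels"]),
        max_channels=int(data["__max_channels"]),
        binarize_threshold=float(data["__threshold"]),
    )
    model = UNet(cfg)
    model.load_state_dict({k: data[k] for k in data.files if not k.startswith("__")})
    return model
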