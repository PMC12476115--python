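"""Training loop: Adam with weight decay, early stopping, checkpoints.

Optimization follows the reference settings (Adam, lr 0.01, weight decay
0.1, batch size 2, up to 150 epochs) with an early-stopping rule on the
epoch-mean training loss: when the improvement is below ``early_stop_delta``
for ``patience`` consecutive epochs, training stops. Weight decay is
applied as an L2 term added to the gradient (classic Adam); gradients are
clipped at global norm 1.0, which guards the fairly aggressive learning
rate on small batches.

All randomness (parameter init, batch shuffling, dropout, RReLU slopes)
derives from the configured seeds, so identical configs give bit-identical
loss histories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import DynamicMap, ModelConfig, SpatioTemporalModel
from .objective import LossConfig, composite_loss

logger = logging.getLogger("dynamap")

__all__ = ["TrainConfig", "Adam", "train", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    lr: float = 0.01
    weight_decay: float = 0.1
    epochs: int = 150
    batch_size: int = 2
    early_stop_delta: float = 1e-5
    patience: int = 10
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


class Adam:
    """Adam over a list of (name, Tensor) parameters, with L2 decay."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for _, p in params]
        self.v = [np.zeros_like(p.data) for _, p in params]

    def step(self):
        self.t += 1
        for i, (_, p) in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, p in self.params:
            p.grad = None


def _clip_gradients(params, max_norm: float) -> float:
    total = 0.0
    for _, p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if max_norm and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for _, p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
        logger.debug("clipped gradients: norm %.3f -> %.3f", norm, max_norm)
    return norm


def train(
    pairs,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    loss_cfg: LossConfig | None = None,
    model: SpatioTemporalModel | None = None,
    n_steps: int | None = None,
) -> tuple[SpatioTemporalModel, list[float]]:
    """Fit the model to (preprocessed volume, aligned prior maps) pairs.

    ``pairs`` is a list of (FmriVolume-or-ndarray, prior ndarray shaped
    (n_networks, h, w, d, t)). Returns the trained model and the per-epoch
    mean loss history. ``n_steps`` caps the total number of update steps
    (useful for overfitting contracts); otherwise training runs for
    ``epochs`` epochs or until early stopping.
    """
    loss_cfg = loss_cfg or LossConfig()
    if not pairs:
        raise ValueError("empty training set")
    data_list, prior_list = [], []
    for vol, prior in pairs:
        arr = vol if isinstance(vol, np.ndarray) else vol.data
        # single precision end to end: the model parameters are float32
        prior_list.append(np.asarray(prior, dtype=np.float32))
        data_list.append(np.asarray(arr, dtype=np.float32))
    shape = data_list[0].shape
    for arr, prior in zip(data_list, prior_list):
        if arr.shape != shape:
            raise ValueError("all training volumes must share a shape")
        if prior.shape != (model_cfg.n_networks,) + shape:
            raise ValueError(
                f"prior shape {prior.shape} incompatible with volume "
                f"{shape} and {model_cfg.n_networks} networks"
            )
    if model is None:
        model = SpatioTemporalModel(model_cfg, shape[:3], shape[3])
    params = model.parameters()
    opt = Adam(params, lr=train_cfg.lr,
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)

    history: list[float] = []
    stall = 0
    best = np.inf
    steps_done = 0
    n = len(data_list)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            opt.zero_grad()
            loss_t = None
            for i in idx:
                pred = model.forward(data_list[i], rng=rng)
                if not np.all(np.isfinite(pred.data)):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: "
                        "non-finite prediction"
                    )
                term = composite_loss(prior_list[i], pred, loss_cfg)
                loss_t = term if loss_t is None else loss_t + term
            loss_t = loss_t * (1.0 / len(idx))
            value = float(loss_t.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={value}"
                )
            loss_t.backward()
            _clip_gradients(params, train_cfg.grad_clip)
            opt.step()
            epoch_losses.append(value)
            steps_done += 1
            if n_steps is not None and steps_done >= n_steps:
                break
        epoch_mean = float(np.mean(epoch_losses))
        history.append(epoch_mean)
        logger.info("epoch %d: loss %.6f", epoch, epoch_mean)
        if n_steps is not None and steps_done >= n_steps:
            break
        # early stopping: the epoch must beat the best loss by more than
        # delta to count as an improvement
        if best - epoch_mean > train_cfg.early_stop_delta:
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                best = min(best, epoch_mean)
                break
        best = min(best, epoch_mean)
    return model, history


def predict(model: SpatioTemporalModel, vol, subject_id: str = ""
            ) -> DynamicMap:
    """Evaluation-mode prediction (dropout off, RReLU at its mean slope)."""
    arr = vol if isinstance(vol, np.ndarray) else vol.data
    expected = model.patch_embed.spatial_shape + (model.patch_embed.t,)
    if arr.shape != expected:
        raise ValueError(
            f"input shape {arr.shape} does not match the checkpointed "
            f"model ({expected})"
        )
    if not subject_id and hasattr(vol, "subject_id"):
        subject_id = vol.subject_id
    return model.predict(arr, subject_id=subject_id)


def save_checkpoint(model: SpatioTemporalModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {name: p.data for name, p in model.parameters()}
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "model_config": model.cfg.to_dict(),
        "spatial_shape": list(model.patch_embed.spatial_shape),
        "n_timepoints": model.patch_embed.t,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path) -> SpatioTemporalModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**meta["model_config"])
    model = SpatioTemporalModel(cfg, tuple(meta["spatial_shape"]),
                                meta["n_timepoints"])
    arrays = np.load(path.with_suffix(".npz"))
    params = dict(model.parameters())
    missing = set(params) ^ set(arrays.files)
    if missing:
        raise ValueError(f"checkpoint/model parameter mismatch: {missing}")
    for name, p in params.items():
        if p.data.shape != arrays[name].shape:
            raise ValueError(f"shape mismatch for {name}")
        p.data = arrays[name].copy()
    return model
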