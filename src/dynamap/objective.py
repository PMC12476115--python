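"""Composite photometric/perceptual training objective.

The loss on one (prior y, prediction y_hat) pair is

    mean(log cosh(y - y_hat)) / max(epsilon, SSIM(y, y_hat))

averaged over the batch. log cosh behaves like squared error for small
residuals and like |r| - log 2 for large ones, so stray voxels cannot
dominate; dividing by the structural-similarity index pushes the optimizer
toward predictions that also match the prior's global structure, with the
max(epsilon, .) clamp keeping the loss positive and finite when SSIM is
near zero or negative. The photometric term is averaged over voxels (not
summed) so the loss scale does not depend on volume resolution.

SSIM is computed with global first/second moments over each sample's whole
tensor by default; a local 3D sliding-window mode is available for
evaluation. Stabilizers C1 = (0.01 R)^2 and C2 = (0.03 R)^2 use the
dynamic range R of the reference (floored at 1 for z-scored maps whose
range is not meaningful on an absolute scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .autodiff import Tensor

__all__ = ["LossConfig", "ssim", "composite_loss"]


@dataclass
class LossConfig:
    epsilon: float = 0.001
    ssim_c1: float | None = None      # None -> (0.01 * range)^2
    ssim_c2: float | None = None      # None -> (0.03 * range)^2
    ssim_window: int | str = "global"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for c in (self.ssim_c1, self.ssim_c2):
            if c is not None and c <= 0:
                raise ValueError("SSIM constants must be positive")
        if self.ssim_window != "global":
            w = int(self.ssim_window)
            if w < 1 or w % 2 == 0:
                raise ValueError("ssim_window must be odd or 'global'")


def _constants(cfg: LossConfig, y_data: np.ndarray,
               h_data: np.ndarray) -> tuple[float, float]:
    # joint dynamic range keeps the index symmetric in its arguments
    rng_ = max(float(np.ptp(y_data)), float(np.ptp(h_data)))
    R = max(rng_, 1.0)
    c1 = cfg.ssim_c1 if cfg.ssim_c1 is not None else (0.01 * R) ** 2
    c2 = cfg.ssim_c2 if cfg.ssim_c2 is not None else (0.03 * R) ** 2
    return c1, c2


def ssim(y, y_hat, cfg: LossConfig | None = None):
    """Structural similarity index in [-1, 1]; symmetric in its arguments.

    Accepts ndarrays (returns a float) or Tensors (returns a differentiable
    Tensor; global mode only).
    """
    cfg = cfg or LossConfig()
    if isinstance(y, Tensor) or isinstance(y_hat, Tensor):
        return _ssim_global_tensor(Tensor.as_tensor(y),
                                   Tensor.as_tensor(y_hat), cfg)
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    c1, c2 = _constants(cfg, y, y_hat)
    if cfg.ssim_window == "global":
        return _ssim_formula(
            y.mean(), y_hat.mean(), y.var(), y_hat.var(),
            ((y - y.mean()) * (y_hat - y_hat.mean())).mean(), c1, c2,
        )
    # local 3D windows averaged over the volume (population moments)
    w = int(cfg.ssim_window)
    if y.ndim != 3:
        raise ValueError("windowed SSIM expects 3D maps")
    mu_y = uniform_filter(y, w)
    mu_h = uniform_filter(y_hat, w)
    var_y = uniform_filter(y * y, w) - mu_y**2
    var_h = uniform_filter(y_hat * y_hat, w) - mu_h**2
    cov = uniform_filter(y * y_hat, w) - mu_y * mu_h
    smap = ((2 * mu_y * mu_h + c1) * (2 * cov + c2)) / (
        (mu_y**2 + mu_h**2 + c1) * (var_y + var_h + c2)
    )
    return float(smap.mean())


def _ssim_formula(mu_y, mu_h, var_y, var_h, cov, c1, c2):
    num = (2 * mu_y * mu_h + c1) * (2 * cov + c2)
    den = (mu_y**2 + mu_h**2 + c1) * (var_y + var_h + c2)
    out = num / den
    return float(out) if np.isscalar(out) or np.ndim(out) == 0 else out


def _ssim_global_tensor(y: Tensor, y_hat: Tensor, cfg: LossConfig) -> Tensor:
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    c1, c2 = _constants(cfg, y.data, y_hat.data)
    mu_y = y.mean()
    mu_h = y_hat.mean()
    yc = y - mu_y
    hc = y_hat - mu_h
    var_y = (yc * yc).mean()
    var_h = (hc * hc).mean()
    cov = (yc * hc).mean()
    num = (2.0 * mu_y * mu_h + c1) * (2.0 * cov + c2)
    den = (mu_y * mu_y + mu_h * mu_h + c1) * (var_y + var_h + c2)
    return num / den


def composite_loss(y, y_hat, cfg: LossConfig | None = None):
    """Batch-mean of log-cosh photometric error over clamped SSIM.

    ``y``/``y_hat`` may be single samples (array or Tensor) or lists of
    samples (a batch). Zero exactly when every y_hat equals its y.
    """
    cfg = cfg or LossConfig()
    ys = y if isinstance(y, (list, tuple)) else [y]
    hs = y_hat if isinstance(y_hat, (list, tuple)) else [y_hat]
    if len(ys) != len(hs):
        raise ValueError("batch size mismatch")
    total = None
    for yi, hi in zip(ys, hs):
        yi = Tensor.as_tensor(yi)
        hi = Tensor.as_tensor(hi)
        if yi.shape != hi.shape:
            raise ValueError(f"shape mismatch {yi.shape} vs {hi.shape}")
        if not (np.all(np.isfinite(yi.data))
                and np.all(np.isfinite(hi.data))):
            raise ValueError("non-finite values in loss inputs")
        photometric = (yi - hi).logcosh().mean()
        s = _ssim_global_tensor(yi, hi, cfg).clamp_min(cfg.epsilon)
        term = photometric / s
        total = term if total is None else total + term
    out = total * (1.0 / len(ys))
    if out.requires_grad:
        return out
    return float(out.data)
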