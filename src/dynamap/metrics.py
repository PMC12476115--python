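"""Evaluation metrics for dynamic brain maps.

Covers the map-quality and dynamicity descriptors used to assess generated
4D maps against their priors: mean absolute relative error (mARE), mean
intersection-over-union of percentile-binarized maps (mIOU), structural
similarity (see :mod:`dynamap.objective`), within-ROI temporal homogeneity
(Hgt), temporal-gradient maps (per-voxel summed absolute forward
differences), Shannon-entropy trends of the per-step gradients, and counts
of suprathreshold connected components ("blobs") per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import generate_binary_structure, label

from .objective import LossConfig, ssim

logger = logging.getLogger("dynamap")

__all__ = [
    "MetricConfig",
    "temporal_gradient",
    "mare",
    "miou",
    "homogeneity",
    "entropy_trend",
    "blob_density",
    "evaluate_maps",
]


@dataclass
class MetricConfig:
    binarize_percentile: float = 80.0
    blob_threshold: float = 0.65
    blob_connectivity: str = "faces"      # or "faces_edges_corners"
    blob_min_size: int = 1
    entropy_bins: int = 256
    epsilon_rel: float = 1e-6

    def __post_init__(self):
        if not (0 < self.binarize_percentile < 100):
            raise ValueError("binarize_percentile must be in (0, 100)")
        if not np.isfinite(self.blob_threshold):
            raise ValueError("blob_threshold must be finite")
        if self.blob_connectivity not in ("faces", "faces_edges_corners"):
            raise ValueError("unknown blob_connectivity")
        if self.entropy_bins < 1:
            raise ValueError("entropy_bins must be positive")


def temporal_gradient(map4d: np.ndarray) -> np.ndarray:
    """Summed absolute forward differences over time, per voxel.

    TG(v) = sum_tau |x(v, tau+1) - x(v, tau)|; input (h, w, d, t), t >= 2.
    """
    map4d = np.asarray(map4d, dtype=np.float64)
    if map4d.ndim != 4 or map4d.shape[3] < 2:
        raise ValueError("need a 4D map with at least 2 time points")
    return np.abs(np.diff(map4d, axis=3)).sum(axis=3)


def mare(y: np.ndarray, y_hat: np.ndarray,
         cfg: MetricConfig | None = None,
         mask: np.ndarray | None = None) -> float:
    """Mean absolute relative error |y - y_hat| / (|y| + eps) over voxels."""
    cfg = cfg or MetricConfig()
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    rel = np.abs(y - y_hat) / (np.abs(y) + cfg.epsilon_rel)
    if mask is not None:
        rel = rel[mask]
    return float(rel.mean())


def _binarize(m: np.ndarray, percentile: float,
              mask: np.ndarray | None) -> np.ndarray:
    vals = m[mask] if mask is not None else m
    thr = np.percentile(vals, percentile)
    out = m > thr
    if mask is not None:
        out &= mask
    return out


def miou(y: np.ndarray, y_hat: np.ndarray,
         cfg: MetricConfig | None = None,
         mask: np.ndarray | None = None) -> float:
    """IOU of the two maps binarized at their own percentile threshold.

    For 4D inputs the IOU is averaged over time points. Two empty
    suprathreshold sets count as IOU 1 (identical maps stay at 1).
    """
    cfg = cfg or MetricConfig()
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    if y.ndim == 4:
        vals = [
            miou(y[..., k], y_hat[..., k], cfg, mask)
            for k in range(y.shape[3])
        ]
        return float(np.mean(vals))
    a = _binarize(y, cfg.binarize_percentile, mask)
    b = _binarize(y_hat, cfg.binarize_percentile, mask)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def homogeneity(map4d: np.ndarray, roi: np.ndarray) -> float:
    """Mean correlation of each ROI voxel's time series with the ROI mean.

    Zero-variance voxels are excluded (logged); a zero-variance ROI-mean
    series yields 0 by convention. Requires >= 2 ROI voxels and t >= 3.
    """
    map4d = np.asarray(map4d, dtype=np.float64)
    roi = np.asarray(roi, dtype=bool)
    if roi.sum() < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    if map4d.shape[3] < 3:
        raise ValueError("need at least 3 time points")
    series = map4d[roi, :]                   # (n_vox, t)
    mean_ts = series.mean(axis=0)
    mean_sd = mean_ts.std()
    if mean_sd == 0:
        return 0.0
    sd = series.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("every ROI voxel has a constant time series")
    if (~keep).any():
        logger.debug("homogeneity: excluded %d zero-variance voxels",
                     int((~keep).sum()))
    series = series[keep]
    sc = series - series.mean(axis=1, keepdims=True)
    mc = mean_ts - mean_ts.mean()
    corr = (sc @ mc) / (np.linalg.norm(sc, axis=1) * np.linalg.norm(mc))
    return float(corr.mean())


def entropy_trend(map4d: np.ndarray, cfg: MetricConfig | None = None,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Shannon entropy (bits) of each consecutive-frame gradient map.

    Each |x(tau+1) - x(tau)| map is histogrammed into ``entropy_bins``
    equal-width bins over its own range; length t - 1. A constant gradient
    map has zero entropy.
    """
    cfg = cfg or MetricConfig()
    map4d = np.asarray(map4d, dtype=np.float64)
    if map4d.ndim != 4 or map4d.shape[3] < 2:
        raise ValueError("need a 4D map with at least 2 time points")
    out = []
    for k in range(map4d.shape[3] - 1):
        g = np.abs(map4d[..., k + 1] - map4d[..., k])
        vals = g[mask] if mask is not None else g.ravel()
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            out.append(0.0)
            continue
        counts, _ = np.histogram(vals, bins=cfg.entropy_bins,
                                 range=(lo, hi))
        p = counts[counts > 0] / counts.sum()
        out.append(float(-(p * np.log2(p)).sum()))
    return np.asarray(out)


def _structure(connectivity: str) -> np.ndarray:
    if connectivity == "faces":
        return generate_binary_structure(3, 1)
    return generate_binary_structure(3, 3)


def blob_density(map4d: np.ndarray, cfg: MetricConfig | None = None
                 ) -> np.ndarray:
    """Per-frame count of suprathreshold 3D connected components.

    Frames are binarized at value >= blob_threshold; components are
    labeled under the configured connectivity and those with at least
    ``blob_min_size`` voxels are counted. Maps should be on a normalized
    scale (z-scored or unit-max) for the default threshold of 0.65 to be
    meaningful.
    """
    cfg = cfg or MetricConfig()
    map4d = np.asarray(map4d, dtype=np.float64)
    if map4d.ndim != 4:
        raise ValueError("need a 4D map")
    structure = _structure(cfg.blob_connectivity)
    counts = []
    for k in range(map4d.shape[3]):
        binary = map4d[..., k] >= cfg.blob_threshold
        labels, n = label(binary, structure=structure)
        if cfg.blob_min_size > 1 and n:
            sizes = np.bincount(labels.ravel())[1:]
            n = int((sizes >= cfg.blob_min_size).sum())
        counts.append(int(n))
    return np.asarray(counts)


def evaluate_maps(priors: np.ndarray, predictions: np.ndarray,
                  cfg: MetricConfig | None = None,
                  loss_cfg: LossConfig | None = None,
                  mask: np.ndarray | None = None,
                  subject_id: str = "") -> pd.DataFrame:
    """Per-network metric table comparing predictions with their priors.

    Inputs are (n_networks, h, w, d, t) stacks. Hgt is computed on the
    prediction within the ROI given by the top-(100 - percentile)% voxels
    of the prior's time average. Returns a tidy DataFrame with one row per
    network and columns mare/miou/ssim/hgt.
    """
    cfg = cfg or MetricConfig()
    loss_cfg = loss_cfg or LossConfig()
    priors = np.asarray(priors, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    if priors.shape != predictions.shape:
        raise ValueError("prior/prediction shape mismatch")
    rows = []
    for k in range(priors.shape[0]):
        y, y_hat = priors[k], predictions[k]
        roi = _binarize(y.mean(axis=3), cfg.binarize_percentile, mask)
        rows.append({
            "subject": subject_id,
            "network": k,
            "mare": mare(y, y_hat, cfg,
                         None if mask is None else
                         np.broadcast_to(mask[..., None], y.shape)),
            "miou": miou(y, y_hat, cfg, mask),
            "ssim": ssim(y, y_hat, loss_cfg),
            "hgt": homogeneity(y_hat, roi),
        })
    return pd.DataFrame(rows)
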