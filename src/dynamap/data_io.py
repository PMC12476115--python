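"""NIfTI input/output and the fMRI preprocessing chain.

Volumes are handled in stored voxel order — (x, y, z, t) as laid out in the
NIfTI file — with no reorientation. Preprocessing follows the pipeline used
throughout the package: uniform temporal subsampling (every ``stride``-th
frame starting at index 0), per-frame Gaussian smoothing, then a single
global z-scoring over all in-mask voxels and time points. Global (rather
than per-voxel) standardization preserves relative spatial amplitude, which
the structural-similarity term of the training loss depends on; a per-voxel
mode is available via ``PreprocessConfig.zscore_mode``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

logger = logging.getLogger("dynamap")


def setup_logging(verbose: bool = False) -> None:
    """Structured logging to stderr; DEBUG when verbose."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers.clear()
    logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def load_config(path=None, overrides=None) -> dict:
    """Read a YAML config with preprocess/model/train/loss/metrics sections.

    ``overrides`` are dotted key=value strings (e.g. "model.patch_size=4")
    mirroring the CLI flags; values are YAML-parsed.
    """
    cfg: dict = {}
    if path is not None:
        cfg = yaml.safe_load(Path(path).read_text()) or {}
    for item in overrides or []:
        key, _, raw = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} is not key=value")
        node = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(raw)
    return cfg

__all__ = [
    "FmriVolume",
    "PreprocessConfig",
    "DataIOError",
    "NonFourDimensionalImageError",
    "GridMismatchError",
    "MissingFileError",
    "PreprocessError",
    "load_volume",
    "save_volume",
    "preprocess",
]


class DataIOError(Exception):
    """Base class for volume I/O errors."""


class MissingFileError(DataIOError):
    """Input path does not exist."""


class NonFourDimensionalImageError(DataIOError):
    """The functional image is not 4D."""


class GridMismatchError(DataIOError):
    """Mask and image do not share a spatial grid."""


class PreprocessError(DataIOError):
    """Preprocessing configuration is incompatible with the data."""


@dataclass
class FmriVolume:
    """A subject's 4D BOLD scan with affine and optional brain mask."""

    data: np.ndarray                       # (h, w, d, t)
    affine: np.ndarray                     # 4x4 voxel-to-world
    mask: np.ndarray | None = None         # boolean (h, w, d)
    subject_id: str = ""
    tr_seconds: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise NonFourDimensionalImageError(
                f"expected 4D data, got {self.data.ndim}D"
            )
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise GridMismatchError(
                    f"mask shape {self.mask.shape} != spatial shape "
                    f"{self.data.shape[:3]}"
                )
        # NaN/Inf policy: zero outside the mask, reject inside
        bad = ~np.isfinite(self.data)
        if bad.any():
            if self.mask is not None:
                outside = bad & ~self.mask[..., None]
                self.data[outside] = 0.0
                bad = ~np.isfinite(self.data)
            if bad.any():
                raise ValueError("non-finite values inside the brain mask")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def mask_or_full(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        return np.ones(self.spatial_shape, dtype=bool)


@dataclass
class PreprocessConfig:
    """Temporal subsampling + smoothing + normalization parameters.

    Defaults are the settings used for the full pipeline: every 10th frame
    retained for 10 frames total, Gaussian kernel of sigma=6 voxels,
    global z-scoring.
    """

    temporal_stride: int = 10
    n_timepoints: int = 10
    gaussian_sigma: float = 6.0
    zscore: bool = True
    zscore_mode: str = "global"        # "global" | "voxel"
    boundary_mode: str = "nearest"

    def __post_init__(self):
        if self.temporal_stride < 1 or self.n_timepoints < 1:
            raise ValueError("temporal_stride and n_timepoints must be >= 1")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be nonnegative")
        if self.zscore_mode not in ("global", "voxel"):
            raise ValueError("zscore_mode must be 'global' or 'voxel'")


def load_volume(path, mask_path=None) -> FmriVolume:
    """Load a 4D NIfTI scan (and optional 3D mask on the same grid)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise NonFourDimensionalImageError(
            f"{path} is {data.ndim}D, expected 4D"
        )
    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        if not mask_path.exists():
            raise MissingFileError(str(mask_path))
        mimg = nib.load(str(mask_path))
        mdata = np.asanyarray(mimg.dataobj)
        if mdata.ndim != 3:
            raise GridMismatchError(f"mask {mask_path} is not 3D")
        if mdata.shape != data.shape[:3]:
            raise GridMismatchError(
                f"mask grid {mdata.shape} != image grid {data.shape[:3]}"
            )
        mask = mdata > 0
    tr = None
    zooms = img.header.get_zooms()
    if len(zooms) >= 4 and zooms[3] > 0:
        tr = float(zooms[3])
    vol = FmriVolume(
        data=data.astype(np.float64),
        affine=np.asarray(img.affine, dtype=np.float64),
        mask=mask,
        subject_id=path.name.split(".")[0],
        tr_seconds=tr,
    )
    logger.debug("loaded %s: shape %s", path, vol.data.shape)
    return vol


def save_volume(vol: FmriVolume, path) -> Path:
    """Write the scan back to NIfTI, preserving data and affine exactly."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    if vol.tr_seconds:
        img.header.set_zooms(img.header.get_zooms()[:3] + (vol.tr_seconds,))
    nib.save(img, str(path))
    return path


def save_map3d(data: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
             str(path))
    return path


def _zscore(data: np.ndarray, mask: np.ndarray, mode: str) -> np.ndarray:
    out = data.copy()
    if mode == "global":
        vals = data[mask, :]
        mu = vals.mean()
        sd = vals.std()
        if sd == 0:
            raise PreprocessError("zero variance inside mask; cannot z-score")
        out[mask, :] = (vals - mu) / sd
    else:  # per-voxel time series
        vals = data[mask, :]
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        out[mask, :] = (vals - mu) / sd
    out[~mask, :] = 0.0
    return out


def preprocess(vol: FmriVolume, cfg: PreprocessConfig) -> FmriVolume:
    """Subsample frames, smooth each retained frame, and z-score.

    Frames are taken at indices 0, s, 2s, ... (0-based); smoothing is per
    3D frame with sigma in voxel units and "nearest" boundary handling.
    """
    t = vol.n_timepoints
    if cfg.temporal_stride * cfg.n_timepoints > t:
        raise PreprocessError(
            f"stride {cfg.temporal_stride} x {cfg.n_timepoints} frames "
            f"exceeds the {t} available time points"
        )
    idx = np.arange(cfg.n_timepoints) * cfg.temporal_stride
    frames = vol.data[..., idx].copy()
    if cfg.gaussian_sigma > 0:
        for k in range(frames.shape[3]):
            frames[..., k] = gaussian_filter(
                frames[..., k], cfg.gaussian_sigma, mode=cfg.boundary_mode
            )
    if cfg.zscore:
        mask = vol.mask_or_full()
        frames = _zscore(frames, mask, cfg.zscore_mode)
    return FmriVolume(
        data=frames,
        affine=vol.affine.copy(),
        mask=None if vol.mask is None else vol.mask.copy(),
        subject_id=vol.subject_id,
        tr_seconds=(
            None if vol.tr_seconds is None
            else vol.tr_seconds * cfg.temporal_stride
        ),
    )
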