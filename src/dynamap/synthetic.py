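"""Phantom 4D fMRI generator with known ground truth.

Each phantom contains a handful of spatially smooth, partially overlapping
"network" sources — isotropic Gaussian blobs whose centers can drift
linearly over the scan — modulated by per-network amplitude waveforms and
buried in AR(1) temporal noise that is white in space. Two-group
populations add either a multiplicative amplitude effect or a zero-mean
temporal-variability effect inside a chosen region, so that downstream
group statistics have an analytically known planted signal.

The blobs deliberately trade realism for checkability: every downstream
contract (ICA recovery, prior alignment, group-level sensitivity) can be
verified against the returned :class:`PhantomTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import FmriVolume, save_map3d

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_subject",
    "generate_population",
    "export_references",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Defaults give three well-separated networks on a 16^3 grid with slowly
    varying sinusoidal amplitudes, mild center drift, and AR(1) noise at
    roughly 20% of signal amplitude — a regime in which spatial ICA with
    reference constraints is clearly identifiable but not trivial.
    """

    shape: tuple[int, int, int] = (16, 16, 16)
    n_timepoints: int = 60
    n_networks: int = 3
    source_centers: list | None = None        # (n_networks, 3) voxel coords
    source_sigma: float = 2.0
    drift_amplitude: float = 1.0
    amplitude_waveforms: np.ndarray | None = None   # (n_networks, t), > 0
    noise_sigma: float = 0.2
    ar_coefficient: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.source_centers is None:
            self.source_centers = _default_centers(self.shape,
                                                   self.n_networks)
        self.source_centers = np.asarray(self.source_centers, dtype=float)
        if self.source_centers.shape != (self.n_networks, 3):
            raise ValueError("need one 3D center per network")
        for c in self.source_centers:
            if np.any(c < 0) or np.any(c >= np.asarray(self.shape)):
                raise ValueError(f"source center {c} outside grid")
        if self.amplitude_waveforms is None:
            self.amplitude_waveforms = _default_waveforms(
                self.n_networks, self.n_timepoints
            )
        self.amplitude_waveforms = np.asarray(self.amplitude_waveforms,
                                              dtype=float)
        if self.amplitude_waveforms.shape != (self.n_networks,
                                              self.n_timepoints):
            raise ValueError("waveforms must be (n_networks, n_timepoints)")
        if np.any(self.amplitude_waveforms <= 0):
            raise ValueError("amplitude waveforms must be positive")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sigma < 0 or self.source_sigma <= 0:
            raise ValueError("invalid sigma")


def _default_centers(shape, n_networks) -> np.ndarray:
    """Spread centers along the main diagonal, well inside the grid."""
    shape = np.asarray(shape, dtype=float)
    fracs = np.linspace(0.25, 0.75, n_networks)
    return np.stack([shape * f for f in fracs])


def _default_waveforms(n_networks, t) -> np.ndarray:
    tau = np.arange(t)
    rows = []
    for k in range(n_networks):
        # distinct frequencies/phases, strictly positive
        rows.append(1.0 + 0.5 * np.sin(2 * np.pi * (k + 1) * tau / t
                                       + 0.7 * k))
    return np.stack(rows)


@dataclass
class PhantomTruth:
    """Ground truth for one phantom subject."""

    source_maps: np.ndarray            # (n_networks, t, h, w, d), >= 0
    mixing: np.ndarray                 # (t, n_networks) amplitudes
    group_effect_region: np.ndarray | None = None

    @property
    def time_avg_maps(self) -> np.ndarray:
        return self.source_maps.mean(axis=1)


def _blob(shape, center, sigma) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    sq = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-sq / (2.0 * sigma**2))


def _ar1_noise(rng, shape, t, sigma, rho) -> np.ndarray:
    """AR(1)-in-time noise, white in space, innovation std sigma."""
    noise = np.zeros(shape + (t,))
    if sigma == 0:
        return noise
    innov = rng.standard_normal(shape + (t,)) * sigma
    # start from stationary distribution so lag-1 autocorrelation == rho
    noise[..., 0] = innov[..., 0] / np.sqrt(1.0 - rho**2)
    for k in range(1, t):
        noise[..., k] = rho * noise[..., k - 1] + innov[..., k]
    return noise


def generate_subject(spec: PhantomSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[FmriVolume, PhantomTruth]:
    """Render one phantom subject and its ground truth.

    data(v, tau) = sum_k waveform[k][tau] * blob(center_k(tau)) + AR(1)
    noise; centers translate linearly by ``drift_amplitude`` voxels over
    the scan. Identical spec (including seed) gives bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w, d = spec.shape
    t = spec.n_timepoints
    m = spec.n_networks
    source_maps = np.zeros((m, t, h, w, d))
    data = np.zeros((h, w, d, t))
    # deterministic drift directions per network (unit vectors)
    dirs = np.stack([
        np.array([np.cos(2.39996 * k), np.sin(2.39996 * k),
                  np.cos(2.39996 * k + 1.0)])
        for k in range(m)
    ])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    for k in range(m):
        for tau in range(t):
            frac = tau / max(t - 1, 1)
            center = spec.source_centers[k] + \
                spec.drift_amplitude * frac * dirs[k]
            center = np.clip(center, 0, np.asarray(spec.shape) - 1)
            smap = _blob(spec.shape, center, spec.source_sigma)
            source_maps[k, tau] = smap
            data[..., tau] += spec.amplitude_waveforms[k, tau] * smap
    data += _ar1_noise(rng, (h, w, d), t, spec.noise_sigma,
                       spec.ar_coefficient)
    vol = FmriVolume(
        data=data,
        affine=np.eye(4),
        mask=None,
        subject_id=f"phantom-{spec.seed}",
    )
    truth = PhantomTruth(
        source_maps=source_maps,
        mixing=spec.amplitude_waveforms.T.copy(),
    )
    return vol, truth


def generate_population(
    spec: PhantomSpec,
    n_per_group: int,
    effect_size: float,
    effect_region: np.ndarray,
    effect_mode: str = "amplitude",
    center_jitter: float = 0.5,
    waveform_jitter: float = 0.1,
) -> list[tuple[FmriVolume, PhantomTruth, int]]:
    """Simulate a two-group cohort with a localized planted effect.

    Group 1 subjects receive, inside ``effect_region``:

    - ``amplitude`` mode: the summed network signal multiplied by
      (1 + effect_size) — an "activity level" difference that shifts the
      time-averaged map;
    - ``variability`` mode: an added alternating-sign modulation of the
      local signal, ``effect_size * signal * cos(pi * tau)``, which leaves
      the time average (for even t) untouched but raises temporal-gradient
      magnitude.

    Every subject gets its own random jitter of source centers and
    waveforms. Returns (volume, truth, group_label) triples, group 0 first.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if effect_mode not in ("amplitude", "variability"):
        raise ValueError("effect_mode must be 'amplitude' or 'variability'")
    effect_region = np.asarray(effect_region, dtype=bool)
    if effect_region.shape != tuple(spec.shape):
        raise ValueError("effect_region must match the phantom grid")
    rng = np.random.default_rng(spec.seed)
    out = []
    for group in (0, 1):
        for _ in range(n_per_group):
            sub_spec = PhantomSpec(
                shape=spec.shape,
                n_timepoints=spec.n_timepoints,
                n_networks=spec.n_networks,
                source_centers=spec.source_centers
                + rng.normal(0, center_jitter, size=(spec.n_networks, 3)),
                source_sigma=spec.source_sigma,
                drift_amplitude=spec.drift_amplitude,
                amplitude_waveforms=spec.amplitude_waveforms
                * (1.0 + np.abs(rng.normal(0, waveform_jitter,
                                           size=(spec.n_networks, 1)))),
                noise_sigma=spec.noise_sigma,
                ar_coefficient=spec.ar_coefficient,
                seed=spec.seed,
            )
            vol, truth = generate_subject(sub_spec, rng=rng)
            if group == 1 and effect_size != 0:
                signal = np.einsum("ktxyz,tk->xyzt", truth.source_maps,
                                   truth.mixing)
                region = effect_region[..., None]
                if effect_mode == "amplitude":
                    vol.data += effect_size * signal * region
                else:
                    tau = np.arange(spec.n_timepoints)
                    osc = np.cos(np.pi * tau)       # +1, -1, +1, ...
                    vol.data += effect_size * signal * osc * region
            truth.group_effect_region = effect_region.copy()
            out.append((vol, truth, group))
    return out


def export_references(truth: PhantomTruth, out_dir=None,
                      affine: np.ndarray | None = None) -> list[np.ndarray]:
    """Time-averaged, z-scored true maps, usable as ICA spatial references.

    When ``out_dir`` is given, each reference is also written as a 3D NIfTI
    plus a JSON sidecar describing the phantom truth.
    """
    refs = []
    for k in range(truth.source_maps.shape[0]):
        ref = truth.time_avg_maps[k]
        ref = (ref - ref.mean()) / ref.std()
        refs.append(ref)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        aff = np.eye(4) if affine is None else affine
        for k, ref in enumerate(refs):
            save_map3d(ref, aff, out_dir / f"reference_{k:02d}.nii.gz")
        sidecar = {
            "n_networks": int(truth.source_maps.shape[0]),
            "n_timepoints": int(truth.source_maps.shape[1]),
            "mixing": truth.mixing.tolist(),
            "group_effect_region": (
                None if truth.group_effect_region is None
                else truth.group_effect_region.astype(int).tolist()
            ),
        }
        (out_dir / "phantom_truth.json").write_text(
            json.dumps(sidecar, indent=1)
        )
    return refs
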