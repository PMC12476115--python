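"""Windowed spatially constrained ICA used as weak supervision.

The data matrix X (time x voxels) is modeled as X = A S with spatially
independent sources S; an unmixing vector w_i per network maximizes the
negentropy surrogate J(w) = (E[G(C)] - E[G(v)])^2 for C = w^T X (G = log
cosh, v standard normal), subject to the estimated source keeping at least
a Pearson correlation ``epsilon`` with a supplied spatial reference map and
unit variance. Estimation runs one component at a time (deflation in
reference order) on data whitened to the leading principal components; the
constraint is enforced by an adaptive blend toward the reference direction
whenever the correlation drops below the threshold.

Run over overlapping temporal windows (size 30, stride 1 by default), the
per-window component maps form the spatiotemporal prior a dense-prediction
model can be trained against when no ground truth exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import FmriVolume

logger = logging.getLogger("dynamap")

__all__ = [
    "IcaProblem",
    "IcaPrior",
    "fit_constrained",
    "run_windowed",
    "align_priors_to_frames",
    "n_windows",
]


@dataclass
class IcaProblem:
    """One windowed constrained-ICA estimation problem.

    X: (t_w, n) data, rows centered over voxels during fitting.
    references: (m, n) spatial maps, each z-scored over voxels.
    """

    X: np.ndarray
    references: np.ndarray
    epsilon_constraint: float = 0.3
    contrast: str = "logcosh"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.references = np.asarray(self.references, dtype=np.float64)
        if self.X.ndim != 2 or self.references.ndim != 2:
            raise ValueError("X and references must be 2D")
        if self.X.shape[1] != self.references.shape[1]:
            raise ValueError("X and references disagree on voxel count")
        if not (0 < self.epsilon_constraint < 1):
            raise ValueError("epsilon_constraint must be in (0, 1)")
        if self.contrast != "logcosh":
            raise ValueError("only the logcosh contrast is implemented")
        # normalize references to zero mean / unit variance over voxels
        mu = self.references.mean(axis=1, keepdims=True)
        sd = self.references.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("reference map with zero variance")
        self.references = (self.references - mu) / sd


@dataclass
class IcaPrior:
    """Constrained components for one temporal window."""

    components: np.ndarray              # (m, n), unit variance rows
    time_courses: np.ndarray            # (t_w, m) mixing columns
    window_index: int
    constraint_correlations: np.ndarray  # (m,), achieved corr with refs
    converged: np.ndarray                # (m,) bool


def _negentropy(c: np.ndarray) -> float:
    # E[G(C)] - E[G(v)] squared, G = log cosh; E[log cosh v] for v~N(0,1)
    EG_GAUSS = 0.3745672
    return float((np.mean(np.log(np.cosh(c))) - EG_GAUSS) ** 2)


def fit_constrained(problem: IcaProblem, max_iter: int = 200,
                    tol: float = 1e-6, seed: int = 0) -> IcaPrior:
    """Estimate all constrained components of one window.

    Fixed-point negentropy ascent (the classic tanh update) in whitened
    space with deflation; after each step the component is blended halfway
    toward the reference's projection whenever its correlation with the
    reference falls below epsilon. Components whose final correlation still
    misses the threshold (or whose fixed point did not settle) are flagged
    ``converged=False`` rather than raising.
    """
    X = problem.X
    R = problem.references
    m, n = R.shape
    t_w = X.shape[0]
    if m > t_w:
        raise ValueError(f"{m} components but only {t_w} time points")
    eps = problem.epsilon_constraint
    rng = np.random.default_rng(seed)

    # center rows, whiten to m principal components
    Xc = X - X.mean(axis=1, keepdims=True)
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(svals > max(svals[0], 1e-300) * 1e-10))
    r = min(m, rank)
    # Z: (r, n) whitened rows, unit variance, mutually orthogonal
    Z = Vt[:r] * np.sqrt(n)

    W = np.zeros((m, r))
    comps = np.zeros((m, n))
    phis = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    for i in range(m):
        # reference direction in whitened space
        u_ref = Z @ R[i] / n
        nrm = np.linalg.norm(u_ref)
        if nrm > 1e-8:
            u = u_ref / nrm
        else:
            u = rng.standard_normal(r)
            u /= np.linalg.norm(u)
        u = _deflate(u, W[:i])
        settled = False
        for _ in range(max_iter):
            u_old = u
            c = u @ Z
            # fixed-point negentropy step, G' = tanh
            u = (Z @ np.tanh(c)) / n - np.mean(1.0 - np.tanh(c) ** 2) * u
            u = _deflate(u, W[:i])
            norm = np.linalg.norm(u)
            if norm < 1e-12:
                u = rng.standard_normal(r)
                u = _deflate(u, W[:i])
                norm = np.linalg.norm(u)
            u /= norm
            phi = (u @ Z) @ R[i] / n
            if abs(phi) < eps and nrm > 1e-8:
                # pull back toward the reference subspace
                u = 0.5 * u + 0.5 * np.sign(phi if phi != 0 else 1.0) \
                    * (u_ref / nrm)
                u = _deflate(u, W[:i])
                u /= np.linalg.norm(u)
            if abs(abs(u @ u_old) - 1.0) < tol:
                settled = True
                break
        c = u @ Z
        phi = c @ R[i] / n
        if phi < 0:
            u, c, phi = -u, -c, -phi
        W[i] = u
        comps[i] = c
        phis[i] = phi
        converged[i] = settled and phi >= eps
        if not converged[i]:
            logger.debug("component %d not converged (phi=%.3f)", i, phi)

    # mixing time courses: least squares of X on the recovered sources
    A, *_ = np.linalg.lstsq(comps.T, Xc.T, rcond=None)
    return IcaPrior(
        components=comps,
        time_courses=A.T,
        window_index=0,
        constraint_correlations=phis,
        converged=converged,
    )


def _deflate(u: np.ndarray, W_prev: np.ndarray) -> np.ndarray:
    if len(W_prev):
        u = u - W_prev.T @ (W_prev @ u)
    return u


def n_windows(t: int, window: int, stride: int) -> int:
    return (t - window) // stride + 1


def run_windowed(vol: FmriVolume, references, window: int = 30,
                 stride: int = 1, epsilon_constraint: float = 0.3,
                 max_iter: int = 200, tol: float = 1e-6,
                 seed: int = 0) -> list[IcaPrior]:
    """Constrained ICA over overlapping temporal windows.

    One :class:`IcaPrior` per window start 0, stride, 2*stride, ...;
    exactly ``(t - window) // stride + 1`` windows.
    """
    t = vol.n_timepoints
    if window > t:
        raise ValueError(f"window {window} exceeds {t} time points")
    mask = vol.mask_or_full()
    X_full = vol.data[mask, :].T          # (t, n)
    references = np.asarray(references, dtype=np.float64)
    if references.ndim == 4:              # stack of 3D maps
        references = references.reshape(references.shape[0], -1)[:, mask.ravel()]
    priors = []
    for w_idx in range(n_windows(t, window, stride)):
        start = w_idx * stride
        problem = IcaProblem(
            X=X_full[start:start + window],
            references=references,
            epsilon_constraint=epsilon_constraint,
        )
        prior = fit_constrained(problem, max_iter=max_iter, tol=tol,
                                seed=seed)
        prior.window_index = start
        priors.append(prior)
    return priors


def align_priors_to_frames(priors: list[IcaPrior], frame_times,
                           mask: np.ndarray, window: int) -> np.ndarray:
    """Map window-wise priors onto retained frames (the training target y).

    For each frame time the window whose center is nearest is selected
    (ties go to the earlier window); frames outside the covered range are
    clamped to the first/last window with a warning. Component rows are
    un-flattened through the mask. Returns (n_networks, h, w, d, n_frames).
    """
    if not priors:
        raise ValueError("no priors given")
    centers = np.array([p.window_index + (window - 1) / 2.0 for p in priors])
    m = priors[0].components.shape[0]
    h, w, d = mask.shape
    frame_times = np.asarray(frame_times)
    out = np.zeros((m, h, w, d, len(frame_times)))
    lo, hi = centers.min(), centers.max()
    for j, tau in enumerate(frame_times):
        if tau < lo or tau > hi:
            logger.warning(
                "frame %d outside window-center range [%.1f, %.1f]; "
                "clamping", tau, lo, hi,
            )
        dist = np.abs(centers - tau)
        sel = int(np.argmin(dist))   # argmin takes the first == earlier
        for k in range(m):
            vol3 = np.zeros((h, w, d))
            vol3[mask] = priors[sel].components[k]
            out[k, ..., j] = vol3
    return out
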