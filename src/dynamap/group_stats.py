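"""Voxelwise two-group comparison with FDR correction.

Subjects' dynamic maps are reduced to one 3D summary per subject — either
the time average ("activity level") or the temporal-gradient map
("temporal variability") — and compared voxelwise between groups with
Welch's two-sample t-test. Welch is the default because cohort groups are
typically unbalanced; a pooled-variance mode is available. p-values are
adjusted with Benjamini-Hochberg FDR within each network map, and the
display map is -log10(p) x sign(t), zeroed wherever q exceeds alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import temporal_gradient

logger = logging.getLogger("dynamap")

__all__ = ["GroupStatMap", "voxelwise_ttest", "fdr_correct",
           "compare_groups"]


@dataclass
class GroupStatMap:
    """Voxelwise signed significance map for one network."""

    t_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray | None = None
    signed_logp: np.ndarray | None = None
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        if self.q_values is None:
            raise ValueError("run fdr_correct first")
        return int((self.q_values <= self.alpha).sum())


def voxelwise_ttest(group_a: np.ndarray, group_b: np.ndarray,
                    equal_var: bool = False) -> GroupStatMap:
    """Per-voxel two-sample t-test (Welch by default).

    ``group_a``/``group_b`` are (n_subjects, n_vox) matrices on a common
    voxel ordering. Zero-variance voxels (both groups constant and equal)
    get t = 0, p = 1.
    """
    group_a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups disagree on voxel count")
    t, p = stats.ttest_ind(group_a, group_b, axis=0, equal_var=equal_var)
    bad = ~np.isfinite(t)
    if bad.any():
        logger.debug("t-test: %d zero-variance voxels set to t=0, p=1",
                     int(bad.sum()))
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    return GroupStatMap(t_values=t, p_values=p)


def fdr_correct(stat: GroupStatMap, alpha: float = 0.05) -> GroupStatMap:
    """Benjamini-Hochberg adjusted q-values and the masked signed-logp map.

    signed_logp = -log10(p) * sign(t) where q <= alpha, 0 elsewhere.
    """
    p = stat.p_values.ravel()
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    q = q.reshape(stat.p_values.shape)
    with np.errstate(divide="ignore"):
        logp = -np.log10(np.maximum(stat.p_values, np.finfo(float).tiny))
    signed = logp * np.sign(stat.t_values)
    signed[q > alpha] = 0.0
    return GroupStatMap(
        t_values=stat.t_values,
        p_values=stat.p_values,
        q_values=q,
        signed_logp=signed,
        alpha=alpha,
    )


def _subject_summary(map4d: np.ndarray, mode: str) -> np.ndarray:
    if mode == "time_average":
        return map4d.mean(axis=3)
    if mode == "temporal_gradient":
        return temporal_gradient(map4d)
    raise ValueError("mode must be time_average or temporal_gradient")


def compare_groups(maps, labels, mode: str = "time_average",
                   alpha: float = 0.05,
                   mask: np.ndarray | None = None,
                   equal_var: bool = False) -> list[GroupStatMap]:
    """Group comparison of per-subject dynamic maps, one result per network.

    ``maps``: per-subject arrays shaped (n_networks, h, w, d, t) (a
    DynamicMap's ``data`` works directly); ``labels``: 0/1 per subject.
    The q/signed-logp fields are FDR-corrected within each network over
    in-mask voxels; out-of-mask voxels are 0/1-filled.
    """
    labels = np.asarray(labels)
    arrays = [np.asarray(getattr(m, "data", m), dtype=np.float64)
              for m in maps]
    if len(arrays) != len(labels):
        raise ValueError("one label per subject required")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all subjects must share map shape")
    n_networks = shape[0]
    spatial = shape[1:4]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    results = []
    for k in range(n_networks):
        summaries = np.stack(
            [_subject_summary(a[k], mode)[mask] for a in arrays]
        )
        stat = voxelwise_ttest(summaries[labels == 0],
                               summaries[labels == 1],
                               equal_var=equal_var)
        stat = fdr_correct(stat, alpha=alpha)
        full = GroupStatMap(
            t_values=_unflatten(stat.t_values, mask, 0.0),
            p_values=_unflatten(stat.p_values, mask, 1.0),
            q_values=_unflatten(stat.q_values, mask, 1.0),
            signed_logp=_unflatten(stat.signed_logp, mask, 0.0),
            alpha=alpha,
        )
        results.append(full)
    return results


def _unflatten(vals: np.ndarray, mask: np.ndarray, fill: float) -> np.ndarray:
    out = np.full(mask.shape, fill)
    out[mask] = vals
    return out
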