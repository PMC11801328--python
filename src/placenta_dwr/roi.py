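"""ROI reduction: supraphysiological-T2* exclusion and parenchyma means.

Voxels whose fitted T2* exceeds 200 ms are treated as supraphysiological
(fluid / maternal blood pool contamination) and excluded before the
region mean is taken; the exclusion is strictly greater-than, so a voxel
at exactly 200 ms is retained.  For the two-compartment model the rule
is applied to each compartment's T2* map through the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import ParameterMaps

__all__ = ["RoiSummary", "apply_t2star_threshold", "summarise_roi", "roi_summary"]

DEFAULT_T2_THRESHOLD_MS = 200.0

#: which fitted map(s) the exclusion threshold applies to, per model
_THRESHOLD_MAPS = {
    "t2adc": ("t2_star",),
    "t2ivim": ("t2_star_fast", "t2_star_slow"),
    "fa": (),
}


@dataclass
class RoiSummary:
    """Per-parameter means over retained parenchyma voxels."""

    means: dict[str, float]
    n_voxels_total: int
    n_voxels_retained: int
    threshold_ms: float
    excluded: bool = False  # True when no voxel survived thresholding


def apply_t2star_threshold(
    t2_map: np.ndarray, mask: np.ndarray, threshold_ms: float = DEFAULT_T2_THRESHOLD_MS
) -> np.ndarray:
    """Mask of voxels retained after the supraphysiological-T2* exclusion.

    retained = mask AND (t2 <= threshold).  NaN T2* (non-converged voxel)
    is excluded.  Idempotent: thresholding a thresholded mask is a no-op.
    """
    if threshold_ms <= 0:
        raise ValueError(f"threshold must be > 0 ms, got {threshold_ms}")
    t2_map = np.asarray(t2_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    with np.errstate(invalid="ignore"):
        keep = t2_map <= threshold_ms
    return mask & keep


def summarise_roi(
    param_maps: dict[str, np.ndarray] | ParameterMaps,
    retained_mask: np.ndarray,
    n_voxels_total: int | None = None,
    threshold_ms: float = DEFAULT_T2_THRESHOLD_MS,
    statistic: str = "mean",
) -> RoiSummary:
    """Arithmetic mean of each parameter map over the retained voxels.

    An empty retained mask yields NaN means and ``excluded=True`` with a
    warning (the subject is then dropped from cohort statistics) rather
    than an exception.  ``statistic="median"`` is available but the mean
    is the default summary.
    """
    maps = param_maps.maps if isinstance(param_maps, ParameterMaps) else param_maps
    retained_mask = np.asarray(retained_mask, dtype=bool)
    n_ret = int(retained_mask.sum())
    n_tot = int(n_voxels_total) if n_voxels_total is not None else n_ret
    reduce = np.nanmedian if statistic == "median" else np.nanmean
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_ret == 0:
        warnings.warn("empty retained mask: ROI means undefined, subject flagged for exclusion")
        return RoiSummary({k: float("nan") for k in maps}, n_tot, 0, threshold_ms, excluded=True)
    means = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for name, arr in maps.items():
            means[name] = float(reduce(np.asarray(arr, dtype=float)[retained_mask]))
    return RoiSummary(means, n_tot, n_ret, threshold_ms)


def roi_summary(
    fitted: ParameterMaps,
    threshold_ms: float = DEFAULT_T2_THRESHOLD_MS,
    statistic: str = "mean",
) -> RoiSummary:
    """Threshold a fitted volume on its model's T2* map(s) and summarise."""
    retained = fitted.mask
    for map_name in _THRESHOLD_MAPS.get(fitted.model, ()):
        retained = apply_t2star_threshold(fitted.maps[map_name], retained, threshold_ms)
    return summarise_roi(
        fitted, retained, n_voxels_total=int(fitted.mask.sum()),
        threshold_ms=threshold_ms, statistic=statistic,
    )
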