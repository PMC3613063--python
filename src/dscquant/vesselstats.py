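"""Final vessel removal, hemispheric ROI statistics and rank tests.

The final vessel mask uses fixed absolute dual thresholds — CBV > 8
mL/100 g or CBF > 100 mL/100 g/min, strict inequalities — and records
which criterion fired per voxel (1: CBV only, 2: CBF only, 3: both), so
structures such as the choroid plexus (high CBV, low CBF) are visibly
CBV-only.  ROI statistics are reported per hemisphere under the four
cumulative masking conditions (all brain, CSF removed, vessels removed,
both removed).  Group comparisons use a Mann-Whitney U test implemented
from the rank definitions, with an exact permutation null for small
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from . import constants
from .autoscale import ScalingFactors
from .types import ParametricMap, VoxelMask

__all__ = [
    "CategorizedVesselMask",
    "final_vessel_mask",
    "threshold_comparison",
    "percent_below_final",
    "hemispheric_roi_stats",
    "mann_whitney_u",
]

CONDITIONS = ("all", "csf-removed", "vessel-removed", "both-removed")


@dataclass
class CategorizedVesselMask:
    """3-D integer codes {0: none, 1: CBV-only, 2: CBF-only, 3: both}."""

    data: np.ndarray
    cbv_threshold: float
    cbf_threshold: float
    method: str

    @property
    def any_vessel(self) -> np.ndarray:
        return self.data > 0

    def counts(self) -> dict[int, int]:
        return {code: int((self.data == code).sum()) for code in (1, 2, 3)}


def final_vessel_mask(
    cbv: ParametricMap,
    cbf: ParametricMap,
    brain_mask: VoxelMask,
    cbv_threshold: float = constants.FINAL_CBV_THRESHOLD,
    cbf_threshold: float = constants.FINAL_CBF_THRESHOLD,
) -> CategorizedVesselMask:
    """Dual-threshold vessel classification on the absolute maps."""
    by_cbv = brain_mask.data & (cbv.data > cbv_threshold)
    by_cbf = brain_mask.data & (cbf.data > cbf_threshold)
    codes = np.zeros(brain_mask.data.shape, dtype=np.int8)
    codes[by_cbv & ~by_cbf] = 1
    codes[by_cbf & ~by_cbv] = 2
    codes[by_cbv & by_cbf] = 3
    return CategorizedVesselMask(
        data=codes,
        cbv_threshold=cbv_threshold,
        cbf_threshold=cbf_threshold,
        method=cbf.method,
    )


def percent_below_final(prelim_abs: float, final: float) -> float:
    """How far the preliminary absolute threshold sits below the final
    one, as a percentage of the final threshold."""
    return (final - prelim_abs) / final * 100.0


def threshold_comparison(
    prelim_rcbv_threshold: float,
    prelim_rcbf_thresholds: dict[str, float],
    factors: ScalingFactors,
    final_cbv: float = constants.FINAL_CBV_THRESHOLD,
    final_cbf: float = constants.FINAL_CBF_THRESHOLD,
) -> dict:
    """Convert the preliminary (relative) 2x-median thresholds to absolute
    units and report their percent difference from the final thresholds."""
    prelim_abs_cbv = factors.sf_cbv * prelim_rcbv_threshold
    record = {
        "prelim_abs_cbv": prelim_abs_cbv,
        "final_cbv": final_cbv,
        "pct_below_final_cbv": percent_below_final(prelim_abs_cbv, final_cbv),
        "prelim_abs_cbf": {},
        "final_cbf": final_cbf,
        "pct_below_final_cbf": {},
    }
    for method, thr in prelim_rcbf_thresholds.items():
        prelim_abs = factors.sf_cbf[method] * thr
        record["prelim_abs_cbf"][method] = prelim_abs
        record["pct_below_final_cbf"][method] = percent_below_final(
            prelim_abs, final_cbf
        )
    return record


def _hemisphere_masks(
    brain_mask: VoxelMask, midline: int | None = None
) -> dict[str, np.ndarray]:
    """Split the brain along the first in-plane axis; default midline is
    the midpoint of the brain-mask bounding box."""
    data = brain_mask.data
    if midline is None:
        xs = np.where(data.any(axis=(1, 2)))[0]
        if xs.size == 0:
            raise ValueError("brain mask is empty")
        midline = int((xs[0] + xs[-1] + 1) // 2)
    left = np.zeros_like(data)
    left[:midline] = True
    return {"left": data & left, "right": data & ~left}


def hemispheric_roi_stats(
    maps: dict[str, ParametricMap],
    brain_mask: VoxelMask,
    csf_mask: VoxelMask,
    vessel_mask: CategorizedVesselMask,
    midline: int | None = None,
    slice_index: int | None = None,
) -> pd.DataFrame:
    """Mean, SD and voxel count of each map per hemisphere under the four
    cumulative masking conditions.

    ``slice_index`` restricts the ROI to one slice (the anatomical
    placement at the lateral-ventricle level); default uses all slices.
    Empty ROIs yield NaN means with n = 0 rather than an error.
    """
    hemis = _hemisphere_masks(brain_mask, midline)
    conditions = {
        "all": brain_mask.data,
        "csf-removed": brain_mask.data & ~csf_mask.data,
        "vessel-removed": brain_mask.data & ~vessel_mask.any_vessel,
        "both-removed": brain_mask.data & ~csf_mask.data & ~vessel_mask.any_vessel,
    }
    rows = []
    for cond, cond_mask in conditions.items():
        for hemi, hemi_mask in hemis.items():
            roi = cond_mask & hemi_mask
            if slice_index is not None:
                keep = np.zeros_like(roi)
                keep[:, :, slice_index] = True
                roi = roi & keep
            for key, pmap in maps.items():
                vals = pmap.data[roi]
                rows.append(
                    {
                        "condition": cond,
                        "hemisphere": hemi,
                        "quantity": pmap.quantity,
                        "method": pmap.method,
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                        "n": int(vals.size),
                    }
                )
    return pd.DataFrame(rows)


def _rank_with_ties(pooled: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _u_statistic(pooled: np.ndarray, idx_a: tuple[int, ...], n_a: int) -> float:
    ranks = _rank_with_ties(pooled)
    r_a = ranks[list(idx_a)].sum()
    return r_a - n_a * (n_a + 1) / 2.0


def mann_whitney_u(
    sample_a: np.ndarray, sample_b: np.ndarray, exact_max: int = 8
) -> tuple[float, float]:
    """Mann-Whitney U for sample_a with a two-sided p value.

    For groups of at most ``exact_max`` observations each, the null
    distribution of U is enumerated exactly over all assignments of the
    pooled values (ties included); otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    u_a = _u_statistic(pooled, tuple(range(n_a)), n_a)
    mu = n_a * n_b / 2.0

    if n_a <= exact_max and n_b <= exact_max:
        dev = abs(u_a - mu)
        hits = 0
        total = comb(n_a + n_b, n_a)
        for idx in combinations(range(n_a + n_b), n_a):
            if abs(_u_statistic(pooled, idx, n_a) - mu) >= dev - 1e-12:
                hits += 1
        return u_a, hits / total

    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_a, 1.0
    z = (abs(u_a - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))
    return u_a, min(p, 1.0)
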