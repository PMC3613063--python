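"""Signal-to-concentration conversion, brain masking and CSF removal.

The tracer concentration follows the standard T2* relation

    C(t) = -(k1 / TE) * ln(S(t) / S0),

with S0 the voxelwise mean of the 6th-10th dynamics.  The sign is chosen
so the bolus-induced signal drop maps to positive concentration; k1 is a
proportionality factor that cancels in every downstream ratio and is kept
at 1.

CSF voxels are found on the ratio image (first dynamic / baseline): CSF
is unsaturated in the first source image and therefore the HIGH-ratio
class.  The threshold comes from Otsu's method on the within-brain ratio
distribution, floored at 1 + CSF_MIN_RATIO_EXCESS so a CSF-free volume
(unimodal ratio around 1) yields an empty mask instead of a forced split.
"""

from __future__ import annotations

import logging

import numpy as np

from . import constants
from .types import ConcentrationSeries, MaskLabel, PerfusionSeries, VoxelMask

__all__ = [
    "otsu_threshold",
    "compute_brain_mask",
    "compute_baseline",
    "signal_to_concentration",
    "compute_ratio_image",
    "compute_csf_mask",
]

log = logging.getLogger(__name__)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing the between-class variance.

    When several split points achieve the maximum (a flat valley between
    well-separated modes leaves the variance constant across the gap),
    the mean of the maximizing bin centers is returned, placing the
    threshold mid-gap rather than at the foot of the dominant mode.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("Otsu threshold needs at least two distinct values")
    hist, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist / hist.sum()
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, m[:-1] / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (m[-1] - m[:-1]) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    best = sigma_b.max()
    if not np.isfinite(best) or best <= 0:
        raise ValueError("Otsu threshold needs at least two distinct values")
    at_max = sigma_b >= best - 1e-12 * best
    return float(centers[:-1][at_max].mean())


def compute_brain_mask(series: PerfusionSeries, n_bins: int = 256) -> VoxelMask:
    """Voxels whose first-dynamic signal exceeds the Otsu threshold."""
    first = series.data[..., 0]
    thr = otsu_threshold(first, n_bins=n_bins)
    mask = first > thr
    if not mask.any():
        raise ValueError("brain mask is empty")
    return VoxelMask(
        mask,
        MaskLabel.BRAIN,
        provenance=f"first image > Otsu({thr:.4g})",
        stats={"threshold": thr},
    )


def compute_baseline(series: PerfusionSeries) -> np.ndarray:
    """Pre-bolus baseline S0: mean of the 6th-10th dynamics (indices 5..9)."""
    lo, hi = constants.BASELINE_WINDOW
    if series.n_dynamics < hi:
        raise ValueError(
            f"need at least {hi} dynamics for the baseline window, "
            f"got {series.n_dynamics}"
        )
    return series.data[..., lo:hi].mean(axis=-1)


def signal_to_concentration(
    series: PerfusionSeries,
    s0: np.ndarray | None = None,
    k1: float = constants.K1,
    signal_floor: float = constants.SIGNAL_FLOOR_FRACTION,
) -> ConcentrationSeries:
    """Convert signal to concentration, C(t) = -(k1/TE) ln(S/S0).

    Signals are floored at ``signal_floor * S0`` before the log so noisy
    vessel voxels cannot produce infinities; voxels with S0 <= 0 (outside
    the head) get zero concentration.
    """
    if series.te <= 0:
        raise ValueError("te must be positive")
    if s0 is None:
        s0 = compute_baseline(series)
    s0 = np.asarray(s0, dtype=float)
    valid = s0 > 0
    safe_s0 = np.where(valid, s0, 1.0)
    s = np.maximum(series.data, signal_floor * safe_s0[..., None])
    conc = -(k1 / series.te) * np.log(s / safe_s0[..., None])
    conc[~valid] = 0.0
    return ConcentrationSeries(
        data=conc, baseline=s0, tr=series.tr, te=series.te, k1=k1
    )


def compute_ratio_image(
    series: PerfusionSeries, s0: np.ndarray, brain_mask: VoxelMask | None = None
) -> np.ndarray:
    """First dynamic divided by baseline; zero outside the brain mask."""
    s0 = np.asarray(s0, dtype=float)
    ratio = np.zeros(series.spatial_shape)
    if brain_mask is None:
        inside = s0 > 0
    else:
        inside = brain_mask.data & (s0 > 0)
    ratio[inside] = series.data[..., 0][inside] / s0[inside]
    return ratio


def compute_csf_mask(
    ratio: np.ndarray,
    brain_mask: VoxelMask,
    n_bins: int = 256,
    high_ratio_is_csf: bool = True,
    min_ratio_excess: float = constants.CSF_MIN_RATIO_EXCESS,
) -> VoxelMask:
    """CSF as the extreme-ratio class within the brain mask.

    By default CSF is the high-ratio tail (first image unsaturated); set
    ``high_ratio_is_csf=False`` for acquisitions where CSF is dark in the
    first image instead.
    """
    if not brain_mask.data.any():
        raise ValueError("brain mask is empty")
    inside = ratio[brain_mask.data]
    floor = 1.0 + min_ratio_excess
    try:
        thr = otsu_threshold(inside, n_bins=n_bins)
    except ValueError:
        log.warning("degenerate ratio distribution; returning empty CSF mask")
        return VoxelMask(
            np.zeros_like(brain_mask.data), MaskLabel.CSF,
            provenance="degenerate ratio distribution", stats={"threshold": None},
        )
    if high_ratio_is_csf:
        if thr < floor:
            log.warning(
                "Otsu ratio threshold %.3f below the CSF floor %.3f; "
                "likely no CSF class present", thr, floor,
            )
            thr = floor
        mask = brain_mask.data & (ratio > thr)
    else:
        ceil = 1.0 - min_ratio_excess
        if thr > ceil:
            log.warning(
                "Otsu ratio threshold %.3f above the CSF ceiling %.3f; "
                "likely no CSF class present", thr, ceil,
            )
            thr = ceil
        mask = brain_mask.data & (ratio < thr)
    return VoxelMask(
        mask,
        MaskLabel.CSF,
        provenance=f"ratio {'>' if high_ratio_is_csf else '<'} {thr:.4g} within brain",
        stats={"threshold": float(thr)},
    )
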