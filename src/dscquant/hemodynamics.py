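"""Relative perfusion maps: rCBV, rCBF (sSVD/cSVD), TTP and MTT.

The tissue curve is modelled as a convolution of the arterial input
function with the flow-scaled residue function,

    C_tissue(t) = (rho/k_H) * AIF(t) (x) [rCBF * R(t)],

and inverted by truncated singular-value decomposition of either the
lower-triangular Toeplitz operator (sSVD) or a zero-padded circulant
operator (cSVD, insensitive to bolus-arrival delay).  Singular values
below a configurable fraction of the largest are discarded.  rCBF is the
maximum of the recovered signed curve; rCBV is the ratio of the tissue
and arterial concentration integrals over the 11th-70th dynamics scaled
by k_H/rho = 0.705 cc/g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import circulant, toeplitz

from . import constants
from .types import ArterialInputFunction, ConcentrationSeries, ParametricMap, VoxelMask

__all__ = [
    "DeconvolutionConfig",
    "select_aif_auto",
    "compute_rcbv",
    "build_convolution_operator",
    "deconvolve",
    "compute_rcbf",
    "compute_ttp",
    "compute_mtt",
]

log = logging.getLogger(__name__)


@dataclass
class DeconvolutionConfig:
    """Settings for one truncated-SVD deconvolution variant."""

    method: str = "sSVD"                 # "sSVD" or "cSVD"
    truncation_fraction: float | None = None
    pad_factor: int = constants.DEFAULT_PAD_FACTOR
    tr: float = constants.DEFAULT_TR

    def __post_init__(self) -> None:
        if self.method not in ("sSVD", "cSVD"):
            raise ValueError("method must be 'sSVD' or 'cSVD'")
        if self.truncation_fraction is None:
            self.truncation_fraction = (
                constants.DEFAULT_TRUNCATION_SSVD
                if self.method == "sSVD"
                else constants.DEFAULT_TRUNCATION_CSVD
            )
        if not 0 < self.truncation_fraction < 1:
            raise ValueError("truncation_fraction must lie strictly in (0, 1)")
        if self.method == "cSVD" and self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2 for cSVD")


def _integration_slice(n_dynamics: int) -> slice:
    lo, hi = constants.INTEGRATION_WINDOW
    return slice(lo, min(hi, n_dynamics))


def select_aif_auto(
    conc: ConcentrationSeries,
    brain_mask: VoxelMask,
    k: int = 10,
    voxels: list[tuple[int, int, int]] | None = None,
) -> ArterialInputFunction:
    """Pick arterial voxels and average their concentration curves.

    Without an explicit voxel list, brain voxels are ranked by a composite
    z-score favouring early time-to-peak, high peak concentration and a
    narrow first-moment width — the signature of an arterial curve — and
    the top ``k`` are averaged.
    """
    if voxels is not None:
        curves = np.stack([conc.data[v] for v in voxels])
        return ArterialInputFunction(
            curves.mean(axis=0), source_voxels=list(voxels), method="MANUAL"
        )
    if not brain_mask.data.any():
        raise ValueError("brain mask is empty")

    coords = np.argwhere(brain_mask.data)
    curves = conc.data[brain_mask.data]          # (n_vox, n_dyn)
    win = _integration_slice(conc.n_dynamics)
    seg = curves[:, win]
    peaks = seg.max(axis=1)
    candidates = peaks > 0
    if not candidates.any():
        raise ValueError("no voxel with positive peak concentration")
    coords = coords[candidates]
    curves = curves[candidates]
    seg = seg[candidates]
    peaks = peaks[candidates]

    t = (np.arange(seg.shape[1]) + win.start) * conc.tr
    ttp = t[np.argmax(seg, axis=1)]
    pos = np.clip(seg, 0.0, None)
    area = pos.sum(axis=1)
    area = np.where(area > 0, area, 1.0)
    first_moment = (pos * t).sum(axis=1) / area
    width = np.sqrt((pos * (t - first_moment[:, None]) ** 2).sum(axis=1) / area)

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    score = (_z(peaks) - _z(ttp) - _z(width)) / 3.0
    if k > score.size:
        log.warning("requested k=%d arterial voxels but only %d candidates", k, score.size)
        k = score.size
    top = np.argsort(score)[::-1][:k]
    return ArterialInputFunction(
        curves[top].mean(axis=0),
        source_voxels=[tuple(c) for c in coords[top]],
        method="AUTO",
    )


def compute_rcbv(
    conc: ConcentrationSeries,
    aif: ArterialInputFunction,
    mask: VoxelMask | None = None,
) -> ParametricMap:
    """Relative CBV: (k_H/rho) * sum C(t) / sum AIF(t) over the
    integration window, clamped to the number of dynamics."""
    win = _integration_slice(conc.n_dynamics)
    aif_sum = float(aif.curve[win].sum())
    if aif_sum <= 0:
        raise ValueError("AIF integral over the integration window is not positive")
    rcbv = constants.KH_OVER_RHO * conc.data[..., win].sum(axis=-1) / aif_sum
    if mask is not None:
        rcbv = np.where(mask.data, rcbv, 0.0)
    return ParametricMap(rcbv, "rCBV", units="a.u.")


def build_convolution_operator(
    aif_curve: np.ndarray, config: DeconvolutionConfig
) -> np.ndarray:
    """Discrete convolution matrix for the flow-scaled residue model.

    sSVD: lower-triangular Toeplitz, A[i, j] = (rho/k_H) * TR * AIF[i-j].
    cSVD: circulant matrix of the AIF zero-padded to pad_factor * n.
    """
    a = np.asarray(aif_curve, dtype=float)
    scale = constants.RHO_OVER_KH * config.tr
    if config.method == "sSVD":
        first_row = np.zeros_like(a)
        first_row[0] = a[0]
        return scale * toeplitz(a, first_row)
    padded = np.concatenate([a, np.zeros((config.pad_factor - 1) * a.size)])
    return scale * circulant(padded)


def deconvolve(
    tissue: np.ndarray, operator: np.ndarray, config: DeconvolutionConfig
) -> np.ndarray:
    """Recover the flow-scaled residue curve f(t) by truncated SVD.

    ``tissue`` may be a single curve (n,) or a stack (..., n).  Singular
    values below truncation_fraction * s_max get zero inverse weight; for
    cSVD the input is zero-padded and the output truncated back to n.
    """
    tissue = np.asarray(tissue, dtype=float)
    single = tissue.ndim == 1
    stack = np.atleast_2d(tissue)
    n = stack.shape[-1]
    L = operator.shape[0]
    if L != n:
        padded = np.zeros(stack.shape[:-1] + (L,))
        padded[..., :n] = stack
        stack = padded

    u, s, vt = np.linalg.svd(operator)
    if s[0] <= 0:
        raise ValueError("degenerate operator: all singular values truncated")
    keep = s >= config.truncation_fraction * s[0]
    inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    f = (stack @ u) * inv @ vt            # == V diag(inv) U^T c, batched
    f = f[..., :n]
    return f[0] if single else f


def compute_rcbf(
    conc: ConcentrationSeries,
    aif: ArterialInputFunction,
    config: DeconvolutionConfig,
    mask: VoxelMask | None = None,
) -> ParametricMap:
    """Relative CBF: voxelwise maximum of the deconvolved signed curve.

    The rare voxels whose whole recovered curve is negative are clamped
    to zero and flagged.
    """
    operator = build_convolution_operator(aif.curve, config)
    shape = conc.spatial_shape
    if mask is not None:
        curves = conc.data[mask.data]
    else:
        curves = conc.data.reshape(-1, conc.n_dynamics)
    f = deconvolve(curves, operator, config)
    fmax = f.max(axis=-1)
    negative = fmax < 0
    fmax = np.clip(fmax, 0.0, None)

    rcbf = np.zeros(shape)
    flags = np.zeros(shape, dtype=bool)
    if mask is not None:
        rcbf[mask.data] = fmax
        flags[mask.data] = negative
    else:
        rcbf = fmax.reshape(shape)
        flags = negative.reshape(shape)
    return ParametricMap(rcbf, "rCBF", units="a.u./s", method=config.method, flags=flags)


def compute_ttp(conc: ConcentrationSeries) -> ParametricMap:
    """Time-to-peak: seconds from series start to the concentration
    maximum within the integration window; first occurrence wins ties.

    Voxels with a flat non-positive curve get the window start and a QC
    flag (``map.flags``).
    """
    win = _integration_slice(conc.n_dynamics)
    seg = conc.data[..., win]
    idx = np.argmax(seg, axis=-1)
    ttp = (idx + win.start) * conc.tr
    flat = seg.max(axis=-1) <= 0
    ttp = np.where(flat, win.start * conc.tr, ttp)
    return ParametricMap(ttp, "TTP", units="s", flags=flat)


def compute_mtt(
    cbv_map: ParametricMap,
    cbf_map: ParametricMap,
    cbf_floor: float = constants.MTT_CBF_FLOOR,
    flow_units: str = "per_min",
) -> ParametricMap:
    """Mean transit time from the central volume theorem, MTT = CBV/CBF.

    With CBF per minute (absolute maps) the ratio is multiplied by 60 to
    give seconds; pass ``flow_units='per_s'`` for flow already per second.
    Voxels with CBF at or below ``cbf_floor`` get MTT = 0 and a QC flag.
    """
    if cbv_map.data.shape != cbf_map.data.shape:
        raise ValueError("CBV and CBF maps must share the grid")
    factor = {"per_min": 60.0, "per_s": 1.0}[flow_units]
    cbf = cbf_map.data
    low = cbf <= cbf_floor
    mtt = np.zeros_like(cbf)
    np.divide(cbv_map.data, cbf, out=mtt, where=~low)
    mtt = np.where(low, 0.0, mtt * factor)
    return ParametricMap(mtt, "MTT", units="s", method=cbf_map.method, flags=low)
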