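"""Automatic conversion of relative maps to absolute CBV/CBF/MTT.

The pipeline never measures absolute tracer concentration, so the
relative maps are anchored to literature values for normal tissue:
composite references of 3.2 mL/100 g (CBV) and 40 mL/100 g/min (CBF),
assuming normal parenchyma is 60% gray and 40% white matter.  Normal
parenchyma is segmented automatically — CSF removed, preliminary vessel
voxels removed (rCBV or rCBF above twice the median), then voxels whose
time-to-peak lies within 3 s below the median TTP — and the scaling
factor for each quantity is the composite reference divided by the mean
relative value over that mask.  CBF gets its own factor per
deconvolution method, because SVD-based flow estimates carry
method-specific bias that a CBV-derived factor would not cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .hemodynamics import compute_mtt
from .types import MaskLabel, ParametricMap, VoxelMask

__all__ = [
    "ReferenceConstants",
    "ScalingFactors",
    "composite_reference",
    "preliminary_vessel_mask",
    "normal_brain_mask",
    "compute_scaling_factors",
    "apply_scaling",
]

log = logging.getLogger(__name__)


@dataclass
class ReferenceConstants:
    """Literature CBV/CBF for normal gray and white matter."""

    cbv_gm: float = constants.REF_CBV_GM
    cbv_wm: float = constants.REF_CBV_WM
    cbf_gm: float = constants.REF_CBF_GM
    cbf_wm: float = constants.REF_CBF_WM
    gm_fraction: float = constants.GM_FRACTION

    def __post_init__(self) -> None:
        if not 0 <= self.gm_fraction <= 1:
            raise ValueError("gm_fraction must lie in [0, 1]")
        if min(self.cbv_gm, self.cbv_wm, self.cbf_gm, self.cbf_wm) <= 0:
            raise ValueError("reference values must be positive")


@dataclass
class ScalingFactors:
    """Multipliers converting relative maps to absolute units."""

    sf_cbv: float
    sf_cbf: dict[str, float]          # per deconvolution method
    n_normal_voxels: int
    references: ReferenceConstants = field(default_factory=ReferenceConstants)


def composite_reference(ref: ReferenceConstants, quantity: str) -> float:
    """GM/WM-weighted reference: gm_fraction*GM + (1-gm_fraction)*WM."""
    if quantity == "CBV":
        gm, wm = ref.cbv_gm, ref.cbv_wm
    elif quantity == "CBF":
        gm, wm = ref.cbf_gm, ref.cbf_wm
    else:
        raise ValueError("quantity must be 'CBV' or 'CBF'")
    return ref.gm_fraction * gm + (1.0 - ref.gm_fraction) * wm


def preliminary_vessel_mask(
    rcbv: ParametricMap,
    rcbf: ParametricMap,
    eligible: VoxelMask,
    median_factor: float = constants.PRELIM_VESSEL_MEDIAN_FACTOR,
) -> VoxelMask:
    """Voxels with rCBV or rCBF above ``median_factor`` times the median
    of the eligible (brain-minus-CSF) voxels."""
    if not eligible.data.any():
        raise ValueError("eligible mask is empty")
    med_cbv = float(np.median(rcbv.data[eligible.data]))
    med_cbf = float(np.median(rcbf.data[eligible.data]))
    thr_cbv = median_factor * med_cbv
    thr_cbf = median_factor * med_cbf
    mask = eligible.data & ((rcbv.data > thr_cbv) | (rcbf.data > thr_cbf))
    log.info(
        "preliminary vessel thresholds: rCBV > %.4g (median %.4g), "
        "rCBF > %.4g (median %.4g); %d voxels flagged",
        thr_cbv, med_cbv, thr_cbf, med_cbf, int(mask.sum()),
    )
    return VoxelMask(
        mask,
        MaskLabel.PRELIM_VESSEL,
        provenance=f"rCBV > {thr_cbv:.4g} or rCBF > {thr_cbf:.4g}",
        stats={
            "median_rcbv": med_cbv,
            "median_rcbf": med_cbf,
            "threshold_rcbv": thr_cbv,
            "threshold_rcbf": thr_cbf,
        },
    )


def normal_brain_mask(
    ttp: ParametricMap,
    eligible: VoxelMask,
    window_s: float = constants.TTP_WINDOW_S,
) -> VoxelMask:
    """Normal parenchyma: eligible voxels whose TTP lies in
    [median - window, median], bounds inclusive.

    Voxels flagged as flat (undefined TTP) are excluded before the median.
    """
    data = eligible.data
    if ttp.flags is not None:
        data = data & ~ttp.flags
    if not data.any():
        raise ValueError("no eligible voxels with defined TTP")
    values = ttp.data[data]
    med = float(np.median(values))
    mask = data & (ttp.data >= med - window_s) & (ttp.data <= med)
    if not mask.any():
        raise ValueError(
            "normal-brain mask is empty; inspect the TTP map — no tissue "
            f"falls within {window_s} s below the median TTP ({med:.3g} s)"
        )
    log.info("TTP median %.3g s; normal-brain mask has %d voxels", med, int(mask.sum()))
    return VoxelMask(
        mask,
        MaskLabel.NORMAL_BRAIN,
        provenance=f"TTP in [{med - window_s:.4g}, {med:.4g}] s",
        stats={"ttp_median": med, "window_s": window_s},
    )


def compute_scaling_factors(
    rcbv: ParametricMap,
    rcbf_by_method: dict[str, ParametricMap],
    normal_mask: VoxelMask,
    ref: ReferenceConstants | None = None,
) -> ScalingFactors:
    """SF = composite reference / mean relative value over normal brain."""
    if ref is None:
        ref = ReferenceConstants()
    if not normal_mask.data.any():
        raise ValueError("normal mask is empty")
    mean_rcbv = float(rcbv.data[normal_mask.data].mean())
    if mean_rcbv <= 0:
        raise ValueError("mean rCBV over the normal mask is not positive")
    sf_cbv = composite_reference(ref, "CBV") / mean_rcbv
    sf_cbf: dict[str, float] = {}
    cbf_ref = composite_reference(ref, "CBF")
    for method, rcbf in rcbf_by_method.items():
        mean_rcbf = float(rcbf.data[normal_mask.data].mean())
        if mean_rcbf <= 0:
            raise ValueError(
                f"mean rCBF ({method}) over the normal mask is not positive"
            )
        sf_cbf[method] = cbf_ref / mean_rcbf
    return ScalingFactors(
        sf_cbv=sf_cbv,
        sf_cbf=sf_cbf,
        n_normal_voxels=normal_mask.count,
        references=ref,
    )


def apply_scaling(
    rcbv: ParametricMap,
    rcbf_by_method: dict[str, ParametricMap],
    factors: ScalingFactors,
) -> dict[str, ParametricMap]:
    """Absolute maps: CBV = SF_CBV*rCBV, CBF = SF_CBF*rCBF per method,
    and MTT recomputed from the scaled maps (the two factors differ in
    general, so scaling does not commute with the MTT ratio)."""
    out: dict[str, ParametricMap] = {
        "CBV": ParametricMap(factors.sf_cbv * rcbv.data, "CBV", units="mL/100 g")
    }
    for method, rcbf in rcbf_by_method.items():
        cbf = ParametricMap(
            factors.sf_cbf[method] * rcbf.data,
            "CBF",
            units="mL/100 g/min",
            method=method,
            flags=rcbf.flags,
        )
        out[f"CBF_{method}"] = cbf
        out[f"MTT_{method}"] = compute_mtt(out["CBV"], cbf, flow_units="per_min")
    return out
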