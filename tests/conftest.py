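"""Shared fixtures: phantoms and staged pipeline artifacts, computed once."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from dscquant import (
    ArterialInputFunction,
    ConcentrationSeries,
    DeconvolutionConfig,
    MaskLabel,
    PhantomConfig,
    VoxelMask,
    build_phantom,
    compute_baseline,
    compute_brain_mask,
    compute_csf_mask,
    compute_ratio_image,
    compute_rcbf,
    compute_rcbv,
    compute_scaling_factors,
    compute_ttp,
    apply_scaling,
    normal_brain_mask,
    preliminary_vessel_mask,
    select_aif_auto,
    signal_to_concentration,
)


@dataclass
class StagedRun:
    """All intermediate objects of one pipeline pass, for stage-level tests."""

    dataset: object
    series: object
    brain: object
    s0: np.ndarray
    conc: ConcentrationSeries
    aif: ArterialInputFunction
    rcbv: object
    rcbf: dict
    ttp: object
    csf: object
    eligible: VoxelMask
    prelim: object
    eligible_normal: VoxelMask
    normal: object
    factors: object
    absolute: dict


def stage_run(config: PhantomConfig, aif_true: bool = False) -> StagedRun:
    ds = build_phantom(config)
    series = ds.series
    brain = compute_brain_mask(series)
    s0 = compute_baseline(series)
    conc = signal_to_concentration(series, s0)
    if aif_true:
        aif = ArterialInputFunction(ds.aif_true, source_voxels=[], method="MANUAL")
    else:
        aif = select_aif_auto(conc, brain)
    rcbv = compute_rcbv(conc, aif, mask=brain)
    rcbf = {
        m: compute_rcbf(conc, aif, DeconvolutionConfig(method=m, tr=series.tr), mask=brain)
        for m in ("sSVD", "cSVD")
    }
    ttp = compute_ttp(conc)
    ratio = compute_ratio_image(series, s0, brain)
    csf = compute_csf_mask(ratio, brain)
    eligible = VoxelMask(brain.data & ~csf.data, MaskLabel.BRAIN, "brain minus CSF")
    prelim = preliminary_vessel_mask(rcbv, rcbf["sSVD"], eligible)
    eligible_normal = VoxelMask(
        eligible.data & ~prelim.data, MaskLabel.BRAIN, "eligible minus prelim vessels"
    )
    normal = normal_brain_mask(ttp, eligible_normal)
    factors = compute_scaling_factors(rcbv, rcbf, normal)
    absolute = apply_scaling(rcbv, rcbf, factors)
    return StagedRun(
        dataset=ds, series=series, brain=brain, s0=s0, conc=conc, aif=aif,
        rcbv=rcbv, rcbf=rcbf, ttp=ttp, csf=csf, eligible=eligible,
        prelim=prelim, eligible_normal=eligible_normal, normal=normal,
        factors=factors, absolute=absolute,
    )


@pytest.fixture(scope="session")
def noise_free_phantom():
    return build_phantom(PhantomConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noise_free_run():
    """Staged pipeline on the noise-free phantom, auto-selected AIF."""
    return stage_run(PhantomConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_run():
    """Staged pipeline on the default-noise phantom."""
    return stage_run(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def delayed_run():
    """One hemisphere delayed beyond the TTP window, noise-free, true AIF."""
    return stage_run(
        PhantomConfig(noise_sigma=0.0, impaired_delay=4.0), aif_true=True
    )


@pytest.fixture(scope="session")
def aif_curve(noise_free_phantom):
    return noise_free_phantom.aif_true
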