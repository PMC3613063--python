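"""End-to-end orchestration: one call runs every stage and records a
manifest with all derived scalars, parameters and output files."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants
from .autoscale import (
    ReferenceConstants,
    apply_scaling,
    compute_scaling_factors,
    normal_brain_mask,
    preliminary_vessel_mask,
)
from .hemodynamics import (
    DeconvolutionConfig,
    compute_rcbf,
    compute_rcbv,
    compute_ttp,
    select_aif_auto,
)
from .io import read_series, write_map, write_mask, write_series
from .phantom import PhantomConfig, build_phantom
from .preprocess import (
    compute_baseline,
    compute_brain_mask,
    compute_csf_mask,
    compute_ratio_image,
    signal_to_concentration,
)
from .types import MaskLabel, PerfusionSeries, VoxelMask
from .vesselstats import final_vessel_mask, hemispheric_roi_stats, threshold_comparison

__all__ = ["PipelineConfig", "RunManifest", "PipelineStageError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage and keeps the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run."""

    input_path: str | None = None          # NIfTI series; or use phantom
    phantom: PhantomConfig | None = None
    output_dir: str = "dscquant-out"
    tr: float | None = None                # overridden by a sidecar
    te: float | None = None
    methods: tuple[str, ...] = ("sSVD", "cSVD")
    truncation: dict[str, float] = field(default_factory=dict)
    pad_factor: int = constants.DEFAULT_PAD_FACTOR
    references: ReferenceConstants = field(default_factory=ReferenceConstants)
    ttp_window_s: float = constants.TTP_WINDOW_S
    final_cbv_threshold: float = constants.FINAL_CBV_THRESHOLD
    final_cbf_threshold: float = constants.FINAL_CBF_THRESHOLD
    aif_mode: str = "auto"                 # "auto" or "voxels=x,y,z;x,y,z;..."
    aif_k: int = 10
    seed: int = 0
    write_outputs: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.phantom is not None:
            d["phantom"] = self.phantom.to_dict()
        return d


@dataclass
class RunManifest:
    """Provenance for one pipeline run; the single source of every
    reported scalar."""

    parameters: dict
    input_sha256: str
    scalars: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _parse_aif_voxels(mode: str) -> list[tuple[int, int, int]] | None:
    if not mode.startswith("voxels="):
        return None
    out = []
    for chunk in mode[len("voxels=") :].split(";"):
        x, y, z = (int(v) for v in chunk.split(","))
        out.append((x, y, z))
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and return the populated manifest.

    Stage order: brain mask -> baseline -> concentration -> AIF ->
    rCBV/rCBF/TTP -> CSF mask -> preliminary vessel mask -> normal-brain
    mask -> scaling factors -> absolute maps -> final vessel mask -> ROI
    report.  Any stage error aborts with the stage name; the partial
    manifest is written if outputs are enabled.
    """
    out_dir = Path(config.output_dir)
    if config.write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        parameters=config.to_dict(),
        input_sha256="",
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    stage = "load-input"
    try:
        if config.phantom is not None:
            dataset = build_phantom(config.phantom)
            series = dataset.series
        elif config.input_path is not None:
            series = read_series(config.input_path, tr=config.tr, te=config.te)
        else:
            raise ValueError("config needs input_path or a phantom")
        manifest.input_sha256 = hashlib.sha256(
            np.ascontiguousarray(series.data).tobytes()
        ).hexdigest()
        manifest.stages.append(stage)

        def _done(name: str) -> None:
            manifest.stages.append(name)

        def _write_volume(kind: str, name: str, obj) -> None:
            if not config.write_outputs:
                return
            path = out_dir / f"{name}.nii"
            if kind == "map":
                write_map(obj, path)
            else:
                write_mask(obj, path)
            manifest.outputs.append(str(path))

        stage = "brain-mask"
        brain = compute_brain_mask(series)
        manifest.scalars["brain_otsu_threshold"] = brain.stats["threshold"]
        manifest.scalars["n_brain_voxels"] = brain.count
        _write_volume("mask", "mask_brain", brain.data)
        _done(stage)

        stage = "baseline"
        s0 = compute_baseline(series)
        _done(stage)

        stage = "concentration"
        conc = signal_to_concentration(series, s0)
        _done(stage)

        stage = "aif"
        voxels = _parse_aif_voxels(config.aif_mode)
        aif = select_aif_auto(conc, brain, k=config.aif_k, voxels=voxels)
        manifest.scalars["aif_peak"] = float(aif.curve.max())
        manifest.scalars["aif_method"] = aif.method
        _done(stage)

        stage = "relative-maps"
        rcbv = compute_rcbv(conc, aif, mask=brain)
        rcbf = {}
        for method in config.methods:
            dcfg = DeconvolutionConfig(
                method=method,
                truncation_fraction=config.truncation.get(method),
                pad_factor=config.pad_factor,
                tr=series.tr,
            )
            rcbf[method] = compute_rcbf(conc, aif, dcfg, mask=brain)
        ttp = compute_ttp(conc)
        _write_volume("map", "rcbv", rcbv)
        for method, m in rcbf.items():
            _write_volume("map", f"rcbf_{method.lower()}", m)
        _write_volume("map", "ttp", ttp)
        _done(stage)

        stage = "csf-mask"
        ratio = compute_ratio_image(series, s0, brain)
        csf = compute_csf_mask(ratio, brain)
        manifest.scalars["csf_ratio_threshold"] = csf.stats.get("threshold")
        manifest.scalars["n_csf_voxels"] = csf.count
        _write_volume("mask", "mask_csf", csf.data)
        _done(stage)

        stage = "preliminary-vessel-mask"
        eligible = VoxelMask(brain.data & ~csf.data, MaskLabel.BRAIN, "brain minus CSF")
        # preliminary thresholds are defined on one rCBF map per method;
        # the union of per-method masks is used downstream
        prelim_masks = {
            m: preliminary_vessel_mask(rcbv, rcbf[m], eligible) for m in config.methods
        }
        prelim_union = np.zeros_like(brain.data)
        for m, pm in prelim_masks.items():
            prelim_union |= pm.data
            manifest.scalars[f"prelim_rcbv_threshold_{m}"] = pm.stats["threshold_rcbv"]
            manifest.scalars[f"prelim_rcbf_threshold_{m}"] = pm.stats["threshold_rcbf"]
        manifest.scalars["n_prelim_vessel_voxels"] = int(prelim_union.sum())
        _write_volume("mask", "mask_prelim_vessel", prelim_union)
        _done(stage)

        stage = "normal-brain-mask"
        eligible_normal = VoxelMask(
            eligible.data & ~prelim_union, MaskLabel.BRAIN,
            "brain minus CSF minus preliminary vessels",
        )
        normal = normal_brain_mask(ttp, eligible_normal, window_s=config.ttp_window_s)
        manifest.scalars["ttp_median_s"] = normal.stats["ttp_median"]
        manifest.scalars["n_normal_voxels"] = normal.count
        _write_volume("mask", "mask_normal_brain", normal.data)
        _done(stage)

        stage = "scaling"
        factors = compute_scaling_factors(rcbv, rcbf, normal, config.references)
        manifest.scalars["sf_cbv"] = factors.sf_cbv
        for method, sf in factors.sf_cbf.items():
            manifest.scalars[f"sf_cbf_{method}"] = sf
        _done(stage)

        stage = "absolute-maps"
        absolute = apply_scaling(rcbv, rcbf, factors)
        for name, pmap in absolute.items():
            _write_volume("map", name.lower(), pmap)
        _done(stage)

        stage = "threshold-comparison"
        first = config.methods[0]
        comparison = threshold_comparison(
            prelim_masks[first].stats["threshold_rcbv"],
            {m: prelim_masks[m].stats["threshold_rcbf"] for m in config.methods},
            factors,
            final_cbv=config.final_cbv_threshold,
            final_cbf=config.final_cbf_threshold,
        )
        manifest.scalars["prelim_abs_cbv_threshold"] = comparison["prelim_abs_cbv"]
        manifest.scalars["pct_below_final_cbv"] = comparison["pct_below_final_cbv"]
        for method in config.methods:
            manifest.scalars[f"prelim_abs_cbf_threshold_{method}"] = comparison[
                "prelim_abs_cbf"
            ][method]
            manifest.scalars[f"pct_below_final_cbf_{method}"] = comparison[
                "pct_below_final_cbf"
            ][method]
        _done(stage)

        stage = "final-vessel-mask"
        vessel_by_method = {}
        for method in config.methods:
            vm = final_vessel_mask(
                absolute["CBV"],
                absolute[f"CBF_{method}"],
                brain,
                cbv_threshold=config.final_cbv_threshold,
                cbf_threshold=config.final_cbf_threshold,
            )
            vessel_by_method[method] = vm
            for code, count in vm.counts().items():
                manifest.scalars[f"n_final_vessel_code{code}_{method}"] = count
            _write_volume("mask", f"mask_final_vessel_{method.lower()}", vm.data)
        _done(stage)

        stage = "roi-report"
        report = hemispheric_roi_stats(
            absolute, brain, csf, vessel_by_method[first]
        )
        if config.write_outputs:
            report_path = out_dir / "roi_report.csv"
            report.to_csv(report_path, index=False)
            manifest.outputs.append(str(report_path))
        _done(stage)

        if config.write_outputs and config.phantom is not None:
            series_path = out_dir / "series.nii"
            write_series(series, series_path, extra_meta={"seed": config.seed})
            manifest.outputs.append(str(series_path))

        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        if config.write_outputs:
            (out_dir / "manifest.json").write_text(manifest.to_json())
            manifest.outputs.append(str(out_dir / "manifest.json"))
        return manifest

    except PipelineStageError:
        raise
    except Exception as exc:
        if config.write_outputs:
            manifest.finished = f"failed at {stage}"
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "manifest.partial.json").write_text(manifest.to_json())
        raise PipelineStageError(stage, exc) from exc
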