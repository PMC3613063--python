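"""NIfTI-1 reading/writing with YAML/JSON sidecars for TR/TE metadata."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .types import ParametricMap, PerfusionSeries, VoxelMask

__all__ = [
    "read_series",
    "write_series",
    "write_map",
    "write_mask",
    "sidecar_path",
]


def sidecar_path(path: Path) -> Path | None:
    """Locate a .json or .yaml sidecar next to a NIfTI file, if any."""
    path = Path(path)
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    for ext in (".json", ".yaml", ".yml"):
        cand = path.with_name(stem + ext)
        if cand.exists():
            return cand
    return None


def _load_sidecar(path: Path) -> dict:
    text = Path(path).read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_series(
    path: str | Path, tr: float | None = None, te: float | None = None
) -> PerfusionSeries:
    """Load a 4-D perfusion series; TR/TE come from the sidecar if present
    (sidecar wins over the arguments), else from the arguments."""
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4-D (x, y, slice, dynamic) volume, got shape {data.shape}"
        )
    side = sidecar_path(path)
    meta = _load_sidecar(side) if side else {}
    tr = meta.get("tr", tr)
    te = meta.get("te", te)
    if tr is None:
        raise ValueError("TR not found in sidecar; pass tr= (CLI: --tr)")
    if te is None:
        raise ValueError("TE not found in sidecar; pass te= (CLI: --te)")
    if "n_dynamics" in meta and int(meta["n_dynamics"]) != data.shape[3]:
        raise ValueError(
            f"sidecar n_dynamics={meta['n_dynamics']} does not match the "
            f"data ({data.shape[3]} dynamics)"
        )
    return PerfusionSeries(data, tr=float(tr), te=float(te))


def _save_nifti(data: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine=np.eye(4)), str(path))


def write_series(
    series: PerfusionSeries, path: str | Path, extra_meta: dict | None = None
) -> Path:
    """Write the series plus a JSON sidecar with TR/TE/n_dynamics."""
    path = Path(path)
    _save_nifti(series.data, path)
    meta = {"tr": series.tr, "te": series.te, "n_dynamics": series.n_dynamics}
    if extra_meta:
        meta.update(extra_meta)
    side = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    side.write_text(json.dumps(meta, indent=2))
    return path


def write_map(pmap: ParametricMap, path: str | Path) -> Path:
    path = Path(path)
    _save_nifti(pmap.data, path)
    side = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    side.write_text(
        json.dumps(
            {"quantity": pmap.quantity, "units": pmap.units, "method": pmap.method},
            indent=2,
        )
    )
    return path


def write_mask(mask_data: np.ndarray, path: str | Path, legend: dict | None = None) -> Path:
    """Write a boolean or integer-coded mask as an integer NIfTI volume."""
    path = Path(path)
    _save_nifti(np.asarray(mask_data, dtype=np.int16), path)
    if legend:
        side = path.with_name(
            path.name.removesuffix(".gz").removesuffix(".nii") + ".json"
        )
        side.write_text(json.dumps(legend, indent=2))
    return path
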