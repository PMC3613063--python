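"""In-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from . import constants


class MaskLabel(str, Enum):
    BRAIN = "BRAIN"
    CSF = "CSF"
    PRELIM_VESSEL = "PRELIM_VESSEL"
    NORMAL_BRAIN = "NORMAL_BRAIN"
    FINAL_VESSEL = "FINAL_VESSEL"


class TissueLabel(str, Enum):
    GM = "GM"
    WM = "WM"
    CSF = "CSF"
    VESSEL = "VESSEL"
    BACKGROUND = "BACKGROUND"


@dataclass
class PerfusionSeries:
    """Raw 4-D bolus-tracking signal, axes (x, y, slice, dynamic)."""

    data: np.ndarray
    tr: float
    te: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected a 4-D (x, y, slice, dynamic) array, got ndim={self.data.ndim}"
            )
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("tr and te must be positive (seconds)")
        if np.any(self.data < 0):
            raise ValueError("signal intensities must be non-negative")

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ConcentrationSeries:
    """Voxelwise contrast-concentration curves C(t), arbitrary units."""

    data: np.ndarray
    baseline: np.ndarray
    tr: float
    te: float
    k1: float = constants.K1

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class VoxelMask:
    """Boolean 3-D mask plus the rule that produced it."""

    data: np.ndarray
    label: MaskLabel
    provenance: str = ""
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class ParametricMap:
    """A 3-D scalar perfusion map (rCBV, rCBF, TTP, CBV, CBF or MTT)."""

    data: np.ndarray
    quantity: str
    units: str
    method: str = "none"      # "none", "sSVD" or "cSVD"
    flags: Optional[np.ndarray] = None   # QC mask for degenerate voxels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("parametric map must be 3-D")


@dataclass
class ArterialInputFunction:
    """Arterial concentration-time curve used as deconvolution kernel."""

    curve: np.ndarray
    source_voxels: list[tuple[int, int, int]]
    method: str = "AUTO"      # "AUTO" or "MANUAL"

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if self.curve.ndim != 1:
            raise ValueError("AIF curve must be 1-D")
        if self.curve.max() <= 0:
            raise ValueError("AIF peak must be positive")
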