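"""Synthetic bolus-tracking phantoms with known ground-truth perfusion.

The phantom is a layered two-hemisphere slab: a cortical gray-matter ring
around a white-matter core, paraventricular CSF pockets, and a small
vessel block per hemisphere, surrounded by zero-signal background.  Each
perfused voxel's concentration curve is produced by the exact discrete
forward model the deconvolution stage inverts:

    C_tissue(t_i) = (rho/k_H) * TR * sum_j AIF(t_j) * f(t_i - t_j),

with f(t) = (CBF/60) * exp(-t / MTT) and MTT = CBV/CBF * 60 s, so the
central-volume theorem holds by construction and the pipeline's relative
CBV comes out directly in mL/100 g.  Flow is carried in per-second units
(CBF/60) so that the area of f equals CBV.

Signal is rendered as a T2*-weighted exponential, S(t) = S0 exp(-TE C(t)),
with the first dynamic multiplied by a class-specific factor emulating the
T1-saturation excess that makes CSF bright in the first source image, and
optional additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import constants
from .types import MaskLabel, ParametricMap, PerfusionSeries, TissueLabel, VoxelMask

__all__ = [
    "TissueClassSpec",
    "PhantomConfig",
    "PhantomDataset",
    "gamma_variate_aif",
    "synthesize_tissue_curve",
    "render_signal",
    "build_phantom",
    "default_class_specs",
]


@dataclass
class TissueClassSpec:
    """Ground-truth perfusion parameters for one tissue class."""

    label: TissueLabel
    cbv_true: float          # mL/100 g
    cbf_true: float          # mL/100 g/min
    delay: float = 0.0       # s, bolus arrival offset vs the AIF
    s0: float = 1000.0       # baseline signal, arbitrary units
    first_image_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.cbv_true < 0 or self.cbf_true < 0:
            raise ValueError("cbv_true and cbf_true must be non-negative")
        if self.label is TissueLabel.CSF and (self.cbv_true != 0 or self.cbf_true != 0):
            raise ValueError("CSF must have zero perfusion")

    @property
    def mtt_true(self) -> float:
        """Mean transit time in seconds; 0 for unperfused classes."""
        if self.cbf_true == 0:
            return 0.0
        return self.cbv_true / self.cbf_true * 60.0


def default_class_specs() -> dict[TissueLabel, TissueClassSpec]:
    """Literature-anchored defaults: GM 4 & 50, WM 2 & 25, vessels 5-fold
    higher, CSF unperfused with a 3x first-image signal excess."""
    return {
        TissueLabel.GM: TissueClassSpec(TissueLabel.GM, 4.0, 50.0),
        TissueLabel.WM: TissueClassSpec(TissueLabel.WM, 2.0, 25.0),
        TissueLabel.CSF: TissueClassSpec(
            TissueLabel.CSF, 0.0, 0.0, s0=800.0, first_image_ratio=3.0
        ),
        TissueLabel.VESSEL: TissueClassSpec(TissueLabel.VESSEL, 20.0, 250.0),
        TissueLabel.BACKGROUND: TissueClassSpec(
            TissueLabel.BACKGROUND, 0.0, 0.0, s0=0.0
        ),
    }


@dataclass
class PhantomConfig:
    """Full recipe for one synthetic dataset; the seed makes it bit-reproducible."""

    shape: tuple[int, int, int] = (48, 48, 3)
    n_dynamics: int = constants.DEFAULT_N_DYNAMICS
    tr: float = constants.DEFAULT_TR
    te: float = constants.DEFAULT_TE
    # gamma-variate bolus: amplitude * (t - t0)^alpha * exp(-(t - t0)/beta);
    # amplitude set so the GM peak signal drop is ~1/3 of baseline at the
    # default TE, typical of a full-dose EPI bolus passage
    aif_amplitude: float = 0.6
    aif_t0: float = 10.0
    aif_alpha: float = 3.0
    aif_beta: float = 1.5
    noise_sigma: float = 5.0
    seed: int = 0
    class_specs: dict = field(default_factory=default_class_specs)
    # hemisphere impairment: extra bolus delay (s) and flow scaling applied
    # to every perfused voxel in the right hemisphere (x >= nx/2)
    impaired_delay: float = 0.0
    impaired_cbf_scale: float = 1.0
    # vessel voxels show the arterial concentration itself (undispersed),
    # as real arterial voxels do, instead of a convolved tissue curve
    vessel_carries_aif: bool = False
    gm_ring_width: int = 8
    border: int = 2

    def __post_init__(self) -> None:
        if self.n_dynamics < 12:
            raise ValueError(
                "n_dynamics must be >= 12 so the baseline and integration "
                "windows are representable"
            )
        csf = self.class_specs.get(TissueLabel.CSF)
        if csf is not None:
            others = [
                s.first_image_ratio
                for lab, s in self.class_specs.items()
                if lab not in (TissueLabel.CSF, TissueLabel.BACKGROUND)
            ]
            if others and csf.first_image_ratio <= max(others):
                raise ValueError(
                    "CSF first_image_ratio must exceed that of every other class"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["class_specs"] = {
            lab.value: {**asdict(spec), "label": lab.value}
            for lab, spec in self.class_specs.items()
        }
        return d


@dataclass
class PhantomDataset:
    """A rendered phantom plus everything needed to grade recovery."""

    series: PerfusionSeries
    truth_maps: dict[str, ParametricMap]
    truth_masks: dict[TissueLabel, VoxelMask]
    aif_true: np.ndarray
    config: PhantomConfig
    concentration_true: np.ndarray   # noise-free C(t), 4-D


def gamma_variate_aif(
    t: np.ndarray, amplitude: float, t0: float, alpha: float, beta: float
) -> np.ndarray:
    """Gamma-variate bolus A*(t-t0)^alpha*exp(-(t-t0)/beta), zero before t0.

    The analytic peak sits at t0 + alpha*beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    curve = np.zeros_like(t)
    pos = dt > 0
    curve[pos] = amplitude * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return curve


def synthesize_tissue_curve(
    aif: np.ndarray, cbv_true: float, cbf_true: float, delay: float, tr: float
) -> np.ndarray:
    """Forward-model a tissue concentration curve from the AIF.

    Discrete causal convolution of the (integer-sample) delayed AIF with
    the flow-scaled residue f(t) = F * exp(-t/MTT); the (rho/k_H)*TR
    prefactor matches the deconvolution operator exactly.  The discrete
    flow amplitude is F = (cbf/60) * (1 - exp(-TR/MTT))/(TR/MTT), i.e. the
    per-second flow times the rectangle-rule correction that makes the
    residue sum TR*sum(f) carry exactly CBV of area — the discrete
    analogue of the central-volume theorem, so
    area(C)/area(AIF) * (k_H/rho) = CBV up to the window tail.
    """
    if cbv_true < 0 or cbf_true < 0:
        raise ValueError("cbv_true and cbf_true must be non-negative")
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    if cbv_true == 0 or cbf_true == 0:
        return np.zeros(n)
    mtt = cbv_true / cbf_true * 60.0
    t = np.arange(n) * tr
    a = tr / mtt
    residue_flow = (cbf_true / 60.0) * ((1.0 - np.exp(-a)) / a) * np.exp(-t / mtt)
    shift = int(round(delay / tr))
    aif_shifted = np.zeros(n)
    if shift < n:
        aif_shifted[shift:] = aif[: n - shift]
    return constants.RHO_OVER_KH * tr * np.convolve(aif_shifted, residue_flow)[:n]


def render_signal(
    concentration: np.ndarray,
    s0: float,
    te: float,
    first_image_ratio: float = 1.0,
    noise_sigma: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Render a T2*-weighted signal curve S(t) = s0*exp(-TE*C(t)).

    Dynamic 1 is scaled by ``first_image_ratio`` (T1-saturation excess);
    Gaussian noise of std ``noise_sigma`` is added and the result clipped
    at zero.  Noise is drawn from ``rng`` if given, else from ``seed``.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    c = np.asarray(concentration, dtype=float)
    signal = s0 * np.exp(-te * c)
    signal[..., 0] = signal[..., 0] * first_image_ratio
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, size=signal.shape)
    return np.clip(signal, 0.0, None)


def _layout(config: PhantomConfig) -> np.ndarray:
    """Per-voxel tissue labels as a fixed-width string array."""
    nx, ny, nz = config.shape
    b = config.border
    w = config.gm_ring_width
    inner = (slice(b + w, nx - b - w), slice(b + w, ny - b - w))
    if inner[0].start >= inner[0].stop or inner[1].start >= inner[1].stop:
        raise ValueError("grid too small for the configured border and GM ring")

    labels = np.full((nx, ny, nz), TissueLabel.BACKGROUND.value, dtype="U10")
    labels[b : nx - b, b : ny - b, :] = TissueLabel.GM.value
    labels[inner[0], inner[1], :] = TissueLabel.WM.value

    # paraventricular CSF pockets, mirrored about the x midline
    cx, cy = nx // 2, ny // 2
    csf_hw, csf_hh = 2, 5
    for x0 in (cx - 2 - 2 * csf_hw, cx + 2):
        sl = (slice(x0, x0 + 2 * csf_hw), slice(cy - csf_hh, cy + csf_hh))
        _check_inside(sl, inner, "CSF")
        labels[sl[0], sl[1], :] = TissueLabel.CSF.value

    # one small vessel block per hemisphere, deep in the WM
    vx = inner[0].start + 2
    for x0 in (vx, nx - vx - 2):
        sl = (slice(x0, x0 + 2), slice(cy - 2, cy + 2))
        _check_inside(sl, inner, "VESSEL")
        labels[sl[0], sl[1], :] = TissueLabel.VESSEL.value
    return labels


def _check_inside(sl: tuple[slice, slice], inner: tuple[slice, slice], name: str) -> None:
    for s, lim in zip(sl, inner):
        if s.start < lim.start or s.stop > lim.stop:
            raise ValueError(f"{name} region exceeds the phantom interior")


def build_phantom(config: PhantomConfig) -> PhantomDataset:
    """Assemble the full synthetic dataset: series, truth maps, truth masks."""
    nx, ny, nz = config.shape
    n = config.n_dynamics
    t = np.arange(n) * config.tr
    aif = gamma_variate_aif(
        t, config.aif_amplitude, config.aif_t0, config.aif_alpha, config.aif_beta
    )

    labels = _layout(config)
    right = np.zeros(config.shape, dtype=bool)
    right[nx // 2 :, :, :] = True

    conc = np.zeros((nx, ny, nz, n))
    s0_vol = np.zeros(config.shape)
    fir_vol = np.ones(config.shape)
    cbv_map = np.zeros(config.shape)
    cbf_map = np.zeros(config.shape)
    delay_map = np.zeros(config.shape)

    # one curve per (class, hemisphere) is enough: broadcast to voxels
    for lab, spec in config.class_specs.items():
        cls = labels == lab.value
        if not cls.any():
            continue
        s0_vol[cls] = spec.s0
        fir_vol[cls] = spec.first_image_ratio
        for side, side_mask in (("L", cls & ~right), ("R", cls & right)):
            if not side_mask.any():
                continue
            impaired = side == "R" and lab in (TissueLabel.GM, TissueLabel.WM,
                                               TissueLabel.VESSEL)
            cbf = spec.cbf_true * (config.impaired_cbf_scale if impaired else 1.0)
            delay = spec.delay + (config.impaired_delay if impaired else 0.0)
            cbv_map[side_mask] = spec.cbv_true
            cbf_map[side_mask] = cbf
            delay_map[side_mask] = delay
            if lab is TissueLabel.VESSEL and config.vessel_carries_aif:
                shift = int(round(delay / config.tr))
                curve = np.zeros(n)
                if shift < n:
                    curve[shift:] = aif[: n - shift]
            else:
                curve = synthesize_tissue_curve(
                    aif, spec.cbv_true, cbf, delay, config.tr
                )
            conc[side_mask] = curve

    mtt_map = np.zeros(config.shape)
    perfused = cbf_map > 0
    mtt_map[perfused] = cbv_map[perfused] / cbf_map[perfused] * 60.0

    lo, hi = constants.INTEGRATION_WINDOW
    hi = min(hi, n)
    ttp_map = np.argmax(conc[..., lo:hi], axis=-1) * config.tr + lo * config.tr

    rng = np.random.default_rng(config.seed)
    signal = s0_vol[..., None] * np.exp(-config.te * conc)
    signal[..., 0] *= fir_vol
    if config.noise_sigma > 0:
        signal = signal + rng.normal(0.0, config.noise_sigma, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    series = PerfusionSeries(signal, tr=config.tr, te=config.te)
    truth_maps = {
        "CBV": ParametricMap(cbv_map, "CBV", "mL/100 g"),
        "CBF": ParametricMap(cbf_map, "CBF", "mL/100 g/min"),
        "MTT": ParametricMap(mtt_map, "MTT", "s"),
        "TTP": ParametricMap(ttp_map, "TTP", "s"),
    }
    truth_masks = {
        lab: VoxelMask(labels == lab.value, MaskLabel.BRAIN, provenance=f"truth:{lab.value}")
        for lab in TissueLabel
    }
    return PhantomDataset(
        series=series,
        truth_maps=truth_maps,
        truth_masks=truth_masks,
        aif_true=aif,
        config=config,
        concentration_true=conc,
    )
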