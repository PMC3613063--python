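# Methods

## Model and procedure

`dscquant` implements indicator-dilution quantification of
dynamic-susceptibility-contrast (DSC) perfusion MRI. The T2\*-weighted
signal drop during bolus passage is converted to tracer concentration,
C(t) = −(k₁/TE)·ln(S(t)/S₀); the published form of this relation carries
no minus sign, which makes concentration negative during the bolus, so the
standard negated form is used and noted here. k₁ is a proportionality
factor that cancels in every downstream ratio and is fixed at 1. S₀ is the
voxelwise mean of the 6th–10th dynamics (0-based half-open window
[5, 10)); the concentration integrals run over the 11th–70th dynamics
([10, 70), clamped to the series length). The conversion floors S(t) at
10⁻³·S₀ before the logarithm so noise excursions to zero in high-uptake
vessel voxels cannot produce infinities.

Relative blood volume is rCBV = (k_H/ρ)·ΣC/ΣAIF with k_H/ρ = 0.705 cc/g
(hematocrit correction k_H = 0.73, brain density ρ = 1.04 g/cc). Flow is
recovered by deconvolving C_tissue(t) = (ρ/k_H)·AIF ⊗ [rCBF·R(t)]:
the discrete operator is (ρ/k_H)·TR·Toeplitz(AIF) (sSVD) or the circulant
matrix of the AIF zero-padded to twice its length (cSVD); inverse singular
values below a truncation fraction of the largest are zeroed; rCBF is the
maximum of the recovered signed curve (the rare all-negative voxels are
clamped to zero and flagged). TTP is the time of the concentration maximum
within the integration window, in seconds from series start, first
occurrence winning ties; flat non-positive curves get the window start and
a QC flag, and are excluded from every TTP median. MTT = CBV/CBF with a
factor 60 when CBF is per minute; `compute_mtt` takes an explicit
flow-units argument because relative flow from deconvolution is per
second. Voxels with CBF below 0.01 get MTT = 0 and a flag.

The automatic scaling chain: Otsu brain mask on the first dynamic → CSF
mask on the first-image/baseline ratio image (CSF, unsaturated in the
first source image, is the high-ratio class; Otsu threshold over the
within-brain ratio distribution, whole-volume) → preliminary vessel mask
at twice the median rCBV or rCBF over brain-minus-CSF → normal-parenchyma
mask as the remaining voxels with TTP in [median − 3 s, median], both ends
inclusive so the median voxel itself is kept → SF_CBV = 3.2/mean(rCBV) and
SF_CBF = 40/mean(rCBF) over that mask, CBF per deconvolution method →
absolute maps; MTT is recomputed from the scaled CBV and CBF rather than
scaled directly, because the two factors differ in general. Final vessel
removal uses fixed absolute thresholds, CBV > 8 mL/100 g or
CBF > 100 mL/100 g/min, strict inequalities, with a 3-category mask
(CBV-only / CBF-only / both). Hemispheric ROI statistics are reported for
four cumulative conditions (all brain, CSF removed, vessels removed, both
removed); the default midline is the midpoint of the brain-mask bounding
box along the first in-plane axis, and an optional slice index stands in
for the anatomical lateral-ventricle plane.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k_H/ρ | 0.705 | cc/g | standard hematocrit/density correction |
| baseline window | dynamics 6–10 | — | pre-bolus steady state at a 1 s TR |
| integration window | dynamics 11–70 | — | bolus passage; clamped to series |
| composite CBV / CBF reference | 3.2 / 40 | mL/100 g, mL/100 g/min | 60/40 GM/WM mix of literature values (GM 4 & 50, WM 2 & 25) |
| TTP window | 3 | s | normal-transit spread below the median |
| preliminary vessel factor | 2× median | — | robust outlier rule on rCBV/rCBF |
| final thresholds | CBV > 8, CBF > 100 | absolute | fixed vessel criteria on scaled maps |
| truncation fraction | 0.20 (sSVD), 0.10 (cSVD) | — | community-standard noise suppression |
| cSVD pad factor | 2 | — | avoids cyclic wrap of delayed curves |
| CSF ratio floor | 1.15 | — | see below |
| AIF voxel count k | 10 | — | averaging arterial candidates |

All are CLI-configurable; defaults live in `dscquant/constants.py`.

## Arterial input function

Arterial-voxel selection by independent component analysis is out of
scope; the automatic selector ranks brain voxels by a composite z-score
(early TTP, high peak concentration, narrow first-moment width, equal
weights), averages the top k = 10 curves, and is deterministic. An
explicit voxel list bypasses scoring. Because every downstream quantity is
either a ratio against the AIF or normalized through the scaling factors,
the pipeline's absolute outputs are invariant to the overall scale of the
selected AIF; AIF shape errors (dispersion of the arterial curve) bias all
tissue classes by a common factor that the scaling also absorbs when
transit times are comparable.

## The synthetic phantom

The phantom is a two-hemisphere slab: a cortical gray-matter ring (CBV 4,
CBF 50), a white-matter core (2, 25), paraventricular CSF pockets (zero
perfusion, baseline 800, first-image ratio 3 emulating the T1-saturation
excess of unsaturated CSF in the first source image), one vessel block per
hemisphere (20, 250) and zero-signal background. The gray-ring width is
chosen so parenchyma is ≈60/40 GM/WM, matching the composition the scaling
step assumes. The bolus is a gamma-variate, A·(t−t₀)^α·e^(−(t−t₀)/β) with
t₀ = 10 s, α = 3, β = 1.5 s and amplitude 0.6, which at TE = 40 ms gives a
~33% peak signal drop in gray matter — a typical full-dose EPI regime.
Acquisition defaults: TR = 1 s, TE = 40 ms, 70 dynamics. Noise is additive
Gaussian on the signal (σ = 5 on a baseline of 1000), seeded and
bit-reproducible; a Rician regime is not simulated because at these SNRs
the two are indistinguishable away from the background.

Tissue curves are produced by the exact discrete forward model that the
deconvolution inverts: the residue is mono-exponential, R(t) = e^(−t/MTT)
with MTT = CBV/CBF·60 (the residue is estimated, not assumed, by the
pipeline itself — the choice matters only for the generator), and the
discrete flow amplitude carries the rectangle-rule correction
(1 − e^(−TR/MTT))/(TR/MTT) so the residue sum holds exactly CBV of area.
This makes the discrete central-volume theorem hold to the window tail
(<0.1%): concentration-curve area over AIF area times k_H/ρ returns CBV,
and the generator-vs-operator identity `A @ f == synthesize_tissue_curve`
is exact. The default classes share MTT = 4.8 s, so the method-specific
truncation bias in recovered flow is a class-common factor that the
scaling factors cancel; scaled per-class recovery on a zero-noise phantom
is then limited only by the small mismatch between the phantom's actual
GM fraction (0.626) and the assumed 0.6 (≈1.6% on CBV/CBF means).

An impaired-hemisphere option adds a bolus delay (integer samples) and a
flow scale to one side, emulating carotid stenosis; a
`vessel_carries_aif` option makes vessel voxels show the undispersed
arterial curve itself, as real arterial voxels do, which is the regime the
AIF-selector accuracy test uses. What the phantom does **not** model:
contrast recirculation and leakage, partial-volume mixing, motion, EPI
artifacts. Clinical scaling factors (≈0.2 for CBV) therefore are not
numerically reproduced — phantom concentration units are arbitrary — and
passing tests demonstrate internal consistency and segmentation behaviour,
not robustness to those clinical confounds.

## Numerical choices

- **Otsu threshold.** Computed from a 256-bin histogram by exhaustive
  maximization of the between-class variance. When several split points
  attain the maximum — a flat valley between well-separated modes — the
  mean of the maximizing bin centers is used, placing the threshold
  mid-gap. (A first-argmax tie-break, as in some library implementations,
  puts the threshold at the foot of the dominant mode, which misbehaves
  when the upper class holds only a few percent of the voxels, exactly the
  CSF situation.) Thresholds are shift-equivariant by construction.
- **CSF ratio floor.** With no CSF present the within-brain ratio
  distribution is unimodal around 1 and a forced histogram split would
  flag half the brain. The CSF threshold is therefore floored at 1.15: the
  T1-saturation excess is a large positive offset over unity, and nothing
  below the floor is anatomically plausible CSF. A polarity switch is
  provided for acquisitions where CSF is dark in the first image.
- **Truncation in validation.** The truncation defaults suppress noise at
  clinical SNR and bias a noise-free delta low (the AIF deconvolved by
  itself peaks at 0.32 rather than 0.705 at the 0.20 default). Oracle
  tests on noise-free curves therefore use truncation fractions of
  10⁻⁴–0.05, where recovery is near-exact; pipeline-level recovery checks
  run at the defaults, where the bias cancels through the scaling factors.
- **Delays** are applied in integer samples (TR quanta); sub-sample delay
  interpolation is not implemented.
- **Degenerate inputs.** Constant inputs to Otsu, empty masks, all-zero
  operators and empty TTP windows raise informative errors; an absent CSF
  class yields an empty mask with a warning, not an error.
- **Mann-Whitney U.** Implemented from the rank definition with average
  ranks for ties. For groups of ≤8 the two-sided p comes from exact
  enumeration of all C(n_a+n_b, n_a) assignments of the observed pooled
  values (ties included); otherwise the normal approximation with tie and
  continuity corrections is used.

## Problem sizes

The default phantom is 48×48×3 voxels × 70 dynamics (≈7,000 voxels), large
enough that every tissue class is represented by dozens to thousands of
voxels while a full two-method pipeline pass completes in well under a
second; the test suite and the acceptance script use this size throughout.

## Known limitations

- No leakage (K2) correction, no delay/dispersion correction beyond cSVD,
  no oscillation-index regularization.
- The 60/40 GM/WM composition is an assumption, not measured per subject;
  reference values are not age- or sex-stratified.
- Hemisphere splitting is geometric (bounding-box midline), not anatomical.
- The automatic AIF selector is a simple composite score, not an ICA
  decomposition; on data whose arterial voxels are heavily dispersed it
  returns a dispersed kernel, which the scaling step compensates only in
  aggregate.
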