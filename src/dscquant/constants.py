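"""Frozen defaults for the perfusion-quantification pipeline.

Every threshold and physical constant used anywhere in the package lives
here, so a run is fully characterized by these values plus the explicit
overrides recorded in its manifest.
"""

# Physical constants relating tracer concentration integrals to blood
# volume: k_H corrects for the large-/small-vessel hematocrit difference,
# rho is the density of brain tissue.
HEMATOCRIT_CORRECTION = 0.73          # k_H, dimensionless
BRAIN_DENSITY = 1.04                  # rho, g/cc
KH_OVER_RHO = 0.705                   # k_H / rho, cc/g
RHO_OVER_KH = 1.0 / KH_OVER_RHO

# Acquisition defaults (gradient-echo EPI bolus tracking).
DEFAULT_TR = 1.0                      # s
DEFAULT_TE = 0.040                    # s
DEFAULT_N_DYNAMICS = 70

# Dynamic windows, 0-based half-open.  The field convention counts
# dynamics from 1: baseline = mean of the 6th..10th images, and the
# concentration integral runs over the 11th..70th images.  The upper
# integration bound is clamped to the actual number of dynamics.
BASELINE_WINDOW = (5, 10)
INTEGRATION_WINDOW = (10, 70)

# Eq.-(1) conversion: proportionality factor (cancels in every ratio the
# pipeline forms) and the relative signal floor applied before the log.
K1 = 1.0
SIGNAL_FLOOR_FRACTION = 1e-3

# Literature reference values for normal tissue, used to build the
# composite references (60% gray / 40% white) that anchor the scaling
# factors: composite CBV = 3.2 mL/100 g, composite CBF = 40 mL/100 g/min.
REF_CBV_GM = 4.0                      # mL/100 g
REF_CBV_WM = 2.0                      # mL/100 g
REF_CBF_GM = 50.0                     # mL/100 g/min
REF_CBF_WM = 25.0                     # mL/100 g/min
GM_FRACTION = 0.6

# Normal-parenchyma segmentation: voxels within this window below the
# median time-to-peak are kept.
TTP_WINDOW_S = 3.0

# Preliminary vessel removal: multiples of the median rCBV / rCBF.
PRELIM_VESSEL_MEDIAN_FACTOR = 2.0

# Final vessel removal thresholds on the absolute maps (strict >).
FINAL_CBV_THRESHOLD = 8.0             # mL/100 g
FINAL_CBF_THRESHOLD = 100.0           # mL/100 g/min

# Truncated-SVD deconvolution defaults.
DEFAULT_TRUNCATION_SSVD = 0.20
DEFAULT_TRUNCATION_CSVD = 0.10
DEFAULT_PAD_FACTOR = 2

# MTT is undefined where flow vanishes; voxels below this CBF floor
# (mL/100 g/min for absolute maps, same units as the map otherwise)
# get MTT = 0 and a QC flag.
MTT_CBF_FLOOR = 0.01

# CSF detection: the first-image/baseline ratio threshold never drops
# below 1 + this excess, so a CSF-free brain (unimodal ratio ~= 1) does
# not get half its voxels flagged by a forced histogram split.
CSF_MIN_RATIO_EXCESS = 0.15
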