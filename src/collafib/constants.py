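"""Named constants shared across the package.

Physical constants are pinned to the rounded values used throughout the
dosimetry arithmetic (so printed-precision round trips are exact); phantom
label cutoffs are the generator's convention and are referenced by both the
synthetic generators and the texture tests.
"""

# --- physical constants (pinned rounding) ---
ELEMENTARY_CHARGE_C = 1.602e-19
PLANCK_J_S = 6.626e-34
SPEED_OF_LIGHT_M_S = 2.998e8

# --- AFM image grid ---
PX_PER_UM = 51            # sampling density of a standard scan
ROI_PX = 51               # 1 um x 1 um patch edge, in pixels
PX_SIZE_NM = 1000.0 / PX_PER_UM

# canonical axial repeat of native collagen fibrils
DBAND_PERIOD_NM = 67.0

# --- phantom ground-truth label cutoffs ---
# A phantom's ROI labels are derived from its generating parameters, never
# from rendered pixels.  Tests place phantoms unambiguously on either side
# of these cutoffs.
DBAND_DEPTH_MIN = 0.10       # banding label false below this modulation depth
DBAND_BLUR_MAX_NM = 25.0     # banding label false above this blur sigma
CLARITY_BLUR_MAX_NM = 40.0   # clarity label false above this blur sigma
CLARITY_NOISE_MAX_NM = 8.0   # clarity label false above this noise sigma

# --- LDA regularization ---
# ridge added to the pooled covariance diagonal, as a fraction of the mean
# diagonal element; guarantees positive-definiteness on small training sets
LDA_RIDGE_DEFAULT = 1e-3
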