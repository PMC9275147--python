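"""Default study conditions: stimulus grids, analysis windows, and ground-truth
parameter tables used by the synthetic generator.

All geometry is in degrees of visual angle, spatial frequency in cycles/degree
(cpd), speed in degrees/second, time in milliseconds after stimulus onset.
"""

from __future__ import annotations

import numpy as np

# 12-step disk diameter grid (degrees), 3.55-53.25
DISK_DIAMETERS = (
    3.55, 7.1, 10.65, 14.20, 17.75, 21.3,
    24.85, 28.4, 31.95, 39.05, 46.15, 53.25,
)

# Ring stimuli: fixed 60 deg outer aperture, inner diameters on the same grid
RING_OUTER_DIAMETER = 60.0
RING_INNER_DIAMETERS = DISK_DIAMETERS

# Supplementary small-diameter set (1-7.1 deg) for the three highest SFs.
# Six log-spaced values sharing 3.55 and 7.1 with the main grid so the merged
# curve has 16 unique points after rescaling at the common 7.1 deg diameter.
SMALL_DIAMETERS = (1.0, 1.78, 2.37, 3.55, 5.33, 7.1)
MERGE_COMMON_DIAMETER = 7.1

SF_SET = (0.12, 0.18, 0.36, 0.72, 1.06, 1.41)    # cpd
HIGH_SF_SET = (0.72, 1.06, 1.41)                 # supplementary experiment
SPEED_SET = (15.0, 30.0, 45.0)                   # deg/s
DEFAULT_SF = 0.36
DEFAULT_SPEED = 30.0

# Annulus-mask control: thin mean-luminance ring over the full 60 deg grating
MASK_WIDTH = 3.4

DIRECTIONS = ("rightward", "leftward")

# Open-loop analysis windows (ms after stimulus onset)
WINDOWS_10MS = ((60, 70), (70, 80), (80, 90), (90, 100), (100, 110), (110, 120))
WINDOWS_20MS = ((45, 65), (65, 85), (85, 105))
REFERENCE_WINDOW = (85, 105)

# Response dynamics and noise of the generator
LATENCY_MS = 55.0          # monkey ocular following latency
RISE_MS = 40.0             # smoothstep rise to constant-velocity plateau
NOISE_SD = 0.005           # deg, per-sample position noise
DRIFT_SD = 0.1             # deg/s, blank-trial drift-rate SD
PRE_STIM_MS = 100          # fixation samples before onset
POST_STIM_MS = 250         # >= 220 ms stimulus epoch

# Trial-rejection defaults
FIXATION_LIMIT = 1.0       # deg
SACCADE_VELOCITY_LIMIT = 100.0  # deg/s (offline criterion; conventional choice)

# Model-free criterion levels
GSA_CRITERION = 0.95       # fraction of R_opt
SEXT_CRITERION = 0.05      # band around R_asy
AMD_CRITERION = 0.05       # band above the ring floor R_min

# Per-SF DoG summation parameter means (sigma_e, sigma_i, g_e, g_i).
# The 0.72 cpd surround gain (0.16) is internally inconsistent with its printed
# gi/ge ratio (0.56 -> ~0.009) and is flagged suspect: excluded from recovery
# fixtures and from the default simulation truth table.
DOG_TABLE = {
    0.12: (12.96, 25.21, 0.009, 0.008),
    0.18: (3.98, 11.84, 0.008, 0.005),
    0.36: (4.18, 7.6, 0.017, 0.009),
    0.72: (3.04, 5.43, 0.016, 0.16),
    1.06: (2.62, 4.85, 0.007, 0.004),
    1.41: (2.36, 4.88, 0.004, 0.001),
}
SUSPECT_SFS = (0.72,)

# Printed sigma_i/sigma_e ratio means per SF (same rows as DOG_TABLE)
SIGMA_RATIO_TABLE = {
    0.12: 2.15, 0.18: 3.03, 0.36: 1.85, 0.72: 2.10, 1.06: 2.98, 1.41: 2.36,
}

# Ring decay size constants (deg): anchors at the two SFs with printed values
TAU_ANCHORS = {0.18: 97.2, 1.41: 39.5}
TAU_MAX = 100.0            # upper bound on tau during fitting


def tau_default(sf: float) -> float:
    """Default decay size constant at ``sf``, from the exponential-decay
    family through the two printed anchors, clipped at the 100 deg bound."""
    (sf1, t1), (sf2, t2) = sorted(TAU_ANCHORS.items())
    b = (sf2 - sf1) / np.log(t1 / t2)
    a = t1 * np.exp(sf1 / b)
    return float(min(a * np.exp(-sf / b), TAU_MAX))
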