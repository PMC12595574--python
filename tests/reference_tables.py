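"""Published reference values for the urban-China family-physician-team
motivator study (15 factors F1–F15), at the 2-decimal precision they were
printed with: the total-relation matrix and the per-factor influence
profiles (R, C, prominence, relation, cause/effect group)."""

import numpy as np

# Total-relation matrix T, rows = influencing factor F1..F15.
TOTAL_RELATION = np.array([
    [0.51, 0.52, 0.57, 0.58, 0.60, 0.55, 0.55, 0.54, 0.54, 0.52, 0.51, 0.49, 0.50, 0.50, 0.50],
    [0.54, 0.43, 0.54, 0.55, 0.56, 0.51, 0.52, 0.50, 0.50, 0.49, 0.47, 0.45, 0.46, 0.46, 0.46],
    [0.57, 0.52, 0.51, 0.58, 0.60, 0.55, 0.56, 0.55, 0.54, 0.53, 0.51, 0.48, 0.49, 0.49, 0.49],
    [0.57, 0.51, 0.57, 0.50, 0.60, 0.54, 0.55, 0.53, 0.53, 0.52, 0.49, 0.47, 0.48, 0.48, 0.48],
    [0.60, 0.54, 0.59, 0.61, 0.56, 0.59, 0.60, 0.58, 0.57, 0.56, 0.53, 0.50, 0.52, 0.51, 0.52],
    [0.66, 0.59, 0.65, 0.66, 0.68, 0.56, 0.65, 0.62, 0.61, 0.60, 0.57, 0.55, 0.56, 0.55, 0.56],
    [0.63, 0.57, 0.63, 0.63, 0.65, 0.60, 0.55, 0.60, 0.60, 0.58, 0.55, 0.53, 0.54, 0.53, 0.54],
    [0.60, 0.54, 0.59, 0.60, 0.64, 0.59, 0.61, 0.52, 0.59, 0.57, 0.55, 0.52, 0.53, 0.52, 0.53],
    [0.61, 0.55, 0.61, 0.61, 0.64, 0.59, 0.61, 0.60, 0.52, 0.57, 0.55, 0.52, 0.53, 0.52, 0.54],
    [0.67, 0.60, 0.66, 0.67, 0.70, 0.65, 0.67, 0.65, 0.65, 0.56, 0.61, 0.59, 0.60, 0.59, 0.60],
    [0.66, 0.59, 0.65, 0.66, 0.69, 0.64, 0.65, 0.64, 0.64, 0.62, 0.53, 0.58, 0.58, 0.57, 0.59],
    [0.61, 0.55, 0.60, 0.61, 0.62, 0.59, 0.61, 0.58, 0.59, 0.57, 0.55, 0.47, 0.55, 0.53, 0.55],
    [0.63, 0.57, 0.62, 0.63, 0.65, 0.61, 0.63, 0.60, 0.60, 0.59, 0.57, 0.54, 0.49, 0.54, 0.56],
    [0.60, 0.54, 0.59, 0.61, 0.62, 0.58, 0.58, 0.56, 0.56, 0.56, 0.54, 0.51, 0.52, 0.46, 0.52],
    [0.60, 0.54, 0.60, 0.62, 0.63, 0.59, 0.61, 0.59, 0.60, 0.59, 0.56, 0.54, 0.54, 0.53, 0.48],
])

# factor_id -> (R, C, prominence R+C, relation R-C, group)
PROFILES = {
    "F1": (7.96, 9.05, 17.00, -1.09, "Effect"),
    "F2": (7.42, 8.16, 15.58, -0.73, "Effect"),
    "F3": (7.96, 8.96, 16.92, -1.01, "Effect"),
    "F4": (7.81, 9.10, 16.92, -1.29, "Effect"),
    "F5": (8.38, 9.41, 17.79, -1.03, "Effect"),
    "F6": (9.06, 8.75, 17.80, 0.31, "Cause"),
    "F7": (8.72, 8.94, 17.66, -0.21, "Effect"),
    "F8": (8.48, 8.65, 17.14, -0.17, "Effect"),
    "F9": (8.57, 8.64, 17.21, -0.07, "Effect"),
    "F10": (9.46, 8.42, 17.88, 1.04, "Cause"),
    "F11": (9.27, 8.07, 17.35, 1.20, "Cause"),
    "F12": (8.56, 7.72, 16.28, 0.84, "Cause"),
    "F13": (8.83, 7.87, 16.70, 0.96, "Cause"),
    "F14": (8.34, 7.79, 16.13, 0.56, "Cause"),
    "F15": (8.62, 7.92, 16.54, 0.70, "Cause"),
}

THRESHOLD = 0.566
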