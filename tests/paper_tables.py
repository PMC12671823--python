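"""Frozen reference values for the published worked examples.

Three biconvex IOLs measured on a wet-cell bench (n_ambient = 1.334,
n_iol = 1.46): dual-orientation back-vertex readings A (normal) and
B (flipped) in diopters and central thickness t in mm, plus the tabulated
radii the retrieval is expected to reproduce at 3-decimal precision.
"""

# lens label -> (A, B, t_mm)
LENSES = {
    "low": (15.72, 15.79, 0.85),
    "medium": (24.9, 25.1, 1.15),
    "high": (34.34, 33.71, 1.45),
}

N_IOL = 1.46
N_AMBIENT = 1.334

# Case 1 worked example: a single lens at d = 0.
CASE1 = {
    "A": 22.23,
    "B": 22.35,
    "t": 1.0,
    "P": 22.12,
    "P1": 7.20,
    "P2": 15.00,
    "R1": 17.51,
    "R2": -8.40,
}

# Spacing sweep, d = 0.00 .. 1.00 mm in 0.10 mm steps: (R1, R2) per row, mm.
OFFSET_TABLE = {
    "low": [
        (31.058, -10.812), (31.095, -10.825), (31.132, -10.838), (31.168, -10.850),
        (31.205, -10.863), (31.242, -10.876), (31.278, -10.889), (31.315, -10.901),
        (31.352, -10.914), (31.388, -10.927), (31.425, -10.939),
    ],
    "medium": [
        (17.028, -7.218), (17.059, -7.231), (17.091, -7.245), (17.123, -7.258),
        (17.155, -7.272), (17.187, -7.285), (17.218, -7.298), (17.250, -7.312),
        (17.282, -7.325), (17.314, -7.339), (17.346, -7.352),
    ],
    "high": [
        (4.848, -16.450), (4.860, -16.492), (4.872, -16.533), (4.884, -16.575),
        (4.897, -16.617), (4.909, -16.659), (4.921, -16.701), (4.933, -16.742),
        (4.945, -16.784), (4.958, -16.826), (4.970, -16.868),
    ],
}
OFFSET_GRID = [round(0.1 * i, 10) for i in range(11)]

# Thickness sweep at d = 0, delta_t in {-0.10, 0.00, +0.10, +0.20} mm.
THICKNESS_TABLE = {
    "low": [(35.496, -10.359), (31.058, -10.812), (28.271, -11.200), (26.359, -11.535)],
    "medium": [(18.207, -7.022), (17.028, -7.218), (16.151, -7.392), (15.474, -7.547)],
    "high": [(4.721, -18.062), (4.848, -16.450), (4.964, -15.266), (5.071, -14.359)],
}
THICKNESS_GRID = [-0.10, 0.00, 0.10, 0.20]

# Intrinsic powers quoted alongside the tables (d = 0).  The medium lens's
# quoted 24.76 D recomputes to 24.755 D and is a rounding slip; not asserted.
CAPTION_POWERS = {"low": 15.68, "high": 33.45}
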