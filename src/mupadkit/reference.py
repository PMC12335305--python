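"""Published characterisation data for the G/Pt-modified 3D origami μPAD.

These tables summarise the measured behaviour of the physical device —
colour-development time constants, static calibration performance, multiplex
HSV readings and manual-vs-automatic accuracy — and serve as reference inputs
for the analysis routines and their evaluation.  Keys for the catalyst are the
Pt-precursor molarity labels used during synthesis (0.0 = uncatalysed paper).
"""

from __future__ import annotations

#: Colour-development time constants τ (seconds) by reagent system, analyte
#: and G/Pt catalyst level.
TIME_CONSTANTS_S: dict[str, dict[str, dict[float, float]]] = {
    "FeCl3+phenanthroline": {
        "dopamine": {0.0: 306.891, 2.5: 17.761, 5.0: 16.066, 7.5: 16.719, 10.0: 6.689},
        "NADH": {0.0: 21.193, 2.5: 8.7190, 5.0: 5.5638, 7.5: 5.9603, 10.0: 4.5869},
    },
    # dopamine read with DNP, NADH with resazurin
    "DNP/resazurin": {
        "dopamine": {0.0: 971.34, 10.0: 66.34},
        "NADH": {0.0: 1305.45, 10.0: 979.446},
    },
}

#: Static sensing performance: (analyte, reagent, G/Pt mM) →
#: dict(sensitivity per mM, r_squared, lod mM, loq mM).
SENSING_PERFORMANCE: dict[tuple[str, str, float], dict[str, float]] = {
    ("dopamine", "FeCl3+phenanthroline", 2.5): {"sensitivity": 1.91, "r_squared": 0.97, "lod": 0.66, "loq": 1.99},
    ("dopamine", "FeCl3+phenanthroline", 5.0): {"sensitivity": 0.23, "r_squared": 0.32, "lod": 5.58, "loq": 16.90},
    ("dopamine", "FeCl3+phenanthroline", 7.5): {"sensitivity": 2.37, "r_squared": 0.97, "lod": 0.66, "loq": 2.00},
    ("dopamine", "FeCl3+phenanthroline", 10.0): {"sensitivity": 4.26, "r_squared": 0.98, "lod": 0.56, "loq": 1.70},
    ("dopamine", "DNP", 10.0): {"sensitivity": 0.55, "r_squared": 0.61, "lod": 4.03, "loq": 12.20},
    ("NADH", "FeCl3+phenanthroline", 2.5): {"sensitivity": 1.42, "r_squared": 0.90, "lod": 1.40, "loq": 4.23},
    ("NADH", "FeCl3+phenanthroline", 5.0): {"sensitivity": 1.64, "r_squared": 0.87, "lod": 1.62, "loq": 4.92},
    ("NADH", "FeCl3+phenanthroline", 7.5): {"sensitivity": 1.20, "r_squared": 0.91, "lod": 1.69, "loq": 5.12},
    ("NADH", "FeCl3+phenanthroline", 10.0): {"sensitivity": 1.61, "r_squared": 0.92, "lod": 1.20, "loq": 3.63},
    ("NADH", "resazurin", 10.0): {"sensitivity": 6.00, "r_squared": 0.94, "lod": 0.99, "loq": 2.99},
}

#: Multiplex test HSV readings and detected concentrations (mM); ``None``
#: marks a reagent that does not react with that analyte (non-selective route).
MULTIPLEX_HSV: dict[str, dict[str, float | None]] = {
    "FeCl3+phenanthroline": {"h": 42.27, "s": 46.20, "v": 92.18, "dopamine_mM": 9.62, "NADH_mM": 15.77},
    "resazurin": {"h": 263.08, "s": 51.38, "v": 73.50, "dopamine_mM": None, "NADH_mM": 8.02},
    "DNP": {"h": 30.94, "s": 14.35, "v": 91.41, "dopamine_mM": 9.77, "NADH_mM": None},
}

#: Manual (desktop tool) vs automatic (app) mean absolute percentage error (%)
#: for the multiplex accuracy test, by analyte and G/Pt level.
MAPE_SUMMARY: dict[str, dict[float, dict[str, float]]] = {
    "dopamine": {
        2.5: {"manual": 0.12, "automatic": 0.26},
        5.0: {"manual": 0.28, "automatic": 0.37},
        7.5: {"manual": 0.16, "automatic": 0.44},
        10.0: {"manual": 0.52, "automatic": 1.05},
    },
    "NADH": {
        2.5: {"manual": 0.06, "automatic": 0.04},
        5.0: {"manual": 0.05, "automatic": 0.05},
        7.5: {"manual": 0.03, "automatic": 0.05},
        10.0: {"manual": 0.07, "automatic": 0.04},
    },
}

#: Analyte concentration range (mM) over which the linear calibration holds.
LINEAR_RANGE_MM: tuple[float, float] = (0.01, 10.0)

#: Number of concentration levels used in the static calibration protocol.
N_CALIBRATION_LEVELS: int = 16
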