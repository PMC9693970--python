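"""Published reference values used as validation inputs.

Group-level summary statistics (per-group n, mean, SD) and the
corresponding published pooled-t results for all 50 gait variables of a
two-group (healthy vs Parkinson's disease) insole study.  Means and SDs
are as printed, rounded to 3 decimals; ``significant`` mirrors the
published star marking at the Bonferroni-corrected threshold of 0.001.

These rows serve as inputs to the summary-statistic t-test path — they are
never used to train or tune anything.
"""

from __future__ import annotations

from typing import Dict, List

#: (variable, block, n_hs, mean_hs, sd_hs, n_pd, mean_pd, sd_pd, t, df, significant)
GROUP_SUMMARY_ROWS: List[tuple] = [
    ("Gait Speed (m/s)", "kinematic", 88, 1.260, 0.166, 108, 1.019, 0.227, 8.278, 194, True),
    ("Time Up and Go (s)", "kinematic", 62, 9.300, 1.604, 90, 12.056, 3.962, -5.187, 150, True),
    ("Ave left SWING", "kinematic", 88, 0.442, 0.040, 108, 0.439, 0.046, 0.361, 194, False),
    ("Ave right SWING", "kinematic", 88, 0.443, 0.041, 108, 0.435, 0.047, 1.158, 194, False),
    ("Ave left SWING %", "kinematic", 88, 41.804, 3.143, 108, 40.781, 4.018, 1.951, 194, False),
    ("Ave right SWING %", "kinematic", 88, 41.916, 3.488, 108, 40.395, 4.284, 2.682, 194, False),
    ("Ave left STANCE", "kinematic", 88, 0.618, 0.071, 108, 0.646, 0.109, -2.127, 194, False),
    ("Ave right STANCE", "kinematic", 88, 0.616, 0.074, 108, 0.650, 0.109, -2.431, 194, False),
    ("Ave left STANCE %", "kinematic", 88, 58.196, 3.143, 108, 59.219, 4.018, -1.951, 194, False),
    ("Ave right STANCE %", "kinematic", 88, 58.084, 3.488, 108, 59.605, 4.284, -2.682, 194, False),
    ("Ave DOUBLE SUPPORT", "kinematic", 88, 0.115, 0.095, 108, 0.133, 0.120, -1.106, 194, False),
    ("Ave DOUBLE SUPPORT %", "kinematic", 88, 10.681, 8.528, 108, 11.734, 9.492, -0.808, 194, False),
    ("Med left SWING", "kinematic", 88, 0.441, 0.040, 108, 0.440, 0.048, 0.123, 194, False),
    ("Med right SWING", "kinematic", 88, 0.442, 0.041, 108, 0.436, 0.047, 0.963, 194, False),
    ("Med left SWING %", "kinematic", 88, 41.999, 3.195, 108, 41.029, 4.003, 1.844, 194, False),
    ("Med right SWING %", "kinematic", 88, 42.064, 3.487, 108, 40.655, 4.240, 2.502, 194, False),
    ("Med left STANCE", "kinematic", 88, 0.611, 0.069, 108, 0.638, 0.106, -2.043, 194, False),
    ("Med right STANCE", "kinematic", 88, 0.611, 0.073, 108, 0.642, 0.106, -2.303, 194, False),
    ("Med left STANCE %", "kinematic", 88, 58.001, 3.195, 108, 58.971, 4.003, -1.844, 194, False),
    ("Med right STANCE %", "kinematic", 88, 57.936, 3.487, 108, 59.345, 4.240, -2.502, 194, False),
    ("Med DOUBLE SUPPORT", "kinematic", 88, 0.113, 0.094, 108, 0.127, 0.110, -0.943, 194, False),
    ("Med DOUBLE SUPPORT %", "kinematic", 88, 10.483, 8.518, 108, 11.441, 9.368, -0.742, 194, False),
    ("SD left SWING", "kinematic", 88, 0.022, 0.009, 108, 0.032, 0.017, -4.851, 194, True),
    ("SD right SWING", "kinematic", 88, 0.022, 0.008, 108, 0.034, 0.025, -4.357, 194, True),
    ("SD left SWING %", "kinematic", 88, 1.686, 0.762, 108, 2.357, 1.254, -4.400, 194, True),
    ("SD right SWING %", "kinematic", 88, 1.568, 0.613, 108, 2.383, 1.127, -6.093, 194, True),
    ("SD left STANCE", "kinematic", 88, 0.035, 0.016, 108, 0.065, 0.170, -1.640, 194, False),
    ("SD right STANCE", "kinematic", 88, 0.033, 0.014, 108, 0.058, 0.135, -1.736, 194, False),
    ("SD left STANCE %", "kinematic", 88, 1.686, 0.762, 108, 2.357, 1.254, -4.400, 194, True),
    ("SD right STANCE %", "kinematic", 88, 1.568, 0.613, 108, 2.383, 1.127, -6.093, 194, True),
    ("SD DOUBLE SUPPORT", "kinematic", 88, 0.019, 0.015, 108, 0.045, 0.171, -1.441, 194, False),
    ("SD DOUBLE SUPPORT %", "kinematic", 88, 1.386, 0.718, 108, 2.072, 1.780, -3.396, 194, True),
    ("IQR left SWING", "kinematic", 88, 0.017, 0.006, 108, 0.027, 0.014, -6.651, 194, True),
    ("IQR right SWING", "kinematic", 88, 0.017, 0.006, 108, 0.027, 0.016, -5.821, 194, True),
    ("IQR left SWING %", "kinematic", 88, 1.326, 0.323, 108, 1.896, 0.799, -6.279, 194, True),
    ("IQR right SWING %", "kinematic", 88, 1.229, 0.337, 108, 1.905, 0.852, -7.009, 194, True),
    ("IQR left STANCE", "kinematic", 88, 0.026, 0.009, 108, 0.037, 0.020, -4.577, 194, True),
    ("IQR right STANCE", "kinematic", 88, 0.026, 0.009, 108, 0.037, 0.020, -4.902, 194, True),
    ("IQR left STANCE %", "kinematic", 88, 1.326, 0.323, 108, 1.896, 0.799, -6.279, 194, True),
    ("IQR right STANCE %", "kinematic", 88, 1.229, 0.337, 108, 1.905, 0.852, -7.009, 194, True),
    ("IQR DOUBLE SUPPORT", "kinematic", 88, 0.013, 0.008, 108, 0.018, 0.014, -2.875, 194, False),
    ("IQR DOUBLE SUPPORT %", "kinematic", 88, 1.141, 0.502, 108, 1.613, 1.203, -3.446, 194, True),
    ("Ave Force left", "dynamic", 88, 372.346, 181.982, 108, 392.385, 162.683, -0.813, 194, False),
    ("Ave Force right", "dynamic", 88, 369.036, 181.877, 108, 394.455, 158.804, -1.044, 194, False),
    ("Med Force left", "dynamic", 88, 467.395, 235.065, 108, 484.518, 210.938, -0.537, 194, False),
    ("Med Force right", "dynamic", 88, 459.291, 235.530, 108, 491.887, 209.364, -1.025, 194, False),
    ("SD Force left", "dynamic", 88, 324.871, 160.322, 108, 336.977, 141.656, -0.561, 194, False),
    ("SD Force right", "dynamic", 88, 324.106, 160.490, 108, 337.011, 136.732, -0.608, 194, False),
    ("IQR Force left", "dynamic", 88, 671.779, 332.736, 108, 706.230, 297.570, -0.764, 194, False),
    ("IQR Force right", "dynamic", 88, 671.246, 332.261, 108, 710.175, 288.892, -0.877, 194, False),
]

FIELDS = (
    "variable", "block", "n_hs", "mean_hs", "sd_hs",
    "n_pd", "mean_pd", "sd_pd", "t", "df", "significant",
)


def as_records() -> List[Dict]:
    """The reference rows as a list of dicts."""
    return [dict(zip(FIELDS, row)) for row in GROUP_SUMMARY_ROWS]


def get_row(variable: str) -> Dict:
    for row in GROUP_SUMMARY_ROWS:
        if row[0] == variable:
            return dict(zip(FIELDS, row))
    raise KeyError(variable)
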