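"""Reference cohort summary tables.

Published cross-tabulations and group summary statistics from the community
cohort (364 adults, 184 male / 180 female, aged 18-79) that this package's
default synthetic cohort emulates.  These are *inputs*: the contingency tables
feed the chi-square battery directly, and the group means / standard errors
parameterize the cohort generator.

Cognition columns are ordered NC, SCD, SCD-plus, MCI throughout.
"""

from __future__ import annotations

import numpy as np

STAGE_NAMES = ("NC", "SCD", "SCD_p", "MCI")

# observed stage counts of the full cohort (NC, SCD, SCD-plus, MCI)
STAGE_COUNTS = np.array([104, 104, 79, 77])

# sex x cognition counts (rows: male, female)
SEX_BY_COGNITION = np.array([
    [65, 47, 34, 38],
    [39, 58, 43, 40],
])

# age group x cognition counts (rows: youth <=44, middle 45-59, older >=60)
AGE_BY_COGNITION = np.array([
    [66, 45, 38, 15],
    [26, 37, 22, 34],
    [12, 21, 19, 29],
])

# school education x cognition counts
# (rows: middle school 8-9 y, high school 10-12 y, undergraduate 14-16 y,
#  postgraduate >= 17 y)
EDUCATION_BY_COGNITION = np.array([
    [9, 15, 10, 24],
    [20, 23, 17, 27],
    [52, 52, 38, 25],
    [23, 14, 14, 1],
])

# career x cognition counts (rows: mental, mental+physical, physical)
CAREER_BY_COGNITION = np.array([
    [75, 70, 58, 33],
    [16, 19, 6, 18],
    [13, 14, 15, 26],
])

# tea habit counts over the full cohort in increasing-consumption order
# (none, non-daily, daily); row sums of the tea x cognition cross-tabulation
TEA_HABIT_COUNTS = np.array([118, 99, 144])

# chi-square statistics as printed in the source report.  The sex and age
# values are NOT reproducible from the printed counts above (recomputation
# gives ~8.71 and ~38.6; the printed column totals are internally
# inconsistent across groupings) — kept here only to document the mismatch.
PRINTED_CHI2 = {
    "sex": (8.963, 3),
    "age": (38.483, 6),
    "education": (38.777, 9),
    "career": (26.920, 6),
}

# SCV feature names in the standard summary column order
SCV_FEATURES = (
    "number_total", "number_right", "number_left",
    "diameter_right", "diameter_left",
    "curvature_right", "curvature_left",
    "length_right", "length_left",
)

# per-sex SCV feature summaries: mean and standard error of the mean,
# with stratum sizes MALE_N / FEMALE_N
MALE_N, FEMALE_N = 184, 180
SEX_SCV_MEAN_SE = {
    "male": {
        "number_total": (642.94, 14.60),
        "number_right": (327.01, 7.51),
        "number_left": (315.93, 7.52),
        "diameter_right": (1.4134, 0.0131),
        "diameter_left": (1.3849, 0.0130),
        "curvature_right": (1.2043, 0.0111),
        "curvature_left": (1.1063, 0.0098),
        "length_right": (16.443, 0.166),
        "length_left": (16.173, 0.174),
    },
    "female": {
        "number_total": (535.09, 12.50),
        "number_right": (277.42, 6.39),
        "number_left": (257.67, 6.42),
        "diameter_right": (1.3939, 0.0124),
        "diameter_left": (1.3366, 0.0139),
        "curvature_right": (1.1811, 0.0102),
        "curvature_left": (1.0593, 0.0099),
        "length_right": (15.773, 0.159),
        "length_left": (15.270, 0.171),
    },
}

# blood biomarker marginals (mean, SE, n) pooled over the youth no-tea /
# occasional / daily cells of the tea analysis subset
BIOMARKERS = {
    "abeta_1_42": (230.5, 25.0),   # ug/L
    "t_tau": (1955.8, 160.0),      # pg/mL
    "p_tau181": (95.9, 12.0),      # ng/L
}

# reported rank correlations the synthetic cohort's copula targets
TARGET_RANK_CORRELATIONS = {
    ("tea_level", "t_tau"): -0.227,
    ("number_total", "t_tau"): -0.138,
    ("curvature_right", "p_tau181"): -0.156,
    ("curvature_right", "t_tau"): -0.145,
}

# ordinal-regression structure of the cognition model on the blood-test
# subset (n = 226): reported coefficient for right-hemisphere curvature and
# length (PLUM convention, positive = worse cognition)
REPORTED_ORDINAL_COEFFS = {
    "curvature_right": (8.153, 2.642),
    "length_right": (-0.336, 0.162),
}


def se_to_sd(se: float, n: int) -> float:
    """Convert a standard error of the mean to a standard deviation."""
    return se * np.sqrt(n)
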