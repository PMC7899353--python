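"""Frozen regression vectors from the reference demo-data scoring run.

``None`` marks a missing value.  These vectors pin down the scoring rules
(element-for-element) and the domain-status precedence; they are inputs to
tests, never recomputed.
"""

# -- quiet validators --------------------------------------------------------

AGE_INPUT = [7, 8, 9, 10, 11, 12, 13, "", None, "12", 8.5]
AGE_EXPECTED = [None, 8, 9, 10, 11, 12, None, None, None, 12, 8]

GENDER_GIRL_INPUT = ["Girl", "GIRL", "g", "G", "Female", "f", "F", "", None, 1]
GENDER_GIRL_EXPECTED = ["girl"] * 7 + [None, None, "girl"]

GENDER_BOY_INPUT = ["Boy", "BOY", "b", "B", "Male", "m", "M", "", None, 0]
GENDER_BOY_EXPECTED = ["boy"] * 7 + [None, None, "boy"]

# -- shuttle run (first 180 lap counts, first 250 scores) --------------------

PACER_LAPS_20M = [
    18, 31, 169, 38, 63, 12, 25, 110, 33, None, 127, 62, 39, 19, None, 84, 145, 166,
    108, 125, 98, 147, 85, 49, 4, 118, 144, 85, 122, 85, 197, 5, 184, 19, 63, 112,
    89, 46, 178, 35, 69, 122, 54, 79, 120, 85, 1, 187, 59, 178, 47, 55, 89, 98,
    79, 119, 11, 70, 89, 88, 68, 82, 116, 38, 152, 195, 4, 69, 100, 99, None, 88,
    57, 43, 98, 125, 127, 5, 16, 173, 20, 33, 89, 99, 39, 35, 43, 100, 177, 15,
    141, 141, 39, None, 8, 41, 43, 2, 101, None, 54, 78, 90, 176, 40, 2, 122, 58,
    98, 5, 51, 112, 101, 122, 12, 177, 38, 92, 31, 53, 102, 200, 138, 166, 62, 31,
    86, 75, 87, 56, 147, 140, 45, 51, 136, 74, 148, 194, 67, 142, 172, 121, None, 78,
    40, 18, 59, 190, 78, 69, 33, 78, 78, 58, 84, 122, 27, 199, 147, 75, 180, 84,
    36, 129, 14, 133, 70, 65, 8, 43, 110, 64, 69, 120, 125, 28, 142, 115, 108, 14,
]

PACER_SCORE = [
    3, 6, 10, 7, 10, 2, 5, 10, 6, None, 10, 10, 7, 3, None, 10, 10, 10, 10, 10, 10, 10, 10, 9, 0,
    10, 10, 10, 10, 10, 10, 1, 10, 3, 10, 10, 10, 9, 10, 7, 10, 10, 10, 10, 10, 10, 0, 10, 10, 10,
    9, 10, 10, 10, 10, 10, 2, 10, 10, 10, 10, 10, 10, 7, 10, 10, 0, 10, 10, 10, None, 10, 10, 8, 10,
    10, 10, 1, 3, 10, 4, 6, 10, 10, 7, 7, 8, 10, 10, 3, 10, 10, 7, None, 1, 8, 8, 0, 10, None,
    10, 10, 10, 10, 8, 0, 10, 10, 10, 1, 10, 10, 10, 10, 2, 10, 7, 10, 6, 10, 10, 10, 10, 10, 10,
    6, 10, 10, 10, 10, 10, 10, 9, 10, 10, 10, 10, 10, 10, 10, 10, 10, None, 10, 8, 3, 10, 10, 10, 10,
    6, 10, 10, 10, 10, 10, 5, 10, 10, 10, 10, 10, 7, 10, 2, 10, 10, 10, 1, 8, 10, 10, 10, 10, 10,
    5, 10, 10, 10, 2, 10, 10, 8, 10, 10, 10, 10, 10, 10, 10, 10, 10, 5, 4, 8, 10, 10, 3, 10, 10,
    3, 5, 10, 10, 10, 10, 10, 3, None, 10, 10, 6, 7, 10, 10, None, 5, 9, 10, 10, 7, 9, None, 10, 9,
    10, 10, 9, 10, 10, None, 6, 10, 7, 10, 5, 10, 10, 10, 10, 10, 10, None, 10, 10, 10, 1, 10, None, 10,
]

# -- daily behaviour (250 triples) -------------------------------------------

STEP_SCORE = [
    25, 25, 19, 21, 23, 22, 23, 15, 22, 23, 25, 12, 19, 20, 9, 24, 24, 22, 24, 21, 21, 25, 23, 22, 23,
    25, 21, 23, 22, 22, 23, 23, 18, 22, 20, 25, 25, 25, 25, 23, 19, 25, 23, 25, 22, 16, 13, 24, 21, 12,
    25, 25, 24, 20, 23, 25, 14, 23, 25, 20, 25, 20, 13, 25, 21, 22, 5, 21, 25, 18, 24, 14, 25, 19, 20,
    22, 20, 8, 25, 21, 25, 25, 19, 21, 14, 25, 25, 25, 16, 25, 21, 20, 21, 25, 25, 25, 25, 23, 25, 25,
    24, 22, 23, 25, 23, 13, 11, 25, None, 23, 25, 10, 25, 25, 19, 13, 24, 21, 16, 18, 25, 25, 24, 20, 19,
    22, 11, 23, 14, 15, 17, 24, 24, 14, 23, 25, 21, 20, 22, 13, 18, 25, 20, 18, 19, 12, 14, 25, 23, 25,
    22, 17, 22, 18, 22, 23, 25, 23, 14, 19, 18, 25, 25, 17, 25, 16, 25, 22, 19, 22, 22, 6, 22, 16, 25,
    24, 22, 23, 22, 24, 15, 21, 25, 25, 22, 25, 24, 25, 22, 22, 23, 14, 22, 14, 22, 22, 24, 19, 23, 16,
    14, 17, 4, 24, 22, 25, 23, 20, 25, 19, 24, 22, 25, 24, 15, 25, 22, 21, 25, 22, 16, 23, 16, 25, 25,
    25, 19, 13, 20, 25, 20, 25, 21, 25, 25, 22, 21, 18, 18, 24, 21, 15, 23, 18, 21, 25, 24, 25, 25, 25,
]

SELF_REPORT_PA_SCORE = [
    None, 1, 1, 3, 2, 4, None, 5, 5, 5, None, 3, 1, 4, 5, 5, 0, 5, 5, 5, 5, 5, 5, None, 5,
    3, 4, 5, 4, 1, 2, 0, 5, 5, 5, 5, 4, 3, 4, 2, 4, 5, 5, 5, 2, 5, 5, None, 5, 5,
    1, 5, 3, 1, 0, 5, 3, 2, 5, 1, 2, 0, 5, None, 3, 5, 4, 0, 3, None, 5, 4, 1, None, 0,
    5, 0, 2, 0, None, 5, 5, 1, 1, 3, 3, 5, 2, 5, 4, 5, 5, 4, 3, 1, 4, 2, 1, 5, 5,
    5, 2, 1, 4, 3, 2, 5, 5, 3, 2, 2, 5, 5, 5, 2, None, 5, 1, 5, 5, None, 5, 5, 1, 0,
    4, 5, 4, 0, 0, 5, 4, 5, 0, 5, 5, 5, 5, 2, 5, 5, 5, 2, 5, 1, 3, 5, 5, None, 5,
    5, 0, 2, 1, 0, 5, 3, 3, 2, 0, 5, 1, 5, 4, 0, 3, 5, 5, 3, 5, 5, 5, 0, 5, 4,
    None, 5, 5, 4, 5, 3, 4, 3, 0, 2, 1, 5, 3, 0, 5, 1, 5, 5, 5, 5, 0, 2, 3, 0, 1,
    0, 1, 5, 5, 5, 2, 5, 3, 4, 2, 5, 5, 5, 5, 2, 5, 5, 1, 0, 1, 5, 4, 1, 5, 3,
    4, 3, 5, 0, 5, 2, 5, 0, None, 5, 3, 3, None, 2, 0, 4, 5, 5, 5, 5, 4, 0, 3, 3, 2,
]

DB_SCORE = [
    None, 26, 20, 24, 25, 26, None, 20, 27, 28, None, 15, 20, 24, 14, 29, 24, 27, 29, 26, 26, 30, 28, None, 28,
    28, 25, 28, 26, 23, 25, 23, 23, 27, 25, 30, 29, 28, 29, 25, 23, 30, 28, 30, 24, 21, 18, None, 26, 17,
    26, 30, 27, 21, 23, 30, 17, 25, 30, 21, 27, 20, 18, None, 24, 27, 9, 21, 28, None, 29, 18, 26, None, 20,
    27, 20, 10, 25, None, 30, 30, 20, 22, 17, 28, 30, 27, 21, 29, 26, 25, 25, 28, 26, 29, 27, 24, 30, 30,
    29, 24, 24, 29, 26, 15, 16, 30, None, 25, 27, 15, 30, 30, 21, None, 29, 22, 21, 23, None, 30, 29, 21, 19,
    26, 16, 27, 14, 15, 22, 28, 29, 14, 28, 30, 26, 25, 24, 18, 23, 30, 22, 23, 20, 15, 19, 30, None, 30,
    27, 17, 24, 19, 22, 28, 28, 26, 16, 19, 23, 26, 30, 21, 25, 19, 30, 27, 22, 27, 27, 11, 22, 21, 29,
    None, 27, 28, 26, 29, 18, 25, 28, 25, 24, 26, 29, 28, 22, 27, 24, 19, 27, 19, 27, 22, 26, 22, 23, 17,
    14, 18, 9, 29, 27, 27, 28, 23, 29, 21, 29, 27, 30, 29, 17, 30, 27, 22, 25, 23, 21, 27, 17, 30, 28,
    29, 22, 18, 20, 30, 22, 30, 21, None, 30, 25, 24, None, 20, 24, 25, 20, 28, 23, 26, 29, 24, 28, 28, 27,
]

# -- knowledge & understanding (first 80 of each component, first 80 totals) --

PA_GUIDELINE_SCORE = [
    0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
    1, 1, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 1, 0, 0, 1, 0,
    0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 1,
    0, 0, 0, 1, 1,
]

CRF_MEANS_SCORE = [
    0, 0, 0, 1, 1, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0,
    0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0,
    0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 1, 1, 0, 1,
    0, 0, 0, 0, 0,
]

MS_MEANS_SCORE = [
    0, 0, 1, 0, 0, 1, 1, 0, 0, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
    0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0,
    0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 0, 0, 0, 0, 1, 1, 1, 1, 0, 1, 1, 1, 0, 1, 0,
    0, 0, 0, 0, 0,
]

SPORTS_SKILL_SCORE = [
    0, 1, 1, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0,
    0, 0, 1, 1, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0,
    0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1,
    0, 0, 1, 0, 1,
]

FILL_IN_THE_BLANKS_SCORE = [
    1, 5, 2, 5, 5, 3, 3, 3, 3, 4, 5, 4, 3, 4, 4, 3, 2, 2, 3, 4, 3, 3, 4, 1, 5,
    4, 6, 4, 4, 4, 4, 4, 1, 4, 4, 2, 4, 4, 3, 5, 4, 3, 4, 3, 5, 5, 4, 5, 2, 3,
    4, 4, 2, 3, 6, 3, 3, 5, 5, 2, 6, 2, 2, 4, 2, 4, 3, 3, 6, 2, 3, 5, 5, 3, 3,
    2, 5, 2, 3, 3,
]

KU_SCORE = [
    1, 7, 4, 6, 6, 4, 6, 3, 4, 4, 8, 6, 4, 4, 6, 4, 2, 3, 4, 4, 3, 4, 4, 1, 5,
    5, 7, 5, 5, 5, 4, 5, 1, 5, 6, 2, 4, 4, 3, 6, 4, 3, 5, 4, 6, 7, 4, 7, 3, 3,
    4, 5, 3, 4, 7, 4, 6, 7, 6, 4, 6, 2, 2, 4, 4, 5, 5, 6, 8, 4, 4, 7, 7, 4, 6,
    2, 5, 3, 4, 5,
]

# -- physical competence status fixture (first 30 rows) ----------------------

PC_PACER_SCORE = PACER_SCORE[:30]

PC_PLANK_SCORE = [
    10, 10, 0, 10, 10, 9, 1, 10, 0, 3, 10, 10, 10, 10, 10, 10, 10, 10, 0, 10,
    10, 5, 3, 10, 9, 10, 10, 0, 10, 5,
]

PC_CAMSA_SCORE = [
    5.357143, 3.571429, 9.285714, 5.000000, 6.785714, None, None, 7.857143, 4.285714, 8.571429,
    5.357143, 8.571429, 8.571429, 9.285714, 6.428571, 9.285714, None, 6.428571, 3.214286, 3.571429,
    6.428571, 5.714286, 8.928571, 7.500000, None, 8.571429, None, 8.214286, 10.000000, 2.857143,
]

PC_SCORE = [
    19.5, 24.0, 15.0, 22.0, 30.0, 16.5, 9.0, 30.0, 9.0, None, 30.0, 30.0, 25.5, 19.5, None,
    30.0, 30.0, 30.0, 15.0, 30.0, 30.0, 22.5, 19.5, 28.5, 13.5, 30.0, 30.0, 15.0, 30.0, 22.5,
]

PC_INTERPRETATION = [
    "achieving", "excelling", "progressing", "excelling", "excelling",
    "progressing", "beginning", "excelling", "beginning", None,
    None, "excelling", None, None, None,
    "excelling", "excelling", "excelling", "progressing", "excelling",
    "excelling", "excelling", "achieving", None, None,
    None, "excelling", None, "excelling", "achieving",
]

PC_STATUS = [
    "complete", "complete", "complete", "complete", "complete",
    "missing protocol", "missing protocol", "complete", "complete", "incomplete",
    "missing interpretation", "complete", "missing interpretation", "missing interpretation", "incomplete",
    "complete", "missing protocol", "complete", "complete", "complete",
    "complete", "complete", "complete", "missing interpretation", "missing interpretation",
    "missing interpretation", "missing protocol", "missing interpretation", "complete", "complete",
]

# -- self-perception subscales (first 180 of each) ---------------------------

PREDILECTION_SCORE = [
    3.6, 4.9, 5.5, 3.0, None, 3.0, 6.2, 4.9, 4.8, 4.9, 3.0, 3.0, 5.6, 4.9, 5.5, 5.5, 4.9, 4.3,
    5.6, 3.6, 4.2, 3.6, 6.1, 3.6, 4.3, 4.8, 5.6, 3.0, 4.3, 4.3, 6.1, 4.9, 6.2, 3.6, 6.8, 5.5,
    5.5, 6.2, 3.0, 2.4, 4.3, 3.6, 5.5, 6.1, None, 4.3, 2.4, 4.9, 4.9, None, 5.5, 4.3, 4.2, 4.2,
    4.9, 6.2, 4.3, 5.5, 1.8, 3.7, 4.9, 3.7, 6.8, 4.8, 6.2, 4.2, 3.7, 1.8, 5.5, 3.0, 5.5, 4.2,
    4.8, 5.5, 4.9, 3.6, 4.9, 3.7, 3.6, 3.6, 4.9, 6.2, 4.2, 3.7, 3.7, 3.6, 3.0, 2.4, 4.2, 4.2,
    3.0, 5.4, 5.5, 6.2, 4.3, 3.6, 5.6, 6.1, 4.9, None, 4.2, 5.5, 6.8, 4.8, 4.9, 4.9, 4.9, 2.4,
    4.8, 3.0, 3.6, 3.6, 4.9, 3.6, 4.3, 3.7, 2.4, 3.0, 3.6, 4.2, 4.3, 4.3, 6.8, 5.6, 4.9, 6.2,
    3.0, 3.0, 5.5, 3.6, 4.2, 3.7, 6.1, 3.7, 3.6, 6.2, 6.1, 4.8, 3.6, 4.9, 1.8, 5.6, 3.0, 4.9,
    4.9, 4.8, 3.0, 4.8, 4.2, 4.9, 2.4, 5.5, 3.7, 4.3, 3.6, 3.0, 4.8, 5.5, 7.5, 4.9, 4.8, 4.2,
    3.0, 2.4, 5.5, 2.4, 5.5, 6.1, 3.6, 5.5, 4.3, 4.2, 4.3, None, 6.1, 3.6, 4.9, 5.6, 3.7, 2.4,
]

ADEQUACY_SCORE = [
    2.4, 5.5, 7.5, 4.3, 5.5, 5.5, 4.2, 4.3, 3.6, 4.3, 6.2, 4.9, 4.9, 4.2, 4.3, 5.6, 4.2, 4.8,
    4.8, 6.2, 4.3, 4.8, 4.9, 3.6, 6.8, 4.3, 6.2, 6.2, 4.3, 7.5, 6.1, 5.6, 4.9, 6.2, 6.2, 2.4,
    4.2, 5.6, 5.6, 4.2, 5.5, 4.9, 5.5, 4.9, 4.2, 6.2, 5.6, 6.2, 4.9, 4.2, 3.6, 3.7, 3.6, 6.8,
    1.8, 3.6, 5.6, 4.9, 3.6, 3.0, 3.6, 4.9, 3.7, 4.9, 3.6, 3.7, 4.2, 5.6, 6.1, 4.9, 3.6, 3.0,
    2.4, 4.3, 6.1, 3.0, 3.0, 3.7, 4.9, 4.3, 5.4, 5.5, 3.0, 2.4, 6.1, 5.6, 5.5, 3.7, 4.2, 2.4,
    5.6, 4.9, 3.0, 5.6, 4.9, 3.6, 4.9, 6.8, 4.9, 2.4, 5.6, 4.8, 4.2, 3.0, 4.9, 3.0, 3.0, 3.7,
    4.9, 3.7, 6.2, 4.9, 5.5, 5.6, 5.6, 4.8, 3.7, 6.2, 3.0, 5.4, 4.9, 3.6, 5.4, 3.0, 4.8, 3.6,
    4.8, 4.2, 4.2, 2.4, 4.9, 4.3, 6.2, 2.4, 4.9, 4.9, 4.9, 4.2, 4.9, 5.5, 4.9, 5.5, 7.5, 5.6,
    5.5, 3.0, 4.9, 6.1, 4.9, 5.5, 3.0, 5.6, 6.2, 4.9, 4.3, 4.9, 5.6, 4.2, 2.4, 5.5, 4.9, 3.7,
    4.3, 4.3, 4.9, 4.3, 6.1, 4.8, 4.9, 5.5, 6.2, 6.1, 3.6, 2.4, 3.6, 4.9, 6.2, 4.3, 4.3, 4.2,
]

# -- exercise-regulation subscales (first 180 of each) -----------------------

INTRINSIC_MOTIVATION_SCORE = [
    6.0, 4.5, 5.0, 4.5, 4.0, 5.5, 6.5, None, 5.5, None, 6.5, 5.0, 4.0, 3.5, None, 6.0, 4.5, 4.5,
    5.0, 3.0, 2.0, 2.5, 3.5, None, 5.0, 4.0, 4.5, 7.0, 3.5, 4.0, None, 6.0, 5.0, 3.5, None, 4.5,
    4.5, None, 5.0, 5.0, 4.0, 3.5, 6.5, 4.0, None, 4.5, 3.0, None, 5.0, 5.0, 4.0, 6.5, None, 4.0,
    5.0, 3.5, 6.5, 2.5, 6.5, 5.0, 6.0, 5.5, 4.5, 3.5, 3.0, 2.5, 4.5, 4.5, 4.5, 4.5, 4.5, 3.0,
    4.5, 4.5, 5.0, 5.0, 2.5, 6.5, 5.5, 4.5, 6.0, 2.5, 4.0, 7.0, 4.5, None, 3.5, None, 3.5, 3.0,
    4.0, 4.0, 5.0, 5.0, 2.5, None, 3.5, 6.0, 1.5, 6.5, 5.5, 5.5, 5.5, 4.0, 4.0, 4.0, None, 3.0,
    None, 4.0, 5.0, 5.5, 3.5, 4.0, 3.0, 4.0, 6.5, 3.5, 6.0, 3.0, 4.5, 6.0, None, 3.0, 3.5, None,
    5.0, 3.0, None, 5.5, 5.5, 6.5, 4.0, None, 5.0, 5.0, 5.0, None, 3.0, 2.5, None, 4.0, 6.0, 5.0,
    5.0, 3.5, 4.5, 5.0, None, 4.5, 2.5, 4.0, 4.0, 5.5, 3.0, 7.0, 5.0, 5.0, 5.0, None, 5.5, 7.5,
    4.0, 2.5, 3.5, 5.5, None, 4.5, 6.0, 5.0, 5.0, 5.5, 2.5, 4.5, 5.5, 2.0, 5.0, 7.0, None, 6.0,
]

PA_COMPETENCE_SCORE = [
    5.5, 5.0, 3.0, 5.0, 4.0, 2.5, 4.5, 4.5, 4.5, 6.0, 4.5, 4.0, 3.5, 4.0, 4.0, 3.5, 5.0, 3.5,
    5.0, 6.0, 5.5, 4.0, None, 4.5, 5.5, None, 5.0, 4.0, 5.0, 5.0, 4.0, None, 3.0, None, 4.5, 3.0,
    6.0, None, 1.5, 3.5, 4.5, 6.5, 2.5, 5.5, 3.5, 6.0, 4.0, 6.5, 5.5, 5.0, 6.0, None, 3.0, 5.5,
    5.0, 5.0, 5.5, None, 5.0, 5.0, 5.0, None, 4.5, 5.0, 4.0, 7.0, 3.5, 5.5, 4.5, 4.5, None, 2.5,
    4.0, 3.5, 4.5, 5.0, 4.0, 4.0, 3.5, 3.5, 2.5, 5.0, 5.0, 3.0, 5.0, 3.0, 5.0, None, 3.0, 3.5,
    3.5, 5.0, 5.0, None, None, 5.0, 3.5, 5.0, 5.0, 4.0, None, 3.5, 5.0, 4.5, 5.5, 7.5, 4.0, 5.0,
    None, 4.0, 6.0, None, 5.5, 6.0, 5.5, 3.0, 4.0, 3.5, 4.0, 6.0, 3.5, 4.0, None, 5.0, 6.0, 7.0,
    4.0, 4.5, 4.5, 2.5, None, 2.5, 7.5, 4.5, 4.0, 4.0, None, 3.0, 4.0, 5.5, None, 4.0, 3.5, 4.5,
    3.5, 5.0, 3.0, None, 5.5, 4.5, 5.5, 3.5, 6.0, 5.0, 6.5, 6.0, 4.0, 2.0, 4.0, None, 2.5, 4.5,
    4.5, 5.0, 6.0, 5.5, 2.0, 7.0, None, 3.5, 3.5, None, 5.0, None, 5.5, 6.0, 5.5, 5.0, 4.0, 4.0,
]

# -- agility course (first 70 combined scores) -------------------------------

CAMSA_SCORE = [
    5.357143, 3.571429, 9.285714, 5.000000, 6.785714, None, None,
    7.857143, 4.285714, 8.571429, 5.357143, 8.571429, 8.571429, 9.285714,
    6.428571, 9.285714, None, 6.428571, 3.214286, 3.571429, 6.428571,
    5.714286, 8.928571, 7.500000, None, 8.571429, None, 8.214286,
    10.000000, 2.857143, None, 5.714286, None, 8.571429, 10.000000,
    7.500000, 7.857143, 6.428571, 7.142857, 6.428571, 5.714286, None,
    6.071429, 5.714286, 9.642857, 2.142857, 7.500000, 8.214286, 8.571429,
    7.857143, 7.500000, 10.000000, 7.142857, 7.142857, None, 4.285714,
    6.785714, 6.428571, 7.857143, 6.428571, 3.928571, 4.285714, 10.000000,
    5.714286, None, 7.500000, 6.071429, None, 7.500000, None,
]
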