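"""Reference summary statistics for the traffic-sign Go/Nogo study design.

These are the per-shape behavioural counts, group-average ERP component
latencies, correct-vs-incorrect gap times and cross-validation fold
accuracies of the driving-simulator study (10 elderly and 10 young
drivers, three sign shapes, 20 trials per shape) whose statistical
structure the synthetic generator emulates.  They serve three purposes:

* generator defaults (latencies, shifts, error rates),
* worked examples that exercise the summary arithmetic in
  :mod:`erpsign.behavior` and :mod:`erpsign.mlp`,
* the fixed inputs of ``scripts/acceptance.py``.

Latencies are milliseconds after stimulus onset; counts are per-subject
trial counts out of 20 per shape.
"""

from __future__ import annotations

GROUPS = ("elderly", "youth")
SHAPES = ("triangle", "circle", "rectangle")
COMPONENTS = ("N200", "P300", "N400", "P600")

# Per-shape behavioural summary: (mean correct, sd correct, mean incorrect,
# sd incorrect) across the 10 subjects of each group.
BEHAVIOR_COUNTS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "elderly": {
        "triangle": (15.2, 2.68, 5.0, 3.38),
        "circle": (16.7, 2.83, 3.7, 1.95),
        "rectangle": (15.9, 1.97, 3.9, 1.51),
    },
    "youth": {
        "triangle": (17.1, 1.37, 2.4, 0.8),
        "circle": (16.5, 1.80, 3.2, 1.6),
        "rectangle": (16.8, 1.25, 3.1, 1.6),
    },
}

# Published per-shape error-rate percentages (per group, plus the group
# average row).  Note these are not all exactly incorrect/(correct+incorrect)
# of the printed count means.
ERROR_RATE_PCT: dict[str, dict[str, float]] = {
    "elderly": {"triangle": 24.1, "circle": 18.5, "rectangle": 19.8, "avg": 20.8},
    "youth": {"triangle": 12.4, "circle": 16.2, "rectangle": 15.3, "avg": 14.6},
}

# Published group-average behavioural row: (mean correct, sd correct,
# mean incorrect, sd incorrect).
BEHAVIOR_AVG_ROW: dict[str, tuple[float, float, float, float]] = {
    "elderly": (15.93, 1.48, 4.2, 2.28),
    "youth": (16.8, 1.48, 2.9, 1.35),
}

# Per-shape ERP component latencies (ms) by (group, condition).
COMPONENT_LATENCIES: dict[tuple[str, str], dict[str, dict[str, float]]] = {
    ("elderly", "correct"): {
        "triangle": {"N200": 249, "P300": 406, "N400": 498, "P600": 634},
        "circle": {"N200": 241, "P300": 376, "N400": 490, "P600": 668},
        "rectangle": {"N200": 218, "P300": 411, "N400": 539, "P600": 618},
    },
    ("elderly", "incorrect"): {
        "triangle": {"N200": 248, "P300": 414, "N400": 510, "P600": 625},
        "circle": {"N200": 232, "P300": 420, "N400": 517, "P600": 618},
        "rectangle": {"N200": 265, "P300": 447, "N400": 541, "P600": 642},
    },
    ("youth", "correct"): {
        "triangle": {"N200": 222, "P300": 432, "N400": 535, "P600": 610},
        "circle": {"N200": 203, "P300": 356, "N400": 480, "P600": 595},
        "rectangle": {"N200": 234, "P300": 400, "N400": 505, "P600": 672},
    },
    ("youth", "incorrect"): {
        "triangle": {"N200": 254, "P300": 427, "N400": 487, "P600": 639},
        "circle": {"N200": 236, "P300": 403, "N400": 479, "P600": 617},
        "rectangle": {"N200": 266, "P300": 453, "N400": 534, "P600": 681},
    },
}

# Published group-average latency rows (ms) and their printed SD rows.
AVG_LATENCIES: dict[tuple[str, str], dict[str, float]] = {
    ("elderly", "correct"): {"N200": 236, "P300": 398, "N400": 509, "P600": 640},
    ("elderly", "incorrect"): {"N200": 248, "P300": 427, "N400": 523, "P600": 628},
    ("youth", "correct"): {"N200": 220, "P300": 396, "N400": 507, "P600": 626},
    ("youth", "incorrect"): {"N200": 252, "P300": 427, "N400": 500, "P600": 646},
}

STD_LATENCIES: dict[tuple[str, str], dict[str, float]] = {
    ("elderly", "correct"): {"N200": 13.13, "P300": 15.48, "N400": 21.21, "P600": 20.82},
    ("elderly", "incorrect"): {"N200": 13.64, "P300": 14.61, "N400": 13.20, "P600": 10.07},
    ("youth", "correct"): {"N200": 12.55, "P300": 31.08, "N400": 22.65, "P600": 33.27},
    ("youth", "incorrect"): {"N200": 12.50, "P300": 20.44, "N400": 24.56, "P600": 26.80},
}

# Correct-vs-incorrect latency gap times (ms, incorrect minus correct).
GAP_TIMES_MS: dict[str, dict[str, float]] = {
    "elderly": {"N200": 12, "P300": 29, "N400": 14, "P600": -12},
    "youth": {"N200": 32, "P300": 31, "N400": -7, "P600": 20},
}

# 4-fold cross-validation accuracies of the 70-20-10-1 correctness
# classifier, by group and preprocessing variant, with the published
# mean/SD aggregation.
CV_FOLD_ACCURACIES: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("elderly", "original_avg"): (0.40, 0.33, 0.60, 0.71),
    ("elderly", "smoothed"): (0.53, 0.80, 0.87, 0.64),
    ("elderly", "zero_phase"): (0.60, 0.53, 0.67, 0.36),
    ("elderly", "zero_phase_smoothed"): (0.53, 0.47, 0.53, 0.64),
    ("youth", "original_avg"): (0.67, 0.60, 0.47, 0.64),
    ("youth", "smoothed"): (0.53, 0.47, 0.47, 0.50),
    ("youth", "zero_phase"): (0.33, 0.67, 0.60, 0.50),
    ("youth", "zero_phase_smoothed"): (0.73, 0.47, 0.47, 0.86),
}

CV_PUBLISHED_MEAN_SD: dict[tuple[str, str], tuple[float, float]] = {
    ("elderly", "original_avg"): (0.55, 0.15),
    ("elderly", "smoothed"): (0.75, 0.13),
    ("elderly", "zero_phase"): (0.54, 0.12),
    ("elderly", "zero_phase_smoothed"): (0.54, 0.06),
    ("youth", "original_avg"): (0.59, 0.08),
    ("youth", "smoothed"): (0.49, 0.03),
    ("youth", "zero_phase"): (0.53, 0.13),
    ("youth", "zero_phase_smoothed"): (0.63, 0.17),
}
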