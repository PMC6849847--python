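"""Development-cohort reference values.

Per-subject kinetic parameters and characteristics of the four-subject
development cohort (low-normal to high plasma triglyceride).  These serve
two purposes in the pipeline: they are the arithmetic inputs for cohort
summary checks, and their min-max ranges are the sampling envelopes of the
synthetic-subject generator.

Values are keyed by the same row names used in :class:`trlkin.fitting.
KineticSummary`; units: productions in mg/day (apoB) or g/day (TG), FCR /
FDC / FTR in pools/day.
"""

from __future__ import annotations

SUBJECT_IDS = ("S1", "S2", "S3", "S4")

#: body weight (kg), fasting plasma triglyceride (mmol/L), TG tier label
SUBJECT_CHARACTERISTICS = {
    "S1": {"body_weight": 92.5, "fasting_tg": 0.74, "tier": "low"},
    "S2": {"body_weight": 89.1, "fasting_tg": 1.1, "tier": "normal"},
    "S3": {"body_weight": 93.1, "fasting_tg": 2.1, "tier": "normal"},
    "S4": {"body_weight": 98.5, "fasting_tg": 5.7, "tier": "high"},
}

#: per-subject kinetic parameters (columns S1..S4)
REFERENCE_KINETICS: dict[str, tuple[float, float, float, float]] = {
    "apob48_total_prod": (248, 416, 142, 327),
    "apob48_basal_prod": (27.8, 27.3, 57.4, 101),
    "apob48_pp_prod": (220, 388, 85, 226),
    "apob48_total_fcr": (17.5, 27.5, 3.0, 2.0),
    "apob48_cm_fcr": (49.9, 26.5, 4.5, 5.1),
    "apob48_vldl1_fcr": (1.5, 5.0, 1.7, 1.5),
    "apob48_vldl2_fcr": (3.8, 19, 3.0, 0.9),
    "tg_apob48_total_prod": (67.8, 67.1, 68, 67.7),
    "tg_apob48_basal_prod": (1.3, 0.6, 1.5, 1.2),
    "tg_apob48_pp_prod": (66.5, 66.5, 66.5, 66.5),
    "tg_apob48_cm_fcr": (238, 44, 55, 23.5),
    "tg_apob48_vldl1_fcr": (3.4, 23.2, 2.5, 3.1),
    "tg_apob48_vldl2_fcr": (12.9, 23.1, 4, 1.3),
    "apob100_vldl1_fcr": (51.9, 18.7, 10.4, 1.9),
    "apob100_vldl1_fdc": (33.1, 13.4, 9.2, 0.6),
    "apob100_vldl1_ftr": (18.8, 5.3, 1.1, 1.4),
    "apob100_vldl1_prod": (1080, 960, 987, 559),
    "apob100_vldl2_fcr": (6.3, 3.1, 2.8, 1),
    "apob100_vldl2_prod": (607, 633, 418, 578),
    "apob100_vldl2_dir_prod": (216, 360, 312, 180),
    "apob100_vldl_total_prod": (1296, 1320, 1272, 739.2),
    "tg_apob100_vldl1_fcr": (58.6, 20.4, 12.1, 2.3),
    "tg_apob100_vldl1_fdc": (43.1, 15.3, 11.6, 1.5),
    "tg_apob100_vldl1_ftr": (15.5, 5.1, 0.6, 0.8),
    "tg_apob100_vldl1_prod": (31.3, 27.8, 29.1, 14.7),
    "tg_apob100_vldl2_fcr": (33.8, 17.6, 4.6, 2.8),
    "tg_apob100_vldl2_prod": (12.9, 16.2, 5.3, 7.5),
    "tg_apob100_vldl2_dir_prod": (4.6, 9.2, 4, 2.3),
    "tg_apob100_vldl_total_prod": (35.9, 37, 33, 17.1),
}

#: published cohort means for the rows above (mean, SD with n divisor)
REFERENCE_MEANS = {
    "apob48_total_prod": (283, 100),
    "apob48_basal_prod": (53.4, 30),
    "apob48_pp_prod": (230, 110),
    "apob48_total_fcr": (12.5, 11),
    "apob48_cm_fcr": (21.3, 19),
    "apob48_vldl1_fcr": (2.4, 1.5),
    "apob48_vldl2_fcr": (6.7, 7.2),
    "apob100_vldl2_prod": (559, 84),
    "apob100_vldl_total_prod": (1157, 240),
    "tg_apob100_vldl_total_prod": (31, 8),
}

#: basal apoB48 secretion during the separate fasting-protocol study:
#: cohort mean 74 +/- 29 mg/day (individual values not published)
FASTED_BASAL_MEAN = 74.0
FASTED_BASAL_SD = 29.0

#: fasting plasma TG range spanned by the development cohort (mmol/L)
COHORT_TG_RANGE = (0.74, 5.7)


def reference_envelope(row: str) -> tuple[float, float]:
    """Min-max range of a kinetic parameter across the reference cohort."""
    vals = REFERENCE_KINETICS[row]
    return (min(vals), max(vals))
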