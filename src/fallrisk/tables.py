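"""Published group summary statistics used to parameterize the synthetic cohort.

Each row is (name, domain, source, faller_mean, faller_sd, nonfaller_mean,
nonfaller_sd) for a continuous variable of the 60-woman cohort (21 fallers,
39 non-fallers).  ``source`` separates the baseline descriptive
characteristics ("descriptives") from the 51 variables that entered the
multi-domain analysis ("multi_domain": 11 balance, 11 gait, 5 clinical,
14 strength, 10 body-composition variables).  Binary descriptives carry
per-group event probabilities instead of means/SDs.
"""

from __future__ import annotations

# -- baseline descriptive characteristics (continuous) -----------------------
DESCRIPTIVES = [
    ("Age (years)", "clinical", 71.52, 4.33, 68.87, 3.41),
    ("Mass (kg)", "clinical", 65.43, 10.67, 62.31, 10.55),
    ("Height (m)", "clinical", 1.62, 0.05, 1.60, 0.06),
    ("BMI (kg/m^2)", "clinical", 25.13, 4.06, 24.25, 3.6),
    ("Systolic BP (mmHg)", "clinical", 121.27, 12.73, 125.56, 13.65),
    ("Diastolic BP (mmHg)", "clinical", 75.56, 5.94, 77.33, 8.39),
    ("Resting HR (bpm)", "clinical", 69.52, 7.22, 69.5, 6.82),
    ("Number of medications", "clinical", 1.14, 1.06, 0.92, 1.11),
    ("Weekly alcohol (units)", "clinical", 10.6, 9.61, 8.06, 8.13),
    ("FES-I", "clinical", 20.43, 2.77, 18.68, 2.61),
    ("GDS", "clinical", 1.29, 1.71, 1.33, 2.25),
    ("Mini-Mental State Examination", "clinical", 29.43, 0.98, 29.36, 0.84),
    ("Total physical activity (MET-min/week)", "clinical", 5990.0, 3711.0, 7463.0, 3860.0),
]

# binary descriptives: (name, domain, faller count yes, faller n, non-faller
# count yes, non-faller n)
BINARY_DESCRIPTIVES = [
    ("Visual impairment", "clinical", 20, 21, 36, 39),
    ("Hearing impairment", "clinical", 5, 21, 7, 39),
]

# -- variables of the multi-domain package -----------------------------------
BALANCE = [
    ("Posterior endpoint excursion (%)", 43.95, 13.34, 42.62, 12.02),
    ("Anterior maximum excursion (%)", 82.05, 17.60, 91.67, 15.52),
    ("Eyes closed left sway velocity (deg/s)", 5.67, 3.18, 6.03, 2.71),
    ("Posterior directional control (%)", 65.52, 20.38, 59.35, 19.08),
    ("Right endpoint excursion (%)", 61.57, 22.52, 65.87, 15.82),
    ("Eyes closed right sway velocity (deg/s)", 7.02, 3.56, 5.97, 2.75),
    ("Right directional control (%)", 81.1, 8.28, 75.74, 10.28),
    ("Eyes open right sway velocity (deg/s)", 1.61, 0.98, 1.24, 0.45),
    ("Eyes closed somatosensory ratio", 4.07, 1.35, 3.93, 1.38),
    ("Composite directional control (%)", 78.27, 7.36, 74.25, 8.11),
    ("Foam eyes closed sway velocity (deg/s)", 1.62, 0.45, 1.49, 0.43),
]

GAIT = [
    ("UGS braking phase duration (s)", 0.32, 0.03, 0.30, 0.03),
    ("UGS TO knee angle (deg)", 127.0, 4.0, 130.0, 5.0),
    ("UGS step length index", 0.43, 0.02, 0.46, 0.03),
    ("MAD UGS step length (%)", 1.80, 1.38, 1.37, 0.47),
    ("MAD UGS braking phase duration (%)", 2.77, 1.85, 4.94, 2.64),
    ("MGS step length index", 0.49, 0.02, 0.52, 0.03),
    ("MAD MGS TO knee angle (%)", 1.17, 0.54, 0.83, 0.47),
    ("MAD MGS step frequency (%)", 0.62, 0.52, 1.11, 0.82),
    ("MGS TO knee angle (deg)", 132.0, 3.0, 134.0, 4.0),
    ("MAD UGS braking peak force (%)", 6.45, 3.83, 4.62, 2.24),
    ("MAD UGS time to mid-stance peak force (%)", 2.59, 1.72, 1.78, 0.88),
]

CLINICAL = [
    ("POMA total score", 26.22, 1.7, 27.31, 1.17),
    ("TUG time (s)", 8.24, 1.18, 7.61, 1.17),
    ("POMA balance score", 15.09, 1.58, 15.69, 0.57),
    ("UGS (m/s)", 1.42, 0.12, 1.50, 0.14),
    ("GS reserve", 1.33, 0.13, 1.29, 0.12),
]

STRENGTH = [
    ("Plantar flexion 120 DL PT (Nm/kg)", 0.43, 0.16, 0.51, 0.15),
    ("Plantar flexion 60 SA (%)", 7.77, 6.51, 6.68, 4.48),
    ("Knee extension 60 SA (%)", 4.59, 4.41, 4.55, 3.46),
    ("Dorsiflexion 120 DL PT (Nm/kg)", 0.20, 0.04, 0.23, 0.05),
    ("Plantar flexion 120 NDL PT (Nm/kg)", 0.34, 0.13, 0.41, 0.13),
    ("Knee flexion 120 DL PT (Nm/kg)", 0.59, 0.15, 0.67, 0.15),
    ("Knee flexion 120 NDL PT (Nm/kg)", 0.49, 0.15, 0.59, 0.15),
    ("Knee flexion 60 NDL PT (Nm/kg)", 0.63, 0.13, 0.71, 0.14),
    ("Plantar flexion 60 NDL PT (Nm/kg)", 0.50, 0.17, 0.60, 0.22),
    ("Knee flexion 120 SA (%)", 6.72, 4.41, 4.33, 2.44),
    ("Trunk flexion 45 AngPT (deg)", 57.62, 11.64, 51.98, 9.37),
    ("Knee flexion 60 DL PT (Nm/kg)", 0.74, 0.12, 0.81, 0.13),
    ("Dorsiflexion 60 NDL PT (Nm/kg)", 0.23, 0.04, 0.27, 0.06),
    ("Dorsiflexion 120 NDL PT (Nm/kg)", 0.17, 0.04, 0.20, 0.05),
]

BODY_COMPOSITION = [
    ("DL thigh MQ (combined torque; Nm/kg)", 34.01, 4.26, 36.07, 5.18),
    ("SA shank MQ (PF torque; %)", 7.48, 5.40, 7.27, 4.87),
    ("DL thigh MQ (KE torque; Nm/kg)", 21.98, 3.12, 23.43, 3.92),
    ("Thigh MQ (combined torque; Nm/kg)", 31.69, 4.73, 34.44, 5.22),
    ("Femoral strength index", 1.37, 0.29, 1.45, 0.23),
    ("DL thigh MQ (Isometric KE torque; Nm/kg)", 30.09, 5.00, 32.21, 7.02),
    ("Trochanter BMD (g/cm^2)", 0.70, 0.11, 0.67, 0.10),
    ("NDL shank MQ (PF torque; Nm/kg)", 19.66, 6.85, 22.34, 8.53),
    ("ALMI (kg/m^2)", 6.27, 0.72, 6.21, 0.68),
    ("Total fat mass (kg)", 24.14, 7.69, 21.46, 7.19),
]

MULTI_DOMAIN = (
    [(nm, "balance", *rest) for nm, *rest in BALANCE]
    + [(nm, "gait", *rest) for nm, *rest in GAIT]
    + [(nm, "clinical", *rest) for nm, *rest in CLINICAL]
    + [(nm, "strength", *rest) for nm, *rest in STRENGTH]
    + [(nm, "body_composition", *rest) for nm, *rest in BODY_COMPOSITION]
)

# -- published between-domain shared-information (measured inertia) ----------
# keys are frozensets of domain names; values the measured singular-value
# inertia of the cross-domain analysis
MEASURED_INERTIA = {
    frozenset(("balance", "body_composition")): 206.61,
    frozenset(("balance", "clinical")): 166.08,
    frozenset(("balance", "gait")): 263.55,
    frozenset(("balance", "strength")): 241.39,
    frozenset(("body_composition", "clinical")): 123.74,
    frozenset(("body_composition", "gait")): 241.16,
    frozenset(("body_composition", "strength")): 464.28,
    frozenset(("clinical", "gait")): 195.55,
    frozenset(("clinical", "strength")): 170.94,
    frozenset(("gait", "strength")): 352.62,
}

# -- published variable-selection bookkeeping --------------------------------
# The nine variables both importance engines agreed on:
SELECTED_BY_BOTH = [
    "MAD UGS braking phase duration (%)",
    "UGS braking phase duration (s)",
    "UGS step length index",
    "MGS step length index",
    "MAD UGS time to mid-stance peak force (%)",
    "UGS TO knee angle (deg)",
    "Knee flexion 120 SA (%)",
    "Knee flexion 120 NDL PT (Nm/kg)",
    "POMA total score",
]

# The random forest selected 12 variables (7 gait, 2 strength, 2 clinical,
# 1 body composition); the leave-one-variable-out analysis selected 15
# (9 gait, 5 strength, 1 clinical).  The nine above are their intersection;
# the published union has 18 members.  The domain bookkeeping pins down the
# engine-specific members up to which single extra gait variable the forest
# contributed; that assignment is fixed here.
SELECTED_RF_ONLY = [
    "MAD UGS step length (%)",  # gait (7th gait variable of the forest set)
    "TUG time (s)",  # clinical
    "Thigh MQ (combined torque; Nm/kg)",  # body composition
]
SELECTED_LOVO_ONLY = [
    "MAD MGS TO knee angle (%)",  # gait
    "MAD MGS step frequency (%)",  # gait
    "MAD UGS braking peak force (%)",  # gait
    "Dorsiflexion 120 DL PT (Nm/kg)",  # strength
    "Dorsiflexion 60 NDL PT (Nm/kg)",  # strength
    "Dorsiflexion 120 NDL PT (Nm/kg)",  # strength
]

SELECTED_RF = SELECTED_BY_BOTH + SELECTED_RF_ONLY
SELECTED_LOVO = SELECTED_BY_BOTH + SELECTED_LOVO_ONLY
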