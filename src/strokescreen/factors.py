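"""Canonical risk-factor vocabulary and cohort-table schema.

The screening questionnaire records eight binary risk factors per person.
The canonical order below is used everywhere a deterministic ordering of
factors or factor combinations is needed.
"""

from __future__ import annotations

# Canonical order of the eight preliminary-screening risk factors.
FACTORS: tuple[str, ...] = (
    "hypertension",
    "atrial_fibrillation",
    "smoking",
    "dyslipidemia",
    "diabetes",
    "lack_of_exercise",
    "overweight",
    "family_history",
)

#: The four lab-confirmed factors whose center-level positive rates drive
#: the outlier screen (blood pressure, glucose, ECG and lipid panel are
#: measured at the center, so a center-level anomaly shows up in these).
CLEANING_FACTORS: tuple[str, ...] = (
    "hypertension",
    "diabetes",
    "atrial_fibrillation",
    "dyslipidemia",
)

#: The seven geographic districts used for grouping; crossed with
#: urban/rural this yields the 14 cleaning groups.
DISTRICTS: tuple[str, ...] = (
    "east",
    "northeast",
    "north",
    "central",
    "south",
    "northwest",
    "southwest",
)

STROKE_SUBTYPES: tuple[str, ...] = (
    "cerebral_infarction",
    "cerebral_hemorrhage",
    "tia",
    "none",
)

#: Non-factor columns of a cohort table, in write order.
META_COLUMNS: tuple[str, ...] = (
    "person_id",
    "center_id",
    "district",
    "urban",
    "age",
)

OUTCOME_COLUMNS: tuple[str, ...] = (
    "prior_stroke",
    "incident_stroke",
    "stroke_subtype",
    "lost_to_followup",
    "data_error",
)

COHORT_COLUMNS: tuple[str, ...] = META_COLUMNS + FACTORS + OUTCOME_COLUMNS

BOOL_COLUMNS: tuple[str, ...] = (
    ("urban",) + FACTORS + ("prior_stroke", "incident_stroke", "lost_to_followup", "data_error")
)


def validate_factor_names(names) -> list[str]:
    """Return ``names`` as a list, raising ``ValueError`` on unknown factors."""
    names = list(names)
    unknown = [f for f in names if f not in FACTORS]
    if unknown:
        raise ValueError(f"unknown risk factor(s): {unknown!r}; expected a subset of {list(FACTORS)}")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in {names!r}")
    return names


def canonical_sort(names) -> list[str]:
    """Sort factor names into the canonical questionnaire order."""
    names = validate_factor_names(names)
    return sorted(names, key=FACTORS.index)
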