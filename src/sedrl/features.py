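"""Canonical state-feature vocabulary for ICU sedation trajectories.

The patient state is a 14-dimensional vector of routinely charted measures:
haemodynamics, respiratory mechanics, oximetry/gases, and two static
demographics. Gender is a binary indicator (male coded 0) and is excluded
from z-scaling; every other feature is treated as continuous.
"""

from __future__ import annotations

FEATURE_NAMES: tuple[str, ...] = (
    "diastolic_bp",
    "nibp_mean",
    "resp_rate",
    "heart_rate",
    "spo2",
    "arterial_ph",
    "peep",
    "fio2",
    "pao2",
    "plateau_pressure",
    "mean_airway_pressure",
    "map",
    "age",
    "gender",
)

N_FEATURES = len(FEATURE_NAMES)

#: index of mean arterial pressure within the state vector
MAP_INDEX = FEATURE_NAMES.index("map")
#: index of the binary gender feature (excluded from normalization)
GENDER_INDEX = FEATURE_NAMES.index("gender")
#: features that are z-scored (all continuous measures)
CONTINUOUS_INDICES = tuple(i for i in range(N_FEATURES) if i != GENDER_INDEX)

#: non-feature channels carried alongside the state
SAS_COLUMN = "sas"
PROPOFOL_COLUMN = "propofol_dose"
FENTANYL_COLUMN = "fentanyl_dose"
DOSE_COLUMNS = (PROPOFOL_COLUMN, FENTANYL_COLUMN)

ALL_VARIABLES = FEATURE_NAMES + (SAS_COLUMN,) + DOSE_COLUMNS
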