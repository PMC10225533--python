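"""Published reference demand parameters for validation.

Individual best-fit exponential demand parameters (shared k = 2.218) for
the 28 adolescent rats — 14 Wistar, 14 SHR — that completed demand
assessment at the 30 μg/kg nicotine unit dose in the study this package's
generator emulates, as printed: demand elasticity alpha (1/responses),
demand intensity Q0 (mg/kg), Pmax (FR per mg/kg), Omax (responses per
session) and fit r² on log10 consumption.  These printed values serve as
fixed inputs for validating the derived-index formulas and the strain
comparison; they are not produced by this package.

``REFERENCE_K`` is the globally fitted range constant.  The printed
per-sex Mean/SEM summary cells that are arithmetically consistent with the
individual rows are kept in ``REFERENCE_STRATUM_MEANS`` (some printed
summary cells are not the arithmetic means of the printed individual
values — e.g. the Wistar male Pmax mean — and are excluded).
"""

from __future__ import annotations

import pandas as pd

REFERENCE_K = 2.218

#: unit dose (mg/kg) at which demand was assessed
REFERENCE_DOSE_MG_KG = 0.03

_COLUMNS = ["subject_id", "strain", "sex", "alpha", "q0", "pmax", "omax", "r2"]

_ROWS = [
    ("1",  "Wistar", "male",   0.000362, 1.85, 377.9,  223.3, 0.94),
    ("2",  "Wistar", "male",   0.000226, 1.75, 638.8,  357.5, 0.96),
    ("3",  "Wistar", "male",   0.000166, 1.79, 846.8,  485.5, 0.97),
    ("4",  "Wistar", "male",   0.000247, 2.92, 349.3,  326.8, 0.94),
    ("5",  "Wistar", "male",   0.001899, 0.85, 156.6,  42.5,  0.97),
    ("6",  "Wistar", "male",   0.000560, 1.57, 287.5,  144.3, 0.90),
    ("7",  "Wistar", "female", 0.000228, 1.46, 758.4,  354.5, 0.96),
    ("8",  "Wistar", "female", 0.000084, 2.30, 1310.5, 966.0, 0.97),
    ("9",  "Wistar", "female", 0.000321, 2.70, 290.5,  251.4, 0.97),
    ("10", "Wistar", "female", 0.000109, 1.62, 1433.9, 744.6, 0.93),
    ("11", "Wistar", "female", 0.000631, 1.52, 262.9,  128.0, 0.99),
    ("12", "Wistar", "female", 0.001010, 3.20, 78.2,   80.0,  0.93),
    ("13", "Wistar", "female", 0.000328, 1.82, 423.0,  246.3, 0.96),
    ("14", "Wistar", "female", 0.000217, 1.89, 615.8,  371.6, 0.99),
    ("15", "SHR",    "male",   0.001000, 1.32, 190.7,  80.8,  0.94),
    ("16", "SHR",    "male",   0.000161, 1.45, 1078.1, 501.1, 0.98),
    ("17", "SHR",    "male",   0.000620, 1.07, 379.0,  130.2, 0.88),
    ("18", "SHR",    "male",   0.000333, 1.85, 410.8,  242.7, 0.98),
    ("19", "SHR",    "male",   0.000400, 1.03, 612.6,  201.9, 0.94),
    ("20", "SHR",    "male",   0.000544, 0.32, 1431.6, 148.4, 0.64),
    ("21", "SHR",    "male",   0.000307, 1.94, 424.0,  263.1, 0.99),
    ("22", "SHR",    "female", 0.000655, 0.73, 530.0,  123.3, 0.92),
    ("23", "SHR",    "female", 0.000401, 1.70, 369.6,  201.5, 0.96),
    ("24", "SHR",    "female", 0.000415, 1.61, 377.0,  194.7, 0.92),
    ("25", "SHR",    "female", 0.000256, 2.36, 418.5,  315.3, 0.82),
    ("26", "SHR",    "female", 0.000132, 1.44, 1328.4, 612.0, 0.97),
    ("27", "SHR",    "female", 0.001036, 2.96, 82.3,   78.0,  0.93),
    ("28", "SHR",    "female", 0.001362, 0.51, 366.0,  59.3,  0.88),
]

#: printed per-sex and overall summary cells used for cross-checks,
#: as (strain, sex-or-"all", measure) → (printed mean, decimals printed)
REFERENCE_STRATUM_MEANS = {
    ("SHR", "male", "alpha"): (0.000481, 6),
    ("SHR", "female", "alpha"): (0.000608, 6),
    ("SHR", "all", "alpha"): (0.000545, 6),
    ("SHR", "male", "omax"): (224.0, 1),
    ("SHR", "female", "omax"): (226.3, 1),
    ("SHR", "all", "omax"): (225.2, 1),
    ("Wistar", "male", "q0"): (1.79, 2),
    ("Wistar", "female", "q0"): (2.06, 2),
    ("Wistar", "all", "q0"): (1.94, 2),
}


def reference_parameters() -> pd.DataFrame:
    """The printed individual-subject parameter table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
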