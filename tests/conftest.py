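import numpy as np
import pandas as pd
import pytest

import opdemand as od


@pytest.fixture(scope="session")
def fixture_cohort():
    return od.make_fixture_cohort()


@pytest.fixture(scope="session")
def reference_table():
    """Printed individual best-fit parameters (28 subjects, k = 2.218)."""
    return od.reference_parameters()


def make_subject_frame(subject_id, active, inactive, infusions,
                       strain="Wistar", sex="male", dose=30.0,
                       n_fr1=7):
    """Long-format acquisition rows from per-session count arrays."""
    rows = []
    for i, (a, ina, inf) in enumerate(zip(active, inactive, infusions), start=1):
        fr = 1 if i <= n_fr1 else 2
        rows.append({
            "subject_id": subject_id, "strain": strain, "sex": sex,
            "unit_dose_ug_kg": dose,
            "phase": "FR1_acq" if fr == 1 else "FR2_acq",
            "session_index": i, "fr_value": fr,
            "active_responses": int(a), "inactive_responses": int(ina),
            "infusions": int(inf),
        })
    return pd.DataFrame(rows, columns=od.data_model.SESSION_COLUMNS)


def exhaustive_window_classification(active, inactive, infusions, ci_upper):
    """Brute-force oracle: evaluate every 3-session window independently.

    ``ci_upper`` maps window end-session -> saline CI upper bound.
    Returns {session: True/False} for sessions 3..S.
    """
    active = np.asarray(active, float)
    inactive = np.asarray(inactive, float)
    infusions = np.asarray(infusions, float)
    out = {}
    for s in range(3, len(active) + 1):
        w = slice(s - 3, s)
        a, i, f = active[w].mean(), inactive[w].mean(), infusions[w].mean()
        out[s] = (a > 0) and (a >= 2 * i) and (f > ci_upper[s])
    return out
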