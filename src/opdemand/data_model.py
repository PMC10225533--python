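"""Domain types and CSV interchange for operant self-administration data.

The canonical on-disk format is a long-format ``sessions.csv`` with one row
per subject-day.  In memory a cohort is a :class:`Cohort`: a mapping of
:class:`Subject` metadata plus a validated :class:`pandas.DataFrame` of
session rows.  Consumption is never stored — it is always derived as
``infusions × unit dose`` (the infusion count is the canonical intake field).

Units
-----
unit_dose_ug_kg   μg/kg per infusion (0 encodes saline)
unit dose (mg/kg) unit_dose_ug_kg / 1000
unit price        FR per mg/kg
consumption       mg/kg per session
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRAINS = ("SHR", "Wistar", "WKY")
SEXES = ("male", "female")
PHASES = ("FR1_acq", "FR2_acq", "demand")

#: unit doses used in study-replication mode (μg/kg; 0 = saline)
STUDY_DOSES_UG_KG = (0.0, 4.0, 30.0)

SESSION_COLUMNS = [
    "subject_id", "strain", "sex", "unit_dose_ug_kg", "phase",
    "session_index", "fr_value", "active_responses", "inactive_responses",
    "infusions",
]

PARAMETER_COLUMNS = [
    "subject_id", "strain", "sex", "alpha", "q0", "k",
    "pmax_exact", "pmax_approx", "omax", "r2", "n_points",
]

#: subject_id tokens reserved for summary rows in parameters.csv
_SUMMARY_TOKENS = ("mean", "sem")


class FormatError(ValueError):
    """Malformed input file (missing column, bad header, unparseable value)."""


class ValidationError(ValueError):
    """Well-formed file whose contents violate a domain invariant."""


@dataclass(frozen=True)
class Subject:
    """One animal: immutable design-cell metadata."""

    subject_id: str
    strain: str
    sex: str
    unit_dose_ug_kg: float

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown strain {self.strain!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"subject {self.subject_id}: unknown sex {self.sex!r}"
            )
        if self.unit_dose_ug_kg < 0:
            raise ValidationError(
                f"subject {self.subject_id}: negative unit dose"
            )

    @property
    def unit_dose_mg_kg(self) -> float:
        return self.unit_dose_ug_kg / 1000.0

    @property
    def is_saline(self) -> bool:
        return self.unit_dose_ug_kg == 0


@dataclass(frozen=True)
class SessionRecord:
    """One subject-day of operant data."""

    subject_id: str
    phase: str
    session_index: int
    fr_value: int
    active_responses: int
    inactive_responses: int
    infusions: int

    def __post_init__(self) -> None:
        sid, s = self.subject_id, self.session_index
        if self.phase not in PHASES:
            raise ValidationError(f"{sid} session {s}: unknown phase {self.phase!r}")
        if s < 1:
            raise ValidationError(f"{sid}: session_index must be >= 1")
        if self.fr_value < 1:
            raise ValidationError(f"{sid} session {s}: fr_value must be >= 1")
        if min(self.active_responses, self.inactive_responses, self.infusions) < 0:
            raise ValidationError(f"{sid} session {s}: negative count")
        # Timeout responses are recorded but unreinforced, so
        # infusions*fr <= active is NOT required; infusions <= active is.
        if self.infusions > self.active_responses:
            raise ValidationError(
                f"{sid} session {s}: infusions ({self.infusions}) exceed "
                f"active responses ({self.active_responses})"
            )
        if self.phase == "FR1_acq" and self.fr_value != 1:
            raise ValidationError(f"{sid} session {s}: FR1_acq requires fr_value 1")
        if self.phase == "FR2_acq" and self.fr_value != 2:
            raise ValidationError(f"{sid} session {s}: FR2_acq requires fr_value 2")


@dataclass(frozen=True)
class DemandObservation:
    """One (unit price, consumption) point on a subject's demand curve."""

    unit_price: float       # FR per mg/kg
    consumption: float      # mg/kg per session
    replaced_zero: bool = False

    def __post_init__(self) -> None:
        if self.unit_price <= 0:
            raise ValidationError("unit_price must be positive")
        if self.consumption < 0:
            raise ValidationError("consumption must be non-negative")
        if self.replaced_zero and self.consumption != 0.01:
            raise ValidationError("replaced_zero observation must have consumption 0.01")


@dataclass
class DemandParameters:
    """Best-fit exponential demand parameters and derived indices.

    ``alpha`` is the demand elasticity (1/responses), ``q0`` the demand
    intensity (mg/kg at zero price), ``k`` the shared log10 consumption
    range.  ``pmax_exact`` is the unit price of unit elasticity,
    ``pmax_approx`` the legacy spreadsheet closed-form approximation, and
    ``omax`` the peak expenditure (responses per session) at ``pmax_exact``.
    """

    q0: float
    alpha: float
    k: float
    pmax_exact: float = float("nan")
    pmax_approx: float = float("nan")
    omax: float = float("nan")
    r2: float = float("nan")
    n_points: int = 0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.q0 <= 0 or self.alpha <= 0 or self.k <= 0:
            raise ValidationError("q0, alpha, and k must all be positive")


@dataclass(frozen=True)
class Cohort:
    """A validated cohort: subject metadata plus long-format session table."""

    subjects: Mapping[str, Subject]
    sessions: pd.DataFrame

    def record_counts(self) -> dict[str, int]:
        """Number of session rows per subject."""
        counts = self.sessions.groupby("subject_id").size()
        return {sid: int(counts.get(sid, 0)) for sid in self.subjects}

    def subject_sessions(self, subject_id: str, phase: str | None = None) -> pd.DataFrame:
        df = self.sessions[self.sessions["subject_id"] == subject_id]
        if phase is not None:
            df = df[df["phase"] == phase]
        return df.sort_values(["phase", "session_index"]).reset_index(drop=True)

    def saline_subjects(self, strain: str | None = None) -> list[str]:
        out = [s.subject_id for s in self.subjects.values() if s.is_saline]
        if strain is not None:
            out = [sid for sid in out if self.subjects[sid].strain == strain]
        return sorted(out)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def cohort_from_frame(df: pd.DataFrame) -> Cohort:
    """Validate a raw long-format session frame into a :class:`Cohort`.

    Every row is checked against the :class:`SessionRecord` invariants and
    subject metadata must be consistent across a subject's rows; the first
    violation raises :class:`ValidationError`, rejecting the whole input.
    """
    df = df.copy()
    if len(df):
        int_cols = ["session_index", "fr_value", "active_responses",
                    "inactive_responses", "infusions"]
        for c in int_cols:
            as_float = pd.to_numeric(df[c], errors="raise").astype(float)
            if not np.all(as_float == np.round(as_float)):
                raise ValidationError(f"column {c} contains non-integer values")
            df[c] = as_float.astype(int)
        df["unit_dose_ug_kg"] = pd.to_numeric(df["unit_dose_ug_kg"]).astype(float)

    subjects: dict[str, Subject] = {}
    for row in df.itertuples(index=False):
        subj = Subject(str(row.subject_id), str(row.strain), str(row.sex),
                       float(row.unit_dose_ug_kg))
        prev = subjects.setdefault(subj.subject_id, subj)
        if prev != subj:
            raise ValidationError(
                f"subject {subj.subject_id}: inconsistent strain/sex/dose across rows"
            )
        SessionRecord(str(row.subject_id), str(row.phase), int(row.session_index),
                      int(row.fr_value), int(row.active_responses),
                      int(row.inactive_responses), int(row.infusions))
    df = df[SESSION_COLUMNS] if len(df) else pd.DataFrame(columns=SESSION_COLUMNS)
    df = df.sort_values(["subject_id", "phase", "session_index"],
                        kind="stable").reset_index(drop=True)
    return Cohort(subjects=subjects, sessions=df)


def load_sessions(path: str | Path) -> Cohort:
    """Read and validate a ``sessions.csv`` file.

    Raises
    ------
    FormatError
        if the file lacks a documented column.
    ValidationError
        if any row violates a :class:`SessionRecord` invariant (e.g. more
        infusions than active-lever responses); the error names the subject
        and session.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc
    _require_columns(df, SESSION_COLUMNS, path)
    return cohort_from_frame(df)


def write_sessions(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to ``sessions.csv`` (lossless for all fields)."""
    cohort.sessions[SESSION_COLUMNS].to_csv(path, index=False)


def parameter_frame(
    params: Sequence[tuple[Subject, DemandParameters]],
) -> pd.DataFrame:
    """Per-subject parameter rows (no summary rows) as a DataFrame."""
    rows = []
    for subj, p in params:
        rows.append({
            "subject_id": subj.subject_id, "strain": subj.strain,
            "sex": subj.sex, "alpha": p.alpha, "q0": p.q0, "k": p.k,
            "pmax_exact": p.pmax_exact, "pmax_approx": p.pmax_approx,
            "omax": p.omax, "r2": p.r2, "n_points": p.n_points,
        })
    return pd.DataFrame(rows, columns=PARAMETER_COLUMNS)


_NUMERIC_PARAM_COLS = ["alpha", "q0", "k", "pmax_exact", "pmax_approx", "omax", "r2"]


def _summary_rows(block: pd.DataFrame, strain: str, sex: str) -> list[dict]:
    mean = {"subject_id": "mean", "strain": strain, "sex": sex,
            "n_points": int(len(block))}
    sem = {"subject_id": "sem", "strain": strain, "sex": sex,
           "n_points": int(len(block))}
    n = len(block)
    for c in _NUMERIC_PARAM_COLS:
        vals = block[c].to_numpy(float)
        mean[c] = float(np.mean(vals))
        sem[c] = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return [mean, sem]


def write_parameter_table(
    params: Sequence[tuple[Subject, DemandParameters]],
    path: str | Path,
) -> pd.DataFrame:
    """Write ``parameters.csv``: one row per subject plus mean and SEM rows.

    Summary rows are appended for every strain × sex stratum and for each
    strain overall, recomputed from the data rows.  Values are written with
    10 significant digits so a read-back round-trips to well beyond 6
    significant digits.  Returns the full frame written.
    """
    if not params:
        raise ValidationError("cannot write an empty parameter table")
    data = parameter_frame(params)
    blocks = [data]
    for strain in sorted(data["strain"].unique()):
        sdf = data[data["strain"] == strain]
        for sex in sorted(sdf["sex"].unique()):
            blocks.append(pd.DataFrame(_summary_rows(sdf[sdf["sex"] == sex], strain, sex),
                                       columns=PARAMETER_COLUMNS))
        blocks.append(pd.DataFrame(_summary_rows(sdf, strain, "all"),
                                   columns=PARAMETER_COLUMNS))
    full = pd.concat(blocks, ignore_index=True)
    full.to_csv(path, index=False, float_format="%.10g")
    return full


def read_parameter_table(
    path: str | Path,
) -> list[tuple[Subject, DemandParameters]]:
    """Read back ``parameters.csv``, skipping mean/SEM summary rows.

    The parameter file does not store unit dose; subjects are rebuilt with a
    30 μg/kg placeholder because demand assessment in the emulated design
    occurs only at that dose.
    """
    df = pd.read_csv(Path(path))
    _require_columns(df, PARAMETER_COLUMNS, Path(path))
    out = []
    for row in df.itertuples(index=False):
        if str(row.subject_id) in _SUMMARY_TOKENS:
            continue
        subj = Subject(str(row.subject_id), str(row.strain), str(row.sex), 30.0)
        p = DemandParameters(
            q0=float(row.q0), alpha=float(row.alpha), k=float(row.k),
            pmax_exact=float(row.pmax_exact), pmax_approx=float(row.pmax_approx),
            omax=float(row.omax), r2=float(row.r2), n_points=int(row.n_points),
        )
        out.append((subj, p))
    return out


def records_to_frame(records: Iterable[SessionRecord],
                     subject: Subject) -> pd.DataFrame:
    """Expand SessionRecords of one subject into long-format rows."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "strain": subject.strain,
            "sex": subject.sex, "unit_dose_ug_kg": subject.unit_dose_ug_kg,
            "phase": r.phase, "session_index": r.session_index,
            "fr_value": r.fr_value, "active_responses": r.active_responses,
            "inactive_responses": r.inactive_responses, "infusions": r.infusions,
        })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)
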