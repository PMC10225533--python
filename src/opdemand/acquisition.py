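"""Acquisition classification for drug self-administration.

A subject is classified as having acquired self-administration at session s
(s >= 3) when, over the window of the three most recent sessions (s-2..s):

1. mean active-lever responding is at least twice mean inactive-lever
   responding (with some active responding), and
2. mean infusions earned exceed — strictly — the upper bound of the 95%
   confidence interval of the mean of saline controls over the same three
   sessions.

Both criteria must hold in the same window.  Subjects that never meet the
joint criterion during acquisition but show the 2:1 lever discrimination in
any three consecutive sessions of the FR-escalation (demand) phase are
counted as acquired via the demand-phase re-check.

Group curves report, per session, the proportion of subjects meeting
criterion; by default the convention is cumulative (once met, counted met
thereafter), which yields the monotone acquisition curves conventionally
plotted; a per-window mode is available.  Strain contrasts of final-session
proportions use Fisher's exact test with a Bonferroni-corrected threshold
of 0.05/2 = 0.025 (one comparison per FR phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Cohort, ValidationError

#: classification begins at the first session with a full 3-session history
FIRST_EVALUABLE_SESSION = 3
WINDOW = 3

#: Bonferroni-corrected significance threshold for the two FR-phase
#: comparisons of final-session acquisition proportions
BONFERRONI_ALPHA = 0.05 / 2

MET, NOT_MET, NOT_EVALUABLE = "met", "not_met", "not_evaluable"


@dataclass(frozen=True)
class SalineReference:
    """Saline-control infusion level over a 3-session window, with 95% CI."""

    window: tuple[int, int]
    n_subjects: int
    mean_infusions: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("saline reference requires >= 2 subjects")
        if not (self.ci_lower <= self.mean_infusions <= self.ci_upper):
            raise ValidationError("CI must bracket the mean")


@dataclass(frozen=True)
class AcquisitionResult:
    """Per-session acquisition status for one subject."""

    subject_id: str
    per_session_status: Mapping[int, str]
    first_session_met: int | None
    acquired_in_demand: bool = False

    @property
    def acquired(self) -> bool:
        return self.first_session_met is not None or self.acquired_in_demand


def saline_reference(
    per_subject_means: Sequence[float],
    window: tuple[int, int],
) -> SalineReference:
    """95% t-interval on the mean of saline subjects' 3-session mean infusions.

    The SEM uses the sample standard deviation (ddof=1) of the per-subject
    window means; the critical value is t(0.975, n-1).
    """
    x = np.asarray(per_subject_means, float)
    n = len(x)
    if n < 2:
        raise ValidationError(
            f"saline CI undefined with {n} subject(s); need >= 2"
        )
    mean = float(x.mean())
    sem = float(x.std(ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1)) * sem
    return SalineReference(window=(int(window[0]), int(window[1])),
                           n_subjects=n, mean_infusions=mean,
                           ci_lower=mean - half, ci_upper=mean + half)


def lever_discrimination_met(active_window_mean: float,
                             inactive_window_mean: float) -> bool:
    """2:1 active:inactive criterion, division-free and boundary-inclusive.

    True iff mean active >= 2 × mean inactive and there is any active
    responding (zero on both levers is not discrimination).
    """
    if active_window_mean < 0 or inactive_window_mean < 0:
        raise ValidationError("window means must be non-negative")
    return active_window_mean > 0 and active_window_mean >= 2 * inactive_window_mean


def build_saline_references(
    cohort: Cohort,
    scope: str = "strain",
    last_session: int | None = None,
) -> dict[str, dict[tuple[int, int], SalineReference]]:
    """Saline references for every 3-session window, per strain or pooled.

    Returns ``{strain: {window: SalineReference}}``; with ``scope="pooled"``
    every strain maps to the same pooled references.  Windows for which any
    saline subject lacks a session are omitted (downstream classification
    marks them not_evaluable).
    """
    if scope not in ("strain", "pooled"):
        raise ValidationError(f"unknown saline scope {scope!r}")
    acq = cohort.sessions[cohort.sessions["phase"].isin(["FR1_acq", "FR2_acq"])]
    if last_session is None:
        last_session = int(acq["session_index"].max()) if len(acq) else 0
    strains = sorted({s.strain for s in cohort.subjects.values()})
    out: dict[str, dict[tuple[int, int], SalineReference]] = {}

    def refs_for(saline_ids: list[str]) -> dict[tuple[int, int], SalineReference]:
        refs = {}
        for s in range(FIRST_EVALUABLE_SESSION, last_session + 1):
            window = (s - WINDOW + 1, s)
            means = []
            ok = len(saline_ids) >= 2
            for sid in saline_ids:
                rows = acq[(acq["subject_id"] == sid)
                           & acq["session_index"].between(*window)]
                if len(rows) < WINDOW:
                    ok = False
                    break
                means.append(float(rows["infusions"].mean()))
            if ok:
                refs[window] = saline_reference(means, window)
        return refs

    if scope == "pooled":
        pooled = refs_for(cohort.saline_subjects())
        return {strain: pooled for strain in strains}
    for strain in strains:
        out[strain] = refs_for(cohort.saline_subjects(strain=strain))
    return out


def classify_acquisition(
    subject_sessions: pd.DataFrame,
    saline_by_window: Mapping[tuple[int, int], SalineReference],
) -> AcquisitionResult:
    """Classify one subject's acquisition sessions window by window.

    ``subject_sessions`` holds the acquisition-phase rows of a single
    subject with contiguous session indices 1..S (S >= 3); windows may span
    the FR 1 → FR 2 boundary since the acquisition phase is analyzed as one
    session sequence.
    """
    df = subject_sessions.sort_values("session_index").reset_index(drop=True)
    sid = str(df["subject_id"].iloc[0])
    idx = df["session_index"].to_numpy(int)
    if idx[0] != 1 or not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValidationError(f"{sid}: session indices must be contiguous from 1")
    if len(idx) < FIRST_EVALUABLE_SESSION:
        raise ValidationError(f"{sid}: need >= 3 acquisition sessions")
    active = df["active_responses"].to_numpy(float)
    inactive = df["inactive_responses"].to_numpy(float)
    infusions = df["infusions"].to_numpy(float)

    status: dict[int, str] = {}
    first_met: int | None = None
    for s in range(FIRST_EVALUABLE_SESSION, len(idx) + 1):
        window = (s - WINDOW + 1, s)
        sl = slice(s - WINDOW, s)
        ref = saline_by_window.get(window)
        if ref is None:
            status[s] = NOT_EVALUABLE
            continue
        discrim = lever_discrimination_met(active[sl].mean(), inactive[sl].mean())
        above_saline = infusions[sl].mean() > ref.ci_upper  # strictly above the CI
        status[s] = MET if (discrim and above_saline) else NOT_MET
        if status[s] == MET and first_met is None:
            first_met = s
    return AcquisitionResult(subject_id=sid, per_session_status=status,
                             first_session_met=first_met)


def demand_phase_recheck(demand_sessions: pd.DataFrame) -> bool | None:
    """2:1 lever-discrimination re-check over the FR-escalation phase.

    True iff any three consecutive demand sessions satisfy the
    discrimination criterion on window means.  Returns None (not evaluable)
    with fewer than three demand sessions.
    """
    df = demand_sessions.sort_values("session_index").reset_index(drop=True)
    if len(df) < WINDOW:
        return None
    active = df["active_responses"].to_numpy(float)
    inactive = df["inactive_responses"].to_numpy(float)
    for i in range(len(df) - WINDOW + 1):
        if lever_discrimination_met(active[i:i + WINDOW].mean(),
                                    inactive[i:i + WINDOW].mean()):
            return True
    return False


def classify_cohort(
    cohort: Cohort,
    saline_scope: str = "strain",
) -> dict[str, AcquisitionResult]:
    """Classify every non-saline subject, applying the demand-phase re-check."""
    refs = build_saline_references(cohort, scope=saline_scope)
    results: dict[str, AcquisitionResult] = {}
    for sid, subj in cohort.subjects.items():
        if subj.is_saline:
            continue
        acq = cohort.subject_sessions(sid)
        acq = acq[acq["phase"].isin(["FR1_acq", "FR2_acq"])]
        if len(acq) < FIRST_EVALUABLE_SESSION:
            continue
        res = classify_acquisition(acq, refs.get(subj.strain, {}))
        if res.first_session_met is None:
            dem = cohort.subject_sessions(sid, phase="demand")
            if len(dem) and demand_phase_recheck(dem):
                res = AcquisitionResult(
                    subject_id=res.subject_id,
                    per_session_status=res.per_session_status,
                    first_session_met=None,
                    acquired_in_demand=True,
                )
        results[sid] = res
    return results


def acquisition_proportions(
    results: Mapping[str, AcquisitionResult],
    groups: Mapping[str, str],
    cumulative: bool = True,
) -> pd.DataFrame:
    """Per-session proportion of each group meeting criterion.

    ``groups`` maps subject_id → group label (typically strain).  Under the
    cumulative convention a subject counts as met at every session at or
    after its first_session_met, giving monotone non-decreasing curves;
    ``cumulative=False`` counts only sessions whose own window status is met.
    """
    if not results:
        raise ValidationError("no acquisition results")
    sessions = sorted({s for r in results.values() for s in r.per_session_status})
    labels = sorted(set(groups[sid] for sid in results))
    rows = []
    for label in labels:
        ids = [sid for sid in results if groups[sid] == label]
        if not ids:
            raise ValidationError(f"empty group {label!r}")
        for s in sessions:
            if cumulative:
                met = sum(
                    1 for sid in ids
                    if results[sid].first_session_met is not None
                    and results[sid].first_session_met <= s
                )
            else:
                met = sum(
                    1 for sid in ids
                    if results[sid].per_session_status.get(s) == MET
                )
            rows.append({"group": label, "session_index": s,
                         "n": len(ids), "n_met": met,
                         "proportion": met / len(ids)})
    return pd.DataFrame(rows)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The two-sided p sums all hypergeometric tables with the margins fixed
    whose probability does not exceed that of the observed table.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValidationError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_significant(p: float, alpha: float = BONFERRONI_ALPHA) -> bool:
    """Apply the Bonferroni-corrected threshold (0.025 for two FR phases)."""
    return p < alpha


def compare_final_session_proportions(
    results: Mapping[str, AcquisitionResult],
    groups: Mapping[str, str],
    session: int,
) -> dict:
    """Fisher exact contrast of cumulative met counts at one session."""
    labels = sorted(set(groups[sid] for sid in results))
    if len(labels) != 2:
        raise ValidationError("exactly two groups required")
    counts = {}
    for label in labels:
        ids = [sid for sid in results if groups[sid] == label]
        met = sum(1 for sid in ids
                  if results[sid].first_session_met is not None
                  and results[sid].first_session_met <= session)
        counts[label] = (met, len(ids) - met)
    (a, b), (c, d) = counts[labels[0]], counts[labels[1]]
    p = fisher_exact_2x2(a, b, c, d)
    return {"session_index": session, "groups": tuple(labels),
            "table": ((a, b), (c, d)), "p_value": p,
            "significant": fisher_significant(p)}
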