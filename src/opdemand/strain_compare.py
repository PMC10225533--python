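"""Between-group comparison of fitted demand parameters.

Fitted indices are compared between strains (and, descriptively, between
sexes within strain) with independent-samples Welch t-tests — unequal
variances, Satterthwaite degrees of freedom, two-sided p.  Demand
elasticity alpha is compared on the log10 scale, which normalizes its
right-skewed distribution; Q0, Pmax and Omax are compared on their natural
scales.  No multiplicity correction is applied across the four measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PARAMETER_COLUMNS, ValidationError

#: measure name → column of parameters.csv and transform
MEASURES = {
    "log10_alpha": ("alpha", np.log10),
    "q0": ("q0", None),
    "pmax": ("pmax_exact", None),
    "omax": ("omax", None),
}


@dataclass(frozen=True)
class ComparisonResult:
    """One Welch two-sample contrast of a demand measure."""

    measure: str
    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    group_sems: tuple[float, float]
    n: tuple[int, int]
    t_statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p-value outside (0, 1]")
        if self.df > self.n[0] + self.n[1] - 2 + 1e-9:
            raise ValidationError("Welch df cannot exceed pooled df")


def welch_t(
    x: Sequence[float],
    y: Sequence[float],
    measure: str = "",
    labels: tuple[str, str] = ("x", "y"),
) -> ComparisonResult:
    """Welch's unequal-variance t-test, two-sided."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        # degenerate: identical constants in both groups
        if x.mean() == y.mean():
            return ComparisonResult(measure, labels,
                                    (float(x.mean()), float(y.mean())),
                                    (0.0, 0.0), (len(x), len(y)),
                                    0.0, float(len(x) + len(y) - 2), 1.0)
        raise ValidationError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    sems = (float(x.std(ddof=1) / np.sqrt(len(x))),
            float(y.std(ddof=1) / np.sqrt(len(y))))
    return ComparisonResult(
        measure=measure, group_labels=labels,
        group_means=(float(x.mean()), float(y.mean())),
        group_sems=sems, n=(len(x), len(y)),
        t_statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue),
    )


def compare_all_parameters(param_table: pd.DataFrame) -> list[ComparisonResult]:
    """All strain (and within-strain sex) contrasts of the demand measures.

    ``param_table`` is a per-subject frame with the ``parameters.csv``
    columns (summary rows excluded).  For each measure the strain contrast
    is primary; sex contrasts within each strain are descriptive.
    """
    missing = [c for c in PARAMETER_COLUMNS if c not in param_table.columns]
    if missing:
        raise ValidationError(f"parameter table missing columns {missing}")
    df = param_table[~param_table["subject_id"].isin(["mean", "sem"])]
    strains = sorted(df["strain"].unique())
    results: list[ComparisonResult] = []

    def values(block: pd.DataFrame, measure: str) -> np.ndarray:
        col, tf = MEASURES[measure]
        v = block[col].to_numpy(float)
        return tf(v) if tf is not None else v

    if len(strains) == 2:
        a = df[df["strain"] == strains[0]]
        b = df[df["strain"] == strains[1]]
        for measure in MEASURES:
            results.append(welch_t(values(a, measure), values(b, measure),
                                   measure=measure,
                                   labels=(strains[0], strains[1])))
    for strain in strains:
        block = df[df["strain"] == strain]
        sexes = sorted(block["sex"].unique())
        if len(sexes) != 2:
            continue
        m = block[block["sex"] == sexes[0]]
        f = block[block["sex"] == sexes[1]]
        if len(m) < 2 or len(f) < 2:
            continue
        for measure in MEASURES:
            results.append(welch_t(values(m, measure), values(f, measure),
                                   measure=measure,
                                   labels=(f"{strain}/{sexes[0]}",
                                           f"{strain}/{sexes[1]}")))
    if not results:
        raise ValidationError("no contrast with two groups of n >= 2")
    return results


def comparisons_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tabulate comparison results for ``comparisons.csv``."""
    return pd.DataFrame([{
        "measure": r.measure,
        "group_a": r.group_labels[0], "group_b": r.group_labels[1],
        "mean_a": r.group_means[0], "mean_b": r.group_means[1],
        "sem_a": r.group_sems[0], "sem_b": r.group_sems[1],
        "n_a": r.n[0], "n_b": r.n[1],
        "t": r.t_statistic, "df": r.df, "p_value": r.p_value,
    } for r in results])
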