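"""Exponential behavioral-economic demand: model, fitting, derived indices.

The model is the exponential demand equation

    log10 Q(C) = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)

where ``C`` is unit price (FR per mg/kg), ``Q`` consumption (mg/kg per
session), ``Q0`` demand intensity (consumption at zero price), ``alpha``
demand elasticity (inversely related to reinforcing efficacy), and ``k`` a
constant fixing the log10 range of the curve, shared across groups so that
``alpha`` is comparable between subjects and conditions.

Derived indices:

* ``pmax_exact`` — the unit price at which the point elasticity
  d(log10 Q)/d(log10 C) equals −1, i.e. where demand turns from inelastic
  to elastic.  Writing u = alpha*Q0*C, elasticity = −k·ln(10)·u·e^(−u), so
  Pmax solves u·e^(−u) = 1/(k·ln 10); the inelastic-side root is
  u* = −W0(−1/(k·ln 10)) with W0 the principal Lambert-W branch, and
  Pmax = u*/(alpha·Q0).
* ``omax`` — peak expenditure C·Q(C) in responses per session, attained at
  Pmax: Omax = (u*/alpha)·10^(k·(e^(−u*) − 1)).
* ``pmax_approx`` — the closed-form approximation used by the legacy
  spreadsheet template, (0.084·k + 0.65)/(Q0·alpha·k^1.5), kept for
  cross-reference with historically reported values.

Fitting minimizes squared residuals in log10-consumption space; zero
consumption at the terminal price is replaced with 0.01 mg/kg (one log
unit below the log of a single 0.03 mg/kg infusion) so the point is defined
on the log scale and the demand function is complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import lambertw

from .data_model import (
    DemandObservation,
    DemandParameters,
    ValidationError,
)

LN10 = math.log(10.0)

#: consumption (mg/kg) substituted for a terminal zero-infusion session
ZERO_REPLACEMENT = 0.01

#: bounds for the shared range constant k when it is estimated
K_BOUNDS = (0.5, 6.0)

#: log10(alpha) search bounds; alpha at the lower bound flags a degenerate fit
_LOG_ALPHA_BOUNDS = (-9.0, 0.0)
_LOG_ALPHA_STARTS = (-5.0, -4.0, -3.5, -3.0, -2.5, -2.0)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries per-start diagnostics."""


@dataclass(frozen=True)
class DemandSeries:
    """One subject's ordered demand curve (ascending unit price)."""

    subject_id: str
    observations: tuple[DemandObservation, ...]
    unit_dose_mg_kg: float

    def __post_init__(self) -> None:
        if self.unit_dose_mg_kg <= 0:
            raise ValidationError("unit_dose_mg_kg must be positive")
        prices = [o.unit_price for o in self.observations]
        if any(b <= a for a, b in zip(prices, prices[1:])):
            raise ValidationError(
                f"{self.subject_id}: unit prices must be strictly increasing"
            )
        for i, o in enumerate(self.observations):
            if o.replaced_zero and i != len(self.observations) - 1:
                raise ValidationError(
                    f"{self.subject_id}: replaced zero must be the final observation"
                )
            if o.consumption == 0:
                raise ValidationError(
                    f"{self.subject_id}: raw zero consumption; apply the "
                    "0.01 replacement via prepare_demand_series"
                )

    @property
    def prices(self) -> np.ndarray:
        return np.array([o.unit_price for o in self.observations], float)

    @property
    def consumptions(self) -> np.ndarray:
        return np.array([o.consumption for o in self.observations], float)


# ---------------------------------------------------------------------------
# price / consumption construction
# ---------------------------------------------------------------------------

def unit_price(fr_value: float, unit_dose_mg_kg: float) -> float:
    """Unit price C = FR / dose, in responses per mg/kg."""
    if fr_value <= 0:
        raise ValidationError("fr_value must be positive")
    if unit_dose_mg_kg <= 0:
        raise ValidationError("unit dose must be positive")
    return fr_value / unit_dose_mg_kg


def consumption_mg_kg(infusions: float, unit_dose_mg_kg: float) -> float:
    """Session consumption Q = infusions × dose, in mg/kg."""
    if unit_dose_mg_kg <= 0:
        raise ValidationError("unit dose must be positive")
    if infusions < 0:
        raise ValidationError("infusions must be non-negative")
    return infusions * unit_dose_mg_kg


def prepare_demand_series(
    demand_sessions: pd.DataFrame,
    unit_dose_mg_kg: float,
    subject_id: str | None = None,
) -> DemandSeries:
    """Build a :class:`DemandSeries` from demand-phase session rows.

    Sessions must be ordered by escalating FR.  A zero-infusion session is
    permitted only in terminal position (the stopping rule ends the phase at
    the first zero); its consumption is replaced with 0.01 mg/kg and flagged
    so that the point — which is part of the individual fit — remains
    distinguishable from measured consumption.
    """
    df = demand_sessions.sort_values("session_index").reset_index(drop=True)
    if subject_id is None:
        subject_id = str(df["subject_id"].iloc[0]) if len(df) else "unknown"
    obs: list[DemandObservation] = []
    n = len(df)
    for i, row in enumerate(df.itertuples(index=False)):
        price = unit_price(int(row.fr_value), unit_dose_mg_kg)
        q = consumption_mg_kg(int(row.infusions), unit_dose_mg_kg)
        if q == 0:
            if i != n - 1:
                raise ValidationError(
                    f"{subject_id}: zero infusions at interior FR {row.fr_value}; "
                    "the escalation should have stopped at the first zero"
                )
            obs.append(DemandObservation(price, ZERO_REPLACEMENT, replaced_zero=True))
        else:
            obs.append(DemandObservation(price, q))
    return DemandSeries(subject_id, tuple(obs), unit_dose_mg_kg)


# ---------------------------------------------------------------------------
# model evaluation and derived indices
# ---------------------------------------------------------------------------

def predict_log_consumption(q0: float, alpha: float, k: float,
                            price) -> np.ndarray | float:
    """log10 consumption predicted by the exponential demand equation."""
    c = np.asarray(price, float)
    out = np.log10(q0) + k * (np.exp(-alpha * q0 * c) - 1.0)
    return float(out) if np.isscalar(price) else out


def predict_consumption(q0: float, alpha: float, k: float, price):
    """Consumption in mg/kg (10 ** predict_log_consumption)."""
    return 10.0 ** predict_log_consumption(q0, alpha, k, price)


def elasticity(q0: float, alpha: float, k: float, price: float) -> float:
    """Point elasticity d(log10 Q)/d(log10 C) at the given unit price."""
    u = alpha * q0 * price
    return -k * LN10 * u * math.exp(-u)


def _u_star(k: float) -> float:
    """Inelastic-side root of u·e^(−u) = 1/(k·ln 10) (principal Lambert-W)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    arg = -1.0 / (k * LN10)
    if arg < -1.0 / math.e:
        # elasticity never reaches −1: max |elasticity| = k·ln10/e < 1
        raise ValidationError(f"k = {k} too small for unit elasticity to occur")
    return float(-lambertw(arg, 0).real)


def pmax_exact(q0: float, alpha: float, k: float) -> float:
    """Unit price of unit elasticity, Pmax = u*/(alpha·Q0)."""
    if q0 <= 0 or alpha <= 0:
        raise ValidationError("q0 and alpha must be positive")
    return _u_star(k) / (alpha * q0)


def pmax_approx(q0: float, alpha: float, k: float) -> float:
    """Legacy spreadsheet-template approximation of Pmax."""
    if q0 <= 0 or alpha <= 0 or k <= 0:
        raise ValidationError("q0, alpha, k must be positive")
    return (0.084 * k + 0.65) / (q0 * alpha * k ** 1.5)


def omax(q0: float, alpha: float, k: float) -> float:
    """Peak expenditure C·Q(C) (responses per session), attained at Pmax."""
    u = _u_star(k)
    return (u / alpha) * 10.0 ** (k * (math.exp(-u) - 1.0))


def _attach_derived(p: DemandParameters) -> DemandParameters:
    p.pmax_exact = pmax_exact(p.q0, p.alpha, p.k)
    p.pmax_approx = pmax_approx(p.q0, p.alpha, p.k)
    p.omax = omax(p.q0, p.alpha, p.k)
    return p


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _residuals(theta: np.ndarray, k: float, c: np.ndarray,
               logq: np.ndarray) -> np.ndarray:
    lq0, lalpha = theta
    q0, alpha = 10.0 ** lq0, 10.0 ** lalpha
    return np.log10(q0) + k * (np.exp(-alpha * q0 * c) - 1.0) - logq


def fit_demand(series: DemandSeries, k: float) -> DemandParameters:
    """Fit (Q0, alpha) at fixed k by least squares on log10 consumption.

    Multi-start: Q0 is initialized at the maximum observed consumption and
    alpha on a log10 grid, since the loss surface has local minima in alpha.
    The replaced-zero terminal point participates in the fit.  r² is
    computed on log10 consumption.  A fit whose alpha lands on the search
    boundary (e.g. a constant-consumption series, where no price decline is
    identifiable) is flagged ``low_confidence``.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    c, q = series.prices, series.consumptions
    if len(c) < 3:
        raise FitError(
            f"{series.subject_id}: need >= 3 demand observations, got {len(c)}"
        )
    logq = np.log10(q)
    lq0_0 = math.log10(max(q.max(), 1e-6))
    best = None
    diagnostics = []
    for la0 in _LOG_ALPHA_STARTS:
        try:
            res = optimize.least_squares(
                _residuals, x0=[lq0_0, la0], args=(k, c, logq),
                # Q0 is consumption at zero price: allow well below the
                # observed maximum but at most 10x above it, which keeps a
                # flat series from being "fit" by riding the 10^(-k)
                # asymptote of an absurdly large Q0.
                bounds=([lq0_0 - 3.0, _LOG_ALPHA_BOUNDS[0]],
                        [lq0_0 + 1.0, _LOG_ALPHA_BOUNDS[1]]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append(f"start log10(alpha)={la0}: {exc}")
            continue
        if not res.success:
            diagnostics.append(f"start log10(alpha)={la0}: {res.message}")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(
            f"{series.subject_id}: demand fit did not converge; " + "; ".join(diagnostics)
        )
    lq0, lalpha = best.x
    q0_hat, alpha_hat = 10.0 ** lq0, 10.0 ** lalpha
    sse = float(2.0 * best.cost)
    sst = float(np.sum((logq - logq.mean()) ** 2))
    low_conf = lalpha <= _LOG_ALPHA_BOUNDS[0] + 1e-6 or sst < 1e-12
    r2 = 1.0 - sse / sst if sst >= 1e-12 else 0.0
    p = DemandParameters(q0=q0_hat, alpha=alpha_hat, k=k, r2=r2,
                         n_points=len(c), low_confidence=bool(low_conf))
    return _attach_derived(p)


def fit_shared_k(
    series_collection: Sequence[DemandSeries],
    k_init: float = 2.0,
) -> tuple[float, list[DemandParameters]]:
    """Joint fit: one k shared across all series, per-series (Q0, alpha).

    The shared k normalizes consumption so that alpha is comparable across
    subjects.  k is bounded to [0.5, 6].  Refitting each series at the
    returned k reproduces the per-series parameters (the per-series blocks
    of the joint problem separate at fixed k).
    """
    m = len(series_collection)
    if m < 2:
        raise ValidationError(
            "shared-k estimation requires >= 2 series; use fit_demand for one"
        )
    data = [(s.prices, np.log10(s.consumptions)) for s in series_collection]
    for s, (c, _) in zip(series_collection, data):
        if len(c) < 3:
            raise FitError(f"{s.subject_id}: need >= 3 demand observations")

    init = [fit_demand(s, k_init) for s in series_collection]
    x0 = np.empty(1 + 2 * m)
    x0[0] = k_init
    for i, p in enumerate(init):
        x0[1 + 2 * i] = math.log10(p.q0)
        x0[2 + 2 * i] = math.log10(p.alpha)

    def joint_residuals(x: np.ndarray) -> np.ndarray:
        k = x[0]
        parts = []
        for i, (c, logq) in enumerate(data):
            parts.append(_residuals(x[1 + 2 * i: 3 + 2 * i], k, c, logq))
        return np.concatenate(parts)

    lo = np.concatenate([[K_BOUNDS[0]],
                         np.tile([-6.0, _LOG_ALPHA_BOUNDS[0]], m)])
    hi = np.concatenate([[K_BOUNDS[1]],
                         np.tile([6.0, _LOG_ALPHA_BOUNDS[1]], m)])
    res = optimize.least_squares(joint_residuals, x0=np.clip(x0, lo, hi),
                                 bounds=(lo, hi),
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not res.success:
        raise FitError(f"shared-k fit did not converge: {res.message}")
    k_hat = float(res.x[0])
    # per-series refit at the shared k yields consistent derived indices/r2
    params = [fit_demand(s, k_hat) for s in series_collection]
    return k_hat, params


# ---------------------------------------------------------------------------
# group curves (illustration only)
# ---------------------------------------------------------------------------

def group_demand_curve(
    series_collection: Sequence[DemandSeries],
    k: float | None = None,
) -> tuple[pd.DataFrame, DemandParameters | None]:
    """Group mean demand curve with zero-padding past each subject's range.

    For plotting group curves, each subject contributes its observed
    consumption at its achieved prices and 0.01 mg/kg at every higher price
    up to the cohort's maximum achieved price (carrying the terminal zero
    forward).  These padded points exist only here — individual fits and
    statistics never see them.  If ``k`` is given, the exponential demand
    equation is also fit to the group means; that fit is illustration-only.

    Returns a frame with columns price, mean_q, n_contributing,
    interpolated_count, and the optional illustration fit.
    """
    if len(series_collection) < 2:
        raise ValidationError("group curve requires >= 2 series")
    all_prices = sorted({float(p) for s in series_collection for p in s.prices})
    max_price = all_prices[-1]
    per_price: dict[float, list[tuple[float, bool]]] = {p: [] for p in all_prices}
    for s in series_collection:
        obs_by_price = {float(o.unit_price): o for o in s.observations}
        top = max(obs_by_price)
        terminated = s.observations[-1].replaced_zero
        for p in all_prices:
            if p in obs_by_price:
                o = obs_by_price[p]
                per_price[p].append((o.consumption, o.replaced_zero))
            elif terminated and p > top:
                # carry the replaced zero forward to the cohort's max price
                per_price[p].append((ZERO_REPLACEMENT, True))
    rows = []
    for p in all_prices:
        vals = per_price[p]
        rows.append({
            "price": p,
            "mean_q": float(np.mean([v for v, _ in vals])),
            "n_contributing": len(vals),
            "interpolated_count": sum(flag for _, flag in vals),
        })
    frame = pd.DataFrame(rows)
    fit = None
    if k is not None:
        obs = tuple(
            DemandObservation(r["price"], max(r["mean_q"], ZERO_REPLACEMENT))
            for _, r in frame.iterrows()
        )
        dose = series_collection[0].unit_dose_mg_kg
        fit = fit_demand(DemandSeries("group-mean", obs, dose), k)
    return frame, fit
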