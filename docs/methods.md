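# Methods

This note records the scientific and numerical choices behind `opdemand`:
what is modeled, which knobs matter, and what the synthetic cohorts do and
do not establish about real data.

## Demand model and derived indices

Consumption is modeled with the exponential demand equation,
`log10 Q(C) = log10 Q0 + k(e^(−αQ0C) − 1)`, fit in log10-consumption space
— the model is stated in log form, consumption is strictly positive, and
the zero-replacement convention (below) is defined on the log scale. `r²`
is likewise computed on log10 consumption.

**Unit price and consumption.** `C = FR / dose` (responses per mg/kg) and
`Q = infusions × dose` (mg/kg per session). The infusion count is the
canonical intake record; consumption is always derived, never stored.

**Zero handling.** The FR-escalation phase ends at the first session with
0 infusions. That terminal zero is replaced with 0.01 mg/kg — one log
unit below the log of a single 0.03 mg/kg infusion — and *participates in
the individual fit*, completing the demand function. An interior zero
violates the stopping rule and is rejected. Separately, for group-mean
curves only, each subject's 0.01 is carried forward from its terminal
price to the cohort's maximum achieved price; these padded points are
illustration-only and never enter individual fits or statistics.

**Derived indices.** With `u = αQ0C`, elasticity is `−k·ln(10)·u·e^(−u)`.
Unit elasticity requires `k ≥ e/ln 10 ≈ 1.18`; below that the curve is
inelastic everywhere and Pmax/Omax are undefined (the package raises).
Pmax uses the principal Lambert-W branch (`u* = −W0(−1/(k ln 10))`, the
root with `u* < 1`). Omax is the expenditure `C·Q(C)` at Pmax. Note that
expenditure is *not* globally maximal there: because consumption floors at
`Q0·10^(−k)`, expenditure grows without bound as `C → ∞` under the model.
Omax is the stationary peak on the inelastic branch, which is the
behaviorally meaningful maximum (the model is not credited beyond the
observed price range). The spreadsheet-legacy approximation
`(0.084k + 0.65)/(Q0αk^1.5)` tracks the exact root within ±5% only for
`k ≳ 1.7`; at `k = 2.218` the two differ by ~0.5%.

**Fitting.** Nonlinear least squares over `(log10 Q0, log10 α)`
(positivity by construction) with multi-start over a log10 α grid from
−5 to −2, since the loss surface has local minima in α. `Q0` is bounded
to at most 10× the maximum observed consumption: without this, a flat
consumption series can be "fit" exactly by an absurdly large `Q0` riding
its own asymptote. Fits with `α` on the search floor (1e−9) or with zero
log-consumption variance are flagged `low_confidence`. Shared-`k`
estimation solves the joint least-squares problem (one `k` in [0.5, 6]
plus per-series `(Q0, α)`); because the per-series blocks separate at
fixed `k`, refitting each subject at the returned `k` reproduces the
per-subject estimates, which the tests verify.

## Acquisition classifier

A subject meets criterion at session `s ≥ 3` when, over sessions
`(s−2..s)`: mean active ≥ 2 × mean inactive with mean active > 0
(division-free, boundary-inclusive), **and** mean infusions are *strictly
above* the upper bound of the 95% t-interval on the mean of saline
controls' per-subject means over the same window ("above the interval"
reads as exceeding, not touching, the bound). Both criteria must hold in
the same window; windows may span the FR 1 → FR 2 boundary because the 14
acquisition sessions form one sequence. The saline reference is
strain-matched by default (both strains have saline groups) and poolable
by flag; the t-interval uses the sample SD of per-subject window means
and `t(0.975, n−1)`, the conventional construction. Windows sit at fixed
session indices shared by all subjects.

Subjects that never meet the joint criterion but show the 2:1
discrimination in any three consecutive escalation-phase sessions count
as acquired via the demand-phase re-check. Group acquisition curves use
the cumulative convention (once met, met thereafter — monotone by
construction); a per-window mode exists behind a flag. Final-session
strain contrasts use the two-sided conditional Fisher exact test at the
Bonferroni-corrected threshold 0.05/2 = 0.025 (one contrast per FR phase).

## Synthetic cohorts

The generator reproduces the study design it emulates: strain × dose groups
(default sizes 20/27/12/10/8/12 across Wistar/SHR at 30/4/0 μg/kg), 7 FR 1
plus 7 FR 2 daily 23-h acquisition sessions, then daily FR escalation
(3, 6, 9, 15, then doubling) until the first zero-infusion session.

* **Counts.** Each session draws a gamma day-activity factor (mean 1,
  shape = `count_dispersion`, default 6) shared by both levers; active and
  inactive counts are Poisson around `mean × factor`. Marginally the
  counts are negative-binomial (daily operant counts are overdispersed);
  the shared factor models general arousal and keeps the active:inactive
  ratio stable, without which saline controls would show frequent spurious
  "discrimination". `count_dispersion = ∞` gives the Poisson limit.
* **Responders.** Each nicotine subject is a latent responder with
  group-level probability (defaults 0.70/0.52 at 30 μg/kg from the
  completion counts 14/20 and 14/27; 0.08 at the near-threshold 4 μg/kg;
  0 for saline). Responders press the active lever at mean 80/day;
  everyone else at 15/day — equal to the inactive-lever mean, since
  non-acquiring groups show no lever discrimination. Session 1 (food on
  the active lever) gets a +10 active boost; the effect size is not
  quantified anywhere, so it is an ordinary configurable choice.
  Infusions are `⌊active/FR⌋` minus an optional timeout-loss fraction
  (default 0). Daily count distributions are not reported for the
  emulated study; these means are plausibility choices, all
  config-exposed.
* **Demand.** Per-subject true `(Q0, α)` are lognormal around strain
  means (defaults: Wistar 1.94 mg/kg & 4.59e−4, SHR 1.45 & 5.45e−4 — the
  published overall means; SDs 0.10 and 0.25 log10 units), `k = 2.218`
  global. Expected consumption follows the demand equation; multiplicative
  lognormal noise with CV 0.1 (median 1) is applied; realized infusions
  are the rounded quotient by dose. Q0 draws are capped at 2.6 mg/kg:
  above `0.5·dose·10^k ≈ 2.48` the model's consumption floor rounds to a
  standing daily infusion and the first-zero stopping rule could never
  fire — a model artifact, not a behavioral prediction.

**What the simulations do not show.** No pharmacokinetics, no within-day
time course, no body-weight growth, no session-to-session autocorrelation
beyond the day factor, no sex effects (sexes alternate for bookkeeping
only), and demand consumption is generated *from* the model being fit —
recovery results certify the estimator, not the model's adequacy for real
rats.

**Known estimator property.** With integer infusions, the 1–2-infusion
tail sessions quantize log consumption coarsely; at noise CV 0.1 the
median relative error of recovered Q0 is ≈ 10–11% (vs ≈ 6% for continuous
consumption), while α recovers to ≈ 5–6% median error. This is inherent
to fitting day-level integer intake and is shared by any implementation
of this procedure.

## Pipeline

`run` chains simulate (or load) → classify → fit → compare, writing CSVs
plus a flat key-value manifest (versions, seed, config hash, stage
counts). Only acquired subjects (criterion or re-check) enter the demand
stage; acquired subjects without demand data are listed in the manifest.
Everything is deterministic given config and seed (per-subject RNG streams
derived from the seed), and reruns are byte-identical.

## Numerical conventions

* Base-10 logarithms throughout (anchored by `log10 0.01 = −2`).
* Least-squares tolerances 1e−15 (xtol/ftol/gtol); Lambert-W from scipy.
* Welch t-tests (unequal variances, Satterthwaite df, two-sided);
  α compared only after log10 transform; no multiplicity correction
  across the four demand measures. Identical constant samples return
  `t = 0, p = 1` rather than NaN.
* Parameter CSVs are written with 10 significant digits and round-trip
  well beyond 6; mean/SEM summary rows are recomputed from data rows.
* Validation-suite problem sizes: 1,000 random draws for the closed-form
  oracles, 200 replicate subjects for recovery, 500 random series and 30
  cohort replicates for the classifier — chosen to make Monte-Carlo error
  small relative to the margins being tested.

## Published-table notes

The bundled reference table reproduces printed values. Two printed
summary cells are not the arithmetic means of their printed individual
values to the printed precision (the SHR overall α and Wistar overall Q0
cells are one unit off in the last digit — evidently computed upstream
from unrounded fits), and the Wistar α/Pmax mean cells deviate further;
the table writer always recomputes summaries from data rows and does not
attempt to reproduce those cells. Printed Pmax values derive from a
spreadsheet solver and differ from the exact unit-elasticity root by up
to ~1%; the exact root is canonical here, with the template approximation
available for cross-reference.
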