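import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import opdemand as od
from opdemand.demand import (
    DemandObservation,
    DemandSeries,
    elasticity,
    fit_demand,
    fit_shared_k,
    group_demand_curve,
    omax,
    pmax_approx,
    pmax_exact,
    predict_consumption,
    predict_log_consumption,
    prepare_demand_series,
)

K = 2.218


def model_series(q0, alpha, k, prices, dose=0.03, subject_id="m"):
    obs = tuple(DemandObservation(c, predict_consumption(q0, alpha, k, c))
                for c in prices)
    return DemandSeries(subject_id, obs, dose)


def pmax_root_oracle(q0, alpha, k):
    """Independent oracle: bracketed root of elasticity = -1 on the
    inelastic side (u < 1), using the analytic elasticity expression."""
    f = lambda c: elasticity(q0, alpha, k, c) + 1.0
    hi = 1.0 / (alpha * q0)          # u = 1: elasticity magnitude maximal
    lo = 1e-12 / (alpha * q0)
    return optimize.brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16)


def omax_grid_oracle(q0, alpha, k):
    """Dense log-grid expenditure maximum, polished with Brent.

    The peak expenditure is the stationary point on the inelastic branch
    (u = alpha*Q0*C < 1; elasticity is below -1 everywhere in (u*, 1]), so
    the search covers u in [1e-3, 1].  Beyond the second unit-elasticity
    crossing expenditure rises again without bound because consumption
    floors at Q0*10^(-k) — the global supremum over all C is infinite and
    not the quantity of interest.
    """
    grid = np.logspace(math.log10(1e-3 / (alpha * q0)),
                       math.log10(1.0 / (alpha * q0)), 4000)
    expend = grid * predict_consumption(q0, alpha, k, grid)
    i = int(np.argmax(expend))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda c: -c * predict_consumption(q0, alpha, k, c),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * grid[i]})
    return -res.fun


class TestPriceAndConsumption:
    @pytest.mark.parametrize("fr,dose,expected", [
        (1, 0.03, 100 / 3), (3, 0.03, 100.0), (2, 0.004, 500.0)])
    def test_unit_price(self, fr, dose, expected):
        assert od.unit_price(fr, dose) == pytest.approx(expected)

    def test_unit_price_rejects_nonpositive_dose(self):
        with pytest.raises(od.ValidationError):
            od.unit_price(3, 0.0)

    def test_consumption(self):
        assert od.consumption_mg_kg(10, 0.03) == pytest.approx(0.3)
        assert od.consumption_mg_kg(0, 0.03) == 0.0
        # a single 0.03 mg/kg infusion sits at -1.52 log units
        assert math.log10(od.consumption_mg_kg(1, 0.03)) == pytest.approx(
            -1.52, abs=0.005)


class TestPrepareSeries:
    @staticmethod
    def frame(frs, infusions):
        return pd.DataFrame({
            "subject_id": "a", "phase": "demand",
            "session_index": range(1, len(frs) + 1), "fr_value": frs,
            "active_responses": [f * i for f, i in zip(frs, infusions)],
            "inactive_responses": 0, "infusions": infusions,
        })

    def test_terminal_zero_replaced(self):
        series = prepare_demand_series(self.frame([3, 6, 9], [40, 25, 0]), 0.03)
        assert list(series.prices) == [100.0, 200.0, 300.0]
        assert list(series.consumptions) == pytest.approx([1.2, 0.75, 0.01])
        assert series.observations[-1].replaced_zero

    def test_no_zero_no_flag(self):
        series = prepare_demand_series(self.frame([3, 6], [40, 25]), 0.03)
        assert not any(o.replaced_zero for o in series.observations)

    def test_interior_zero_rejected(self):
        with pytest.raises(od.ValidationError, match="zero"):
            prepare_demand_series(self.frame([3, 6, 9], [40, 0, 10]), 0.03)


class TestModelPrediction:
    def test_zero_price_gives_intensity(self):
        assert predict_log_consumption(1.85, 3.62e-4, K, 0.0) == pytest.approx(
            math.log10(1.85))

    def test_high_price_asymptote(self):
        val = predict_log_consumption(1.85, 3.62e-4, K, 1e9)
        assert val == pytest.approx(math.log10(1.85) - K, abs=1e-9)

    def test_value_at_published_pmax(self):
        assert predict_log_consumption(1.85, 3.62e-4, K, 377.9) == pytest.approx(
            -0.2287596, abs=1e-6)

    def test_strictly_decreasing_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            q0 = float(rng.uniform(0.2, 4.0))
            alpha = float(10 ** rng.uniform(-5, -2))
            k = float(rng.uniform(1.3, 4.0))
            # cover u = alpha*q0*C up to 30; past that the curve sits at
            # its asymptote below floating-point resolution
            c = np.logspace(-4, math.log10(30.0), 300) / (alpha * q0)
            y = predict_log_consumption(q0, alpha, k, c)
            assert (np.diff(y) < 0).all()
            assert (y <= math.log10(q0)).all()
            assert (y > math.log10(q0) - k).all()


class TestDerivedIndices:
    def test_pmax_exact_matches_published_subject(self):
        # SHR male, alpha=0.000161, Q0=1.45: published 1078.1
        assert pmax_exact(1.45, 0.000161, K) == pytest.approx(1078.1, rel=0.005)

    def test_pmax_scales_inversely_with_alpha_q0(self):
        base = pmax_exact(1.85, 3.62e-4, K)
        assert pmax_exact(1.85, 7.24e-4, K) == pytest.approx(base / 2)
        assert pmax_exact(3.70, 3.62e-4, K) == pytest.approx(base / 2)

    def test_pmax_exact_agrees_with_elasticity_root(self):
        for q0, alpha in [(1.85, 3.62e-4), (0.51, 1.362e-3), (2.96, 1.036e-3)]:
            assert pmax_exact(q0, alpha, K) == pytest.approx(
                pmax_root_oracle(q0, alpha, K), rel=1e-9)

    def test_elasticity_at_pmax_is_minus_one(self):
        for q0, alpha in [(1.85, 3.62e-4), (1.45, 1.61e-4)]:
            c = pmax_exact(q0, alpha, K)
            h = 1e-7
            num = (predict_log_consumption(q0, alpha, K, c * math.exp(h))
                   - predict_log_consumption(q0, alpha, K, c * math.exp(-h))
                   ) / (2 * h) * math.log(10)
            assert num == pytest.approx(-1.0, abs=1e-6)

    def test_pmax_undefined_for_small_k(self):
        # unit elasticity is unattainable when k*ln(10) < e
        with pytest.raises(od.ValidationError):
            pmax_exact(1.0, 1e-3, 1.0)

    def test_pmax_approx_closed_form(self):
        assert pmax_approx(1.85, 3.62e-4, K) == pytest.approx(378.047, rel=1e-4)
        base = pmax_approx(1.0, 1e-3, K)
        assert pmax_approx(2.0, 1e-3, K) == pytest.approx(base / 2)
        assert pmax_approx(1.0, 2e-3, K) == pytest.approx(base / 2)

    def test_pmax_approx_tracks_exact_for_typical_k(self):
        for k in np.linspace(1.7, 4.0, 24):
            ratio = pmax_approx(1.5, 5e-4, k) / pmax_exact(1.5, 5e-4, k)
            assert 0.95 <= ratio <= 1.05

    @pytest.mark.parametrize("q0,alpha,printed", [
        (1.32, 0.001000, 80.8),   # SHR male
        (0.85, 0.001899, 42.5),   # Wistar male
    ])
    def test_omax_matches_published_values(self, q0, alpha, printed):
        assert round(omax(q0, alpha, K), 1) == printed

    def test_omax_alpha_product_constant_at_fixed_k(self):
        products = {omax(q0, a, K) * a
                    for q0, a in [(1.85, 3.62e-4), (0.51, 1.362e-3),
                                  (1.45, 1.61e-4)]}
        assert max(products) - min(products) < 1e-12
        assert next(iter(products)) == pytest.approx(0.08078, abs=1e-4)

    def test_omax_equals_expenditure_at_pmax(self):
        q0, alpha = 1.85, 3.62e-4
        c = pmax_exact(q0, alpha, K)
        assert omax(q0, alpha, K) == pytest.approx(
            c * predict_consumption(q0, alpha, K, c), rel=1e-12)


class TestFitDemand:
    def test_exact_recovery_on_noise_free_series(self):
        prices = [100, 200, 300, 500, 1000, 2000, 4000, 8000, 16000]
        series = model_series(1.85, 3.62e-4, K, prices)
        p = fit_demand(series, K)
        assert p.q0 == pytest.approx(1.85, rel=1e-6)
        assert p.alpha == pytest.approx(3.62e-4, rel=1e-6)
        assert p.r2 == pytest.approx(1.0, abs=1e-9)
        assert p.n_points == len(prices)

    def test_fit_invariant_to_observation_order(self):
        # the loss is a sum over points; shuffling input rows cannot matter
        df = pd.DataFrame({
            "subject_id": "a", "phase": "demand",
            "session_index": [3, 1, 2, 4], "fr_value": [9, 3, 6, 15],
            "active_responses": [90, 120, 120, 45],
            "inactive_responses": 0, "infusions": [10, 40, 20, 3],
        })
        p1 = fit_demand(prepare_demand_series(df, 0.03), K)
        p2 = fit_demand(prepare_demand_series(
            df.sort_values("session_index"), 0.03), K)
        assert p1.alpha == pytest.approx(p2.alpha, rel=1e-10)

    def test_matches_grid_search_with_replaced_zero(self):
        series = od.simulate_demand_series((1.4, 6e-4, K), 0.03, 0.1,
                                           np.random.default_rng(17))
        p = fit_demand(series, K)
        c, q = series.prices, np.log10(series.consumptions)

        def sse(q0, alpha):
            pred = np.log10(q0) + K * (np.exp(-alpha * q0 * c) - 1)
            return float(np.sum((pred - q) ** 2))

        grid_best = min(sse(q0, a)
                        for q0 in np.logspace(-0.7, 0.8, 150)
                        for a in np.logspace(-5, -2, 150))
        assert sse(p.q0, p.alpha) <= grid_best + 1e-9

    def test_constant_series_flagged_low_confidence(self):
        obs = tuple(DemandObservation(c, 1.2) for c in (100, 200, 400, 800))
        p = fit_demand(DemandSeries("flat", obs, 0.03), K)
        assert p.low_confidence
        assert p.alpha <= 1.1e-9

    def test_fewer_than_three_points_rejected(self):
        obs = (DemandObservation(100, 1.2), DemandObservation(200, 0.8))
        with pytest.raises(od.FitError):
            fit_demand(DemandSeries("short", obs, 0.03), K)


class TestSharedK:
    @staticmethod
    def make_collection(k, n=6):
        out = []
        for i in range(n):
            q0 = 1.2 + 0.3 * i
            alpha = 2e-4 * (1 + 0.4 * i)
            out.append(od.simulate_demand_series(
                (q0, alpha, k), 0.03, 0.0, np.random.default_rng([8, i]),
                round_infusions=False, subject_id=f"s{i}"))
        return out

    def test_recovers_common_k(self):
        k_hat, params = fit_shared_k(self.make_collection(2.5))
        assert k_hat == pytest.approx(2.5, abs=1e-4)
        assert len(params) == 6
        assert all(p.k == k_hat for p in params)

    def test_refit_at_returned_k_reproduces_parameters(self):
        coll = self.make_collection(2.5)
        k_hat, params = fit_shared_k(coll)
        for series, p in zip(coll, params):
            refit = fit_demand(series, k_hat)
            assert refit.alpha == pytest.approx(p.alpha, rel=1e-8)
            assert refit.q0 == pytest.approx(p.q0, rel=1e-8)

    def test_joint_sse_locally_optimal_in_k(self):
        coll = self.make_collection(2.5)
        k_hat, params = fit_shared_k(coll)

        def joint_sse(k):
            return sum(
                float(np.sum((np.log10(p.q0)
                              + k * (np.exp(-p.alpha * p.q0 * s.prices) - 1)
                              - np.log10(s.consumptions)) ** 2))
                for s, p in zip(coll, (fit_demand(s, k) for s in coll)))

        base = joint_sse(k_hat)
        assert base <= joint_sse(k_hat * 1.1) + 1e-12
        assert base <= joint_sse(k_hat * 0.9) + 1e-12

    def test_single_series_redirects_to_fit_demand(self):
        with pytest.raises(od.ValidationError, match="fit_demand"):
            fit_shared_k(self.make_collection(2.5, n=1))


class TestGroupCurve:
    def test_early_terminator_padded_with_replacement_value(self):
        s1 = od.simulate_demand_series((1.8, 4e-4, K), 0.03, 0.0, 0,
                                       subject_id="long")
        s2 = od.simulate_demand_series((1.2, 2e-3, K), 0.03, 0.0, 0,
                                       subject_id="short")
        assert s2.prices[-1] < s1.prices[-1]
        frame, _ = group_demand_curve([s1, s2])
        top = frame[frame["price"] == s1.prices[-1]].iloc[0]
        assert top["n_contributing"] == 2
        assert top["interpolated_count"] == 2  # both at 0.01 there
        lowest = frame.iloc[0]
        assert lowest["mean_q"] == pytest.approx(
            (s1.consumptions[0] + s2.consumptions[0]) / 2)

    def test_padding_never_enters_individual_fits(self):
        s1 = od.simulate_demand_series((1.8, 4e-4, K), 0.03, 0.0, 0)
        s2 = od.simulate_demand_series((1.2, 2e-3, K), 0.03, 0.0, 0)
        n1, n2 = len(s1.observations), len(s2.observations)
        group_demand_curve([s1, s2], k=K)
        assert len(s1.observations) == n1 and len(s2.observations) == n2
        p2 = fit_demand(s2, K)
        assert p2.n_points == n2

    def test_illustration_fit_is_returned_separately(self):
        s1 = od.simulate_demand_series((1.8, 4e-4, K), 0.03, 0.0, 0)
        s2 = od.simulate_demand_series((1.6, 5e-4, K), 0.03, 0.0, 1)
        frame, fit = group_demand_curve([s1, s2], k=K)
        assert fit is not None and fit.q0 > 0
        frame2, fit2 = group_demand_curve([s1, s2])
        assert fit2 is None
        pd.testing.assert_frame_equal(frame, frame2)
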