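"""Window enumeration, aggregation, scan selection and the randomization test."""

import numpy as np
import pandas as pd
import pytest

import condclim as cc
from condclim.windows import (
    aggregate_window,
    enumerate_windows,
    randomization_test,
    scan_variable,
)

from conftest import synthetic_condition


class TestEnumerateWindows:
    def test_full_year_count(self):
        assert len(enumerate_windows(365, 1)) == 66_795

    @pytest.mark.parametrize(
        "max_lag,stride,expected",
        [
            (2, 1, [(1, 1), (2, 1), (2, 2)]),
            (10, 5, [(5, 5), (10, 5), (10, 10)]),
        ],
    )
    def test_small_grids(self, max_lag, stride, expected):
        assert sorted(enumerate_windows(max_lag, stride)) == expected

    def test_count_matches_brute_force_formula(self):
        for max_lag in (7, 30):
            n = max_lag
            assert len(enumerate_windows(max_lag, 1)) == n * (n + 1) // 2

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            enumerate_windows(0, 1)


class TestAggregateWindow:
    def _series(self, n=30, ref="2005-08-15"):
        ref = pd.Timestamp(ref)
        idx = pd.date_range(ref - pd.Timedelta(days=n), ref - pd.Timedelta(days=1))
        # value at offset k (k days before ref) is k
        return pd.Series(np.arange(n, 0, -1, dtype=float), index=idx)

    def test_single_day_window(self):
        s = self._series()
        agg = aggregate_window(s, (1, 1), [pd.Timestamp("2005-08-15")])
        assert agg.iloc[0] == 1.0

    def test_sequence_mean(self):
        s = self._series()
        agg = aggregate_window(s, (10, 1), [pd.Timestamp("2005-08-15")])
        assert agg.iloc[0] == pytest.approx(5.5)

    def test_constant_series_any_window(self):
        s = self._series() * 0 + 7.0
        for w in [(1, 1), (15, 3), (30, 30)]:
            agg = aggregate_window(s, w, [pd.Timestamp("2005-08-15")])
            assert agg.iloc[0] == 7.0

    def test_missing_day_names_gap(self):
        s = self._series().drop(pd.Timestamp("2005-08-05"))
        with pytest.raises(ValueError, match="2005-08-05"):
            aggregate_window(s, (15, 1), [pd.Timestamp("2005-08-15")])


def _constant_climate(value=5.0, years=range(2004, 2011)):
    idx = pd.date_range(f"{min(years)-1}-01-01", f"{max(years)}-12-31")
    return {"st": pd.Series(value, index=idx)}


def _random_climate(seed, years=range(2004, 2011), sd=1.0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range(f"{min(years)-1}-01-01", f"{max(years)}-12-31")
    return {"st": pd.Series(rng.normal(10, sd, len(idx)), index=idx)}


class TestScan:
    def test_constant_climate_tie_breaks_to_most_recent_day(self):
        cond = synthetic_condition(n_rows=150, n_years=5, seed=1)
        res = scan_variable(cond, _constant_climate(), stride=1, max_lag=10, method="ols")
        assert res.window == (1, 1)
        assert res.shape == "linear"
        assert res.delta_aicc <= 0

    def test_row_order_invariance(self):
        cond = synthetic_condition(n_rows=200, seed=2)
        clim = _random_climate(3)
        a = scan_variable(cond, clim, stride=5, max_lag=60, method="ols")
        shuffled = cond.sample(frac=1.0, random_state=7)
        b = scan_variable(shuffled, clim, stride=5, max_lag=60, method="ols")
        assert a.window == b.window and a.shape == b.shape
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-12)

    def test_best_window_minimizes_aicc_over_table(self):
        cond = synthetic_condition(n_rows=200, seed=4)
        res = scan_variable(cond, _random_climate(5), stride=5, max_lag=50, method="ols")
        best_tab = min(res.table["aicc_linear"].min(), res.table["aicc_quadratic"].min())
        assert res.aicc_best == pytest.approx(best_tab, abs=1e-10)

    def test_climate_shift_leaves_slope_unchanged(self):
        # adding a constant to the daily series only moves the intercept:
        # grand-mean centring makes the centred aggregates identical
        cond = synthetic_condition(n_rows=200, seed=6)
        clim = _random_climate(8)
        a = scan_variable(cond, clim, stride=5, max_lag=40, method="ols")
        shifted = {"st": clim["st"] + 100.0}
        b = scan_variable(cond, shifted, stride=5, max_lag=40, method="ols")
        assert a.window == b.window
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-9)
        assert a.beta2 == pytest.approx(b.beta2, rel=1e-9, abs=1e-12)

    def test_planted_window_recovered_exactly_with_strong_signal(
        self, small_design, small_climate, planted_truth, planted_condition, site_to_station
    ):
        sp = small_design.species["species"].iloc[0]
        cond = planted_condition[planted_condition["species"] == sp]
        res = scan_variable(
            cond, small_climate, variable="temp", site_to_station=site_to_station,
            stride=5, method="ols",
        )
        truth_days = set(range(40, 101))
        found = set(range(res.window[1], res.window[0] + 1))
        jacc = len(truth_days & found) / len(truth_days | found)
        assert jacc >= 0.6
        assert res.delta_aicc > 2

    def test_mixed_engine_agrees_with_ols_when_no_recaptures(self):
        cond = synthetic_condition(n_rows=120, seed=9)
        clim = _random_climate(10)
        cands = [(10, 1), (20, 11), (5, 5)]
        a = scan_variable(cond, clim, candidates=cands, method="ols")
        b = scan_variable(cond, clim, candidates=cands, method="mixed")
        assert a.window == b.window
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-3)


class TestScanOracle:
    def test_equals_brute_force_least_squares(self):
        """Vectorized scan == independent per-candidate lstsq loop (<= 50 windows)."""
        import patsy

        from condclim.windows import DEFAULT_BASELINE
        from condclim._stats import aicc, gaussian_loglik

        cond = synthetic_condition(n_rows=250, n_years=6, seed=12).sort_values(
            ["site", "date", "individual"], kind="stable"
        ).reset_index(drop=True)
        clim = _random_climate(13, years=range(2004, 2012))
        cands = enumerate_windows(35, 5)  # 28 windows
        assert len(cands) <= 50
        res = scan_variable(cond, clim, candidates=cands, method="ols")

        # --- oracle: explicit per-candidate OLS fits ----------------------
        X0 = np.asarray(patsy.dmatrix(DEFAULT_BASELINE, cond, return_type="dataframe"))
        y = cond["condition"].to_numpy(float)
        n, p0 = X0.shape
        refs = {
            yr: pd.Timestamp(f"{yr}-08-15") for yr in sorted(cond["year"].unique())
        }
        sites = sorted(cond["site"].unique())
        best = None
        for w in cands:
            per_sy = {}
            for s in sites:
                for yr, ref in refs.items():
                    per_sy[(s, yr)] = aggregate_window(clim["st"], w, [ref]).iloc[0]
            center = np.mean(list(per_sy.values()))
            x = np.array(
                [per_sy[(r.site, r.year)] - center for r in cond.itertuples()]
            )
            for shape, cols, k in (
                ("linear", [x], p0 + 2),
                ("quadratic", [x, x**2], p0 + 3),
            ):
                X = np.column_stack([X0] + cols)
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(((y - X @ coef) ** 2).sum())
                a_val = aicc(gaussian_loglik(rss, n), k, n)
                key = (a_val, w[0] - w[1] + 1, w[1], shape != "linear")
                if best is None or key < best[0]:
                    best = (key, w, shape, coef)

        _, w_star, shape_star, coef_star = best
        assert res.window == w_star
        assert res.shape == shape_star
        assert res.aicc_best == pytest.approx(best[0][0], abs=1e-10)
        if shape_star == "linear":
            assert res.beta1 == pytest.approx(coef_star[-1], abs=1e-10)
        else:
            assert res.beta1 == pytest.approx(coef_star[-2], abs=1e-10)
            assert res.beta2 == pytest.approx(coef_star[-1], abs=1e-10)


class TestRandomization:
    def test_constant_climate_gives_p_of_one_exactly(self):
        # every permutation reproduces the observed (no-information) scan
        cond = synthetic_condition(n_rows=150, n_years=5, seed=1)
        res = randomization_test(
            cond, _constant_climate(), n_rand=19, seed=0, stride=1, max_lag=5,
            method="ols",
        )
        assert res.p_value == pytest.approx(1.0)

    def test_strong_signal_beats_all_permutations(
        self, small_design, small_climate, planted_condition, site_to_station
    ):
        sp = small_design.species["species"].iloc[0]
        cond = planted_condition[planted_condition["species"] == sp]
        res = randomization_test(
            cond, small_climate, variable="temp", site_to_station=site_to_station,
            n_rand=19, seed=1, stride=5, method="ols",
        )
        assert res.p_value == pytest.approx(1.0 / 20.0)

    def test_too_few_permutations_rejected(self):
        cond = synthetic_condition(n_rows=60, seed=3)
        with pytest.raises(ValueError, match="n_rand"):
            randomization_test(cond, _random_climate(4), n_rand=10)

    def test_too_few_years_rejected(self):
        cond = synthetic_condition(n_rows=60, n_years=2, seed=3)
        with pytest.raises(ValueError, match="years"):
            randomization_test(
                cond, _random_climate(4), n_rand=19, stride=1, max_lag=5
            )
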