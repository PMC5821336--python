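"""Collinearity grouping, all-subsets AICc selection and model averaging."""

import numpy as np
import pandas as pd
import pytest

from condclim._stats import aicc, akaike_weights, gaussian_loglik
from condclim.combine import (
    FittedModel,
    ModelSet,
    all_subsets,
    collinear_groups,
    prune_and_average,
    site_interaction_fit,
)


class TestAiccFormula:
    def test_printed_arithmetic(self):
        # -2(-100) + 2*4 + 2*4*5/95 = 208 + 40/95
        assert aicc(-100.0, 4, 100) == pytest.approx(208 + 40 / 95)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_normalized_and_monotone(self):
        a = np.array([100.0, 101.3, 104.0, 100.2])
        w = akaike_weights(a)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(np.diff(w[np.argsort(a)]) <= 0)

    def test_equal_aicc_gives_equal_weights(self):
        assert np.allclose(akaike_weights([5.0, 5.0]), 0.5)


class TestCollinearGroups:
    def _frame(self, cols):
        return pd.DataFrame(cols)

    def test_identical_series_form_one_group(self):
        x = np.arange(10.0)
        g = collinear_groups(self._frame({"a": x, "b": x.copy()}))
        assert g == [["a", "b"]]

    def test_uncorrelated_stay_singletons(self):
        rng = np.random.default_rng(0)
        g = collinear_groups(
            self._frame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
        )
        assert sorted(map(tuple, g)) == [("a",), ("b",)]

    def test_transitive_closure_joins_chain(self):
        rng = np.random.default_rng(1)
        n = 2000
        b = rng.normal(size=n)
        a = 0.75 * b + rng.normal(scale=0.66, size=n)   # r(a,b) ~ 0.75
        c = 0.75 * b + rng.normal(scale=0.66, size=n)   # r(b,c) ~ 0.75, r(a,c) ~ 0.56
        df = self._frame({"a": a, "b": b, "c": c})
        r = df.corr().abs()
        assert r.loc["a", "b"] > 0.6 and r.loc["b", "c"] > 0.6 and r.loc["a", "c"] <= 0.6
        assert collinear_groups(df) == [["a", "b", "c"]]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            collinear_groups(self._frame({"a": np.ones(5), "b": np.arange(5.0)}))


def _toy_condition(n_per_cell=4, n_sites=2, n_years=6, seed=0, slopes=None, noise=0.0):
    """Condition data with per-row climate columns planted directly."""
    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(n_sites)]
    rows, xcols = [], {"temp": [], "rain": []}
    xt = {(s, y): rng.normal() for s in sites for y in range(n_years)}
    xr = {(s, y): rng.normal() for s in sites for y in range(n_years)}
    slopes = slopes or {s: 0.5 for s in sites}
    i = 0
    for s in sites:
        for y in range(n_years):
            for _ in range(n_per_cell):
                cond = slopes[s] * xt[(s, y)] + rng.normal(0, noise)
                rows.append(
                    {
                        "site": s,
                        "year": 2000 + y,
                        "date": pd.Timestamp(f"{2000+y}-06-01"),
                        "individual": f"i{i}",
                        "time": 9.0,
                        "age": "adult",
                        "sex": "F",
                        "day_of_season": 50,
                        "condition": cond,
                    }
                )
                xcols["temp"].append(xt[(s, y)])
                xcols["rain"].append(xr[(s, y)])
                i += 1
    cond = pd.DataFrame(rows)
    per_row = pd.DataFrame(xcols)
    return cond, per_row


BASE = "1"  # intercept-only baseline keeps the toys transparent


class TestAllSubsets:
    def test_one_group_gives_two_models(self):
        cond, per_row = _toy_condition()
        ms = all_subsets(cond, per_row[["temp"]], {"temp": "linear"}, [["temp"]],
                         baseline=BASE, method="ols")
        assert len(ms.models) == 2
        assert {m.variables for m in ms.models} == {(), ("temp",)}

    def test_collinear_pair_never_split(self):
        cond, per_row = _toy_condition()
        per_row["rain"] = per_row["temp"] * 2 + 1  # perfectly collinear
        ms = all_subsets(
            cond, per_row, {"temp": "linear", "rain": "linear"},
            [["temp", "rain"]], baseline=BASE, method="ols",
        )
        for m in ms.models:
            assert ("temp" in m.variables) == ("rain" in m.variables)

    def test_weights_sum_to_one_in_table(self):
        cond, per_row = _toy_condition(noise=0.3)
        ms = all_subsets(cond, per_row, {"temp": "linear", "rain": "linear"},
                         [["temp"], ["rain"]], baseline=BASE, method="ols")
        assert len(ms.models) == 4
        assert ms.table()["weight"].sum() == pytest.approx(1.0)


class TestPruneAndAverage:
    def _model(self, variables, llf, k, coefs=None, covs=None, n=100):
        coefs = coefs or {}
        return FittedModel(
            variables=tuple(variables),
            k=k,
            llf=llf,
            aicc=aicc(llf, k, n),
            coefs={v: np.asarray(c, float) for v, c in coefs.items()},
            covs=covs or {v: np.eye(2) * 0.01 for v in coefs},
        )

    def test_single_top_model_passes_through(self):
        m1 = self._model(["temp"], -100.0, 4, {"temp": [0.7, -0.1]})
        m2 = self._model([], -130.0, 3)
        avg = prune_and_average(ModelSet([m1, m2], n=100))
        assert np.allclose(avg.coefficients["temp"], [0.7, -0.1])

    def test_equal_aicc_zero_substitution_halves_coefficient(self):
        m1 = self._model(["temp"], -100.0, 4, {"temp": [0.8, 0.0]})
        m2 = self._model([], -101.0 - 1 / 2 * (aicc(-100.0, 4, 100) - aicc(-100.0, 3, 100) + 2), 3)
        # build m2 so AICc matches m1 exactly
        m2 = self._model([], (aicc(-100.0, 4, 100) - 2 * 3 - 2 * 3 * 4 / 96) / -2, 3)
        assert m1.aicc == pytest.approx(m2.aicc, abs=1e-10)
        avg = prune_and_average(ModelSet([m1, m2], n=100), hitchhiker_llf=-np.inf)
        assert avg.coefficients["temp"][0] == pytest.approx(0.4, abs=1e-10)
        assert np.allclose(avg.weights, 0.5)

    def test_three_model_hand_computation(self):
        """Weights and full averages match an explicit hand calculation to 1e-10."""
        lls = {"m1": -100.0, "m2": -100.9, "m3": -102.5}
        ks = {"m1": 5, "m2": 4, "m3": 3}
        n = 80
        m1 = self._model(["temp", "rain"], lls["m1"], ks["m1"],
                         {"temp": [0.6, -0.05], "rain": [0.2, 0.0]})
        m2 = self._model(["temp"], lls["m2"], ks["m2"], {"temp": [0.5, -0.04]})
        m3 = self._model([], lls["m3"], ks["m3"], n=n)
        for m in (m1, m2, m3):
            m.aicc = aicc(m.llf, m.k, n)
        a = np.array([m.aicc for m in (m1, m2, m3)])
        delta = a - a.min()
        top = delta <= 2.0
        w = np.exp(-delta[top] / 2)
        w = w / w.sum()
        models_top = [m for m, t in zip((m1, m2, m3), top) if t]
        b_temp = sum(
            wi * m.coefs.get("temp", np.zeros(2))[0] for wi, m in zip(w, models_top)
        )
        avg = prune_and_average(ModelSet([m1, m2, m3], n=n), hitchhiker_llf=-np.inf)
        assert np.allclose(avg.weights, w, atol=1e-10)
        assert avg.coefficients["temp"][0] == pytest.approx(b_temp, abs=1e-10)

    def test_full_averaging_shrinks_towards_zero(self):
        m1 = self._model(["temp"], -100.0, 4, {"temp": [0.8, 0.1]})
        m2 = self._model([], -100.5, 3)
        avg = prune_and_average(ModelSet([m1, m2], n=100), hitchhiker_llf=-np.inf)
        assert abs(avg.coefficients["temp"][0]) <= 0.8

    def test_not_in_top_set_exclusion(self):
        m1 = self._model(["temp"], -100.0, 4, {"temp": [0.8, 0.0]})
        m2 = self._model(["temp", "rain"], -99.9, 6,
                         {"temp": [0.8, 0.0], "rain": [0.01, 0.0]})
        # m2 pays 2 extra parameters for ~nothing: outside the top set
        ms = ModelSet([m1, m2], n=100)
        avg = prune_and_average(ms)
        assert ("rain", "not-in-top-set") in avg.excluded or (
            "rain", "hitchhiker") in avg.excluded
        assert "rain" not in avg.coefficients

    def test_hitchhiker_detected(self):
        # rain present in the best model but contributing no likelihood,
        # with a CI spanning zero -> flagged hitchhiker
        m1 = self._model(["temp", "rain"], -100.0, 5,
                         {"temp": [0.8, 0.0], "rain": [0.01, 0.0]})
        m2 = self._model(["temp"], -100.9, 4, {"temp": [0.8, 0.0]})
        avg = prune_and_average(ModelSet([m1, m2], n=100))
        assert ("rain", "hitchhiker") in avg.excluded
        assert "temp" in avg.retained


class TestSiteInteractions:
    def test_noiseless_site_slopes_recovered(self):
        cond, per_row = _toy_condition(
            n_per_cell=5, slopes={"s0": 0.5, "s1": -0.5}, noise=0.0
        )
        avg = site_interaction_fit(
            cond, per_row[["temp"]], {"temp": "linear"}, ["temp"], [["temp"]],
            baseline=BASE, method="ols",
        )
        assert avg.coefficients[("temp", "s0")][0] == pytest.approx(0.5, abs=1e-6)
        assert avg.coefficients[("temp", "s1")][0] == pytest.approx(-0.5, abs=1e-6)

    def test_homogeneous_sites_agree(self):
        cond, per_row = _toy_condition(n_per_cell=5, noise=0.0)
        avg = site_interaction_fit(
            cond, per_row[["temp"]], {"temp": "linear"}, ["temp"], [["temp"]],
            baseline=BASE, method="ols",
        )
        b0 = avg.coefficients[("temp", "s0")][0]
        b1 = avg.coefficients[("temp", "s1")][0]
        assert b0 == pytest.approx(b1, abs=1e-6)

    def test_site_label_permutation_equivariance(self):
        cond, per_row = _toy_condition(
            n_per_cell=5, slopes={"s0": 0.3, "s1": -0.7}, noise=0.0
        )
        swapped = cond.copy()
        swapped["site"] = swapped["site"].map({"s0": "s1", "s1": "s0"})
        a = site_interaction_fit(cond, per_row[["temp"]], {"temp": "linear"},
                                 ["temp"], [["temp"]], baseline=BASE, method="ols")
        b = site_interaction_fit(swapped, per_row[["temp"]], {"temp": "linear"},
                                 ["temp"], [["temp"]], baseline=BASE, method="ols")
        assert a.coefficients[("temp", "s0")][0] == pytest.approx(
            b.coefficients[("temp", "s1")][0], abs=1e-8
        )
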