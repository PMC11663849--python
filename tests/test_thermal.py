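"""Thermal-performance model tests: evaluation identities, fitting,
model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epfsit.thermal import (
    GrowthRate,
    RadialGrowthSeries,
    aic_gaussian_raw,
    absolute_growth_rate,
    cardinal_summary,
    eval_tpc,
    fit_tpc,
    r2_measures,
    select_model,
    vuong_test,
)


def rates_from(T, y, strain="s"):
    return [
        GrowthRate(strain=strain, temperature=float(t), plate_id=f"p{i}",
                   beta=float(v), intercept=0.0, fit_r2=1.0)
        for i, (t, v) in enumerate(zip(T, y))
    ]


class TestEvalTpc:
    def test_linear_evaluates_everywhere(self):
        assert eval_tpc("linear", {"a": 0.1, "b": 0.05}, 20.0) == pytest.approx(1.1)

    def test_lactin1_hand_value(self):
        # a·(T−Tmin)²·(Tmax−T) = 1e-4·400·15
        assert eval_tpc("lactin1", {"a": 1e-4, "Tmin": 5, "Tmax": 40}, 25.0) == pytest.approx(0.6)

    @pytest.mark.parametrize("model,params", [
        ("lactin1", {"a": 1e-4, "Tmin": 5.0, "Tmax": 40.0}),
        ("ctmi", {"mu_opt": 2.0, "Tmin": 10.0, "Topt": 27.0, "Tmax": 40.0}),
    ])
    def test_zero_at_cardinal_extremes_and_outside(self, model, params):
        tmin, tmax = params["Tmin"], params["Tmax"]
        for T in (tmin, tmax, tmin - 5.0, tmax + 5.0):
            assert eval_tpc(model, params, T) == 0.0

    @given(
        tmin=st.floats(-10, 15),
        gap1=st.floats(1, 20),
        gap2=st.floats(1, 20),
        mu=st.floats(0.01, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_ctmi_equals_mu_opt_at_topt(self, tmin, gap1, gap2, mu):
        """Algebraic identity: the CTMI response at Topt is exactly μopt."""
        params = {"mu_opt": mu, "Tmin": tmin, "Topt": tmin + gap1,
                  "Tmax": tmin + gap1 + gap2}
        assert eval_tpc("ctmi", params, params["Topt"]) == pytest.approx(mu, rel=1e-9)

    @given(T=st.floats(-20, 60))
    @settings(max_examples=100, deadline=None)
    def test_rates_never_negative(self, T):
        params = {"mu_opt": 2.0, "Tmin": 10.0, "Topt": 27.0, "Tmax": 40.0}
        assert eval_tpc("ctmi", params, T) >= 0.0
        assert eval_tpc("lactin1", {"a": 1e-4, "Tmin": 5, "Tmax": 40}, T) >= 0.0

    def test_invalid_ctmi_ordering_rejected(self):
        with pytest.raises(ValueError):
            eval_tpc("ctmi", {"mu_opt": 1.0, "Tmin": 30.0, "Topt": 20.0, "Tmax": 40.0}, 25.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            eval_tpc("gaussian", {}, 25.0)


class TestAbsoluteGrowthRate:
    def _series(self, days, radii, temp=25.0, plate="p1"):
        return [
            RadialGrowthSeries(plate_id=plate, strain="s", temperature=temp,
                               day=int(d), quadrant_radii=(r, r, r, r))
            for d, r in zip(days, radii)
        ]

    def test_exact_line_recovered(self):
        days = range(1, 15)
        series = self._series(days, [2 + 1.5 * d for d in days])
        (gr,) = absolute_growth_rate(series)
        assert gr.beta == pytest.approx(1.5, abs=1e-12)
        assert gr.intercept == pytest.approx(2.0, abs=1e-10)
        assert gr.fit_r2 == pytest.approx(1.0)

    def test_constant_radius_zero_slope(self):
        series = self._series(range(1, 8), [4.0] * 7)
        (gr,) = absolute_growth_rate(series)
        assert gr.beta == 0.0

    def test_matches_closed_form_ols(self, rng):
        days = np.arange(1, 15)
        radii = 4 + 0.8 * days + rng.normal(0, 0.3, 14)
        series = self._series(days, radii)
        (gr,) = absolute_growth_rate(series)
        # closed-form Σ formulas
        beta = np.sum((days - days.mean()) * (radii - radii.mean())) / np.sum(
            (days - days.mean()) ** 2
        )
        assert gr.beta == pytest.approx(beta, abs=1e-10)
        assert gr.intercept == pytest.approx(radii.mean() - beta * days.mean(), abs=1e-10)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            absolute_growth_rate(self._series([3, 3], [5.0, 5.1]))


class TestFitTpc:
    def test_linear_exact(self):
        T = np.array([15, 20, 25, 30, 35, 40], float)
        fit = fit_tpc(rates_from(T, 0.1 + 0.05 * T), "linear")
        assert fit.params["a"] == pytest.approx(0.1, abs=1e-10)
        assert fit.params["b"] == pytest.approx(0.05, abs=1e-10)
        assert fit.k == 2

    def test_ctmi_noiseless_recovery(self):
        true = {"mu_opt": 2.0, "Tmin": 10.0, "Topt": 27.0, "Tmax": 40.0}
        T = np.repeat([15.0, 20, 25, 30, 35, 40], 4)
        y = eval_tpc("ctmi", true, T)
        fit = fit_tpc(rates_from(T, y), "ctmi")
        assert fit.converged
        for key, val in true.items():
            assert fit.params[key] == pytest.approx(val, abs=1e-3)
        assert fit.rss < 1e-10

    def test_lactin1_self_consistency(self):
        true = {"a": 6e-5, "Tmin": 2.0, "Tmax": 41.0}
        T = np.repeat([15.0, 20, 25, 30, 35, 40], 4)
        fit = fit_tpc(rates_from(T, eval_tpc("lactin1", true, T)), "lactin1")
        assert fit.rss < 1e-10

    def test_deterministic_given_data(self):
        T = np.repeat([15.0, 20, 25, 30, 35, 40], 4)
        y = eval_tpc("ctmi", {"mu_opt": 2.0, "Tmin": 10.0, "Topt": 27.0, "Tmax": 40.0}, T)
        y = y + np.sin(np.arange(y.size))* 0.05  # deterministic perturbation
        f1 = fit_tpc(rates_from(T, y), "ctmi")
        f2 = fit_tpc(rates_from(T, y), "ctmi")
        assert f1.params == f2.params
        assert f1.rss == f2.rss

    def test_too_few_temperatures_rejected(self):
        T = np.array([15.0, 25, 35])
        with pytest.raises(ValueError):
            fit_tpc(rates_from(T, [0.5, 1.5, 1.0]), "ctmi")


class TestGoodnessOfFit:
    def test_aic_hand_value(self):
        assert aic_gaussian_raw(n=24, rss=6.0, k=4) == pytest.approx(
            24 * math.log(0.25) + 10, abs=1e-10
        )

    def test_aic_monotone_in_rss_and_k(self):
        assert aic_gaussian_raw(24, 3.0, 4) < aic_gaussian_raw(24, 6.0, 4)
        assert aic_gaussian_raw(24, 6.0, 2) == aic_gaussian_raw(24, 6.0, 4) - 4

    def test_r2_hand_values(self):
        T = np.arange(1.0, 11.0)
        y = T * 0.1
        tss = float(np.sum((y - y.mean()) ** 2))
        fake = fit_tpc(rates_from(T, y), "linear")
        # perfect fit
        pr2, ar2 = r2_measures(fake, rates_from(T, y))
        assert pr2 == pytest.approx(1.0)
        assert ar2 == pytest.approx(1.0)
        # contrived fit with rss = 0.1·TSS, n=10, k=3 → adj = 1 − 0.1·9/6
        from dataclasses import replace

        fit = replace(fake, rss=0.1 * tss, k=3)
        pr2, ar2 = r2_measures(fit, rates_from(T, y))
        assert pr2 == pytest.approx(0.9, abs=1e-12)
        assert ar2 == pytest.approx(1 - 0.1 * 9 / 6, abs=1e-12)


class TestVuong:
    def _fits(self, rng):
        T = np.repeat([15.0, 20, 25, 30, 35, 40], 4)
        y = eval_tpc("ctmi", {"mu_opt": 2.0, "Tmin": 10.0, "Topt": 27.0, "Tmax": 40.0}, T)
        y = y + rng.normal(0, 0.1, T.size)
        rates = rates_from(T, y)
        return fit_tpc(rates, "ctmi"), fit_tpc(rates, "linear"), rates

    def test_identical_fits_indistinguishable(self, rng):
        fit, _, rates = self._fits(rng)
        res = vuong_test(fit, fit, rates)
        assert res.z == 0.0
        assert res.verdict == "indistinguishable"

    def test_antisymmetry(self, rng):
        fa, fb, rates = self._fits(rng)
        ab = vuong_test(fa, fb, rates)
        ba = vuong_test(fb, fa, rates)
        assert ab.z == pytest.approx(-ba.z, rel=1e-12)
        assert ab.p == pytest.approx(ba.p, rel=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        fa, fb, rates = self._fits(rng)
        res = vuong_test(fa, fb, rates)
        T = np.array([r.temperature for r in rates])
        y = np.array([r.beta for r in rates])
        n = y.size

        def ll(fit):
            mu = eval_tpc(fit.model, fit.params, T)
            s2 = fit.rss / n
            return -0.5 * (np.log(2 * np.pi * s2) + (y - mu) ** 2 / s2)

        m = ll(fa) - ll(fb)
        z = m.sum() / (math.sqrt(n) * np.std(m))
        assert res.z == pytest.approx(z, abs=1e-10)


class TestSelectModel:
    def _fit(self, model, aic, adj):
        from epfsit.thermal import TPCFit

        return TPCFit(model=model, params={}, rss=1.0, n=24, k=2, aic=aic,
                      pseudo_r2=adj, adj_r2=adj, converged=True)

    def test_least_aic_wins(self):
        fits = [self._fit("a", -5.0, 0.5), self._fit("b", -20.0, 0.6),
                self._fit("c", 3.0, 0.4)]
        assert select_model(fits).best.model == "b"

    def test_tie_broken_by_adj_r2(self):
        fits = [self._fit("a", -20.0, 0.90), self._fit("b", -19.5, 0.95)]
        sel = select_model(fits)
        assert sel.best.model == "b"
        assert sel.tie_broken_by_adj_r2

    def test_exact_tie_flagged_for_vuong(self):
        fits = [self._fit("a", -20.0, 0.9), self._fit("b", -20.0, 0.9)]
        sel = select_model(fits)
        assert sel.needs_vuong


class TestCardinalSummary:
    TOPTS = (29.5, 30.8, 27.5, 26.7, 31.1)

    def _per_strain(self):
        tmins = (9.0, -3.7, 8.1, 13.1, 9.8)
        tmaxs = (35.8, 35.2, 35.6, 40.2, 45.4)
        return {
            f"S{i}": (tmins[i], self.TOPTS[i], tmaxs[i], 2.0) for i in range(5)
        }

    def test_topt_range_is_min_max(self):
        summ = cardinal_summary(self._per_strain())
        assert summ.topt_range == (26.7, 31.1)
        assert summ.overall_tmin == -3.7
        assert summ.overall_tmax == 45.4

    def test_single_strain_collapses(self):
        summ = cardinal_summary({"only": (10.0, 27.0, 40.0, 2.0)})
        assert summ.topt_range == (27.0, 27.0)
        assert (summ.overall_tmin, summ.overall_tmax) == (10.0, 40.0)

    def test_order_invariance(self):
        d = self._per_strain()
        rev = dict(reversed(list(d.items())))
        a, b = cardinal_summary(d), cardinal_summary(rev)
        assert a.topt_range == b.topt_range
        assert a.overall_tmin == b.overall_tmin
        assert a.overall_tmax == b.overall_tmax

    def test_linear_fit_without_cardinals_rejected(self):
        from epfsit.thermal import TPCFit

        fit = TPCFit(model="linear", params={"a": 0.1, "b": 0.05}, rss=1.0, n=24,
                     k=2, aic=0.0, pseudo_r2=0.5, adj_r2=0.5, converged=True)
        with pytest.raises(ValueError):
            cardinal_summary({"s": fit})
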