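"""Benchmark-concentration engine: closed forms, likelihood identities,
profile bounds, lack of fit and the model battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from dotox import bmc, synthetic


def lognormal_data(a=2.5, b=0.018, c=6.0, sigma=0.35, n=75, seed=0,
                   doses=(0.0, 1.0, 10.0, 100.0)):
    frame = synthetic.simulate_dose_response(
        doses=doses, n_per_group=n, a=a, b=b, c=c, sigma_log=sigma, seed=seed
    )
    return bmc.DoseResponseData.from_individual(frame["dose_ppm"], frame["response"])


class TestEvalExponential:
    def test_background_and_asymptote(self):
        assert bmc.eval_exponential(2.5, 0.1, 4.0, 0.0) == 2.5
        assert bmc.eval_exponential(2.5, 0.1, 4.0, 1e9) == pytest.approx(10.0)

    def test_hand_value(self):
        # 2.5 * (4 - 3 e^-1) = 7.2409...
        assert bmc.eval_exponential(2.5, 0.1, 4.0, 10.0) == pytest.approx(
            2.5 * (4 - 3 * np.exp(-1)), abs=1e-12
        )

    @pytest.mark.parametrize("bad", [(-1, 1, 2), (1, 0, 2), (1, 1, 1.0)])
    def test_domain_violations(self, bad):
        with pytest.raises(ValueError):
            bmc.eval_exponential(*bad, 1.0)


class TestClosedFormBmc:
    @pytest.mark.parametrize(
        "a,b,c,r,expected",
        [
            (1.0, 1.0, 2.0, 1.1, -np.log(0.9)),  # ~0.10536
            (1.0, 1.0, 2.0, 1.5, np.log(2.0)),  # 1-SD example with sd=0.5, a=1
        ],
    )
    def test_textbook_values(self, a, b, c, r, expected):
        assert bmc.bmc_closed_form(a, b, c, r) == pytest.approx(expected, abs=1e-12)

    def test_matches_bisection_on_random_parameters(self):
        # independent oracle: bisect mu(X) = r * a on eval_exponential
        rng = np.random.default_rng(12345)
        for _ in range(100):
            a = rng.uniform(0.5, 10.0)
            c = rng.uniform(1.2, 20.0)
            b = rng.uniform(0.01, 2.0)
            r = 1.0 + rng.uniform(0.05, 0.95) * (c - 1.0 - 1e-6)
            target = a * r

            def f(x):
                return bmc.eval_exponential(a, b, c, x) - target

            hi = 1.0
            while f(hi) < 0:
                hi *= 2.0
            oracle = optimize.bisect(f, 0.0, hi, xtol=1e-13)
            closed = bmc.bmc_closed_form(a, b, c, r)
            assert abs(closed - oracle) <= 1e-8 * max(1.0, closed)

    def test_monotone_in_slope_and_target(self):
        base = bmc.bmc_closed_form(2.0, 0.1, 4.0, 1.1)
        assert bmc.bmc_closed_form(2.0, 0.2, 4.0, 1.1) < base  # steeper -> smaller
        assert bmc.bmc_closed_form(2.0, 0.1, 4.0, 1.5) > base  # farther target


class TestFitExponential:
    def test_summaries_equal_individual_when_sufficient(self):
        # normal case: group (n, mean, sd) are sufficient statistics
        rng = np.random.default_rng(5)
        doses = np.repeat([0.0, 2.0, 10.0, 50.0], 40)
        mu = bmc.eval_exponential(3.0, 0.05, 3.0, doses)
        y = mu + 0.4 * rng.standard_normal(len(doses))
        ind = bmc.DoseResponseData.from_individual(doses, y, distribution="normal")
        g = pd.DataFrame({"dose_ppm": doses, "response": y}).groupby("dose_ppm")
        summ = bmc.DoseResponseData.from_summary(
            g.mean().index.to_numpy(),
            g.size().to_numpy(),
            g["response"].mean().to_numpy(),
            g["response"].std(ddof=1).to_numpy(),
            distribution="normal",
        )
        f1 = bmc.fit_exponential(ind)
        f2 = bmc.fit_exponential(summ)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.a == pytest.approx(f2.a, rel=1e-4)
        assert f1.b == pytest.approx(f2.b, rel=1e-3)
        assert f1.c == pytest.approx(f2.c, rel=1e-3)

    def test_flat_data_collapse_with_no_lack_of_fit(self):
        # truly flat truth: constant median across doses
        rng = np.random.default_rng(60)
        doses = np.repeat([0.0, 1.0, 10.0, 100.0], 60)
        y = np.exp(np.log(2.5) + 0.35 * rng.standard_normal(len(doses)))
        data = bmc.DoseResponseData.from_individual(doses, y)
        fit = bmc.fit_exponential(data)
        mu = fit.predict(np.array([0.0, 100.0]))
        assert mu[1] / mu[0] < 1.2
        assert bmc.lack_of_fit_test(fit, data) > 0.05

    def test_aic_definition(self):
        data = lognormal_data(n=30, seed=7)
        fit = bmc.fit_exponential(data)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 4, abs=1e-10)

    def test_scale_contract(self):
        # multiplying responses by k scales a, leaves b, c and BMC unchanged
        frame = synthetic.simulate_dose_response(n_per_group=60, seed=8)
        d1 = bmc.DoseResponseData.from_individual(frame["dose_ppm"], frame["response"])
        d2 = bmc.DoseResponseData.from_individual(
            frame["dose_ppm"], 5.0 * frame["response"]
        )
        f1, f2 = bmc.fit_exponential(d1), bmc.fit_exponential(d2)
        assert f2.a == pytest.approx(5.0 * f1.a, rel=1e-3)
        assert f2.c == pytest.approx(f1.c, rel=1e-3)
        b1 = bmc.bmc_from_fit(f1, "rel10").bmc
        b2 = bmc.bmc_from_fit(f2, "rel10").bmc
        assert b2 == pytest.approx(b1, rel=1e-3)

    def test_too_few_groups_rejected(self):
        data = bmc.DoseResponseData.from_individual(
            np.repeat([0.0, 1.0], 10), np.ones(20) * 2.0
        )
        with pytest.raises(ValueError):
            bmc.fit_exponential(data)


class TestBmcStatus:
    def test_na_when_target_exceeds_asymptote(self):
        fit = bmc.ExpModelFit(
            a=2.0, b=0.5, c=1.05, sigma=0.3, loglik=0.0, aic=8.0, converged=True
        )
        est = bmc.bmc_from_fit(fit, "rel10")
        assert est.status == bmc.STATUS_NA_ASYMPTOTE
        assert est.bmc is None and est.bmcl is None
        # 1-SD target far above a shallow plateau: same NA semantics
        est2 = bmc.bmc_from_fit(fit, "one_sd", control_sd=2.0)
        assert est2.status == bmc.STATUS_NA_ASYMPTOTE

    def test_non_converged_fit_propagates_status(self):
        fit = bmc.ExpModelFit(
            a=2.0, b=0.5, c=3.0, sigma=0.3, loglik=0.0, aic=8.0, converged=False
        )
        assert bmc.bmc_from_fit(fit, "rel10").status == bmc.STATUS_NA_NO_CONVERGENCE


class TestBmclProfile:
    def test_bound_below_estimate_and_shrinks_with_n(self):
        est_small = bmc.bmcl_profile(
            bmc.fit_exponential(lognormal_data(n=40, seed=9)),
            lognormal_data(n=40, seed=9),
            "rel10",
        )
        est_large = bmc.bmcl_profile(
            bmc.fit_exponential(lognormal_data(n=160, seed=9)),
            lognormal_data(n=160, seed=9),
            "rel10",
        )
        assert est_small.status == est_large.status == bmc.STATUS_OK
        assert 0 < est_small.bmcl <= est_small.bmc
        assert 0 < est_large.bmcl <= est_large.bmc
        gap_small = est_small.bmc - est_small.bmcl
        gap_large = est_large.bmc - est_large.bmcl
        assert gap_large < gap_small

    def test_one_sd_bound(self):
        data = lognormal_data(n=100, seed=10)
        fit = bmc.fit_exponential(data)
        est = bmc.bmcl_profile(fit, data, "one_sd")
        assert est.status == bmc.STATUS_OK
        assert 0 < est.bmcl <= est.bmc


class TestLackOfFit:
    def test_saturated_fit_gives_p_one(self):
        data = lognormal_data(n=40, seed=11)
        # a "fit" whose likelihood equals the saturated model's
        sat = bmc.GenericModelFit(
            model="saturated-proxy",
            params=np.array([]),
            loglik=bmc.saturated_loglik(data),
            aic=0.0,
            converged=True,
            n_mean_params=3,
        )
        assert bmc.lack_of_fit_test(sat, data) == pytest.approx(1.0)

    def test_df_guard(self):
        data = lognormal_data(n=40, seed=12, doses=(0.0, 1.0, 10.0))
        fit = bmc.fit_exponential(data)
        with pytest.raises(ValueError):
            bmc.lack_of_fit_test(fit, data)  # 3 groups - 3 mean params

    def test_calibration_under_the_model(self):
        ps = []
        for s in range(100):
            data = lognormal_data(n=25, seed=1000 + s)
            fit = bmc.fit_exponential(data)
            ps.append(bmc.lack_of_fit_test(fit, data))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_plateau_violation(self):
        # low-dose saturation followed by a high-dose jump: the saturating
        # exponential cannot fit all four medians
        rng = np.random.default_rng(13)
        medians = {0.0: 2.5, 1.0: 3.5, 10.0: 4.5, 100.0: 14.6}
        rejections = 0
        for rep in range(20):
            doses, ys = [], []
            for d, m in medians.items():
                y = np.exp(np.log(m) + 0.35 * rng.standard_normal(100))
                doses.append(np.full(100, d))
                ys.append(y)
            data = bmc.DoseResponseData.from_individual(
                np.concatenate(doses), np.concatenate(ys)
            )
            fit = bmc.fit_exponential(data)
            if bmc.lack_of_fit_test(fit, data) < 0.05:
                rejections += 1
        assert rejections >= 16


class TestDropHighDose:
    def test_drops_exactly_the_top_group(self):
        data = lognormal_data(n=20, seed=14)
        low = bmc.drop_high_dose(data)
        assert list(low.doses) == [0.0, 1.0, 10.0]
        assert any("100.0" in p for p in low.provenance)

    def test_refuses_at_three_groups_and_is_not_reapplicable(self):
        data = lognormal_data(n=20, seed=15, doses=(0.0, 1.0, 10.0))
        with pytest.raises(ValueError):
            bmc.drop_high_dose(data)
        low = bmc.drop_high_dose(lognormal_data(n=20, seed=15))
        with pytest.raises(ValueError):
            bmc.drop_high_dose(low)


class TestModelBattery:
    def test_exponential_data_prefers_exponential(self):
        wins = 0
        for s in range(20):
            battery = bmc.fit_model_battery(lognormal_data(n=50, seed=2000 + s))
            if bmc.select_model(battery) == "exponential":
                wins += 1
        assert wins >= 14

    def test_linear_data_selects_linear_family(self):
        rng = np.random.default_rng(16)
        doses = np.repeat([0.0, 5.0, 25.0, 50.0, 100.0], 60)
        mu = 2.0 + 0.05 * doses
        y = np.exp(np.log(mu) + 0.2 * rng.standard_normal(len(doses)))
        data = bmc.DoseResponseData.from_individual(doses, y)
        battery = bmc.fit_model_battery(data)
        choice = bmc.select_model(battery)
        assert choice in ("linear", "power", "poly2", "exponential")
        by_model = battery.set_index("model")
        b_lin = by_model.loc["linear", "bmc_rel10"]
        b_exp = by_model.loc["exponential", "bmc_rel10"]
        assert b_exp == pytest.approx(b_lin, rel=0.3)

    def test_battery_reports_all_models(self):
        battery = bmc.fit_model_battery(lognormal_data(n=30, seed=17))
        assert set(battery["model"]) == {"exponential", "hill", "linear", "poly2", "power"}
        # AIC definition spot check against the reported loglik
        row = battery[battery["model"] == "linear"].iloc[0]
        assert row["aic"] == pytest.approx(-2 * row["loglik"] + 2 * 3, abs=1e-9)


@given(
    a=st.floats(0.5, 5.0),
    b=st.floats(0.02, 1.0),
    c=st.floats(1.3, 10.0),
)
@settings(deadline=None, max_examples=50)
def test_bmc_inverts_the_mean_model(a, b, c):
    x = bmc.bmc_closed_form(a, b, c, 1.1)
    assert bmc.eval_exponential(a, b, c, x) == pytest.approx(1.1 * a, rel=1e-9)
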