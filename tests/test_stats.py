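import math
import warnings

import numpy as np
import pandas as pd
import pytest

import reefbudget as rb
from reefbudget.stats import StatsError, fit_stratum_glm, select_distribution


def frame(x, y, **extra):
    base = {"coral_cover_pct": x, "parrotfish_biomass_kg_ha": 0.0, "ncp": y,
            "gcp": y, "gce": 0.0, "subregion": "DRTO", "reef_type": "bank"}
    base.update(extra)
    return pd.DataFrame(base)


class TestNcpRegression:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 10.0])
        reg = rb.fit_ncp_regression(frame(x, 2 * x - 1), "coral_cover")
        assert math.isclose(reg.slope, 2.0, rel_tol=1e-12)
        assert math.isclose(reg.intercept, -1.0, abs_tol=1e-12)
        assert math.isclose(reg.r_squared, 1.0, rel_tol=1e-12)

    def test_matches_closed_form_normal_equations(self, rng):
        x = rng.uniform(0, 50, 40)
        y = 0.08 * x - 0.6 + rng.normal(0, 0.4, 40)
        reg = rb.fit_ncp_regression(frame(x, y), "coral_cover")
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        assert abs(reg.slope - slope) < 1e-10
        assert abs(reg.intercept - intercept) < 1e-10

    def test_requires_three_sites_and_variance(self):
        with pytest.raises(StatsError):
            rb.fit_ncp_regression(frame(np.array([1.0, 2.0]),
                                        np.array([0.0, 1.0])), "coral_cover")
        with pytest.raises(StatsError, match="variance"):
            rb.fit_ncp_regression(frame(np.full(5, 3.0), np.arange(5.0)),
                                  "coral_cover")

    def test_pool_filter_restricts_sites(self, rng):
        x = rng.uniform(0, 30, 60)
        df = frame(x, 0.1 * x, subregion=["DRTO"] * 30 + ["SEFL"] * 30)
        reg = rb.fit_ncp_regression(df, "coral_cover",
                                    pool=lambda d: d.subregion == "DRTO")
        assert reg.n == 30

    def test_confidence_band_brackets_fit(self, rng):
        x = rng.uniform(0, 50, 80)
        y = 0.08 * x - 0.6 + rng.normal(0, 0.4, 80)
        reg = rb.fit_ncp_regression(frame(x, y), "coral_cover")
        band = reg.confidence_band(np.linspace(0, 50, 11))
        assert (band["lo"] <= band["mean"]).all()
        assert (band["mean"] <= band["hi"]).all()

    def test_p_display_convention(self, rng):
        x = rng.uniform(0, 50, 200)
        reg = rb.fit_ncp_regression(frame(x, 0.1 * x + rng.normal(0, 0.1, 200)),
                                    "coral_cover")
        assert reg.format_p() == "<0.0001"


class TestZeroCrossingThreshold:
    def _reg(self, slope, intercept, x):
        x = np.asarray(x, dtype=float)
        y = slope * x + intercept
        return rb.RegressionResult(slope=slope, intercept=intercept,
                                   r_squared=1.0, p_value=0.0, f_statistic=0.0,
                                   n=len(x), confidence_band=lambda g: None,
                                   x=x, y=y, predictor="coral_cover")

    def test_threshold_is_minus_intercept_over_slope(self):
        reg = self._reg(0.1, -0.82, np.linspace(0, 52, 50))
        est = rb.zero_crossing_threshold(reg, n_boot=200, seed=0)
        assert est.defined_flag
        assert math.isclose(est.threshold, 8.2, rel_tol=1e-12)

    def test_non_positive_slope_undefined(self):
        reg = self._reg(-0.05, 0.3, np.linspace(0, 52, 50))
        est = rb.zero_crossing_threshold(reg)
        assert not est.defined_flag and est.reason == "non_positive_slope"

    def test_crossing_outside_observed_cover_undefined(self):
        # crossing at 60% but observed cover tops out at 52%
        reg = self._reg(0.1, -6.0, np.linspace(0, 52, 50))
        est = rb.zero_crossing_threshold(reg)
        assert not est.defined_flag and est.reason == "out_of_range"

    def test_equivariant_under_cover_rescaling(self, rng):
        x = rng.uniform(0, 40, 100)
        y = 0.05 * x - 0.5 + rng.normal(0, 0.1, 100)
        c = 2.5
        r1 = rb.fit_ncp_regression(frame(x, y), "coral_cover")
        r2 = rb.fit_ncp_regression(frame(c * x, y), "coral_cover")
        t1 = rb.zero_crossing_threshold(r1, n_boot=0)
        t2 = rb.zero_crossing_threshold(r2, n_boot=0)
        assert math.isclose(t2.threshold, c * t1.threshold, rel_tol=1e-9)

    def test_bootstrap_ci_brackets_point(self, rng):
        x = rng.uniform(0, 40, 150)
        y = 0.05 * x - 0.5 + rng.normal(0, 0.15, 150)
        reg = rb.fit_ncp_regression(frame(x, y), "coral_cover")
        est = rb.zero_crossing_threshold(reg, n_boot=500, seed=1)
        assert est.ci is not None
        assert est.ci[0] <= est.threshold <= est.ci[1]


class TestSelectDistribution:
    def test_normal_sample_selects_normal(self):
        picks = [select_distribution(
            np.random.default_rng(s).normal(0, 1, 1000))[0] for s in range(20)]
        assert picks.count("normal") >= 19

    def test_gamma_sample_selects_gamma(self):
        picks = [select_distribution(
            np.random.default_rng(s).gamma(2.0, 1.0, 500))[0] for s in range(10)]
        assert picks.count("gamma") >= 9

    def test_lognormal_sample_selects_lognormal(self):
        picks = [select_distribution(
            np.random.default_rng(s).lognormal(0.0, 1.0, 500))[0] for s in range(10)]
        assert picks.count("lognormal") >= 9

    def test_aic_ranking_matches_fitdistrplus(self, tmp_path):
        # independent oracle: R's fitdistrplus on the same positive sample
        import subprocess
        y = np.random.default_rng(3).gamma(2.0, 1.5, 400)
        path = tmp_path / "y.csv"
        np.savetxt(path, y)
        script = (
            'suppressMessages(library(fitdistrplus)); '
            f'y <- scan("{path}", quiet=TRUE); '
            'fits <- list(normal=fitdist(y,"norm"), lognormal=fitdist(y,"lnorm"), '
            'gamma=fitdist(y,"gamma")); '
            'aics <- sapply(fits, function(f) f$aic); '
            'cat(names(which.min(aics)), aics, sep="\\n")')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300, check=True)
        r_best, *r_aics = out.stdout.split()
        fam, diag = select_distribution(y)
        assert fam == r_best == "gamma"
        for r_aic, name in zip(map(float, r_aics),
                               ("normal", "lognormal", "gamma")):
            assert abs(diag["aic"][name] - r_aic) < 0.01

    def test_small_sample_warns_and_defaults_normal(self):
        with pytest.warns(UserWarning, match="normal"):
            fam, diag = select_distribution(np.arange(5.0))
        assert fam == "normal" and diag["warning"] == "small_sample"

    def test_shift_applied_only_when_sign_indefinite(self, rng):
        fam, diag = select_distribution(rng.normal(-5, 1, 200))
        assert diag["shift"] < 0
        fam, diag = select_distribution(rng.gamma(3, 1, 200) + 1)
        assert diag["shift"] == 0.0


class TestStratumGlm:
    def test_single_level_factor_error_names_it(self, rng):
        df = frame(np.arange(10.0), rng.normal(size=10),
                   subregion=["A"] * 5 + ["B"] * 5)
        with pytest.raises(StatsError, match="reef_type"):
            fit_stratum_glm(df, "ncp", between="subregion", nested="reef_type")

    def test_nested_smoke_reports_all_factor_tests(self, small_campaign):
        _, budgets = small_campaign
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_stratum_glm(budgets, "ncp", between="subregion",
                                  nested="reef_type")
        assert set(res["tests"]) == {"subregion", "reef_type(within subregion)"}
        for t in res["tests"].values():
            assert t["F"] >= 0 and 0 <= t["p"] <= 1

    def test_power_against_three_sd_shift(self):
        rejections = 0
        n_sims = 100
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            y = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
            df = pd.DataFrame({"ncp": y, "subregion": ["A"] * 40 + ["B"] * 40})
            res = fit_stratum_glm(df, "ncp", between="subregion", nested=None,
                                  family="normal")
            rejections += res["tests"]["subregion"]["p"] < 0.05
        assert rejections / n_sims > 0.95

    def test_unknown_response_rejected(self, small_campaign):
        _, budgets = small_campaign
        with pytest.raises(StatsError):
            fit_stratum_glm(budgets, "biomass")
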