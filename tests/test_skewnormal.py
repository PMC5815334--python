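"""Censored skew-normal likelihood, delayed entry, and life expectancy."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.optimize import minimize
from scipy.stats import norm, skewnorm

from ipwmort.skewnormal import (
    SkewNormalParams,
    fit_censored_sn,
    remaining_life_expectancy,
    sn_density,
    sn_mean,
    sn_survival,
)


class TestDensityAndSurvival:
    def test_alpha_zero_reduces_to_normal(self):
        p = SkewNormalParams(xi=2.0, omega=3.0, alpha=0.0)
        x = np.linspace(-10, 14, 41)
        assert np.allclose(sn_density(x, p), norm.pdf(x, 2.0, 3.0), atol=1e-12)
        assert np.allclose(sn_survival(x, p), norm.sf(x, 2.0, 3.0), atol=1e-12)

    def test_standard_skew_mean_closed_form(self):
        """SN(0, 1, 1) has mean sqrt(2/pi)/sqrt(2) = 1/sqrt(pi)."""
        p = SkewNormalParams(xi=0.0, omega=1.0, alpha=1.0)
        assert sn_mean(p) == pytest.approx(1 / np.sqrt(np.pi), abs=1e-12)
        mean_quad, _ = integrate.quad(lambda x: x * sn_density(x, p), -10, 10)
        assert mean_quad == pytest.approx(1 / np.sqrt(np.pi), abs=1e-8)

    def test_density_normalizes(self):
        p = SkewNormalParams(xi=80.0, omega=12.0, alpha=-4.0)
        total, _ = integrate.quad(lambda x: sn_density(x, p), -100, 250, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("alpha", [-4.0, -1.0, 0.0, 2.5])
    def test_survival_consistent_with_density_integral(self, alpha):
        """sn_survival(x) + integral of the density up to x = 1 on a grid."""
        p = SkewNormalParams(xi=1.0, omega=2.0, alpha=alpha)
        for x in (-3.0, 0.0, 1.0, 4.0):
            cdf, _ = integrate.quad(lambda t: sn_density(t, p), -40, x, limit=200)
            assert sn_survival(x, p) + cdf == pytest.approx(1.0, abs=1e-8)

    def test_survival_matches_scipy(self):
        p = SkewNormalParams(xi=80.0, omega=12.0, alpha=-4.0)
        x = np.linspace(20, 110, 50)
        assert np.allclose(sn_survival(x, p),
                           skewnorm.sf(x, -4.0, loc=80, scale=12), atol=1e-10)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            SkewNormalParams(xi=0.0, omega=0.0, alpha=1.0)


@pytest.fixture(scope="module")
def sn_draws():
    rng = np.random.default_rng(314)
    return skewnorm.rvs(-4, loc=80, scale=12, size=50_000, random_state=rng)


class TestCensoredFit:
    def test_uncensored_parameter_recovery(self, sn_draws):
        """Each parameter of SN(80, 12, -4) recovered within 3 estimated SEs
        from 50,000 uncensored draws."""
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": sn_draws, "died": 1})
        fit = fit_censored_sn(rec)
        assert fit.converged
        for est, true, se in zip(
            (fit.params.xi, fit.params.omega, fit.params.alpha), (80, 12, -4), fit.se
        ):
            assert abs(est - true) < 3 * se

    def test_censored_and_delayed_entry_recovery(self, sn_draws):
        """Right censoring at 90 and entry at age 30 (survivors only) still
        recover the untruncated parameters within 3 SEs."""
        x = sn_draws[sn_draws > 30]
        rec = pd.DataFrame({
            "entry_age": 30.0,
            "exit_age": np.minimum(x, 90.0),
            "died": (x <= 90.0).astype(int),
        })
        fit = fit_censored_sn(rec)
        assert fit.converged
        for est, true, se in zip(
            (fit.params.xi, fit.params.omega, fit.params.alpha), (80, 12, -4), fit.se
        ):
            assert abs(est - true) < 3 * se

    def test_alpha_zero_matches_censored_normal_oracle(self, rng):
        """Profiled at alpha=0 the fit equals an independent censored-normal
        MLE (scipy.stats.norm likelihood) to 1e-4."""
        y = rng.normal(70, 8, 4000)
        c = np.minimum(y, 75.0)
        d = (y <= 75.0).astype(int)
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": c, "died": d})
        fit = fit_censored_sn(rec, fix_alpha=0.0)

        def negll(th):
            mu, ls = th
            s = np.exp(ls)
            return -np.where(d == 1, norm.logpdf(c, mu, s), norm.logsf(c, mu, s)).sum()

        ref = minimize(negll, [c.mean(), np.log(c.std())], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000})
        assert fit.params.xi == pytest.approx(ref.x[0], abs=1e-4)
        assert fit.params.omega == pytest.approx(np.exp(ref.x[1]), abs=1e-4)

    def test_alpha_zero_matches_r_survreg(self, rng, tmp_path):
        """Cross-language oracle: censored-normal fit agrees with R
        survival::survreg(dist='gaussian') on the same records."""
        y = rng.normal(60, 5, 500)
        c = np.minimum(y, 64.0)
        d = (y <= 64.0).astype(int)
        csv = tmp_path / "rec.csv"
        pd.DataFrame({"time": c, "status": d}).to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            f <- survreg(Surv(time, status) ~ 1, data = d, dist = "gaussian",
                         control = survreg.control(rel.tolerance = 1e-12))
            cat(coef(f)[1], f$scale, sep = "\\n")
        """)
        try:
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, timeout=120, check=True)
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.skip(f"Rscript unavailable: {exc}")
        mu_r, scale_r = map(float, out.stdout.strip().split("\n"))
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": c, "died": d})
        fit = fit_censored_sn(rec, min_deaths=10, fix_alpha=0.0)
        assert fit.params.xi == pytest.approx(mu_r, abs=1e-4)
        assert fit.params.omega == pytest.approx(scale_r, abs=1e-4)

    def test_weight_rescaling_invariance(self, sn_draws):
        """Multiplying all weights by a constant leaves estimates unchanged."""
        x = sn_draws[:5000]
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": x, "died": 1, "weight": 1.0})
        rec10 = rec.assign(weight=10.0)
        f1, f10 = fit_censored_sn(rec), fit_censored_sn(rec10)
        assert f1.params.xi == pytest.approx(f10.params.xi, abs=1e-5)
        assert f1.params.omega == pytest.approx(f10.params.omega, abs=1e-5)
        assert f1.params.alpha == pytest.approx(f10.params.alpha, abs=1e-4)

    def test_too_few_deaths_rejected(self):
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": [70.0] * 30, "died": 0})
        with pytest.raises(ValueError, match="deaths"):
            fit_censored_sn(rec)

    def test_exit_before_entry_rejected(self):
        rec = pd.DataFrame({"entry_age": 30.0, "exit_age": [25.0] * 60, "died": 1})
        with pytest.raises(ValueError, match="exceed"):
            fit_censored_sn(rec)


class TestLifeExpectancy:
    def test_normal_case_matches_truncated_normal_closed_form(self):
        """alpha=0, xi=80, omega=10: LE(30) equals the truncated-normal
        closed form E[T | T > 30] - 30 within 0.01 years."""
        p = SkewNormalParams(xi=80.0, omega=10.0, alpha=0.0)
        le, _ = remaining_life_expectancy(p, 30.0)
        z = (30 - 80) / 10
        closed = 80 + 10 * norm.pdf(z) / norm.sf(z) - 30
        assert le == pytest.approx(closed, abs=0.01)

    def test_monotone_decreasing_in_age(self):
        p = SkewNormalParams(xi=80.0, omega=12.0, alpha=-4.0)
        le30, _ = remaining_life_expectancy(p, 30.0)
        le60, _ = remaining_life_expectancy(p, 60.0)
        assert le30 > le60 > 0

    def test_delta_method_ci_brackets_estimate(self, sn_draws):
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": sn_draws[:20000], "died": 1})
        fit = fit_censored_sn(rec)
        le, (lo, hi) = remaining_life_expectancy(fit.params, 30.0, cov=fit.cov)
        assert lo < le < hi
        assert hi - lo < 1.0  # n=20k: the CI is tight

    def test_zero_survival_age_rejected(self):
        p = SkewNormalParams(xi=80.0, omega=5.0, alpha=0.0)
        with pytest.raises(ValueError, match="zero"):
            remaining_life_expectancy(p, 200.0)

    def test_round_trip_simulate_refit(self):
        """Self-consistency: simulate from fitted parameters, refit, recover
        within 3 SEs."""
        rng = np.random.default_rng(99)
        x = skewnorm.rvs(-2.5, loc=75, scale=10, size=50_000, random_state=rng)
        rec = pd.DataFrame({"entry_age": 0.0, "exit_age": x, "died": 1})
        fit1 = fit_censored_sn(rec)
        x2 = skewnorm.rvs(fit1.params.alpha, loc=fit1.params.xi,
                          scale=fit1.params.omega, size=50_000, random_state=rng)
        fit2 = fit_censored_sn(pd.DataFrame(
            {"entry_age": 0.0, "exit_age": x2, "died": 1}))
        for a, b, se in zip(
            (fit1.params.xi, fit1.params.omega, fit1.params.alpha),
            (fit2.params.xi, fit2.params.omega, fit2.params.alpha),
            fit2.se,
        ):
            assert abs(a - b) < 3 * se
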