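"""Nelson–Aalen estimator, participation model, and inverse-probability weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import NelsonAalenFitter
from scipy.optimize import minimize

from ipwmort.ipweights import (
    ParticipationModelSpec,
    compute_ip_weights,
    fit_participation_model,
    nelson_aalen,
    nelson_aalen_at,
)

SIM_SPEC = ParticipationModelSpec(
    covariates=("age", "is_male"),
    include_vital_status=True,
    include_nelson_aalen=False,
    include_age_gender_survival_interactions=False,
)


class TestNelsonAalen:
    def test_hand_computed_steps(self):
        et, ch = nelson_aalen([1, 2, 3], [1, 1, 0])
        assert list(et) == [1, 2]
        assert np.allclose(ch, [1 / 3, 1 / 3 + 1 / 2])
        assert nelson_aalen_at([3.0], et, ch)[0] == pytest.approx(5 / 6)

    def test_tied_events_pooled(self):
        et, ch = nelson_aalen([2, 2, 5], [1, 1, 1])
        assert np.allclose(ch, [2 / 3, 2 / 3 + 1])

    def test_no_events_zero_hazard(self):
        et, ch = nelson_aalen([1.0, 2.0], [0, 0])
        assert len(et) == 0
        assert nelson_aalen_at([0.5, 5.0], et, ch).tolist() == [0.0, 0.0]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            nelson_aalen([], [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_at_risk_counting(self, data):
        """Property: on random small instances the step function equals a
        brute-force loop over distinct event times counting d_j / n_j."""
        n = data.draw(st.integers(1, 30))
        times = np.array(data.draw(st.lists(
            st.integers(1, 8), min_size=n, max_size=n)), dtype=float)
        events = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        if events.sum() == 0:
            et, ch = nelson_aalen(times, events)
            assert len(et) == 0
            return
        et, ch = nelson_aalen(times, events)
        for t in np.unique(times):
            expected = 0.0
            for tj in np.unique(times[events == 1]):
                if tj <= t:
                    d_j = ((times == tj) & (events == 1)).sum()
                    n_j = (times >= tj).sum()
                    expected += d_j / n_j
            assert nelson_aalen_at([t], et, ch)[0] == pytest.approx(expected)

    def test_matches_lifelines(self, rng):
        times = rng.exponential(2.0, 300) + 0.01
        events = rng.integers(0, 2, 300)
        et, ch = nelson_aalen(times, events)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, events)
        ours = nelson_aalen_at(naf.cumulative_hazard_.index.to_numpy()[1:], et, ch)
        theirs = naf.cumulative_hazard_.iloc[1:, 0].to_numpy()
        assert np.allclose(ours, theirs)

    def test_nondecreasing_and_zero_at_origin(self, rng):
        times = rng.exponential(1.0, 200) + 0.01
        events = rng.integers(0, 2, 200)
        et, ch = nelson_aalen(times, events)
        assert np.all(np.diff(ch) >= 0)
        assert nelson_aalen_at([0.0], et, ch)[0] == 0.0


class TestParticipationModel:
    def test_random_membership_no_vital_status_effect(self, medium_population):
        """Membership assigned completely at random: the vital-status
        coefficient sits within 3 SEs of zero."""
        pop = medium_population.copy()
        pop["responded"] = (np.random.default_rng(1).random(len(pop)) < 0.05).astype(int)
        model = fit_participation_model(pop, SIM_SPEC)
        assert model.converged
        z = model.coefficients["died"] / model.bse["died"]
        assert abs(z) < 3

    def test_informative_scenario_vital_status_or_below_one(self, sampled_population):
        """Health-driven nonresponse forces the vital-status OR below 1:
        the upper 95% bound of exp(coef) must be under 1."""
        model = fit_participation_model(sampled_population, SIM_SPEC)
        upper = np.exp(model.coefficients["died"] + 1.96 * model.bse["died"])
        assert upper < 1.0

    def test_score_equation_mean_probability(self, sampled_population):
        model = fit_participation_model(sampled_population, SIM_SPEC)
        assert model.fitted_probabilities.mean() == pytest.approx(
            sampled_population["responded"].mean(), abs=1e-6
        )
        assert np.all((model.fitted_probabilities > 0) & (model.fitted_probabilities < 1))

    def test_loglik_matches_independent_optimizer(self, rng):
        """MLE log-likelihood agrees with a direct Nelder–Mead maximization
        of the Bernoulli likelihood to 1e-6."""
        n = 800
        x = rng.normal(size=n)
        m = rng.integers(0, 2, n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.5 * x - 0.8 * m)))
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"age": x, "is_male": m, "died": 0,
                           "observed_time": 1.0, "responded": y})
        model = fit_participation_model(
            df, ParticipationModelSpec(covariates=("age", "is_male"),
                                       include_vital_status=False,
                                       include_nelson_aalen=False,
                                       include_age_gender_survival_interactions=False))

        X = np.column_stack([np.ones(n), x, m])

        def negll(beta):
            eta = X @ beta
            return -(y * eta - np.logaddexp(0, eta)).sum()

        ref = minimize(negll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000})
        ours = -negll(model.coefficients.to_numpy())
        assert ours == pytest.approx(-ref.fun, abs=1e-6)

    def test_rank_deficient_design_raises(self, rng):
        df = pd.DataFrame({"age": np.ones(50), "is_male": 1, "died": 0,
                           "observed_time": 1.0, "responded": rng.integers(0, 2, 50)})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_participation_model(df, SIM_SPEC)


class TestIPWeights:
    def test_constant_probability_closed_form(self):
        df = pd.DataFrame({"age": np.zeros(1000), "is_male": 0, "died": 0,
                           "observed_time": 1.0,
                           "responded": np.r_[np.ones(50), np.zeros(950)].astype(int)})
        model = fit_participation_model(
            df, ParticipationModelSpec(covariates=(), include_vital_status=False,
                                       include_nelson_aalen=False,
                                       include_age_gender_survival_interactions=False))
        w, diag = compute_ip_weights(model, df)
        assert np.allclose(w, 20.0)
        assert diag["sum"] == pytest.approx(1000)

    def test_horvitz_thompson_population_total(self, sampled_population):
        """IP-weight sum over responders recovers the population size within 2%."""
        model = fit_participation_model(sampled_population, SIM_SPEC)
        _, diag = compute_ip_weights(model, sampled_population)
        assert diag["sum"] == pytest.approx(len(sampled_population), rel=0.02)

    def test_ip_weighted_death_share_corrects_bias(self, sampled_population):
        """The correction CS weights fail: IP-weighted death share matches the
        population within 3 weighted SEs."""
        pop = sampled_population
        model = fit_participation_model(pop, SIM_SPEC)
        w, _ = compute_ip_weights(model, pop)
        resp = pop[pop["responded"] == 1]
        d = resp["died"].to_numpy(dtype=float)
        wv = w.to_numpy()
        share = np.sum(wv * d) / wv.sum()
        resid = wv * (d - share)
        se = np.sqrt(np.sum(resid**2)) / wv.sum()
        assert abs(share - pop["died"].mean()) < 3 * se

    def test_truncation_counted_and_capped(self, sampled_population):
        model = fit_participation_model(sampled_population, SIM_SPEC)
        w_full, _ = compute_ip_weights(model, sampled_population)
        w_trunc, diag = compute_ip_weights(
            model, sampled_population, truncate_percentile=99.0)
        assert diag["n_truncated"] > 0
        assert w_trunc.max() <= w_full.max()
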