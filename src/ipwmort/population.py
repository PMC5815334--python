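"""Synthetic populations with informative-sampling structure.

The generator follows a directed acyclic graph in which observed covariates
(age, gender) drive a latent binary health status, and health drives both
survival and — downstream, in :mod:`ipwmort.sampling` — survey nonresponse.
Survival is constant-hazard (exponential) with a configurable hazard ratio
for poor health, administratively censored at a fixed horizon; the baseline
hazard is calibrated so the marginal death fraction hits a target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "PopulationParams",
    "CalibrationError",
    "calibrate_baseline_hazard",
    "solve_health_intercept",
    "generate_population",
    "POPULATION_COLUMNS",
]

#: Interchange schema shared by every downstream module.
POPULATION_COLUMNS = ["age", "is_male", "poor_health", "observed_time", "died"]


class CalibrationError(RuntimeError):
    """A calibration target (death fraction, prevalence, ...) is unreachable."""


@dataclass(frozen=True)
class PopulationParams:
    """Configuration of one simulated population.

    Parameters
    ----------
    n_individuals
        Population size (the reference study scale is 1,000,000).
    target_death_fraction
        Marginal probability of dying before the administrative censoring
        horizon; the study grid uses 0.10 and 0.25, any value in (0, 1)
        is accepted.
    health_prevalence
        Marginal share of the population with poor (latent) health.
    health_logit_age_coef
        Log-odds of poor health per standard deviation of age.
    health_logit_male_coef
        Log-odds shift of poor health for men.
    hazard_ratio_poor_health
        Hazard ratio of death for poor vs good health (study value 4).
    admin_censor_time
        Administrative censoring horizon in time units (1 = one year of
        follow-up, mirroring the real one-year mortality window).
    age_min, age_max
        Support of the uniform age distribution, in years.
    seed
        Base seed; generation is fully reproducible from it.
    """

    n_individuals: int = 1_000_000
    target_death_fraction: float = 0.10
    health_prevalence: float = 0.2
    health_logit_age_coef: float = float(np.log(2.0))
    health_logit_male_coef: float = float(np.log(1.5))
    hazard_ratio_poor_health: float = 4.0
    admin_censor_time: float = 1.0
    age_min: float = 15.0
    age_max: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(
            [
                self.target_death_fraction,
                self.health_prevalence,
                self.health_logit_age_coef,
                self.health_logit_male_coef,
                self.hazard_ratio_poor_health,
                self.admin_censor_time,
            ]
        ).all():
            raise ValueError("population parameters must be finite")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0.0 < self.target_death_fraction < 1.0:
            raise ValueError("target_death_fraction must lie in (0, 1)")
        if not 0.0 <= self.health_prevalence < 1.0:
            raise ValueError("health_prevalence must lie in [0, 1)")
        if self.hazard_ratio_poor_health <= 0:
            raise ValueError("hazard_ratio_poor_health must be positive")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be positive")
        if self.age_max <= self.age_min:
            raise ValueError("age_max must exceed age_min")


def calibrate_baseline_hazard(params: PopulationParams) -> float:
    """Baseline hazard rate hitting the target marginal death fraction.

    Solves for the rate ``lam0`` such that mixing the exponential death
    probabilities of the good-health stratum (rate ``lam0``) and the
    poor-health stratum (rate ``lam0 * HR``) at the configured prevalence
    reproduces ``target_death_fraction`` by the censoring horizon:

    ``(1-p)(1 - exp(-lam0*tau)) + p(1 - exp(-lam0*HR*tau)) = f``

    The mixture depends on health only through its marginal prevalence, so
    the solution is exact for any age/gender structure of the health model.
    """
    p = params.health_prevalence
    hr = params.hazard_ratio_poor_health
    tau = params.admin_censor_time
    f = params.target_death_fraction

    def death_fraction(lam0: float) -> float:
        return (1 - p) * (-np.expm1(-lam0 * tau)) + p * (-np.expm1(-lam0 * hr * tau))

    lo, hi = 1e-12, 1.0
    while death_fraction(hi) < f:
        hi *= 2.0
        if hi > 1e12:
            raise CalibrationError(
                f"death fraction {f} unreachable by horizon {tau}"
            )
    return float(brentq(lambda lam: death_fraction(lam) - f, lo, hi, xtol=1e-14, rtol=1e-12))


def solve_health_intercept(
    params: PopulationParams, age_std: np.ndarray, is_male: np.ndarray
) -> float:
    """Intercept of the health logit making the realized-expectation
    prevalence equal ``health_prevalence`` exactly (bisection, tol 1e-8)."""
    lin = params.health_logit_age_coef * age_std + params.health_logit_male_coef * is_male
    target = params.health_prevalence
    if target == 0.0:
        return -np.inf

    def mean_prob(b0: float) -> float:
        return float(expit(b0 + lin).mean())

    lo, hi = -50.0, 50.0
    if not mean_prob(lo) <= target <= mean_prob(hi):
        raise CalibrationError(f"prevalence {target} unreachable")
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_population(params: PopulationParams) -> pd.DataFrame:
    """Simulate one population as a data frame.

    Columns: ``age`` (uniform on [age_min, age_max]), ``is_male`` (fair
    coin), ``poor_health`` (logistic in standardized age and gender with
    intercept solved for exact marginal prevalence), ``event_time`` (true
    exponential death time), ``observed_time`` (administratively censored),
    ``died`` (event indicator).  Sampling and response flags are added by
    :mod:`ipwmort.sampling`.
    """
    rng = np.random.default_rng(params.seed)
    # independent substreams per stage so stages can be re-run in isolation
    rng_age, rng_sex, rng_health, rng_surv = rng.spawn(4)
    n = params.n_individuals

    age = rng_age.uniform(params.age_min, params.age_max, size=n)
    is_male = rng_sex.integers(0, 2, size=n)

    # standardize age against the *theoretical* uniform moments so the
    # health model does not drift with n
    age_mean = 0.5 * (params.age_min + params.age_max)
    age_sd = (params.age_max - params.age_min) / np.sqrt(12.0)
    age_std = (age - age_mean) / age_sd

    b0 = solve_health_intercept(params, age_std, is_male)
    p_poor = expit(
        b0
        + params.health_logit_age_coef * age_std
        + params.health_logit_male_coef * is_male
    )
    poor_health = (rng_health.random(n) < p_poor).astype(np.int8)

    lam0 = calibrate_baseline_hazard(params)
    rate = lam0 * np.where(poor_health == 1, params.hazard_ratio_poor_health, 1.0)
    event_time = rng_surv.exponential(1.0 / rate)
    died = (event_time <= params.admin_censor_time).astype(np.int8)
    observed_time = np.minimum(event_time, params.admin_censor_time)

    return pd.DataFrame(
        {
            "age": age,
            "is_male": is_male.astype(np.int8),
            "poor_health": poor_health,
            "event_time": event_time,
            "observed_time": observed_time,
            "died": died,
        }
    )
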