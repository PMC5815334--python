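"""Survey sampling, health-dependent nonresponse, and calibrated-survey weights.

A planned random sample is drawn with a fixed sampling fraction; sampled
individuals then respond with a probability that is logistic in latent
health (poor health raises the odds of *non*response by a configurable odds
ratio).  Calibrated-survey (CS) weights are built from the information a
statistical office would actually hold — the sampling fraction and a
response probability estimated from *observed* covariates only, never the
latent health — which is precisely why CS weights remain biased for
survival outcomes under informative nonresponse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

__all__ = [
    "SamplingParams",
    "draw_sample",
    "solve_nonresponse_intercept",
    "apply_nonresponse",
    "compute_cs_weights",
]


@dataclass(frozen=True)
class SamplingParams:
    """Sampling-design configuration.

    ``sampling_fraction`` and ``nonresponse_fraction`` must lie strictly in
    (0, 1); the study grid uses fractions {0.01, 0.10} and nonresponse
    {0.10, 0.25} with a nonresponse odds ratio of 4 for poor health.
    ``cs_response_model`` chooses how CS weights estimate the response
    probability: ``"covariate"`` (logistic in age and gender among the
    sampled — the nonresponse adjustment an office could do) or
    ``"marginal"`` (one overall response rate). ``"oracle"`` conditions on
    the latent health itself and exists only for contrast in experiments.
    """

    sampling_fraction: float = 0.10
    nonresponse_fraction: float = 0.25
    nonresponse_or_poor_health: float = 4.0
    cs_response_model: str = "covariate"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError("sampling_fraction must lie in (0, 1] ")
        if not 0.0 < self.nonresponse_fraction < 1.0:
            raise ValueError("nonresponse_fraction must lie in (0, 1)")
        if self.nonresponse_or_poor_health <= 0:
            raise ValueError("nonresponse_or_poor_health must be positive")
        if self.cs_response_model not in {"covariate", "marginal", "oracle"}:
            raise ValueError("unknown cs_response_model")


def draw_sample(
    population: pd.DataFrame, params: SamplingParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Set the ``sampled`` flag by independent Bernoulli draws."""
    if len(population) == 0:
        raise ValueError("population is empty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = population.copy()
    out["sampled"] = (rng.random(len(out)) < params.sampling_fraction).astype(np.int8)
    return out


def solve_nonresponse_intercept(
    target_fraction: float, or_poor_health: float, poor_health_share: float
) -> float:
    """Log-odds intercept of the nonresponse model.

    Solves ``(1-p)*expit(b0) + p*expit(b0 + ln OR) = target`` for ``b0``,
    where ``p`` is the poor-health share among the sampled, by bisection to
    1e-8.  With OR = 1 this reduces to ``logit(target)``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if or_poor_health <= 0:
        raise ValueError("odds ratio must be positive")
    log_or = np.log(or_poor_health)
    p = poor_health_share

    def overall(b0: float) -> float:
        return (1 - p) * expit(b0) + p * expit(b0 + log_or)

    lo, hi = -50.0, 50.0
    if not overall(lo) <= target_fraction <= overall(hi):
        raise ValueError(f"nonresponse target {target_fraction} unreachable")
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if overall(mid) < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_nonresponse(
    sample: pd.DataFrame, params: SamplingParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Set the ``responded`` flag among the sampled.

    Nonresponse is logistic in poor health only (the causal route of the
    sampling graph); the intercept is solved so that the realized-expectation
    nonresponse among the sampled equals ``nonresponse_fraction``.  The
    per-individual *non*response probability is stored in
    ``p_nonresponse`` for downstream oracle weighting.
    """
    if "sampled" not in sample.columns:
        raise ValueError("call draw_sample first")
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    out = sample.copy()
    in_sample = out["sampled"].to_numpy() == 1
    if in_sample.sum() == 0:
        out["responded"] = np.int8(0)
        out["p_nonresponse"] = np.nan
        return out

    share = float(out.loc[in_sample, "poor_health"].mean())
    b0 = solve_nonresponse_intercept(
        params.nonresponse_fraction, params.nonresponse_or_poor_health, share
    )
    p_nr = expit(b0 + np.log(params.nonresponse_or_poor_health) * out["poor_health"].to_numpy())
    responded = in_sample & (rng.random(len(out)) >= p_nr)
    out["responded"] = responded.astype(np.int8)
    out["p_nonresponse"] = np.where(in_sample, p_nr, np.nan)
    return out


def compute_cs_weights(sample: pd.DataFrame, params: SamplingParams) -> pd.DataFrame:
    """Attach calibrated-survey weights ``cs_weight`` to responders.

    weight = 1 / (sampling_fraction * estimated response probability).
    The response probability deliberately ignores the latent health:
    ``"covariate"`` fits a logistic response model in age and gender among
    the sampled, ``"marginal"`` uses the overall response rate.  The
    ``"oracle"`` mode uses the true health-conditional probability and is
    unbiased by construction — useful only as a contrast.
    """
    if "responded" not in sample.columns:
        raise ValueError("call apply_nonresponse first")
    out = sample.copy()
    in_sample = out["sampled"].to_numpy() == 1
    responded = out["responded"].to_numpy() == 1
    n_sampled = int(in_sample.sum())
    if n_sampled == 0:
        out["cs_weight"] = np.nan
        return out

    if params.cs_response_model == "marginal":
        p_resp = np.full(len(out), responded.sum() / n_sampled)
    elif params.cs_response_model == "oracle":
        p_resp = 1.0 - out["p_nonresponse"].to_numpy()
    else:  # covariate-based nonresponse adjustment
        X = sm.add_constant(
            out.loc[in_sample, ["age", "is_male"]].to_numpy(dtype=float), prepend=True
        )
        y = responded[in_sample].astype(float)
        if y.min() == y.max():  # all or none responded: degenerate, constant prob
            p_resp = np.full(len(out), max(y.mean(), 1e-12))
        else:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            p_all = np.full(len(out), np.nan)
            p_all[in_sample] = fit.predict(X)
            p_resp = p_all

    p_eff = params.sampling_fraction * p_resp
    if np.any(p_eff[responded] <= 0):
        raise ValueError("zero effective inclusion probability")
    out["cs_weight"] = np.where(responded, 1.0 / p_eff, np.nan)
    return out
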