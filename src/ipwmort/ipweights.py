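"""Inverse-probability weights from a participation model with survival information.

The participation model is a logistic regression for effective-sample
membership, fitted on the *full* population.  Beyond the design covariates
it can condition on survival information — the vital-status indicator, the
Nelson–Aalen cumulative hazard evaluated at each individual's exit time,
and interactions of age and gender with those terms.  IP weights are the
reciprocal fitted probabilities of the responders; because the model sees
the outcome-side information that drives informative nonresponse, the
weighted sample recovers population-level survival quantities that
calibrated-survey weights miss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ParticipationModelSpec",
    "ParticipationModel",
    "nelson_aalen",
    "nelson_aalen_at",
    "fit_participation_model",
    "compute_ip_weights",
]


def nelson_aalen(observed_times, event_indicators):
    """Nelson–Aalen cumulative hazard ``H(t) = sum_{t_j <= t} d_j / n_j``.

    Tied events are pooled at the tied time.  Returns ``(event_times,
    cum_hazard)``: the distinct event times in increasing order and the
    cumulative hazard *at* each of them; ``H(0) = 0`` and the function is a
    right-continuous nondecreasing step function.
    """
    t = np.asarray(observed_times, dtype=float)
    d = np.asarray(event_indicators)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.isin(d, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")

    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    d_sorted = d[order].astype(float)
    uniq, start_idx = np.unique(t_sorted, return_index=True)
    # events and at-risk count at each distinct observed time
    deaths = np.add.reduceat(d_sorted, start_idx)
    at_risk = t.size - start_idx
    is_event_time = deaths > 0
    event_times = uniq[is_event_time]
    increments = deaths[is_event_time] / at_risk[is_event_time]
    return event_times, np.cumsum(increments)


def nelson_aalen_at(eval_times, event_times, cum_hazard):
    """Evaluate a Nelson–Aalen step function at arbitrary times."""
    idx = np.searchsorted(event_times, np.asarray(eval_times, dtype=float), side="right")
    return np.concatenate([[0.0], cum_hazard])[idx]


@dataclass(frozen=True)
class ParticipationModelSpec:
    """What enters the logistic participation model.

    ``covariates`` are column names of the population frame (simulation
    default: continuous age and the male indicator).  The survival terms —
    vital status and/or the Nelson–Aalen cumulative hazard at exit — and
    their interactions with age and gender are toggled individually; the
    real-data analysis uses all of them, the simulation study conditions on
    vital status alone.
    """

    covariates: tuple = ("age", "is_male")
    include_vital_status: bool = True
    include_nelson_aalen: bool = True
    include_age_gender_survival_interactions: bool = True
    time_col: str = "observed_time"
    event_col: str = "died"


@dataclass
class ParticipationModel:
    coefficients: pd.Series
    fitted_probabilities: np.ndarray
    converged: bool
    n_iterations: int
    bse: pd.Series
    spec: ParticipationModelSpec = field(repr=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
        }


def _design_matrix(population: pd.DataFrame, spec: ParticipationModelSpec):
    cols: dict[str, np.ndarray] = {"const": np.ones(len(population))}
    for c in spec.covariates:
        v = population[c]
        if isinstance(v.dtype, pd.CategoricalDtype) or v.dtype == object:
            dummies = pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)
            for dc in dummies.columns:
                cols[dc] = dummies[dc].to_numpy()
        else:
            cols[c] = v.to_numpy(dtype=float)

    survival_terms: dict[str, np.ndarray] = {}
    if spec.include_vital_status:
        survival_terms["died"] = population[spec.event_col].to_numpy(dtype=float)
    if spec.include_nelson_aalen:
        et, ch = nelson_aalen(
            population[spec.time_col].to_numpy(), population[spec.event_col].to_numpy()
        )
        survival_terms["nelson_aalen"] = nelson_aalen_at(
            population[spec.time_col].to_numpy(), et, ch
        )
    cols.update(survival_terms)

    if spec.include_age_gender_survival_interactions and survival_terms:
        for sname, sval in survival_terms.items():
            for c in spec.covariates:
                v = population[c]
                if isinstance(v.dtype, pd.CategoricalDtype) or v.dtype == object:
                    continue  # interactions are with the continuous/binary encodings
                cols[f"{c}:{sname}"] = v.to_numpy(dtype=float) * sval
    X = pd.DataFrame(cols, index=population.index)
    return X


def fit_participation_model(
    population: pd.DataFrame,
    spec: ParticipationModelSpec,
    membership_col: str = "responded",
) -> ParticipationModel:
    """Maximum-likelihood logistic fit of effective-sample membership.

    Fitted on every record of the population frame; raises if the design
    matrix is rank-deficient and flags (never hides) non-convergence or
    separation-like behaviour.
    """
    if membership_col not in population.columns:
        raise ValueError(f"missing membership column {membership_col!r}")
    y = population[membership_col].to_numpy(dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("membership indicator must be 0/1 for every record")
    X = _design_matrix(population, spec)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient after encoding")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    p_hat = np.asarray(res.fittedvalues)
    converged = bool(res.converged) and bool(np.all((p_hat > 0) & (p_hat < 1)))
    return ParticipationModel(
        coefficients=pd.Series(res.params, index=X.columns),
        fitted_probabilities=p_hat,
        converged=converged,
        n_iterations=int(res.fit_history["iteration"]),
        bse=pd.Series(res.bse, index=X.columns),
        spec=spec,
    )


def compute_ip_weights(
    model: ParticipationModel,
    population: pd.DataFrame,
    membership_col: str = "responded",
    stabilized: bool = False,
    truncate_percentile: float | None = None,
):
    """Inverse-probability weights ``1 / p_hat`` for effective-sample members.

    Returns ``(weights, diagnostics)`` where ``weights`` is a Series indexed
    like the responders and diagnostics reports min/max/sum, the coefficient
    of variation and the number of truncated weights.  ``stabilized``
    multiplies by the marginal participation rate; ``truncate_percentile``
    caps weights at that percentile (default: no truncation).
    """
    member = population[membership_col].to_numpy() == 1
    p_hat = model.fitted_probabilities[member]
    w = 1.0 / p_hat
    if stabilized:
        w = w * member.mean()
    n_truncated = 0
    if truncate_percentile is not None:
        cap = np.percentile(w, truncate_percentile)
        n_truncated = int((w > cap).sum())
        w = np.minimum(w, cap)
    weights = pd.Series(w, index=population.index[member], name="ip_weight")
    diagnostics = {
        "min": float(w.min()),
        "max": float(w.max()),
        "sum": float(w.sum()),
        "cv": float(w.std() / w.mean()),
        "n_truncated": n_truncated,
    }
    return weights, diagnostics
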