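"""Weighted Poisson mortality rates, weighted marginals, and crude participation odds ratios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable2x2",
    "crude_participation_or",
    "participation_table_from_counts",
    "fit_weighted_poisson",
    "weighted_marginals",
]

_Z95 = 1.96  # fixed 95% normal quantile so printed CIs round reproducibly


@dataclass(frozen=True)
class CountTable2x2:
    """Participation-by-attribute counts.

    ``a``: participants with the attribute, ``b``: participants without,
    ``c``/``d``: the corresponding counts among NON-participants.  Because
    participants are a subset of the reference population, ``c`` and ``d``
    must already be population-minus-participant counts (see
    :func:`participation_table_from_counts`).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be nonnegative integers")


def participation_table_from_counts(
    participants_attr: int,
    participants_ref: int,
    population_attr: int,
    population_ref: int,
) -> CountTable2x2:
    """Build the table from participant and whole-population counts.

    Subtracts participants from the population so the odds of
    participation are taken against non-participants — the convention that
    reproduces the published census-participation odds ratios exactly.
    """
    c = population_attr - participants_attr
    d = population_ref - participants_ref
    if c < 0 or d < 0:
        raise ValueError("participants exceed population in a cell")
    return CountTable2x2(a=participants_attr, b=participants_ref, c=c, d=d)


def crude_participation_or(table: CountTable2x2):
    """Crude odds ratio of participation with a 95% Wald CI.

    OR = (a/c) / (b/d): odds of being a participant among those with the
    attribute versus without.  CI on the log scale,
    ``exp(ln OR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.  Zero cells raise
    (no continuity correction).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        raise ValueError("zero cell: odds ratio undefined without correction")
    log_or = np.log(a) - np.log(c) - np.log(b) + np.log(d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - _Z95 * se)),
        float(np.exp(log_or + _Z95 * se)),
    )


def fit_weighted_poisson(
    events,
    person_time,
    strata=None,
    weights=None,
    per: float = 1.0,
) -> pd.DataFrame:
    """Weighted Poisson (person-time offset) mortality rates per stratum.

    In a saturated stratum model the weighted Poisson MLE has the closed
    form ``rate = sum(w*d) / sum(w*t)`` per stratum, which is what is
    computed here; a test verifies equality with the iterative GLM fit.
    Confidence intervals use the robust (sandwich) variance of the log
    rate, ``sum(w^2 (d - r t)^2) / (sum(w t) * r)^2``, which reduces to the
    usual ``1/D`` Poisson variance for unit weights.  Strata with zero
    weighted person-time are dropped.  ``per`` rescales reported rates
    (e.g. 1000 for deaths per 1,000 person-years); internal math is per
    single time unit.
    """
    d = np.asarray(events, dtype=float)
    t = np.asarray(person_time, dtype=float)
    if np.any(t <= 0):
        raise ValueError("person_time must be positive")
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w[~np.isnan(w)] < 0):
        raise ValueError("weights must be nonnegative")
    labels = np.zeros(len(d), dtype=int) if strata is None else np.asarray(strata)
    unit_weights = weights is None or np.allclose(w, 1.0)

    rows = []
    for s in pd.unique(labels):
        m = labels == s
        ws, ds, ts = w[m], d[m], t[m]
        wt = float(np.sum(ws * ts))
        wd = float(np.sum(ws * ds))
        if wt <= 0:
            import warnings

            warnings.warn(f"stratum {s!r} has zero weighted person-time; dropped")
            continue
        rate = wd / wt
        if wd > 0:
            if unit_weights:
                var_log = 1.0 / wd  # Poisson variance of log rate
            else:
                resid = ds - rate * ts
                var_log = float(np.sum(ws**2 * resid**2)) / (wt * rate) ** 2
            se = np.sqrt(var_log)
            lo, hi = rate * np.exp(-_Z95 * se), rate * np.exp(_Z95 * se)
        else:
            lo = hi = np.nan
        rows.append(
            {
                "stratum": s,
                "events": wd,
                "person_time": wt,
                "rate": rate * per,
                "ci_low": lo * per,
                "ci_high": hi * per,
            }
        )
    return pd.DataFrame(rows)


def weighted_marginals(data: pd.DataFrame, weights, covariates) -> pd.DataFrame:
    """Weighted percentage distribution of each covariate.

    Returns a tidy frame (covariate, level, percent); percentages sum to
    100 within each covariate.  Unit weights reproduce the unweighted
    percentages.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    total = w.sum()
    rows = []
    for cov in covariates:
        grouped = pd.Series(w).groupby(data[cov].to_numpy()).sum()
        for level, ww in grouped.items():
            rows.append({"covariate": cov, "level": level, "percent": 100.0 * ww / total})
    return pd.DataFrame(rows)
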