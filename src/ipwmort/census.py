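"""Anonymized census schema: vocabularies, validated I/O, packaged count fixture.

The real analysis links a registry-based full population to a micro-census
sample; the anonymized interchange format carries age and follow-up time
rounded to one decimal, categorical covariates with fixed vocabularies, a
participation flag and a death indicator, plus the statistical office's
calibrated survey weight where available.  This module validates that
schema on load, ships the published participation-by-covariate count table
as a packaged fixture, and can generate a clearly-synthetic stand-in
dataset for exercising the real-data pipeline without any download.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = [
    "NATIONALITY_LEVELS",
    "CIVIL_STATUS_LEVELS",
    "REGION_LEVELS",
    "AGE_BAND_LABELS",
    "age_band",
    "read_census_csv",
    "load_table1_counts",
    "crude_or_table",
    "make_synthetic_census",
    "CensusValidationError",
]

NATIONALITY_LEVELS = ("Swiss", "EEA", "Other Europe", "Other World")
CIVIL_STATUS_LEVELS = ("Single", "Married", "Widowed", "Other")
GENDER_LEVELS = ("Men", "Women")
#: 26-level regional factor (two cantons subdivided).
REGION_LEVELS = (
    "City of Zurich",
    "Remainder of canton Zurich",
    "City of Bern",
    "Bernese Jura",
    "Remainder of canton Bern",
    "Lucerne",
    "Uri",
    "Schwyz",
    "Obwalden",
    "Nidwalden",
    "Glarus",
    "Zug",
    "Fribourg",
    "Solothurn",
    "Basel-Stadt",
    "Basel-Landschaft",
    "Schaffhausen",
    "Appenzell Ausserrhoden",
    "Appenzell Innerrhoden",
    "St. Gallen",
    "Graubuenden",
    "Aargau",
    "Thurgau",
    "Ticino",
    "Vaud",
    "Valais",
    "Neuchatel",
    "Geneva",
    "Jura",
)

_BAND_EDGES = np.arange(15, 90, 5)
AGE_BAND_LABELS = tuple(f"[{lo}, {lo + 5})" for lo in range(15, 85, 5)) + (">=85",)

_DEFAULT_COLUMNS = {
    "age": "age",
    "gender": "gender",
    "nationality": "nationality",
    "civil_status": "civil_status",
    "region": "region",
    "in_se": "in_se",
    "died": "died",
    "follow_up": "follow_up",
    "cs_weight": "cs_weight",
}


class CensusValidationError(ValueError):
    """Raised when a census file fails schema validation beyond the error budget."""


def age_band(age) -> np.ndarray:
    """Shared 5-year age banding, [15, 20) ... [80, 85), >=85.

    Every module that stratifies by age uses this single function so the
    banding cannot drift between the odds-ratio table, the rate models and
    the participation model.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 15):
        raise ValueError("ages below 15 are outside the study population")
    idx = np.minimum(np.searchsorted(_BAND_EDGES, a, side="right") - 1, len(AGE_BAND_LABELS) - 1)
    return np.asarray(AGE_BAND_LABELS, dtype=object)[idx]


def read_census_csv(
    path,
    column_map: dict | None = None,
    delimiter: str = ",",
    max_errors: int = 100,
):
    """Load and validate an anonymized census CSV.

    ``column_map`` maps schema names (keys of the default mapping) to the
    file's actual column names — the supplementary file's headers are not
    standardized, so the mapping is configuration, not a hard-coded guess.
    Returns ``(frame, report)``; ``report`` lists row-numbered validation
    errors and the counts by (participation, vital status) so published
    totals can be checked at load time.  More than ``max_errors`` bad rows
    aborts with :class:`CensusValidationError`.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, sep=delimiter)
    missing = [v for k, v in cols.items() if v not in raw.columns and k != "cs_weight"]
    if missing:
        raise CensusValidationError(f"missing required columns: {missing}")

    df = pd.DataFrame(
        {k: raw[v] for k, v in cols.items() if v in raw.columns}
    )
    errors: list[str] = []

    def check_vocab(col: str, levels) -> None:
        bad = ~df[col].isin(levels)
        for row in df.index[bad]:
            errors.append(f"row {row + 2}: {col}={df.loc[row, col]!r} not in vocabulary")

    check_vocab("gender", GENDER_LEVELS)
    check_vocab("nationality", NATIONALITY_LEVELS)
    check_vocab("civil_status", CIVIL_STATUS_LEVELS)
    check_vocab("region", REGION_LEVELS)
    for row in df.index[~df["died"].isin([0, 1])]:
        errors.append(f"row {row + 2}: died={df.loc[row, 'died']!r} not 0/1")
    for row in df.index[~df["in_se"].isin([0, 1])]:
        errors.append(f"row {row + 2}: in_se={df.loc[row, 'in_se']!r} not 0/1")
    fu = pd.to_numeric(df["follow_up"], errors="coerce")
    for row in df.index[~(fu > 0)]:
        errors.append(f"row {row + 2}: follow_up={df.loc[row, 'follow_up']!r} not positive")

    if len(errors) > max_errors:
        raise CensusValidationError(
            f"{len(errors)} validation errors (budget {max_errors}); first: {errors[0]}"
        )
    counts = (
        df.groupby(["in_se", "died"]).size().rename("n").reset_index().to_dict("records")
    )
    report = {"n_rows": len(df), "errors": errors, "counts_by_in_se_died": counts}
    return df, report


def load_table1_counts() -> pd.DataFrame:
    """Published participation-by-covariate counts (packaged fixture).

    Columns: covariate, level, and the alive/died counts for the full
    registry population and the survey sample.
    """
    with importlib.resources.files("ipwmort.data").joinpath("table1_counts.csv").open() as fh:
        return pd.read_csv(fh)


_REFERENCE_LEVELS = {
    "age": "[15, 20)",
    "gender": "Men",
    "nationality": "Swiss",
    "civil_status": "Single",
    "region": "Remainder of canton Zurich",
}


def crude_or_table(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Crude participation odds-ratio table from the count fixture.

    For each covariate level the odds of survey participation (participants
    vs non-participants) are compared against the covariate's reference
    level; the vital-status row compares those who died within follow-up
    against those alive, using the table's column totals.  Reproduces the
    published crude OR table to its printed rounding.
    """
    from .estimators import crude_participation_or, participation_table_from_counts

    if counts is None:
        counts = load_table1_counts()
    counts = counts.copy()
    counts["se_total"] = counts["se_alive"] + counts["se_died"]
    counts["statpop_total"] = counts["statpop_alive"] + counts["statpop_died"]

    rows = []
    for cov, ref in _REFERENCE_LEVELS.items():
        sub = counts[counts["covariate"] == cov]
        ref_row = sub[sub["level"] == ref].iloc[0]
        for _, level_row in sub.iterrows():
            if level_row["level"] == ref:
                rows.append(
                    {"covariate": cov, "level": ref, "odds_ratio": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "reference": True}
                )
                continue
            table = participation_table_from_counts(
                int(level_row["se_total"]),
                int(ref_row["se_total"]),
                int(level_row["statpop_total"]),
                int(ref_row["statpop_total"]),
            )
            or_, lo, hi = crude_participation_or(table)
            rows.append(
                {"covariate": cov, "level": level_row["level"], "odds_ratio": or_,
                 "ci_low": lo, "ci_high": hi, "reference": False}
            )

    # vital status from the column totals of any one covariate block
    gender = counts[counts["covariate"] == "gender"]
    table = participation_table_from_counts(
        int(gender["se_died"].sum()),
        int(gender["se_alive"].sum()),
        int(gender["statpop_died"].sum()),
        int(gender["statpop_alive"].sum()),
    )
    or_, lo, hi = crude_participation_or(table)
    rows.append(
        {"covariate": "vital_status", "level": "Alive", "odds_ratio": np.nan,
         "ci_low": np.nan, "ci_high": np.nan, "reference": True}
    )
    rows.append(
        {"covariate": "vital_status", "level": "Death", "odds_ratio": or_,
         "ci_low": lo, "ci_high": hi, "reference": False}
    )
    return pd.DataFrame(rows)


def make_synthetic_census(n: int = 5000, seed: int = 0) -> pd.DataFrame:
    """SYNTHETIC census-schema dataset for pipeline tests and demos.

    Not a reconstruction of any real population: covariate frequencies and
    mortality are plausible but invented, and the informative-participation
    structure (the dead participate less) is built in so weighting
    pipelines have something to correct.  One-decimal rounding of age and
    follow-up mirrors the anonymized release format.
    """
    rng = np.random.default_rng(seed)
    age = np.round(rng.uniform(15, 95, n), 1)
    gender = rng.choice(GENDER_LEVELS, n)
    nationality = rng.choice(NATIONALITY_LEVELS, n, p=[0.77, 0.15, 0.05, 0.03])
    civil = rng.choice(CIVIL_STATUS_LEVELS, n, p=[0.33, 0.52, 0.06, 0.09])
    region = rng.choice(REGION_LEVELS, n)
    # mortality rising with age, one-year window
    p_die = 1 / (1 + np.exp(-(-8.5 + 0.08 * age)))
    died = (rng.random(n) < p_die).astype(int)
    follow_up = np.where(died == 1, np.round(rng.uniform(0.1, 1.0, n), 1), 1.0)
    # participation ~8%, lower for the dead (informative sampling)
    p_se = np.where(died == 1, 0.056, 0.08)
    in_se = (rng.random(n) < p_se).astype(int)
    cs_weight = np.where(in_se == 1, 1 / 0.08, np.nan)
    return pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "nationality": nationality,
            "civil_status": civil,
            "region": region,
            "in_se": in_se,
            "died": died,
            "follow_up": follow_up,
            "cs_weight": cs_weight,
        }
    )
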