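"""From individual life histories to the 3-year observation-bin model table.

Each female contributes one row per 3-year age window from age 5 (bins
[5,7], [8,10], ... by completed integer age, reported by their mid-age 6, 9,
...) up to and including the bin whose start age she reached before death or
censoring.  A bin scores ``reproduced = 1`` when at least one calving falls
inside it -- two calvings in one window still score 1, which is why the
window width matches the species' long inter-birth interval.

Covariates follow the reproductive-senescence modelling convention: birth
season (born during the hormone-defined high-stress months), birth decade
(cohort effect), censoring status with linear and quadratic age at last
sighting (to separate selective disappearance from within-individual
ageing), and optional maternal covariates (birth order, maternal age)
available only for a subset of females.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BIN_WIDTH, FIRST_AGE

__all__ = [
    "SeasonLabel",
    "label_birth_season",
    "conception_date",
    "build_observation_bins",
    "attach_covariates",
    "senescent_subset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeasonLabel:
    """A high-stress season: calendar months plus the gestation length used to
    shift the label back to conception."""

    months: frozenset = frozenset({6, 7, 8})
    gestation_months: int = 22

    def __post_init__(self):
        if not set(self.months) <= set(range(1, 13)):
            raise ValueError(f"months must lie in 1..12, got {sorted(self.months)}")


def label_birth_season(birth_month, season: SeasonLabel):
    """1 when the birth month falls in the high-stress season, else 0."""
    m = np.asarray(birth_month)
    if np.any((m < 1) | (m > 12)):
        raise ValueError("birth month outside 1..12")
    out = np.isin(m, list(season.months)).astype(int)
    return out if out.ndim else int(out)


def conception_date(birth_year, birth_month, gestation_months: int = 22):
    """Calendar (year, month) exactly ``gestation_months`` before birth."""
    m = np.asarray(birth_month)
    if np.any((m < 1) | (m > 12)):
        raise ValueError("birth month outside 1..12")
    total = np.asarray(birth_year) * 12 + (m - 1) - gestation_months
    year, month = total // 12, total % 12 + 1
    if year.ndim:
        return year, month
    return int(year), int(month)


def build_observation_bins(
    records: pd.DataFrame, bin_width: int = BIN_WIDTH, start_age: int = FIRST_AGE
) -> pd.DataFrame:
    """Expand one-row-per-female records into the per-bin binary table.

    A bin is emitted whenever its start age does not exceed the female's age
    at last sighting (partial final windows are kept; the censoring covariates
    control for them downstream).  Bin membership of a calving uses completed
    integer age.
    """
    rows_id, rows_start, rows_repro = [], [], []
    for rec in records.itertuples(index=False):
        ages = rec.calving_ages
        last = float(rec.last_seen_age)
        if any(a > last + 1e-9 for a in ages):
            raise ValueError(
                f"calving after last sighting for female {rec.id}"
            )
        n_bins = int((last - start_age) // bin_width) + 1 if last >= start_age else 0
        calved_bins = set()
        for a in ages:
            b = (int(a) - start_age) // bin_width
            if b < 0 or b >= n_bins:
                raise ValueError(
                    f"calving age {a} outside observation bins for female {rec.id}"
                )
            calved_bins.add(b)
        for b in range(n_bins):
            rows_id.append(rec.id)
            rows_start.append(start_age + b * bin_width)
            rows_repro.append(1 if b in calved_bins else 0)
    out = pd.DataFrame(
        {
            "id": pd.Series(rows_id, dtype=str),
            "bin_start_age": pd.Series(rows_start, dtype=int),
            "reproduced": pd.Series(rows_repro, dtype=int),
        }
    )
    out["bin_mid_age"] = out["bin_start_age"] + 1
    return out[["id", "bin_start_age", "bin_mid_age", "reproduced"]]


def attach_covariates(
    bins: pd.DataFrame,
    records: pd.DataFrame,
    season: SeasonLabel = SeasonLabel(),
    *,
    scale_age: bool = True,
    reference_decade: str | None = None,
) -> pd.DataFrame:
    """Join per-female covariates onto the bin table and derive model terms.

    Adds the birth-season and conception-season flags, birth decade (string
    such as "1940s", ordered so the earliest decade is the reference level),
    censoring flag, age at last sighting (scaled by 100 with its square), and
    the scaled bin mid-age.  Rows missing any *required* covariate are dropped
    and counted in the log; maternal covariates may stay missing (they only
    restrict the dedicated subset analyses).
    """
    cov = records.set_index("id")
    df = bins.merge(
        cov[
            [
                "birth_year",
                "birth_month",
                "region",
                "birth_order",
                "maternal_age",
                "last_seen_age",
                "censored",
            ]
        ],
        left_on="id",
        right_index=True,
        how="left",
    )
    required = ["birth_year", "birth_month", "region", "last_seen_age", "censored"]
    bad = df[required].isna().any(axis=1)
    if bad.any():
        log.warning("dropping %d bin rows with missing required covariates", bad.sum())
        df = df[~bad].copy()

    df["high_stress_born"] = label_birth_season(df["birth_month"].to_numpy(), season)
    _, cmonth = conception_date(
        df["birth_year"].to_numpy(), df["birth_month"].to_numpy(), season.gestation_months
    )
    df["conception_month"] = cmonth
    df["high_stress_conceived"] = label_birth_season(cmonth, season)
    decade = (df["birth_year"].astype(int) // 10 * 10).astype(str) + "s"
    levels = sorted(decade.unique())
    if reference_decade is not None:
        if reference_decade not in levels:
            raise ValueError(f"reference decade {reference_decade!r} not in data")
        levels = [reference_decade] + [d for d in levels if d != reference_decade]
    df["birth_decade"] = pd.Categorical(decade, categories=levels)
    scale = 100.0 if scale_age else 1.0
    df["age_scaled"] = df["bin_mid_age"] / scale
    df["last_age_scaled"] = df["last_seen_age"] / scale
    df["last_age_scaled_sq"] = df["last_age_scaled"] ** 2
    df["censored"] = df["censored"].astype(int)
    return df.reset_index(drop=True)


def senescent_subset(table: pd.DataFrame, start_bin_mid: int = 24) -> pd.DataFrame:
    """Rows from the senescent phase: bin mid-age >= ``start_bin_mid`` (the
    post-peak stage of the best-fitting trajectory)."""
    mids = table["bin_mid_age"].unique()
    if start_bin_mid not in mids and len(mids):
        valid = (start_bin_mid - (FIRST_AGE + 1)) % BIN_WIDTH == 0
        if not valid:
            raise ValueError(f"{start_bin_mid} is not a valid bin mid-age")
    out = table[table["bin_mid_age"] >= start_bin_mid].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn(f"senescent subset is empty (no bins at mid-age >= {start_bin_mid})")
    return out
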