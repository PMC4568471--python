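"""Lifetime reproductive success and the birth-season contrast.

Two whole-life models per female: a Poisson GLMM of the total number of
calves (lifetime reproductive success) and a binomial GLMM of whether she
ever reproduced, both with the birth-season flag of interest and controls
for cohort (birth decade), observed lifespan (age at last sighting, linear
and quadratic, in years) and censoring.  With one row per female the
individual random intercept is an observation-level effect -- in the Poisson
model it absorbs overdispersion; it is kept by default to mirror the
bin-level models' structure and can be dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import SeasonLabel, label_birth_season
from .glmm import GlmmError, ModelSpec, fit_glmm, likelihood_ratio_test

__all__ = [
    "build_lifetime_table",
    "fit_lifetime_models",
    "season_contrast",
]

MAX_CALVES = 10  # sanity bound on a single female's lifetime output

_RHS = (
    "high_stress_born + last_seen_age + last_age_sq + censored + C(birth_decade)"
)


def build_lifetime_table(
    records: pd.DataFrame, season: SeasonLabel = SeasonLabel()
) -> pd.DataFrame:
    """One row per female: total calves, ever-reproduced flag and covariates.

    Ages here stay in years (unscaled), matching the magnitude convention of
    whole-life models rather than the bin-level ones.
    """
    if records["id"].duplicated().any():
        dupes = records.loc[records["id"].duplicated(), "id"].tolist()
        raise GlmmError(f"duplicate female ids: {dupes[:5]}")
    total = records["calving_ages"].map(len).astype(int)
    decade = (records["birth_year"].astype(int) // 10 * 10).astype(str) + "s"
    out = pd.DataFrame(
        {
            "id": records["id"].astype(str),
            "total_calves": total,
            "ever_reproduced": (total >= 1).astype(int),
            "high_stress_born": label_birth_season(
                records["birth_month"].to_numpy(), season
            ),
            "birth_decade": pd.Categorical(decade, categories=sorted(decade.unique())),
            "last_seen_age": records["last_seen_age"].astype(float),
            "censored": records["censored"].astype(int),
            "region": records["region"].astype(str),
        }
    )
    out["last_age_sq"] = out["last_seen_age"] ** 2
    return out


def fit_lifetime_models(
    table: pd.DataFrame,
    *,
    individual_effect: bool = True,
    binomial_individual_effect: bool = False,
) -> dict:
    """Poisson (calf count) and binomial (ever reproduced) lifetime models.

    ``individual_effect`` keeps the observation-level random intercept in the
    Poisson model, where it absorbs overdispersion.  In the binomial model a
    Bernoulli response carries no information about an observation-level
    variance (the approximate likelihood is maximised by spurious boundary
    solutions), so that term is excluded unless explicitly requested.

    Boundary variance estimates are flagged on the fits, never silently
    dropped; degenerate responses raise a structured error.
    """
    if table["total_calves"].sum() == 0:
        raise GlmmError("every female has zero calves; lifetime models are degenerate")
    if (table["total_calves"] > MAX_CALVES).any():
        raise GlmmError(f"calf count above the plausible maximum {MAX_CALVES}")
    pois_groups = ("id", "region") if individual_effect else ("region",)
    pois = fit_glmm(
        ModelSpec(f"total_calves ~ {_RHS}", pois_groups, "poisson"), table
    )
    ever = table["ever_reproduced"]
    if ever.nunique() < 2:
        raise GlmmError("ever-reproduced flag is constant; binomial model degenerate")
    binom_groups = ("id", "region") if binomial_individual_effect else ("region",)
    binom = fit_glmm(
        ModelSpec(f"ever_reproduced ~ {_RHS}", binom_groups, "binomial"), table
    )
    return {"poisson": pois, "binomial": binom}


def season_contrast(table: pd.DataFrame, fits: dict) -> dict:
    """Birth-season contrast three ways: raw percent difference in mean calves,
    the model-based rate ratio exp(beta_season), and season-term LRTs for both
    lifetime models.

    The raw contrast uses unadjusted group means (a negative value means
    high-stress-born females produced fewer calves); the model-based ratio
    conditions on lifespan, censoring and cohort, so the two need not agree.
    """
    high = table.loc[table["high_stress_born"] == 1, "total_calves"]
    other = table.loc[table["high_stress_born"] == 0, "total_calves"]
    if len(high) == 0 or len(other) == 0:
        raise GlmmError("a birth-season group is empty")
    raw_pct = 100.0 * (high.mean() - other.mean()) / other.mean()
    reduced_rhs = _RHS.replace("high_stress_born + ", "")
    lrts = {}
    for name, fit in fits.items():
        response = fit.spec.formula.split("~")[0].strip()
        red = fit_glmm(
            ModelSpec(f"{response} ~ {reduced_rhs}", fit.spec.groups, fit.spec.family),
            table,
        )
        lrts[name] = likelihood_ratio_test(fit, red).to_dict()
    return {
        "mean_calves_high_stress": float(high.mean()),
        "mean_calves_other": float(other.mean()),
        "raw_percent_difference": float(raw_pct),
        "rate_ratio": float(np.exp(fits["poisson"].coef("high_stress_born"))),
        "season_lrt": lrts,
    }
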