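"""Post-peak (senescent-phase) analyses of reproduction.

Once the trajectory selection has located the reproductive peak, the data are
restricted to bins from the peak age onwards and the central question is
asked directly: do females born in the high-stress season lose reproductive
performance faster with age?  The main model is a binomial GLMM of the
per-bin reproduction flag on birth season, age (centred at the peak so the
season main effect is the peak-height contrast), censoring controls and
birth decade, with individual and region random intercepts; the
season-by-age interaction is the ageing-rate contrast and is tested by a
likelihood-ratio test.  Companion analyses probe confounding (birth order,
maternal age), substitute the conception season for the birth season, and
summarise the fitted decline per 3-year bin on the probability scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import (
    FitResult,
    GlmmError,
    LRTResult,
    ModelSpec,
    fit_glmm,
    likelihood_ratio_test,
    marginal_predict,
)

__all__ = [
    "SenescenceFits",
    "fit_senescence_models",
    "subset_effect_models",
    "conception_sensitivity",
    "decline_rates",
    "peak_probability_test",
]

PEAK_BIN_MID = 24


@dataclass
class SenescenceFits:
    """Interaction and no-interaction fits on the senescent subset."""

    full: FitResult
    reduced: FitResult
    interaction_lrt: LRTResult
    season_col: str
    peak_age: float

    def to_dict(self) -> dict:
        return {
            "season_col": self.season_col,
            "peak_age": self.peak_age,
            "full": self.full.to_dict(),
            "reduced": self.reduced.to_dict(),
            "interaction_lrt": self.interaction_lrt.to_dict(),
        }


def _validate_senescent(table: pd.DataFrame, peak_age: float):
    if len(table) == 0:
        raise GlmmError("senescent table is empty")
    if (table["bin_mid_age"] < peak_age).any():
        raise GlmmError(
            f"table contains bins before the peak age {peak_age}; "
            "apply senescent_subset first"
        )


def fit_senescence_models(
    table: pd.DataFrame,
    *,
    season_col: str = "high_stress_born",
    peak_age: float = float(PEAK_BIN_MID),
    extra_terms: tuple = (),
    groups: tuple = ("id", "region"),
) -> SenescenceFits:
    """Fit the senescent-phase models and test the season-by-age interaction.

    Age enters in years centred at ``peak_age`` (coefficient magnitudes then
    match a per-year logit decline).  ``extra_terms`` append fixed effects to
    both models (used by the confounder subset analyses).
    """
    _validate_senescent(table, peak_age)
    vals = table[season_col].unique()
    if len(vals) < 2:
        raise GlmmError(
            f"{season_col} takes a single value in the senescent subset; "
            "the season contrast is inestimable"
        )
    work = table.assign(age_c=table["bin_mid_age"] - peak_age)
    base = [
        season_col,
        "age_c",
        "last_age_scaled",
        "last_age_scaled_sq",
        "censored",
        "C(birth_decade)",
        *extra_terms,
    ]
    full_rhs = " + ".join(base + [f"{season_col}:age_c"])
    red_rhs = " + ".join(base)
    full = fit_glmm(ModelSpec(f"reproduced ~ {full_rhs}", groups, "binomial"), work)
    reduced = fit_glmm(ModelSpec(f"reproduced ~ {red_rhs}", groups, "binomial"), work)
    lrt = likelihood_ratio_test(full, reduced)
    return SenescenceFits(full, reduced, lrt, season_col, peak_age)


def subset_effect_models(
    table: pd.DataFrame,
    mode: str,
    *,
    season_col: str = "high_stress_born",
    peak_age: float = float(PEAK_BIN_MID),
) -> dict:
    """Confounder analysis on the subset with the maternal covariate observed.

    ``mode`` is ``"birth_order"`` or ``"maternal_age"``.  Returns the
    covariate-adjusted senescence fits plus LRTs for (a) the covariate itself
    and (b) its interaction with birth season.
    """
    if mode not in ("birth_order", "maternal_age"):
        raise GlmmError(f"unknown subset mode {mode!r}")
    sub = table.dropna(subset=[mode]).reset_index(drop=True)
    if len(sub) == 0:
        raise GlmmError(f"covariate {mode!r} is missing for every senescent row")
    if sub[mode].nunique() < 2:
        raise GlmmError(f"covariate {mode!r} is constant in the subset")
    sub["birth_decade"] = _drop_unused(sub["birth_decade"])
    with_cov = fit_senescence_models(
        sub, season_col=season_col, peak_age=peak_age, extra_terms=(mode,)
    )
    without_cov = fit_senescence_models(sub, season_col=season_col, peak_age=peak_age)
    cov_lrt = likelihood_ratio_test(with_cov.full, without_cov.full)
    with_int = fit_senescence_models(
        sub,
        season_col=season_col,
        peak_age=peak_age,
        extra_terms=(mode, f"{mode}:{season_col}"),
    )
    cov_season_lrt = likelihood_ratio_test(with_int.full, with_cov.full)
    return {
        "mode": mode,
        "n_rows": len(sub),
        "n_females": sub["id"].nunique(),
        "fits": with_cov,
        "covariate_lrt": cov_lrt,
        "covariate_season_lrt": cov_season_lrt,
    }


def _drop_unused(s: pd.Series) -> pd.Series:
    return s.cat.remove_unused_categories() if hasattr(s, "cat") else s


def conception_sensitivity(
    table: pd.DataFrame, *, peak_age: float = float(PEAK_BIN_MID)
) -> SenescenceFits:
    """Repeat the interaction analysis with the conception-season flag (the
    season 22 months before birth) replacing the birth-season flag."""
    if "high_stress_conceived" not in table.columns:
        raise GlmmError("high_stress_conceived has not been computed")
    return fit_senescence_models(
        table, season_col="high_stress_conceived", peak_age=peak_age
    )


def decline_rates(
    fits: SenescenceFits,
    table: pd.DataFrame,
    *,
    from_age: float = float(PEAK_BIN_MID),
    to_age: float | None = None,
    step: float = 3.0,
    method: str = "observed",
    reference: dict | None = None,
) -> dict:
    """Average decline in predicted reproduction probability per 3-year bin,
    by birth-season group (random effects at zero).

    ``method="observed"`` (default) standardises over the data: at each age,
    predictions are averaged over the covariates of the females actually
    observed in that bin (with the season flag set to each group in turn), so
    the decline is a population-level (marginal) quantity comparable to raw
    bin means.  ``method="reference"`` instead predicts at a single covariate
    point (default: not censored, earliest birth decade, age at last sighting
    at its subset mean), giving the steeper within-individual decline implied
    by the conditional model.
    """
    if to_age is None:
        to_age = float(table["bin_mid_age"].max())
    if to_age <= from_age:
        raise GlmmError("degenerate age range for decline computation")
    ages = np.arange(from_age, to_age + 1e-9, step)
    out: dict = {"ages": ages.tolist(), "method": method}
    if method == "reference":
        ref = {
            "censored": 0,
            "birth_decade": _first_decade(fits.full),
            "last_age_scaled": float(table["last_age_scaled"].mean()),
        }
        if reference:
            ref.update(reference)
        ref["last_age_scaled_sq"] = ref["last_age_scaled"] ** 2
        out["reference"] = dict(ref)
        for gname, gval in (("other", 0), ("high_stress", 1)):
            rows = pd.DataFrame(
                {
                    fits.season_col: gval,
                    "age_c": ages - fits.peak_age,
                    **{k: [v] * len(ages) for k, v in ref.items()},
                }
            )
            p = marginal_predict(fits.full, rows)
            out[gname] = {
                "predicted": [float(x) for x in p],
                "decline_per_bin": float((p[0] - p[-1]) / (len(ages) - 1)),
            }
    elif method == "observed":
        for gname, gval in (("other", 0), ("high_stress", 1)):
            preds = []
            for a in ages:
                rows = table[table["bin_mid_age"] == a]
                if len(rows) == 0:
                    preds.append(np.nan)
                    continue
                rows = rows.assign(**{fits.season_col: gval, "age_c": a - fits.peak_age})
                preds.append(float(np.mean(marginal_predict(fits.full, rows))))
            p = np.asarray(preds)
            valid = ~np.isnan(p)
            first, last = np.flatnonzero(valid)[[0, -1]]
            out[gname] = {
                "predicted": [float(x) for x in p],
                "decline_per_bin": float((p[first] - p[last]) / max(last - first, 1)),
            }
    else:
        raise GlmmError(f"unknown decline method {method!r}")
    return out


def _first_decade(fit: FitResult) -> str:
    """Reference (first) birth-decade level recorded in the fitted design."""
    for factor, fi in fit.design_info.factor_infos.items():
        if "birth_decade" in factor.name() and fi.categories is not None:
            return str(list(fi.categories)[0])
    raise GlmmError("fit has no birth-decade term")


def peak_probability_test(
    table: pd.DataFrame,
    peak_bin_mid: int = PEAK_BIN_MID,
    *,
    season_col: str = "high_stress_born",
) -> dict:
    """Welch two-sample t-test of the binary reproduction outcome in the peak
    bin, other-born minus high-stress-born (so a negative t means the
    high-stress group peaked higher)."""
    peak = table[table["bin_mid_age"] == peak_bin_mid]
    other = peak.loc[peak[season_col] == 0, "reproduced"].to_numpy(dtype=float)
    high = peak.loc[peak[season_col] == 1, "reproduced"].to_numpy(dtype=float)
    if len(other) < 2 or len(high) < 2:
        raise GlmmError("each birth-season group needs >= 2 peak-bin observations")

    def mean_se(x):
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))

    m_o, se_o = mean_se(other)
    m_h, se_h = mean_se(high)
    if se_o == 0.0 and se_h == 0.0:
        t, p = (0.0, 1.0) if m_o == m_h else (np.inf * np.sign(m_o - m_h), 0.0)
    else:
        t, p = stats.ttest_ind(other, high, equal_var=False)
    return {
        "t": float(t),
        "p_value": float(p),
        "mean_other": m_o,
        "se_other": se_o,
        "n_other": int(len(other)),
        "mean_high_stress": m_h,
        "se_high_stress": se_h,
        "n_high_stress": int(len(high)),
    }
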