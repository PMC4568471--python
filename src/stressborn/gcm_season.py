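"""Monthly glucocorticoid variation and the high-stress season definition.

Faecal glucocorticoid metabolite (GCM) concentrations from repeatedly sampled
females are modelled with a Gaussian mixed model (female identity as a random
intercept, month as a 12-level factor).  The "high stress" season is the
maximal run of consecutive calendar months -- circular across the December /
January boundary -- whose concentration is significantly higher than the
January baseline.  A binary season coding is then compared against the full
month factor by AIC and a likelihood-ratio test, the decision rule that
justifies carrying a single season flag into the reproduction models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import (
    FitResult,
    GlmmError,
    ModelSpec,
    fit_glmm,
    likelihood_ratio_test,
    wald_test,
)

__all__ = [
    "SeasonDefinition",
    "fit_month_model",
    "month_effects",
    "elevated_months",
    "high_stress_season",
    "season_vs_month",
    "seasonal_elevation",
]

_MONTH_TERM = re.compile(r"C\(month, Treatment\(\d+\)\)\[T\.(\d+)\]")


@dataclass(frozen=True)
class SeasonDefinition:
    """A derived high-stress season.

    ``months`` is an ordered tuple forming one consecutive run on the circular
    calendar (possibly empty).  ``per_month`` records the estimates the
    derivation used: month -> {mean, contrast, p_value}.
    """

    months: tuple
    baseline_month: int = 1
    alpha: float = 0.05
    per_month: dict = field(default_factory=dict)

    def __post_init__(self):
        if not _is_circular_run(self.months):
            raise ValueError(
                f"season months must be circularly consecutive, got {self.months}"
            )

    @property
    def month_set(self) -> frozenset:
        return frozenset(self.months)

    def to_dict(self) -> dict:
        return {
            "months": list(self.months),
            "baseline_month": self.baseline_month,
            "alpha": self.alpha,
            "per_month": {
                str(m): {k: float(v) for k, v in d.items()}
                for m, d in self.per_month.items()
            },
        }


def _is_circular_run(months) -> bool:
    months = list(months)
    if len(months) <= 1:
        return True
    s = set(months)
    if len(s) != len(months) or not s <= set(range(1, 13)):
        return False
    if len(s) == 12:
        return True
    # a run iff exactly one month in the set has its predecessor outside it
    starts = sum(1 for m in s if (m - 2) % 12 + 1 not in s)
    return starts == 1


def fit_month_model(samples: pd.DataFrame, baseline: int = 1) -> FitResult:
    """Gaussian mixed model of concentration on calendar month (ML fit).

    Month enters as a factor with ``baseline`` as the reference level; female
    identity is a random intercept.  The month-factor Wald test (chi-square
    and F form) is available through :func:`month_effects`.
    """
    months_present = set(samples["month"].unique())
    if len(months_present) < 2:
        raise GlmmError("need at least two calendar months to model month effects")
    if samples["female_id"].nunique() < 2:
        raise GlmmError("need at least two females for a random-intercept model")
    if baseline not in months_present:
        raise GlmmError(f"baseline month {baseline} has no samples")
    spec = ModelSpec(
        f"concentration_ng_g ~ C(month, Treatment({baseline}))",
        ("female_id",),
        "gaussian",
    )
    return fit_glmm(spec, samples)


def month_effects(fit: FitResult, baseline: int = 1) -> pd.DataFrame:
    """Per-month fitted means and contrasts vs the baseline month."""
    rows = [
        {
            "month": baseline,
            "mean": fit.coef("Intercept"),
            "contrast": 0.0,
            "p_value": np.nan,
        }
    ]
    for name, b, p in zip(fit.param_names, fit.params, fit.p_values):
        m = _MONTH_TERM.match(name)
        if m:
            rows.append(
                {
                    "month": int(m.group(1)),
                    "mean": fit.coef("Intercept") + b,
                    "contrast": b,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows).sort_values("month").reset_index(drop=True)


def month_factor_test(fit: FitResult) -> dict:
    """Joint Wald test of all month contrasts (the month-factor F test)."""
    terms = [n for n in fit.param_names if _MONTH_TERM.match(n)]
    return wald_test(fit, terms)


def elevated_months(fit: FitResult, baseline: int = 1, alpha: float = 0.05) -> set:
    """Months significantly *above* the baseline month (two-sided Wald p <
    alpha with a positive contrast)."""
    eff = month_effects(fit, baseline)
    sel = eff[(eff["month"] != baseline) & (eff["contrast"] > 0) & (eff["p_value"] < alpha)]
    return set(int(m) for m in sel["month"])


def high_stress_season(
    month_set,
    month_means: dict | None = None,
    *,
    baseline: int = 1,
    alpha: float = 0.05,
    per_month: dict | None = None,
) -> SeasonDefinition:
    """Maximal consecutive run (circular over Dec-Jan) within the elevated
    months; ties are broken by higher mean concentration over the run."""
    s = set(month_set)
    if not s:
        return SeasonDefinition((), baseline, alpha, per_month or {})
    if len(s) == 12:
        months = tuple(range(1, 13))
        return SeasonDefinition(months, baseline, alpha, per_month or {})
    runs = []
    for start in sorted(s):
        prev = (start - 2) % 12 + 1
        if prev in s:
            continue
        run = [start]
        while True:
            nxt = run[-1] % 12 + 1
            if nxt in s:
                run.append(nxt)
            else:
                break
        runs.append(tuple(run))
    best_len = max(len(r) for r in runs)
    longest = [r for r in runs if len(r) == best_len]
    if len(longest) > 1 and month_means:
        longest.sort(key=lambda r: -np.mean([month_means[m] for m in r]))
    return SeasonDefinition(longest[0], baseline, alpha, per_month or {})


def derive_season(
    samples: pd.DataFrame, baseline: int = 1, alpha: float = 0.05
) -> SeasonDefinition:
    """Full derivation: fit the month model, find elevated months, take the
    maximal consecutive run."""
    fit = fit_month_model(samples, baseline)
    eff = month_effects(fit, baseline)
    means = dict(zip(eff["month"], eff["mean"]))
    per_month = {
        int(r.month): {"mean": r.mean, "contrast": r.contrast,
                       "p_value": 0.0 if np.isnan(r.p_value) else r.p_value}
        for r in eff.itertuples()
    }
    return high_stress_season(
        elevated_months(fit, baseline, alpha),
        means,
        baseline=baseline,
        alpha=alpha,
        per_month=per_month,
    )


def season_vs_month(samples: pd.DataFrame, season: SeasonDefinition) -> dict:
    """Compare the binary season coding against the 12-level month factor.

    The season model is a coarsening of the month model (the flag is constant
    within each month), so the two are nested; the LRT takes the month model
    as the full model with the parameter-count difference as df.  The AIC
    comparison is the decision rule used downstream.
    """
    months_present = sorted(samples["month"].unique())
    in_season = [m for m in months_present if m in season.month_set]
    if not in_season or len(in_season) == len(months_present):
        raise GlmmError(
            "season flag is constant over the sampled months; "
            "the season and month codings are not comparable"
        )
    df = samples.copy()
    df["high_stress"] = df["month"].isin(season.month_set).astype(int)
    month_fit = fit_month_model(df, baseline=season.baseline_month)
    season_fit = fit_glmm(
        ModelSpec("concentration_ng_g ~ high_stress", ("female_id",), "gaussian"), df
    )
    lrt = likelihood_ratio_test(month_fit, season_fit, validate_names=False)
    return {
        "loglik_month": float(month_fit.loglik),
        "loglik_season": float(season_fit.loglik),
        "aic_month": float(month_fit.aic),
        "aic_season": float(season_fit.aic),
        "preferred_by_aic": "season" if season_fit.aic <= month_fit.aic else "month",
        "lrt": lrt.to_dict(),
        "season_fit": season_fit,
        "month_fit": month_fit,
    }


def seasonal_elevation(samples: pd.DataFrame, season: SeasonDefinition) -> dict:
    """Percent elevation of the season over the rest of the year, computed two
    ways: as unweighted averages of per-month means, and on pooled samples."""
    by_month = samples.groupby("month")["concentration_ng_g"].mean()
    in_s = by_month.index.isin(list(season.month_set))
    if not in_s.any() or in_s.all():
        raise GlmmError("season must cover some but not all sampled months")
    month_based = 100.0 * (by_month[in_s].mean() - by_month[~in_s].mean()) / by_month[~in_s].mean()
    pooled = samples["month"].isin(list(season.month_set))
    pooled_based = 100.0 * (
        samples.loc[pooled, "concentration_ng_g"].mean()
        - samples.loc[~pooled, "concentration_ng_g"].mean()
    ) / samples.loc[~pooled, "concentration_ng_g"].mean()
    return {
        "percent_elevation_month_means": float(month_based),
        "percent_elevation_pooled": float(pooled_based),
    }
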