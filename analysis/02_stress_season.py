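"""Derive the high-stress season from the hormone samples.

Fits the Gaussian mixed model of glucocorticoid metabolite concentration on
calendar month (female identity as a random intercept), finds the months
significantly above the January baseline, takes the maximal consecutive run,
and compares the binary season coding against the 12-level month factor.
Writes ``results/season.json``.
"""

from stressborn import io
from stressborn.gcm_season import (
    derive_season,
    fit_month_model,
    month_factor_test,
    season_vs_month,
    seasonal_elevation,
)

gcm = io.read_csv("results/data/gcm.csv")
season = derive_season(gcm)
fit = fit_month_model(gcm)
ftest = month_factor_test(fit)
cmp = season_vs_month(gcm, season)
elev = seasonal_elevation(gcm, season)

report = season.to_dict()
report["month_factor_test"] = ftest
report["season_vs_month"] = {k: v for k, v in cmp.items()
                             if k not in ("season_fit", "month_fit")}
report["elevation"] = elev
io.write_json(report, "results/season.json")

print(f"high-stress season: months {list(season.months)}")
print(f"month factor F = {ftest['F']:.2f} (df {ftest['df']}), p = {ftest['p_value']:.2g}")
print(
    f"season elevation: {elev['percent_elevation_month_means']:.1f}% above the "
    "rest of the year (month-mean basis)"
)
print(
    f"season vs month coding: AIC {cmp['aic_season']:.1f} vs {cmp['aic_month']:.1f} "
    f"-> {cmp['preferred_by_aic']} preferred; LRT chi2 = {cmp['lrt']['chi_square']:.2f} "
    f"(df {cmp['lrt']['df']})"
)
print("wrote results/season.json")
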