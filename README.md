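# stressborn

Does being born in a physiologically stressful season accelerate
reproductive ageing? This package implements, end to end, the analysis
pipeline for that question in a long-lived mammal: semi-captive female Asian
elephants whose faecal glucocorticoid metabolites (GCM) peak during the
June–August monsoon-onset work season. It is written for quantitative
ecologists and biostatisticians who want the full chain — hormone-defined
season, broken-stick age-trajectory selection, senescence-phase interaction
tests and lifetime-fitness models — as tested, reusable code, exercised on a
synthetic population with known ground truth.

## The analysis

1. **Season definition.** Monthly GCM concentrations are modelled as
   `conc ~ month(factor) + (1 | female)` (Gaussian, exact ML). The
   *high-stress season* is the maximal run of consecutive months
   significantly above the January baseline; a binary season coding is
   checked against the month factor by AIC and LRT.
2. **Age trajectory.** Reproduction is scored 0/1 per female per 3-year age
   window from age 5, and modelled with binomial GLMMs
   `reproduced ~ season + decade + censoring + age-terms + (1|id) + (1|region)`.
   The age effect is selected by AIC among null, polynomial, and continuous
   linear-spline (broken-stick) candidates with one or two breakpoints on a
   grid — under the default generator the winner is `thr(15,24)`: flat to
   ~15, rise to a peak at 24, decline afterwards.
3. **Senescence.** After the peak, the season-by-age interaction
   (the difference in ageing *rate* between birth-season groups) is tested by
   LRT, with maternal-covariate subsets, a conception-season sensitivity
   analysis, per-group percent declines per 3-year bin, and a Welch t-test
   at the peak bin.
4. **Lifetime fitness.** Poisson (total calves) and binomial
   (ever reproduced) GLMMs per female, with the raw percent season contrast
   and the model-based rate ratio reported separately.

All mixed models run through the package's own engine: Laplace-approximate
ML with up to two crossed random intercepts, an exact analytic gradient, and
a brute-force numerical-integration oracle used by the tests
(`docs/methods.md` has the details and the design decisions).

## Worked example

```bash
python analysis/01_simulate_data.py     # 1,078-female cohort + hormone year
python analysis/02_stress_season.py     # derive the high-stress season
python analysis/03_build_cohort.py      # 3-year observation bins
python analysis/04_age_trajectory.py    # AIC selection of the age shape
python analysis/05_senescence.py        # interaction + declines + subsets
python analysis/06_lifetime.py          # lifetime reproductive success
```

Abridged output from a run with the default seed (0):

```
high-stress season: months [6, 7, 8]
month factor F = 40.80 (df 11), p = 2.5e-89
season elevation: 51.1% above the rest of the year (month-mean basis)
season vs month coding: AIC 2716.4 vs 2707.3 -> month preferred; LRT chi2 = 29.09 (df 10)
...
best model: thr(15,24)
three-stage trajectory: flat to ~15, rise to a peak at 24, decline afterwards
...
senescent subset: 2593 rows from 481 females (age 24+)
birth-season x age interaction: chi2(df=1) = 6.20, p = 0.0127
decline in P(reproduce) per 3-year bin: 2.54% (high-stress-born) vs 0.61% (other-born)
peak-bin reproduction: 0.41 +- 0.045 (high-stress) vs 0.32 +- 0.025 (other); t = -1.81, p = 0.072
birth_order subset (n=229 females): covariate LRT p = 0.857; interaction still p = 0.0074
conception-season x age interaction: chi2 = 0.319, p = 0.572 (effect attaches to birth, not conception)
...
calibrated deficit generator (truth -15.9%): mean raw contrast -15.7% over 10 replicates; mean Poisson LRT chi2 7.4
```

Reading it: the hormone model recovers June–August as the elevated season;
the trajectory search finds the true three-stage shape with senescence
starting at 24; high-stress-born females start from a slightly higher peak
but lose reproduction ~4× faster per 3-year bin (truth: 2.2% vs 0.73%); the
effect attaches to the *birth* season, not the conception season 22 months
earlier; and a 15.9% lifetime calf deficit is recovered by the lifetime
models. Every statistic is recomputed from freshly simulated data, so exact
values move with the seed — this particular hormone year even preferred the
month coding by AIC (a ~1-in-40 draw; the season-by-age LRT itself detects
the ageing-rate difference in roughly a third of replicate cohorts at these
study conditions, see `docs/methods.md`).

The same stages are available as a CLI (`stressborn run-all --seed 0`,
plus `simulate`, `stress-season`, `build-cohort`, `fit-trajectory`,
`senescence`, `lifetime` operating on the documented CSV/JSON files).

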