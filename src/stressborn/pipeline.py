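"""End-to-end pipeline: hormones -> season -> cohort -> trajectory ->
senescence -> lifetime.

Each stage reads and writes the documented CSV/JSON contracts so stages can
run (and be tested) independently; ``run_pipeline`` chains them.  Every
output file carries the configuration hash and master seed, and a run under
a fixed seed is byte-identical across repeats (no timestamps in outputs;
timing goes to the log).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io
from .cohort import (
    SeasonLabel,
    attach_covariates,
    build_observation_bins,
    senescent_subset,
)
from .gcm_season import derive_season, season_vs_month, seasonal_elevation
from .glmm import GlmmError
from .lifetime import build_lifetime_table, fit_lifetime_models, season_contrast
from .senescence import (
    conception_sensitivity,
    decline_rates,
    fit_senescence_models,
    peak_probability_test,
    subset_effect_models,
)
from .synthetic import GCMSimConfig, SimConfig, simulate_gcm, simulate_population
from .trajectory import ThresholdGrid, select_trajectory

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML."""

    outdir: str = "results/pipeline"
    seed: int = 0
    simulate: bool = True
    individuals_path: str | None = None
    gcm_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    gcm: GCMSimConfig = field(default_factory=GCMSimConfig)
    alpha: float = 0.05
    baseline_month: int = 1
    gestation_months: int = 22
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    peak_age: int | None = None     # None: take the best model's second threshold
    make_plots: bool = False

    def __post_init__(self):
        # master seed drives the generator sub-seeds unless set explicitly
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed))
        self.gcm = dataclasses.replace(self.gcm, seed=int(self.seed) + 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["season_months"] = sorted(self.sim.season_months)
        d["gcm"]["elevated_months"] = sorted(self.gcm.elevated_months)
        return d

    def science_dict(self) -> dict:
        """Configuration relevant to results (the hashable part): everything
        except where outputs go and whether figures are drawn."""
        d = self.to_dict()
        for k in ("outdir", "make_plots"):
            d.pop(k, None)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (("sim", SimConfig), ("gcm", GCMSimConfig), ("grid", ThresholdGrid)):
            if key in raw and isinstance(raw[key], dict):
                block = dict(raw[key])
                for f in ("season_months", "elevated_months"):
                    if f in block:
                        block[f] = frozenset(block[f])
                for f in ("birth_year_range", "thresholds", "peak_prob",
                          "post_peak_decline", "age_range", "single_range",
                          "double_first", "double_second"):
                    if f in block:
                        block[f] = tuple(block[f])
                if "stage_slopes" in block:
                    block["stage_slopes"] = tuple(tuple(s) for s in block["stage_slopes"])
                raw[key] = klass(**block)
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict written to ``run.json``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.science_dict())
    meta = {"config_hash": chash, "seed": config.seed}
    t_start = time.perf_counter()

    def _stage(name):
        log.info("stage %s (t=%.1fs)", name, time.perf_counter() - t_start)

    # -- data -------------------------------------------------------------
    _stage("data")
    if config.simulate:
        individuals = simulate_population(config.sim)
        gcm = simulate_gcm(config.gcm)
        io.write_individuals(individuals, out / "individuals.csv", meta)
        io.write_csv(gcm, out / "gcm.csv", meta)
    else:
        for name, p in (("individuals", config.individuals_path), ("gcm", config.gcm_path)):
            if not p or not Path(p).exists():
                raise FileNotFoundError(
                    f"simulation disabled and {name} input missing: {p!r}"
                )
        individuals = io.read_individuals(config.individuals_path)
        gcm = io.read_csv(config.gcm_path)

    # -- hormone season ----------------------------------------------------
    _stage("stress-season")
    season_def = derive_season(gcm, config.baseline_month, config.alpha)
    season_report = season_def.to_dict()
    if 0 < len(season_def.months) < gcm["month"].nunique():
        cmp = season_vs_month(gcm, season_def)
        season_report["season_vs_month"] = {
            k: v for k, v in cmp.items() if k not in ("season_fit", "month_fit")
        }
        season_report["elevation"] = seasonal_elevation(gcm, season_def)
    io.write_json(season_report, out / "season.json", meta)
    season = SeasonLabel(season_def.month_set or frozenset(), config.gestation_months)

    # -- cohort ------------------------------------------------------------
    _stage("build-cohort")
    bins = build_observation_bins(individuals)
    table = attach_covariates(bins, individuals, season)
    io.write_csv(table, out / "bins.csv", meta)

    # -- trajectory --------------------------------------------------------
    _stage("fit-trajectory")
    selection = select_trajectory(table, config.grid)
    io.write_csv(selection.table, out / "selection.csv", meta)
    best = selection.best
    if config.peak_age is not None:
        peak_age = int(config.peak_age)
    elif len(best.spec.thresholds) == 2:
        peak_age = int(best.spec.thresholds[1])
    elif len(best.spec.thresholds) == 1:
        peak_age = int(best.spec.thresholds[0])
    else:
        raise GlmmError(
            f"best trajectory {best.spec.label!r} has no threshold; "
            "set peak_age explicitly to run the senescence stage"
        )

    # -- senescence --------------------------------------------------------
    _stage("senescence")
    sen = senescent_subset(table, peak_age)
    fits = fit_senescence_models(sen, peak_age=float(peak_age))
    report = {
        "peak_age": peak_age,
        "best_trajectory": best.spec.label,
        "main": fits.to_dict(),
        "declines": decline_rates(fits, sen),
        "peak_test": peak_probability_test(sen, peak_age),
    }
    try:
        report["conception"] = conception_sensitivity(sen, peak_age=float(peak_age)).to_dict()
    except GlmmError as e:
        report["conception"] = {"error": str(e)}
    for mode in ("birth_order", "maternal_age"):
        try:
            r = subset_effect_models(sen, mode)
            report[mode] = {
                "n_rows": r["n_rows"],
                "n_females": r["n_females"],
                "fits": r["fits"].to_dict(),
                "covariate_lrt": r["covariate_lrt"].to_dict(),
                "covariate_season_lrt": r["covariate_season_lrt"].to_dict(),
            }
        except GlmmError as e:
            report[mode] = {"error": str(e)}
    io.write_json(report, out / "senescence_report.json", meta)

    # -- lifetime ----------------------------------------------------------
    _stage("lifetime")
    lt = build_lifetime_table(individuals, season)
    lt_fits = fit_lifetime_models(lt)
    lt_report = {
        "poisson": lt_fits["poisson"].to_dict(),
        "binomial": lt_fits["binomial"].to_dict(),
        "contrast": season_contrast(lt, lt_fits),
    }
    io.write_json(lt_report, out / "lifetime_report.json", meta)

    if config.make_plots:
        from .plots import plot_monthly_gcm, plot_reproduction_by_age

        plot_monthly_gcm(gcm, season_def, out / "fig_monthly_gcm.png")
        plot_reproduction_by_age(table, fits, out / "fig_reproduction_by_age.png")

    summary = {
        "config_hash": chash,
        "seed": config.seed,
        "n_females": int(individuals["id"].nunique()),
        "n_bin_rows": int(len(table)),
        "season_months": list(season_def.months),
        "best_trajectory": best.spec.label,
        "peak_age": peak_age,
        "interaction_chi2": fits.interaction_lrt.chi_square,
        "interaction_p": fits.interaction_lrt.p_value,
        "decline_other_pct": 100.0 * report["declines"]["other"]["decline_per_bin"],
        "decline_high_stress_pct": 100.0 * report["declines"]["high_stress"]["decline_per_bin"],
        "lifetime_raw_percent_difference": lt_report["contrast"]["raw_percent_difference"],
        "lifetime_season_chi2": lt_report["contrast"]["season_lrt"]["poisson"]["chi_square"],
    }
    io.write_json(summary, out / "run.json", meta)
    _stage("done")
    return summary
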