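"""Life-history and hormone generators: ground truth, determinism, constraints."""

import numpy as np
import pandas as pd
import pytest

from stressborn.synthetic import (
    GCMSimConfig,
    SimConfig,
    simulate_gcm,
    simulate_lifetime_counts,
    simulate_population,
    true_reproduction_probability,
)


class TestTrueTrajectory:
    def test_peak_anchor(self):
        cfg = SimConfig()
        for g, peak in ((0, 0.34), (1, 0.46)):
            assert true_reproduction_probability(cfg, 24, g) == pytest.approx(peak)

    def test_post_peak_decline_is_exact_probability_drop(self):
        cfg = SimConfig(post_peak_decline=(0.0073, 0.022))
        for g, d in ((0, 0.0073), (1, 0.022)):
            drop = true_reproduction_probability(cfg, 27, g) - true_reproduction_probability(cfg, 24, g)
            assert drop == pytest.approx(-d, abs=1e-12)

    def test_continuity_at_thresholds(self):
        cfg = SimConfig()
        for t in cfg.thresholds:
            below = true_reproduction_probability(cfg, t - 1e-9, 1)
            above = true_reproduction_probability(cfg, t + 1e-9, 1)
            assert abs(below - above) < 1e-6

    def test_monotone_rise_then_decline(self):
        cfg = SimConfig()
        ages = np.arange(15.0, 24.1, 0.5)
        p = true_reproduction_probability(cfg, ages, np.zeros(len(ages), dtype=int))
        assert np.all(np.diff(p) >= 0)
        ages2 = np.arange(24.0, 54.1, 3.0)
        p2 = true_reproduction_probability(cfg, ages2, np.zeros(len(ages2), dtype=int))
        assert np.all(np.diff(p2) <= 0)

    def test_age_below_five_raises(self):
        with pytest.raises(ValueError, match="age"):
            true_reproduction_probability(SimConfig(), 4.5, 0)


class TestSimulatePopulation:
    def test_zero_females_gives_empty_table_with_schema(self):
        out = simulate_population(SimConfig(n_females=0))
        assert len(out) == 0
        assert list(out.columns) == [
            "id", "birth_year", "birth_month", "region", "mother_id",
            "birth_order", "maternal_age", "last_seen_age", "censored",
            "calving_ages",
        ]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_females=-1)
        with pytest.raises(ValueError):
            SimConfig(thresholds=(24, 15))

    def test_fixed_seed_reproduces_byte_identical_output(self):
        a = simulate_population(SimConfig(n_females=200, seed=7))
        b = simulate_population(SimConfig(n_females=200, seed=7))
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_calving_constraints(self, small_pop):
        cfg = SimConfig()
        for rec in small_pop.itertuples(index=False):
            ages = rec.calving_ages
            assert all(a >= 5.0 for a in ages)
            assert all(a <= rec.last_seen_age for a in ages)
            gaps = np.diff(ages)
            # placement dates are rounded to 1e-4 years
            assert np.all(gaps >= cfg.min_gap_years - 1e-3)

    def test_identical_group_configs_have_equal_post_peak_rates(self):
        """With the two birth-season groups configured identically, empirical
        post-peak reproduction rates must agree within Monte-Carlo error."""
        cfg = SimConfig(
            n_females=5000, seed=1,
            peak_prob=(0.34, 0.34), post_peak_decline=(0.0073, 0.0073),
            stage_slopes=((0.02, 0.198), (0.02, 0.198)),
        )
        pop = simulate_population(cfg)
        from stressborn.cohort import attach_covariates, build_observation_bins

        tab = attach_covariates(build_observation_bins(pop), pop)
        post = tab[tab.bin_mid_age >= 24]
        g = post.groupby("high_stress_born")["reproduced"]
        p0, p1 = g.mean()
        n0, n1 = g.size()
        se = np.sqrt(p0 * (1 - p0) / n0 + p1 * (1 - p1) / n1)
        assert abs(p1 - p0) < 2.0 * se + 1e-9

    def test_empirical_frequencies_converge_to_truth(self):
        """Sup-norm over age bins between empirical reproduction frequency and
        the configured trajectory, at large n."""
        cfg = SimConfig(n_females=50_000, seed=3)
        pop = simulate_population(cfg)
        from stressborn.cohort import attach_covariates, build_observation_bins

        tab = attach_covariates(build_observation_bins(pop), pop)
        # bins with enough occupancy for the comparison to be meaningful
        for gval in (0, 1):
            sub = tab[tab.high_stress_born == gval]
            g = sub.groupby("bin_mid_age")["reproduced"].agg(["mean", "size"])
            g = g[g["size"] >= 1500]
            mids = g.index.to_numpy(dtype=float)
            truth = true_reproduction_probability(cfg, mids, np.full(len(mids), gval))
            assert np.max(np.abs(g["mean"].to_numpy() - truth)) < 0.02

    def test_attrition_scale_matches_study_population(self, small_pop):
        cfg = SimConfig(seed=123)
        pop = simulate_population(cfg)
        n24 = (pop.last_seen_age >= 24).sum()
        assert 350 <= n24 <= 560  # ~455 of 1,078 reach the senescent phase


class TestSimulateGCM:
    def test_row_count_and_missingness(self):
        full = simulate_gcm(GCMSimConfig(seed=0))
        assert len(full) == 37 * 12
        reduced = simulate_gcm(GCMSimConfig(seed=0, missing_frac=0.203))
        assert 300 < len(reduced) < 400  # toward the 354-sample scheme

    def test_noise_free_values_exact(self):
        cfg = GCMSimConfig(sd_within=0.0, sd_between_female=0.0, seed=5)
        gcm = simulate_gcm(cfg)
        june = gcm.loc[gcm.month == 6, "concentration_ng_g"]
        assert (june == 68.1).all()
        jan = gcm.loc[gcm.month == 1, "concentration_ng_g"]
        assert (jan == 45.6).all()

    def test_null_config_all_months_baseline(self):
        cfg = GCMSimConfig(elevated_months=frozenset(), sd_within=0.0,
                           sd_between_female=0.0, seed=2)
        gcm = simulate_gcm(cfg)
        assert (gcm.concentration_ng_g == 45.6).all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GCMSimConfig(sd_within=-1.0)

    def test_grand_mean_near_mixture_mean(self):
        cfg = GCMSimConfig(seed=9)
        gcm = simulate_gcm(cfg)
        mix = (9 * cfg.baseline_mean + 3 * cfg.elevated_mean) / 12
        se = gcm.concentration_ng_g.std() / np.sqrt(len(gcm))
        # month-mean spread inflates the sample SD, so 3 SEs is conservative
        assert abs(gcm.concentration_ng_g.mean() - mix) < 3 * se + 1.0

    def test_determinism(self):
        a = simulate_gcm(GCMSimConfig(seed=4))
        b = simulate_gcm(GCMSimConfig(seed=4))
        pd.testing.assert_frame_equal(a, b)


class TestLifetimeCounts:
    def test_rate_ratio_recovered_in_expectation(self):
        dfs = [simulate_lifetime_counts(4000, seed=s) for s in range(5)]
        ratios = [
            df.loc[df.high_stress_born == 1, "total_calves"].mean()
            / df.loc[df.high_stress_born == 0, "total_calves"].mean()
            for df in dfs
        ]
        assert abs(np.mean(ratios) - 0.841) < 0.04

    def test_zero_effect_config(self):
        df = simulate_lifetime_counts(4000, season_rate_ratio=1.0, seed=1)
        m1 = df.loc[df.high_stress_born == 1, "total_calves"].mean()
        m0 = df.loc[df.high_stress_born == 0, "total_calves"].mean()
        assert abs(m1 - m0) < 0.12
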