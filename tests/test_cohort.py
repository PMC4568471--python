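"""Observation-bin construction, season labels and covariate attachment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from stressborn import io
from stressborn.cohort import (
    SeasonLabel,
    attach_covariates,
    build_observation_bins,
    conception_date,
    label_birth_season,
    senescent_subset,
)


def _record(id="F1", birth_year=1960, birth_month=7, region="R01",
            birth_order=np.nan, maternal_age=np.nan, last_seen_age=20.0,
            censored=0, calving_ages=()):
    return {
        "id": id, "birth_year": birth_year, "birth_month": birth_month,
        "region": region, "mother_id": "", "birth_order": birth_order,
        "maternal_age": maternal_age, "last_seen_age": last_seen_age,
        "censored": censored, "calving_ages": list(calving_ages),
    }


class TestSeasonLabel:
    def test_july_is_high_stress(self):
        assert label_birth_season(7, SeasonLabel()) == 1

    def test_may_is_not(self):
        assert label_birth_season(5, SeasonLabel()) == 0

    def test_empty_season_labels_nothing(self):
        season = SeasonLabel(frozenset())
        assert all(label_birth_season(m, season) == 0 for m in range(1, 13))

    def test_invalid_month_rejected(self):
        with pytest.raises(ValueError):
            label_birth_season(13, SeasonLabel())
        with pytest.raises(ValueError):
            SeasonLabel(frozenset({0, 6}))


class TestConceptionDate:
    @pytest.mark.parametrize(
        "birth, expected",
        [((1990, 4), (1988, 6)), ((1990, 3), (1988, 5)), ((1990, 12), (1989, 2))],
    )
    def test_calendar_arithmetic(self, birth, expected):
        assert conception_date(*birth) == expected

    def test_composition_with_season_label(self):
        year, month = conception_date(1990, 4)
        assert label_birth_season(month, SeasonLabel()) == 1

    @given(st.integers(1900, 2020), st.integers(1, 12), st.integers(1, 48))
    def test_roundtrip_inverse(self, year, month, gestation):
        cy, cm = conception_date(year, month, gestation)
        total = cy * 12 + (cm - 1) + gestation
        assert (total // 12, total % 12 + 1) == (year, month)


class TestBuildObservationBins:
    def test_example_six_bins_with_two_reproductions(self):
        recs = pd.DataFrame([_record(last_seen_age=20, calving_ages=[9, 19])])
        bins = build_observation_bins(recs)
        assert len(bins) == 6
        flags = dict(zip(bins.bin_mid_age, bins.reproduced))
        assert flags == {6: 0, 9: 1, 12: 0, 15: 0, 18: 1, 21: 0}

    def test_two_calvings_in_one_bin_score_one(self):
        recs = pd.DataFrame([_record(last_seen_age=12, calving_ages=[9, 10])])
        bins = build_observation_bins(recs)
        assert bins.loc[bins.bin_mid_age == 9, "reproduced"].item() == 1
        assert bins.reproduced.sum() == 1

    def test_last_seen_at_five_gives_single_bin(self):
        recs = pd.DataFrame([_record(last_seen_age=5.0)])
        bins = build_observation_bins(recs)
        assert len(bins) == 1
        assert bins.bin_start_age.item() == 5

    def test_calving_after_last_sighting_rejected(self):
        recs = pd.DataFrame([_record(last_seen_age=10, calving_ages=[12])])
        with pytest.raises(ValueError, match="F1"):
            build_observation_bins(recs)

    @given(st.floats(5.0, 60.0))
    def test_bin_count_formula(self, last):
        recs = pd.DataFrame([_record(last_seen_age=last)])
        bins = build_observation_bins(recs)
        assert len(bins) == int((last - 5) // 3) + 1
        assert (bins.bin_mid_age == bins.bin_start_age + 1).all()

    def test_reproduced_sum_bounded_by_calvings(self, small_pop):
        bins = build_observation_bins(small_pop)
        per_female = bins.groupby("id")["reproduced"].sum()
        n_calvings = small_pop.set_index("id")["calving_ages"].map(len)
        assert (per_female <= n_calvings[per_female.index]).all()


class TestAttachCovariates:
    def test_decade_and_scaling(self):
        recs = pd.DataFrame([_record(birth_year=1963, last_seen_age=30)])
        tab = attach_covariates(build_observation_bins(recs), recs)
        assert (tab.birth_decade == "1960s").all()
        assert tab.loc[tab.bin_mid_age == 24, "age_scaled"].item() == pytest.approx(0.24)
        assert tab.last_age_scaled.iloc[0] == pytest.approx(0.30)
        assert tab.last_age_scaled_sq.iloc[0] == pytest.approx(0.09)

    def test_unscaled_parameterization_available(self):
        recs = pd.DataFrame([_record(birth_year=1963, last_seen_age=30)])
        tab = attach_covariates(build_observation_bins(recs), recs, scale_age=False)
        assert tab.loc[tab.bin_mid_age == 24, "age_scaled"].item() == 24

    def test_missing_maternal_covariates_retained(self):
        recs = pd.DataFrame([_record(maternal_age=np.nan, birth_order=np.nan)])
        tab = attach_covariates(build_observation_bins(recs), recs)
        assert len(tab) == 6
        assert tab.maternal_age.isna().all()

    def test_missing_required_covariate_drops_rows(self, caplog):
        recs = pd.DataFrame([_record(), _record(id="F2")])
        recs.loc[1, "region"] = np.nan
        bins = build_observation_bins(recs)
        import logging

        with caplog.at_level(logging.WARNING, logger="stressborn.cohort"):
            tab = attach_covariates(bins, recs)
        assert set(tab.id) == {"F1"}
        assert "missing required covariates" in caplog.text

    def test_conception_season_flag(self):
        recs = pd.DataFrame([_record(birth_year=1990, birth_month=4)])
        tab = attach_covariates(build_observation_bins(recs), recs)
        assert (tab.high_stress_conceived == 1).all()
        assert (tab.high_stress_born == 0).all()


class TestSenescentSubset:
    def test_retains_post_peak_mids(self, small_bins):
        sub = senescent_subset(small_bins)
        assert sub.bin_mid_age.min() >= 24
        expected = {m for m in small_bins.bin_mid_age.unique() if m >= 24}
        assert set(sub.bin_mid_age.unique()) == expected

    def test_empty_subset_warns(self, small_bins):
        young = small_bins[small_bins.bin_mid_age < 15]
        with pytest.warns(UserWarning, match="empty"):
            out = senescent_subset(young, 24)
        assert len(out) == 0

    def test_invalid_mid_rejected(self, small_bins):
        with pytest.raises(ValueError, match="valid bin mid-age"):
            senescent_subset(small_bins, 25)


class TestIORoundTrip:
    def test_individuals_roundtrip_lossless(self, small_pop, tmp_path):
        path = tmp_path / "individuals.csv"
        io.write_individuals(small_pop, path, {"config_hash": "abc", "seed": 7})
        back = io.read_individuals(path)
        assert back.calving_ages.map(tuple).tolist() == small_pop.calving_ages.map(tuple).tolist()
        pd.testing.assert_series_equal(back.last_seen_age, small_pop.last_seen_age)
        assert open(path).readline().startswith("# config_hash=abc seed=7")

    def test_bins_roundtrip(self, small_bins, tmp_path):
        path = tmp_path / "bins.csv"
        io.write_csv(small_bins, path)
        back = io.read_csv(path)
        assert len(back) == len(small_bins)
        assert (back.reproduced == small_bins.reproduced).all()
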