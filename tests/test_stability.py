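"""Event classification and the resistance / resilience / LRR statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ecostab.stability import (
    build_lrr_table,
    build_stability_table,
    classify_years,
    log_response_ratio,
    normal_mean_biomass,
    resilience,
    resistance,
)


def _spei_frame(values, site="s1", start_year=2000):
    return pd.DataFrame(
        {
            "site": site,
            "year": np.arange(start_year, start_year + len(values)),
            "spei": values,
        }
    )


class TestClassification:
    def test_hand_thresholded_series(self):
        cat = classify_years(_spei_frame([-1.5, 0.1, 1.4, 0.8, -0.5]))
        assert list(cat["class"]) == [
            "extreme_dry", "normal", "extreme_wet", "other", "normal",
        ]

    def test_exact_extreme_boundary_is_extreme(self):
        cat = classify_years(_spei_frame([1.28, -1.28]))
        assert list(cat["class"]) == ["extreme_wet", "extreme_dry"]

    def test_exact_normal_boundary_is_other(self):
        cat = classify_years(_spei_frame([0.67, -0.67]))
        assert list(cat["class"]) == ["other", "other"]

    def test_missing_spei_left_unclassified(self):
        cat = classify_years(_spei_frame([0.1, np.nan, 0.2]))
        assert len(cat) == 2

    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_classified_years(self, values):
        cat = classify_years(_spei_frame(values))
        s = cat["spei"].to_numpy()
        c = cat["class"].to_numpy()
        wet, dry = s >= 1.28, s <= -1.28
        normal = (np.abs(s) < 0.67) & ~wet & ~dry
        other = ~(wet | dry | normal)
        assert np.array_equal(c == "extreme_wet", wet)
        assert np.array_equal(c == "extreme_dry", dry)
        assert np.array_equal(c == "normal", normal)
        assert np.array_equal(c == "other", other)


class TestStatistics:
    def test_normal_mean_is_arithmetic_mean(self):
        biomass = pd.DataFrame(
            {
                "site": "s1", "experiment": "e1", "plot": "p1",
                "year": [2000, 2001, 2002], "treatment": "control",
                "biomass": [80.0, 120.0, 999.0],
            }
        )
        cat = classify_years(_spei_frame([0.1, -0.2, 2.0]))
        ybar = normal_mean_biomass(biomass, cat)
        assert ybar["y_normal_mean"].iloc[0] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "yn, ye, expected", [(100.0, 50.0, 2.0), (100.0, 150.0, 2.0), (100.0, 100.0, np.nan)]
    )
    def test_resistance_absolute_deviation_convention(self, yn, ye, expected):
        got = resistance(yn, ye)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    def test_resilience_hand_case(self):
        assert resilience(100.0, 50.0, 75.0, "normal") == pytest.approx(2.0)

    def test_resilience_unity_when_no_change(self):
        assert resilience(100.0, 50.0, 50.0, "other") == pytest.approx(1.0)

    def test_resilience_missing_after_consecutive_extreme(self):
        assert np.isnan(resilience(100.0, 50.0, 75.0, "extreme_dry"))

    @pytest.mark.parametrize(
        "ye, yn, expected", [(100.0, 100.0, 0.0), (200.0, 100.0, np.log(2)), (-1.0, 100.0, np.nan)]
    )
    def test_lrr_values(self, ye, yn, expected):
        got = log_response_ratio(ye, yn)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    @given(
        st.floats(min_value=0.01, max_value=1e4),
        st.floats(min_value=0.01, max_value=1e4),
        st.floats(min_value=0.01, max_value=1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_lrr_antisymmetry_and_scale_invariance(self, a, b, c):
        assert log_response_ratio(a, b) == pytest.approx(
            -log_response_ratio(b * b / a, b), abs=1e-9
        )
        assert log_response_ratio(c * a, c * b) == pytest.approx(
            log_response_ratio(a, b), abs=1e-9
        )


class TestTableAssembly:
    @pytest.fixture()
    def tiny_study(self):
        # one plot, six years: normal, normal, dry event, recovery, wet
        # event, recovery; a second event year follows the wet event
        spei = _spei_frame([0.1, -0.2, -1.6, 0.3, 1.5, 0.2])
        cat = classify_years(spei)
        biomass = pd.DataFrame(
            {
                "site": "s1", "experiment": "e1", "plot": "p1",
                "year": np.arange(2000, 2006), "treatment": "control",
                "biomass": [100.0, 104.0, 60.0, 85.0, 140.0, 110.0],
            }
        )
        props = pd.DataFrame(
            {
                "site": "s1", "experiment": "e1", "plot": "p1",
                "year": np.arange(2000, 2006), "treatment": "control",
                "richness": [10, 11, 12, 9, 8, 10],
                "evenness": 0.7, "dominant_species": "A", "dominance": 0.4,
            }
        )
        return biomass, cat, props

    def test_prior_year_predictors_attached(self, tiny_study):
        biomass, cat, props = tiny_study
        table, excl = build_stability_table(biomass, cat, props)
        dry = table[table["event_type"] == "extreme_dry"].iloc[0]
        assert dry["event_year"] == 2002
        assert dry["prior_richness"] == 11  # from 2001
        wet = table[table["event_type"] == "extreme_wet"].iloc[0]
        assert wet["prior_richness"] == 9  # from 2003

    def test_hand_computed_omega_and_delta(self, tiny_study):
        biomass, cat, props = tiny_study
        table, _ = build_stability_table(biomass, cat, props)
        # normal years 2000, 2001, 2003, 2005 -> Ybar = 99.75
        ybar = np.mean([100.0, 104.0, 85.0, 110.0])
        dry = table[table["event_type"] == "extreme_dry"].iloc[0]
        assert dry["y_normal_mean"] == pytest.approx(ybar)
        assert dry["resistance"] == pytest.approx(ybar / abs(60.0 - ybar))
        assert dry["resilience"] == pytest.approx(abs(60.0 - ybar) / abs(85.0 - ybar))

    def test_missing_prior_year_row_dropped(self, tiny_study):
        biomass, cat, props = tiny_study
        props = props[props["year"] != 2001]  # remove the dry event's prior year
        table, excl = build_stability_table(biomass, cat, props)
        assert excl["missing_prior_year_properties"] == 1
        assert (table["event_type"] == "extreme_wet").all()

    def test_resilience_missing_when_event_follows_event(self):
        spei = _spei_frame([0.1, 0.0, -1.5, -1.4, 0.2])
        cat = classify_years(spei)
        biomass = pd.DataFrame(
            {
                "site": "s1", "experiment": "e1", "plot": "p1",
                "year": np.arange(2000, 2005), "treatment": "control",
                "biomass": [100.0, 102.0, 60.0, 65.0, 90.0],
            }
        )
        table, _ = build_stability_table(biomass, cat)
        first = table[table["event_year"] == 2002].iloc[0]
        assert np.isnan(first["resilience"])
        second = table[table["event_year"] == 2003].iloc[0]
        assert np.isfinite(second["resilience"])

    def test_ln_omega_finite_wherever_defined(self, stability_table):
        omega = stability_table["resistance"].dropna()
        assert (omega > 0).all()
        assert np.isfinite(np.log(omega)).all()

    def test_resistance_increases_with_generated_richness(self, stability_table):
        # the generator buffers dry-event deviations with richness
        dry = stability_table[stability_table["event_type"] == "extreme_dry"].dropna(
            subset=["resistance", "prior_richness"]
        )
        rho = sps.spearmanr(dry["prior_richness"], np.log(dry["resistance"])).statistic
        assert rho > 0

    def test_lrr_table_has_all_metrics(self, lrr_table):
        assert set(lrr_table["metric"]) == {"biomass", "richness", "dominance", "evenness"}
        assert np.isfinite(lrr_table["lrr"]).all()
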