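"""Unit conversion, standardization rules, screening filters, outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seamehg as sm
from seamehg.standardize import (
    UnitError,
    apply_filters,
    convert_units,
    dry_to_wet,
    impute_sampling_year,
    impute_sd,
    remove_outliers,
    standardize_records,
)


def make_record(**overrides):
    base = {
        "study_id": "S1",
        "species_name": "Thunnus sp.",
        "trophic_level": 4.2,
        "group": "marine_fish",
        "marine_area": "Pacific Northwest",
        "sampling_year_start": 2005,
        "sampling_year_end": 2005,
        "publication_year": 2007,
        "tissue": "muscle",
        "weight_basis": "wet",
        "unit": "ng/g",
        "analyte": "MeHg",
        "mean_value": 120.0,
        "sd_value": 30.0,
        "sample_size": 12,
        "polluted_site": False,
        "below_lod": False,
    }
    base.update(overrides)
    return base


def frame_of(*records):
    return pd.DataFrame([make_record(**r) for r in records])


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (1.0, "µg/g", 1000.0),
            (250.0, "ppb", 250.0),
            (0.5, "mg/kg", 500.0),
            (3.0, "ppm", 3000.0),
            (42.0, "ng/g", 42.0),
            (7.0, "µg/kg", 7.0),
            (7.0, "ug/kg", 7.0),  # ascii spelling
        ],
    )
    def test_conversion_to_ng_g(self, value, unit, expected):
        assert convert_units(value, unit) == pytest.approx(expected)

    def test_unknown_unit_is_hard_error(self):
        with pytest.raises(UnitError, match="mol/L"):
            convert_units(1.0, "mol/L")

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip_through_mg_kg(self, x):
        """Expressing an ng/g value in mg/kg and converting back is lossless."""
        assert convert_units(x / 1000.0, "mg/kg") == pytest.approx(x, rel=1e-12)


class TestDryToWet:
    @pytest.mark.parametrize("dw, ww", [(100.0, 20.0), (0.0, 0.0), (500.0, 100.0)])
    def test_eighty_percent_water(self, dw, ww):
        assert dry_to_wet(dw) == pytest.approx(ww)

    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_and_order_preserving(self, a, b, k):
        assert dry_to_wet(a + k * b) == pytest.approx(dry_to_wet(a) + k * dry_to_wet(b))
        if a <= b:
            assert dry_to_wet(a) <= dry_to_wet(b)


class TestImputationRules:
    @pytest.mark.parametrize("mean, sd", [(100.0, 65.0), (1.0, 0.65)])
    def test_sd_is_65_percent_of_mean(self, mean, sd):
        assert impute_sd(mean) == pytest.approx(sd)

    @pytest.mark.parametrize("pub, sampling", [(2020, 2018), (1997, 1995)])
    def test_sampling_year_is_publication_minus_two(self, pub, sampling):
        assert impute_sampling_year(pub) == sampling

    def test_reported_values_pass_through_unflagged(self):
        std, _ = standardize_records(frame_of({}))
        row = std.iloc[0]
        assert row["sd"] == 30.0 and not row["sd_imputed"]
        assert row["year"] == 2005 and not row["year_imputed"]

    def test_missing_sd_and_year_imputed_and_flagged(self):
        std, _ = standardize_records(
            frame_of({"sd_value": None, "sampling_year_start": None, "sampling_year_end": None})
        )
        row = std.iloc[0]
        assert row["sd"] == pytest.approx(0.65 * 120.0) and row["sd_imputed"]
        assert row["year"] == 2005 and row["year_imputed"]  # publication 2007 - 2

    def test_missing_sample_size_defaults_to_one(self):
        std, _ = standardize_records(frame_of({"sample_size": None}))
        assert std.iloc[0]["n"] == 1


class TestPeriodExpansion:
    def test_multi_year_period_expands_to_one_row_per_year(self):
        std, _ = standardize_records(
            frame_of({"sampling_year_start": 2003, "sampling_year_end": 2005})
        )
        assert list(std["year"]) == [2003, 2004, 2005]
        assert std["mean"].nunique() == 1 and std["n"].nunique() == 1

    def test_single_year_period_is_one_row(self):
        std, _ = standardize_records(
            frame_of({"sampling_year_start": 2010, "sampling_year_end": 2010})
        )
        assert len(std) == 1 and std.iloc[0]["year"] == 2010

    def test_dry_weight_and_unit_standardized_together(self):
        std, _ = standardize_records(
            frame_of({"weight_basis": "dry", "unit": "µg/g", "mean_value": 0.5, "sd_value": 0.1})
        )
        # 0.5 ug/g DW -> 500 ng/g DW -> 100 ng/g WW
        assert std.iloc[0]["mean"] == pytest.approx(100.0)
        assert std.iloc[0]["sd"] == pytest.approx(20.0)


class TestFilters:
    def test_clean_record_kept(self):
        kept, log = apply_filters(frame_of({}))
        assert len(kept) == 1 and log.empty

    @pytest.mark.parametrize(
        "override, reason",
        [
            ({"polluted_site": True}, "polluted_site"),
            ({"tissue": "non_muscle"}, "non_muscle"),
            ({"marine_area": None}, "unknown_area"),
            ({"marine_area": "North Sea"}, "unknown_area"),
            ({"weight_basis": "unspecified"}, "unspecified_weight"),
            ({"below_lod": True}, "below_lod"),
        ],
    )
    def test_each_criterion_rejects_with_its_reason(self, override, reason):
        corrupted = {"study_id": "S2", "mean_value": 99.0, **override}
        kept, log = apply_filters(frame_of({}, corrupted))
        assert len(kept) == 1
        assert list(log["reason"]) == [reason]

    def test_duplicates_keep_first(self):
        kept, log = apply_filters(frame_of({}, {}))
        assert len(kept) == 1
        assert list(log["reason"]) == ["duplicate"]

    def test_first_matching_reason_wins(self):
        kept, log = apply_filters(
            frame_of({"polluted_site": True, "tissue": "non_muscle"})
        )
        assert list(log["reason"]) == ["polluted_site"]

    def test_kept_and_rejected_partition_input(self):
        config = sm.SimulationConfig(n_studies=400, seed=3)
        truth = sm.generate_truth(config)
        records = sm.generate_literature_records(truth, config)
        kept, log = apply_filters(records)
        assert len(kept) + len(log) == len(records)
        assert set(kept["record_id"]).isdisjoint(set(log["record_id"]))

    def test_missing_trophic_resolved_by_lookup_else_rejected(self):
        records = frame_of({"trophic_level": None})
        lookup = pd.DataFrame(
            {"species_name": ["Thunnus sp."], "trophic_level": [4.2]}
        )
        std, rej = standardize_records(records, trophic_lookup=lookup)
        assert len(std) == 1 and std.iloc[0]["category"] == "Level 3"
        std, rej = standardize_records(records)
        assert std.empty and list(rej["reason"]) == ["missing_trophic"]


class TestOutlierRemoval:
    def _standardized(self, values):
        records = frame_of(*[{"mean_value": v, "study_id": f"S{i}"} for i, v in enumerate(values)])
        std, _ = standardize_records(records)
        return std

    def test_exactly_five_percent_removed_in_one_stratum(self):
        rng = np.random.default_rng(0)
        std = self._standardized(rng.lognormal(4.0, 0.6, 1000))
        kept, log = remove_outliers(std, 0.05)
        assert len(log) == 50 and len(kept) == 950
        assert set(log["reason"]) == {"outlier"}

    def test_identical_values_floor_to_zero_removals(self):
        std = self._standardized([50.0] * 10)
        kept, log = remove_outliers(std, 0.05)
        assert len(kept) == 10 and log.empty

    def test_extreme_value_is_among_removed(self):
        values = list(np.linspace(90, 110, 99)) + [1e8]
        std = self._standardized(values)
        kept, log = remove_outliers(std, 0.05)
        assert len(log) == 5
        assert 1e8 not in kept["mean"].to_numpy()

    def test_quota_applied_per_stratum(self):
        fish = [{"mean_value": v, "study_id": f"F{i}"} for i, v in enumerate(range(100, 140))]
        ose = [
            {"mean_value": float(v), "study_id": f"O{i}", "group": "other_seafood", "trophic_level": None}
            for i, v in enumerate(range(10, 70))
        ]
        std, _ = standardize_records(frame_of(*fish, *ose))
        kept, log = remove_outliers(std, 0.05)
        # floor(0.05 * 40) + floor(0.05 * 60) = 2 + 3
        assert len(log) == 5

    def test_invalid_fraction_rejected(self):
        std = self._standardized([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            remove_outliers(std, 0.5)


class TestStandardizedInvariants:
    def test_generator_output_satisfies_type_invariants(self):
        """Every standardized row from a messy synthetic corpus has positive
        mean, non-negative SD, integer n >= 1, a year, and a known category."""
        config = sm.SimulationConfig(n_studies=600, seed=21)
        truth = sm.generate_truth(config)
        records = sm.generate_literature_records(truth, config)
        kept, _ = apply_filters(records)
        std, _ = standardize_records(kept)
        assert (std["mean"] > 0).all()
        assert (std["sd"] >= 0).all()
        assert (std["n"] >= 1).all()
        assert std["year"].notna().all()
        assert set(std["category"]) <= set(sm.CATEGORIES)
        assert set(std["marine_area"]) <= set(sm.FAO_AREAS)
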