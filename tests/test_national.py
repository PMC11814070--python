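"""Catch-weighted national aggregation and geometric-mean fallback."""

import numpy as np
import pandas as pd
import pytest

import seamehg as sm
from seamehg.convert import MonteCarloSettings
from seamehg.marine import AreaSeries
from seamehg.national import (
    build_nation_series,
    catch_weighted_mean,
    geometric_fallback,
    load_continent_map,
    propagate_uncertainty,
)

from conftest import brute_catch_mean, brute_geomean


class TestCatchWeightedMean:
    def test_single_area_unit_weight(self):
        assert catch_weighted_mean([80.0], [123.0]) == pytest.approx(80.0)

    def test_two_area_example(self):
        assert catch_weighted_mean([10.0, 30.0], [300.0, 100.0]) == pytest.approx(15.0)

    def test_constant_concentrations_for_any_catch_profile(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            volumes = rng.uniform(1, 1e5, 6)
            assert catch_weighted_mean([42.0] * 6, volumes) == pytest.approx(42.0)

    def test_catch_scaling_invariance(self):
        means = [12.0, 40.0, 7.0]
        volumes = [100.0, 55.0, 9.0]
        a = catch_weighted_mean(means, volumes)
        b = catch_weighted_mean(means, [v * 1e3 for v in volumes])
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_total_catch_is_error(self):
        with pytest.raises(ValueError):
            catch_weighted_mean([10.0], [0.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            k = rng.integers(1, 21)
            means = rng.lognormal(3, 1, k)
            volumes = rng.uniform(0.1, 1e5, k)
            assert catch_weighted_mean(means, volumes) == pytest.approx(
                brute_catch_mean(means, volumes), rel=1e-9
            )


class TestGeometricFallback:
    def test_two_peer_example(self):
        assert geometric_fallback([10.0, 1000.0]) == pytest.approx(100.0)

    def test_single_peer(self):
        assert geometric_fallback([7.5]) == pytest.approx(7.5)

    def test_global_pair_example(self):
        assert geometric_fallback([1.0, 100.0]) == pytest.approx(10.0)

    def test_order_invariant_and_identity_on_constants(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(2, 1, 9)
        assert geometric_fallback(values) == pytest.approx(
            geometric_fallback(values[::-1]), rel=1e-12
        )
        assert geometric_fallback([5.0] * 4) == pytest.approx(5.0)
        assert geometric_fallback(values) == pytest.approx(
            brute_geomean(values), rel=1e-9
        )


class TestPropagateUncertainty:
    def test_zero_sds_give_zero(self):
        sd = propagate_uncertainty([10.0, 20.0], [0.0, 0.0], [1.0, 1.0], MonteCarloSettings(seed=1))
        assert sd == 0.0

    def test_single_area_sd_close_to_area_sd(self):
        settings = MonteCarloSettings(n_draws=20_000, seed=4)
        sd = propagate_uncertainty([100.0], [15.0], [7.0], settings)
        assert sd == pytest.approx(15.0, rel=0.05)

    def test_deterministic_under_seed(self):
        settings = MonteCarloSettings(n_draws=2_000, seed=8)
        a = propagate_uncertainty([50.0, 70.0], [5.0, 9.0], [2.0, 3.0], settings)
        b = propagate_uncertainty([50.0, 70.0], [5.0, 9.0], [2.0, 3.0], settings)
        assert a == b


def small_series_and_catch():
    areas = ("Arctic Sea", "Atlantic Northeast")
    years = (2000, 2001)
    cats = ("Level 2",)
    rows = [
        (c, a, y, {"Arctic Sea": 10.0, "Atlantic Northeast": 30.0}[a], 0.0, 1, "observed")
        for c in cats
        for a in areas
        for y in years
    ]
    frame = pd.DataFrame(
        rows, columns=["category", "marine_area", "year", "mean", "sd", "n_records", "status"]
    )
    series = AreaSeries(frame=frame, areas=areas, categories=cats, years=years)
    catch = pd.DataFrame(
        [
            # NOR fishes both areas 3:1; ISL has no catch at all; PER single area
            ("Norway", "NOR", "Arctic Sea", "Level 2", 2000, 300.0),
            ("Norway", "NOR", "Atlantic Northeast", "Level 2", 2000, 100.0),
            ("Norway", "NOR", "Arctic Sea", "Level 2", 2001, 300.0),
            ("Norway", "NOR", "Atlantic Northeast", "Level 2", 2001, 100.0),
            ("Iceland", "ISL", "Arctic Sea", "Level 2", 2000, 0.0),
            ("Iceland", "ISL", "Arctic Sea", "Level 2", 2001, 0.0),
            ("Peru", "PER", "Atlantic Northeast", "Level 2", 2000, 50.0),
            ("Peru", "PER", "Atlantic Northeast", "Level 2", 2001, 50.0),
        ],
        columns=["nation", "iso3", "marine_area", "category", "year", "volume"],
    )
    return series, catch


class TestBuildNationSeries:
    def test_weighting_fallback_and_provenance(self):
        series, catch = small_series_and_catch()
        nation_series, tally = build_nation_series(
            series, catch, settings=MonteCarloSettings(n_draws=500, seed=1)
        )
        frame = nation_series.frame.set_index(["nation", "year"])
        # Norway: (10*300 + 30*100) / 400 = 15
        assert frame.loc[("Norway", 2000), "mean"] == pytest.approx(15.0)
        assert frame.loc[("Norway", 2000), "provenance"] == "catch_weighted"
        # Peru fishes a single area: inherits that area's value
        assert frame.loc[("Peru", 2001), "mean"] == pytest.approx(30.0)
        # Iceland has zero catch: continent peers are Norway (same continent
        # via the packaged map) -> geometric mean of {15}
        assert frame.loc[("Iceland", 2000), "mean"] == pytest.approx(15.0)
        assert frame.loc[("Iceland", 2000), "provenance"] == "continent_geomean"
        assert tally["catch_weighted"] == 4 and tally["continent_geomean"] == 2

    def test_global_fallback_when_no_continental_peer(self):
        series, catch = small_series_and_catch()
        # move Iceland to a continent with no peers
        continent_map = {"NOR": "Europe", "PER": "South America", "ISL": "Oceania"}
        nation_series, _ = build_nation_series(
            series, catch, continent_map, MonteCarloSettings(n_draws=500, seed=1)
        )
        frame = nation_series.frame.set_index(["nation", "year"])
        assert frame.loc[("Iceland", 2000), "provenance"] == "global_geomean"
        assert frame.loc[("Iceland", 2000), "mean"] == pytest.approx(
            brute_geomean([15.0, 30.0])
        )

    def test_unmapped_nation_is_validation_error(self):
        series, catch = small_series_and_catch()
        with pytest.raises(ValueError, match="ISL"):
            build_nation_series(series, catch, {"NOR": "Europe", "PER": "South America"})

    def test_national_mean_within_contributing_area_range(self):
        series, catch = small_series_and_catch()
        nation_series, _ = build_nation_series(
            series, catch, settings=MonteCarloSettings(n_draws=200, seed=2)
        )
        weighted = nation_series.frame[
            nation_series.frame["provenance"] == "catch_weighted"
        ]
        assert weighted["mean"].between(10.0, 30.0).all()

    def test_packaged_continent_map_loads(self):
        cmap = load_continent_map()
        assert cmap["NOR"] == "Europe"
        assert cmap["PER"] == "South America"
        assert len(cmap) > 50

    def test_clean_run_matches_truth_derived_oracle(self, clean_run):
        """End to end on the noise-free fixture: catch-weighted national
        values equal the brute-force weighting of the latent truth."""
        truth = clean_run["truth"]
        capture = clean_run["capture"]
        out_dir = clean_run["out_dir"]
        truth_lookup = truth.frame.set_index(["category", "marine_area", "year"])[
            "true_mehg"
        ]
        for cat in ("Level 2", "OSE"):
            tag = cat.replace(" ", "")
            means = pd.read_csv(out_dir / f"Nation_{tag}_mean.csv", index_col=0)
            prov = pd.read_csv(out_dir / f"Nation_{tag}_provenance.csv", index_col=0)
            for nation in means.index:
                iso3 = capture.loc[capture["nation"] == nation, "iso3"].iloc[0]
                for year in means.columns:
                    if prov.loc[nation, year] != "catch_weighted":
                        continue
                    sub = capture[
                        (capture["iso3"] == iso3)
                        & (capture["category"] == cat)
                        & (capture["year"] == int(year))
                        & (capture["volume"] > 0)
                    ]
                    oracle = brute_catch_mean(
                        [truth_lookup[(cat, a, int(year))] for a in sub["marine_area"]],
                        sub["volume"].tolist(),
                    )
                    assert means.loc[nation, year] == pytest.approx(oracle, rel=1e-9)
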