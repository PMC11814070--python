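"""Shared fixtures: synthetic corpora, a clean end-to-end run, and oracles.

The brute-force oracles below intentionally use plain Python loops and no
shared code with the package, so they stay independent of the vectorised
implementations they check.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import seamehg as sm

# ---------------------------------------------------------------------------
# Independent oracles


def brute_weighted_mean(means, sds, ns):
    """Sample-size-weighted cell mean and pooled SD, by explicit summation."""
    total = 0.0
    for n in ns:
        total += n
    mean = 0.0
    for c, n in zip(means, ns):
        mean += c * n / total
    var = 0.0
    for c, s, n in zip(means, sds, ns):
        var += n * (s * s + (c - mean) ** 2) / total
    return mean, math.sqrt(var)


def brute_catch_mean(area_means, volumes):
    """Catch-weighted national mean by explicit summation."""
    num = 0.0
    den = 0.0
    for c, f in zip(area_means, volumes):
        num += c * f
        den += f
    return num / den


def brute_geomean(values):
    log_sum = 0.0
    for v in values:
        log_sum += math.log(v)
    return math.exp(log_sum / len(values))


# ---------------------------------------------------------------------------
# Clean (noise-free, corruption-free) end-to-end fixture.
# Small grid: 3 FAO areas x 5 categories x 6 years, 4 records per cell, so
# the per-stratum 5% outlier quota can never empty a cell.

CLEAN_YEARS = (1995, 2000)


def _clean_sim_config(seed: int = 11) -> sm.SimulationConfig:
    return sm.clean_config(
        n_studies=360,
        areas=sm.FAO_AREAS[:3],
        year_start=CLEAN_YEARS[0],
        year_end=CLEAN_YEARS[1],
        n_nations=5,
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_fixture_files(tmp_path_factory):
    """Synthetic fixture files for a clean run, plus the latent truth."""
    config = _clean_sim_config()
    truth = sm.generate_truth(config)
    records = sm.generate_literature_records(truth, config)
    capture, nations = sm.generate_catch_table(config)
    directory = tmp_path_factory.mktemp("clean_fixtures")
    paths = sm.write_fixtures(records, capture, nations, truth, directory)
    return {
        "config": config,
        "truth": truth,
        "records": records,
        "capture": capture,
        "nations": nations,
        "paths": paths,
    }


def make_pipeline_config(paths: dict, out_dir: Path, seed: int = 11) -> sm.PipelineConfig:
    return sm.PipelineConfig(
        records_path=str(paths["records"]),
        capture_path=str(paths["capture"]),
        nation_table_path=str(paths["nation_id"]),
        out_dir=str(out_dir),
        year_start=CLEAN_YEARS[0],
        year_end=CLEAN_YEARS[1],
        seed=seed,
        n_draws=2000,
    )


@pytest.fixture(scope="session")
def clean_run(clean_fixture_files, tmp_path_factory):
    """One clean pipeline run: manifest, output dir, and the inputs."""
    out_dir = tmp_path_factory.mktemp("clean_out")
    config = make_pipeline_config(clean_fixture_files["paths"], out_dir)
    manifest = sm.run_pipeline(config)
    return {**clean_fixture_files, "out_dir": out_dir, "manifest": manifest, "pipeline_config": config}


# ---------------------------------------------------------------------------
# Noisy imputation scenario: trending truth, cells masked at random.


def masked_noisy_series(seed: int = 5, missing_fraction: float = 0.3):
    """An AreaSeries built from noisy truth with a random subset of cells
    hidden; returns (series_with_gaps, truth_lookup, hidden_cell_index)."""
    config = sm.SimulationConfig(
        n_studies=2500,
        areas=sm.FAO_AREAS[:4],
        year_start=1995,
        year_end=2022,
        slope=-0.02,
        noise_sd=0.25,
        thg_fraction=0.0,
        period_rate=0.0,
        missing_sd_rate=0.0,
        missing_n_rate=0.0,
        missing_year_rate=0.0,
        dry_weight_rate=0.0,
        polluted_rate=0.0,
        non_muscle_rate=0.0,
        unknown_area_rate=0.0,
        unspecified_weight_rate=0.0,
        below_lod_rate=0.0,
        unit_mix={"ng/g": 1.0},
        ensure_coverage=True,
        seed=seed,
    )
    truth = sm.generate_truth(config)
    records = sm.generate_literature_records(truth, config)
    kept, _ = sm.apply_filters(records)
    std, _ = sm.standardize_records(kept)
    conv = sm.convert_records(std)
    series, _ = sm.build_area_series(
        conv, year_start=config.year_start, year_end=config.year_end
    )
    rng = np.random.default_rng(seed + 100)
    observed = series.frame.index[series.frame["status"] == "observed"]
    hidden = rng.choice(
        observed, size=int(missing_fraction * len(observed)), replace=False
    )
    series.frame.loc[hidden, ["mean", "sd"]] = np.nan
    series.frame.loc[hidden, "status"] = "missing"
    series.frame.loc[hidden, "n_records"] = 0
    truth_lookup = truth.frame.set_index(["marine_area", "category", "year"])[
        "true_mehg"
    ]
    return series, truth_lookup, hidden
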