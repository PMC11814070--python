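"""End-to-end pipeline: raw records and catch tables to national time series.

Stages run in a fixed order — screening filters, standardization, outlier
removal, THg-to-MeHg conversion, area aggregation, random-forest imputation,
catch-weighted national aggregation — and all randomness (Monte Carlo draws,
forest seeds, train/test splits) derives from a single master seed, so a run
is reproducible file-for-file. Outputs mirror the deposited-dataset naming:
``<Scale>_<Category>_<statistic>.csv`` with Scale in {Marine, Nation} and
statistic in {mean, std} (plus a provenance table per scale and category),
along with intermediate tables, a rejection log, and a JSON run manifest
recording seeds and stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as seamehg_io
from .classify import CATEGORIES
from .convert import MonteCarloSettings, convert_records, default_model
from .impute import ImputationConfig, impute_all
from .marine import AreaSeries, build_area_series
from .national import NationSeries, build_nation_series, load_continent_map
from .standardize import apply_filters, remove_outliers, standardize_records

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, year range, stage settings, and the master seed."""

    records_path: str = "records.csv"
    capture_path: str = "capture.csv"
    out_dir: str = "output"
    trophic_lookup_path: str | None = None
    nation_table_path: str | None = None
    year_start: int = 1995
    year_end: int = 2022
    outlier_fraction: float = 0.05
    seed: int = 0
    n_draws: int = 10_000
    distribution_family: str = "lognormal_moment_matched"
    imputation: ImputationConfig = field(default_factory=ImputationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        imp = ImputationConfig(**raw.pop("imputation", {}))
        return cls(imputation=imp, **raw)


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _sanitize(category: str) -> str:
    return category.replace(" ", "")


def _write_grid(frame_pivot: pd.DataFrame, path: Path) -> None:
    frame_pivot.to_csv(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the output file set; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records = seamehg_io.read_records(config.records_path)
    capture = seamehg_io.read_capture(config.capture_path)
    lookup = (
        seamehg_io.read_trophic_lookup(config.trophic_lookup_path)
        if config.trophic_lookup_path
        else None
    )
    if config.nation_table_path:
        nation_table = seamehg_io.read_nation_table(config.nation_table_path)
    else:
        nation_table = capture[["nation", "iso3"]].drop_duplicates()
    if "continent" in nation_table.columns:
        continent_map = dict(zip(nation_table["iso3"], nation_table["continent"]))
    else:
        continent_map = load_continent_map()

    mc_seed, rf_seed, nat_seed = _child_seeds(config.seed, 3)

    # 1. screening filters
    kept, rejections = apply_filters(records)
    logger.info("filters kept %d of %d records", len(kept), len(records))

    # 2. standardization (+ trophic classification, period expansion)
    standardized, rej_std = standardize_records(kept, trophic_lookup=lookup)
    rejections = pd.concat([rejections, rej_std], ignore_index=True)

    # 3. outlier removal per (group, category) stratum
    standardized, rej_out = remove_outliers(standardized, config.outlier_fraction)
    rejections = pd.concat([rejections, rej_out], ignore_index=True)

    # 4. THg -> MeHg conversion with Monte Carlo propagation
    mc = MonteCarloSettings(
        n_draws=config.n_draws,
        seed=mc_seed,
        distribution_family=config.distribution_family,
    )
    models = {"FISH": default_model("FISH"), "OSE": default_model("OSE")}
    converted = convert_records(standardized, models, mc)

    # 5. sample-size-weighted area aggregation
    area_series, coverage = build_area_series(
        converted, year_start=config.year_start, year_end=config.year_end
    )

    # 6. random-forest imputation
    imp_config = ImputationConfig(
        test_fraction=config.imputation.test_fraction,
        n_trees=config.imputation.n_trees,
        seed=rf_seed,
        min_cells=config.imputation.min_cells,
        use_lag_features=config.imputation.use_lag_features,
    )
    filled, imputation_report = impute_all(area_series, imp_config)

    # 7. catch-weighted national aggregation
    nat_mc = MonteCarloSettings(
        n_draws=config.n_draws,
        seed=nat_seed,
        distribution_family=config.distribution_family,
    )
    nation_series, provenance_tally = build_nation_series(
        filled, capture, continent_map, nat_mc
    )

    _write_outputs(
        out,
        standardized,
        rejections,
        converted,
        filled,
        imputation_report,
        nation_series,
        nation_table,
    )

    manifest = {
        "seed": config.seed,
        "stage_seeds": {"monte_carlo": mc_seed, "random_forest": rf_seed, "national": nat_seed},
        "n_input_records": int(len(records)),
        "n_kept_after_filters": int(len(kept)),
        "rejections_by_reason": {
            k: int(v) for k, v in rejections["reason"].value_counts().items()
        },
        "n_standardized_rows": int(len(standardized)),
        "area_coverage": coverage,
        "imputation": imputation_report.fillna("").to_dict(orient="records"),
        "national_provenance": {k: int(v) for k, v in provenance_tally.items()},
        "year_range": [config.year_start, config.year_end],
        "n_draws": config.n_draws,
        "distribution_family": config.distribution_family,
    }
    filter_reasons = ("duplicate", "polluted_site", "non_muscle", "unknown_area",
                      "unspecified_weight", "below_lod")
    n_filter_rejected = sum(
        manifest["rejections_by_reason"].get(r, 0) for r in filter_reasons
    )
    assert manifest["n_kept_after_filters"] + n_filter_rejected == manifest["n_input_records"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_outputs(
    out: Path,
    standardized: pd.DataFrame,
    rejections: pd.DataFrame,
    converted: pd.DataFrame,
    filled: AreaSeries,
    imputation_report: pd.DataFrame,
    nation_series: NationSeries,
    nation_table: pd.DataFrame,
) -> None:
    standardized.to_csv(out / "standardized.csv", index=False)
    rejections.sort_values(["record_id", "reason"]).to_csv(
        out / "rejections.csv", index=False
    )
    converted.to_csv(out / "converted.csv", index=False)
    imputation_report.to_csv(out / "imputation_report.csv", index=False)
    nation_table[["nation", "iso3"]].drop_duplicates().to_csv(
        out / "nation_id.csv", index=False
    )
    for cat in CATEGORIES:
        tag = _sanitize(cat)
        _write_grid(filled.pivot(cat, "mean"), out / f"Marine_{tag}_mean.csv")
        _write_grid(filled.pivot(cat, "sd"), out / f"Marine_{tag}_std.csv")
        _write_grid(filled.pivot(cat, "status"), out / f"Marine_{tag}_provenance.csv")
        _write_grid(nation_series.pivot(cat, "mean"), out / f"Nation_{tag}_mean.csv")
        _write_grid(nation_series.pivot(cat, "sd"), out / f"Nation_{tag}_std.csv")
        _write_grid(
            nation_series.pivot(cat, "provenance"), out / f"Nation_{tag}_provenance.csv"
        )
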