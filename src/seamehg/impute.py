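"""Random-forest imputation of missing area x category x year cells.

Observed coverage is uneven: mid-trophic marine fishes (Level 2, Level 3) are
comparatively well sampled, while Level 1, Level 4 and other seafoods are
sparse. The fill strategy follows the bioaccumulation structure of the food
web in two passes:

1. *Within-category*: for Level 2 and Level 3, a regression forest is trained
   on observed cells (features: calendar year plus area indicator variables)
   and predicts the missing cells of the same category.
2. *Cross-category*: once Level 2 and Level 3 surfaces are complete, Level 1,
   Level 4 and OSE are predicted from the completed Level 2/3 concentrations
   at the same (area, year), plus year and area indicators — exploiting the
   correlation that trophic transfer induces between categories.

Observed cells are never overwritten. Prediction accuracy is reported on a
randomly held-out 10% of observed cells (refit on the remaining 90%); the
forests used for the actual fill are then refit on all observed cells. Cell
SDs are imputed by a parallel forest trained on observed SDs, falling back to
65% of the imputed mean (the same dispersion rule the standardization stage
uses) when no SD training data exist.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score

from .marine import AreaSeries
from .standardize import SD_IMPUTATION_FRACTION

logger = logging.getLogger(__name__)

#: Categories filled by direct within-category interpolation.
WITHIN_CATEGORIES = ("Level 2", "Level 3")
#: Categories filled from the completed Level 2/3 surfaces.
CROSS_CATEGORIES = ("Level 1", "Level 4", "OSE")


@dataclass
class ImputationConfig:
    """Forest and train/test-split configuration.

    ``test_fraction`` of observed cells (default 10%) is held out to score
    prediction accuracy; the complement trains the evaluation forest. Fewer
    than ``min_cells`` observed cells skips imputation for that category with
    a warning, leaving its gaps to the national-stage geometric-mean fallback.
    """

    test_fraction: float = 0.1
    n_trees: int = 100
    seed: int = 0
    min_cells: int = 10
    use_lag_features: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    @property
    def train_fraction(self) -> float:
        return 1.0 - self.test_fraction


def split_cells(
    index: np.ndarray, config: ImputationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly partition observed-cell indices into train and test sets.

    ``|test| = round(test_fraction * |observed|)``; the partition is uniform
    and fully determined by the config seed.
    """
    index = np.asarray(index)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(index)
    n_test = int(round(config.test_fraction * len(index)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def _features(sub: pd.DataFrame, areas: tuple[str, ...], extra: list[str] | None = None) -> np.ndarray:
    cols = [sub["year"].to_numpy(float)]
    for area in areas:  # fixed indicator order, independent of data
        cols.append((sub["marine_area"] == area).to_numpy(float))
    for name in extra or []:
        cols.append(sub[name].to_numpy(float))
    return np.column_stack(cols)


def _add_lag(sub: pd.DataFrame, series_frame: pd.DataFrame, category: str) -> pd.DataFrame:
    lookup = series_frame[series_frame["category"] == category].set_index(
        ["marine_area", "year"]
    )["mean"]
    sub = sub.copy()
    lag = [
        lookup.get((a, y - 1), np.nan)
        for a, y in zip(sub["marine_area"], sub["year"])
    ]
    sub["lag1"] = pd.Series(lag, index=sub.index).fillna(lookup.mean())
    return sub


def _forest(config: ImputationConfig, seed_offset: int = 0) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        random_state=(config.seed + seed_offset) % (2**32),
        n_jobs=1,
    )


def _fit_and_fill(
    series: AreaSeries,
    category: str,
    config: ImputationConfig,
    extra_features: list[str] | None = None,
    frame_with_extras: pd.DataFrame | None = None,
) -> dict:
    """Shared train / evaluate / fill logic for one target category."""
    frame = series.frame if frame_with_extras is None else frame_with_extras
    sub = frame[frame["category"] == category]
    if config.use_lag_features and not extra_features:
        sub = _add_lag(sub, series.frame, category)
        extra_features = ["lag1"]
    obs = sub[sub["status"] == "observed"]
    gaps = sub[sub["status"] == "missing"]
    report = {
        "category": category,
        "n_observed": len(obs),
        "n_imputed": 0,
        "n_test": 0,
        "rmse": np.nan,
        "r2": np.nan,
    }
    if gaps.empty:
        return report

    X_obs = _features(obs, series.areas, extra_features)
    y_mean = obs["mean"].to_numpy(float)
    y_sd = obs["sd"].to_numpy(float)

    # Held-out accuracy on 10% of observed cells.
    train_idx, test_idx = split_cells(np.arange(len(obs)), config)
    if len(test_idx) >= 1 and len(train_idx) >= 1:
        eval_forest = _forest(config, seed_offset=1)
        eval_forest.fit(X_obs[train_idx], y_mean[train_idx])
        pred = eval_forest.predict(X_obs[test_idx])
        report["n_test"] = len(test_idx)
        report["rmse"] = float(np.sqrt(mean_squared_error(y_mean[test_idx], pred)))
        report["r2"] = (
            float(r2_score(y_mean[test_idx], pred)) if len(test_idx) > 1 else np.nan
        )

    X_gap = _features(gaps, series.areas, extra_features)
    mean_forest = _forest(config)
    mean_forest.fit(X_obs, y_mean)
    filled_mean = mean_forest.predict(X_gap)
    if np.any(y_sd > 0):
        sd_forest = _forest(config, seed_offset=2)
        sd_forest.fit(X_obs, y_sd)
        filled_sd = np.maximum(sd_forest.predict(X_gap), 0.0)
    elif np.all(y_sd == 0):
        filled_sd = np.zeros(len(gaps))
    else:
        filled_sd = SD_IMPUTATION_FRACTION * filled_mean

    series.frame.loc[gaps.index, "mean"] = filled_mean
    series.frame.loc[gaps.index, "sd"] = filled_sd
    series.frame.loc[gaps.index, "status"] = "imputed"
    report["n_imputed"] = len(gaps)
    return report


def impute_within_category(
    series: AreaSeries, category: str, config: ImputationConfig
) -> dict:
    """Fill one of Level 2 / Level 3 by direct within-category interpolation.

    Mutates ``series`` in place (observed cells untouched) and returns the
    accuracy report for the category. Raises if the category has no observed
    cells; skips with a warning below ``config.min_cells``.
    """
    if category not in WITHIN_CATEGORIES:
        raise ValueError(f"within-category imputation applies to {WITHIN_CATEGORIES}")
    sub = series.frame[series.frame["category"] == category]
    obs = sub[sub["status"] == "observed"]
    if obs.empty:
        raise ValueError(
            f"{category} has no observed cells; use the national-stage fallback"
        )
    if obs["year"].nunique() < 2:
        raise ValueError(f"{category} needs observed cells in at least 2 years")
    if len(obs) < config.min_cells:
        warnings.warn(
            f"{category}: only {len(obs)} observed cells (< {config.min_cells}); "
            "imputation skipped, gaps left for the fallback",
            stacklevel=2,
        )
        return {
            "category": category,
            "n_observed": len(obs),
            "n_imputed": 0,
            "n_test": 0,
            "rmse": np.nan,
            "r2": np.nan,
        }
    return _fit_and_fill(series, category, config)


def impute_cross_category(
    series: AreaSeries, target: str, config: ImputationConfig
) -> dict:
    """Fill Level 1 / Level 4 / OSE from the completed Level 2/3 surfaces.

    Requires the Level 2 and Level 3 surfaces to be gap-free; if only one of
    them is complete the other is dropped from the feature set (with a
    warning) rather than aborting the fill. If the target has no observed
    cells at all, its cells stay missing (the national stage falls back to
    geometric means) and the report says so.
    """
    if target not in CROSS_CATEGORIES:
        raise ValueError(f"cross-category imputation applies to {CROSS_CATEGORIES}")
    predictors = []
    for predictor in WITHIN_CATEGORIES:
        psub = series.frame[series.frame["category"] == predictor]
        if (psub["status"] == "missing").any():
            warnings.warn(
                f"{predictor} surface incomplete; dropped as a cross-category "
                "predictor",
                stacklevel=2,
            )
        else:
            predictors.append(predictor)
    if not predictors:
        raise ValueError(
            "no complete predictor surface; run within-category imputation first"
        )

    frame = series.frame.copy()
    keys = list(zip(frame["marine_area"], frame["year"]))
    feature_names = []
    for predictor in predictors:
        surface = series.frame[series.frame["category"] == predictor].set_index(
            ["marine_area", "year"]
        )["mean"]
        name = predictor.replace(" ", "").lower() + "_mean"
        frame[name] = surface.reindex(keys).to_numpy()
        feature_names.append(name)

    obs = frame[(frame["category"] == target) & (frame["status"] == "observed")]
    if obs.empty:
        logger.warning("%s has no observed cells; left to the fallback", target)
        return {
            "category": target,
            "n_observed": 0,
            "n_imputed": 0,
            "n_test": 0,
            "rmse": np.nan,
            "r2": np.nan,
        }
    return _fit_and_fill(
        series,
        target,
        config,
        extra_features=feature_names,
        frame_with_extras=frame,
    )


def impute_all(
    series: AreaSeries, config: ImputationConfig
) -> tuple[AreaSeries, pd.DataFrame]:
    """Run both imputation passes over a copy of the series.

    Returns the filled series and the per-category accuracy report. Cells
    that remain missing (sparse categories below the minimum) are left for
    the national-stage fallback.
    """
    filled = AreaSeries(
        frame=series.frame.copy(),
        areas=series.areas,
        categories=series.categories,
        years=series.years,
    )
    reports = []

    def _empty_report(category: str, n_obs: int) -> dict:
        return {
            "category": category,
            "n_observed": n_obs,
            "n_imputed": 0,
            "n_test": 0,
            "rmse": np.nan,
            "r2": np.nan,
        }

    for category in WITHIN_CATEGORIES:
        try:
            reports.append(impute_within_category(filled, category, config))
        except ValueError as err:
            logger.warning("%s: %s; gaps left for the fallback", category, err)
            n_obs = int(
                (
                    (filled.frame["category"] == category)
                    & (filled.frame["status"] == "observed")
                ).sum()
            )
            reports.append(_empty_report(category, n_obs))
    for target in CROSS_CATEGORIES:
        try:
            reports.append(impute_cross_category(filled, target, config))
        except ValueError as err:
            logger.warning("%s: %s; gaps left for the fallback", target, err)
            n_obs = int(
                (
                    (filled.frame["category"] == target)
                    & (filled.frame["status"] == "observed")
                ).sum()
            )
            reports.append(_empty_report(target, n_obs))
    return filled, pd.DataFrame(reports)
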