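"""Catch-weighted national aggregation with geometric-mean fallback.

A nation's seafood MeHg concentration is the capture-volume-weighted average
of the areas it fishes,

    C_nation = sum_j(C_area_j * F_j) / sum_j(F_j),

where F_j is the nation's catch of that seafood category in FAO area j that
year. Nation-years with no usable catch (zero volumes, or volumes only in
areas with no concentration value) fall back hierarchically: the geometric
mean of the catch-weighted values of same-continent nations, then of all
nations. National SDs are propagated by Monte Carlo — each contributing
area concentration is resampled from its (mean, SD) positive-support
distribution and the weighted mean recomputed per draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .convert import MonteCarloSettings, sample_positive
from .marine import AreaSeries

#: capture.csv interchange schema.
CAPTURE_COLUMNS = ("nation", "iso3", "marine_area", "category", "year", "volume")


@dataclass
class NationSeries:
    """The nation x category x year grid of national MeHg values.

    One row per cell: ``category``, ``nation``, ``iso3``, ``year``, ``mean``,
    ``sd``, ``provenance`` in {catch_weighted, continent_geomean,
    global_geomean}.
    """

    frame: pd.DataFrame

    def pivot(self, category: str, value: str = "mean") -> pd.DataFrame:
        sub = self.frame[self.frame["category"] == category]
        return sub.pivot(index="nation", columns="year", values=value)


def load_continent_map(path=None) -> dict[str, str]:
    """Load an ISO3 -> continent mapping.

    With no path, the packaged static table (major fishing nations; editable
    by supplying your own file) is used. The file needs columns ``iso3`` and
    ``continent``.
    """
    if path is None:
        with resources.files("seamehg.data").joinpath("continents.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    return dict(zip(table["iso3"].astype(str), table["continent"].astype(str)))


def catch_weighted_mean(means, volumes) -> float:
    """Volume-weighted mean of area concentrations; volumes must sum > 0."""
    means = np.asarray(means, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    total = volumes.sum()
    if total <= 0:
        raise ValueError("total catch volume must be positive")
    return float(np.sum(means * volumes) / total)


def geometric_fallback(values: np.ndarray) -> float:
    """Geometric mean of peer national values (all strictly positive)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no peer values available for geometric fallback")
    return float(gmean(values))


def propagate_uncertainty(
    means,
    sds,
    volumes,
    settings: MonteCarloSettings,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte Carlo SD of the catch-weighted mean.

    Each draw resamples every contributing area concentration from its
    (mean, SD) distribution and recomputes the weighted mean; the national SD
    is the SD of the draws. All-zero area SDs give exactly zero.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.all(sds == 0):
        return 0.0
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    draws = sample_positive(
        rng,
        means[None, :],
        sds[None, :],
        (settings.n_draws, means.size),
        settings.distribution_family,
    )
    w = volumes / volumes.sum()
    weighted = draws @ w
    return float(np.std(weighted, ddof=1))


def build_nation_series(
    area_series: AreaSeries,
    catch: pd.DataFrame,
    continent_map: dict[str, str] | None = None,
    settings: MonteCarloSettings | None = None,
) -> tuple[NationSeries, dict]:
    """Aggregate the filled area grid to national values for every nation.

    Pass 1 computes catch-weighted values wherever a nation has positive
    catch in areas carrying a concentration (observed or imputed). Pass 2
    fills the remaining nation-cells with the continent, then global,
    geometric mean of pass-1 values for the same category and year. A cell
    with no values anywhere in the world is a hard error: the pipeline
    cannot produce output for it.

    Returns the series and a tally of provenance counts.
    """
    settings = settings or MonteCarloSettings()
    continent_map = continent_map if continent_map is not None else load_continent_map()
    rng = np.random.default_rng(settings.seed)

    nations = catch[["nation", "iso3"]].drop_duplicates().sort_values("nation")
    unmapped = sorted(set(nations["iso3"]) - set(continent_map))
    if unmapped:
        raise ValueError(
            "nations missing from the continent map: " + ", ".join(unmapped)
        )

    grid = area_series.frame.set_index(["category", "marine_area", "year"])
    has_value = grid["mean"].notna()
    catch_by_cell = {
        key: grp
        for key, grp in catch.groupby(["iso3", "category", "year"], sort=False)
    }

    rows = []
    for nation, iso3 in nations.itertuples(index=False):
        for category in area_series.categories:
            for year in area_series.years:
                entry = {
                    "category": category,
                    "nation": nation,
                    "iso3": iso3,
                    "year": year,
                    "mean": np.nan,
                    "sd": np.nan,
                    "provenance": "pending",
                }
                cell_catch = catch_by_cell.get((iso3, category, year))
                if cell_catch is not None:
                    keys = [
                        (category, a, year) for a in cell_catch["marine_area"]
                    ]
                    usable = np.array(
                        [k in grid.index and bool(has_value.get(k, False)) for k in keys]
                    )
                    vols = cell_catch["volume"].to_numpy(float)
                    usable &= vols > 0
                    if usable.any():
                        means = np.array(
                            [grid.loc[k, "mean"] for k, u in zip(keys, usable) if u]
                        )
                        sds = np.array(
                            [grid.loc[k, "sd"] for k, u in zip(keys, usable) if u]
                        )
                        v = vols[usable]
                        entry["mean"] = catch_weighted_mean(means, v)
                        entry["sd"] = propagate_uncertainty(
                            means, np.nan_to_num(sds), v, settings, rng
                        )
                        entry["provenance"] = "catch_weighted"
                rows.append(entry)

    frame = pd.DataFrame(rows)

    # Pass 2: hierarchical geometric-mean fallback for pending cells.
    frame["continent"] = frame["iso3"].map(continent_map)
    weighted = frame[frame["provenance"] == "catch_weighted"]
    pending = frame.index[frame["provenance"] == "pending"]
    for idx in pending:
        cat = frame.at[idx, "category"]
        year = frame.at[idx, "year"]
        continent = frame.at[idx, "continent"]
        peers = weighted[(weighted["category"] == cat) & (weighted["year"] == year)]
        same = peers[peers["continent"] == continent]
        if len(same):
            pool, provenance = same, "continent_geomean"
        elif len(peers):
            pool, provenance = peers, "global_geomean"
        else:
            raise ValueError(
                f"no national values exist anywhere for category {cat!r}, "
                f"year {year}; cannot build output"
            )
        frame.at[idx, "mean"] = geometric_fallback(pool["mean"].to_numpy())
        sds = pool["sd"].to_numpy(float)
        frame.at[idx, "sd"] = (
            geometric_fallback(sds) if np.all(sds > 0) else float(np.mean(sds))
        )
        frame.at[idx, "provenance"] = provenance

    frame = frame.drop(columns="continent")
    tally = frame["provenance"].value_counts().to_dict()
    return NationSeries(frame=frame), tally
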