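"""Sample-size-weighted aggregation of records to the FAO-area grid.

Study-level MeHg distributions are collapsed to one (mean, SD) per
(category, marine area, year) cell. Studies report means of m samples, so the
cell mean is the sample-size-weighted average of study means,

    C_cell = sum_i(C_i * m_i) / sum_i(m_i),

with missing sample sizes already defaulted to 1 upstream. The cell SD pools
within-study variance and between-study dispersion with the same weights:

    var_cell = sum_i m_i * (sd_i^2 + (C_i - C_cell)^2) / sum_i m_i,

which reduces to the study SD when the cell holds a single study. The grid
spans the configured areas x five categories x years (1995-2022 by default);
cells without any record are marked ``missing`` for the imputation stage, and
records dated before the window are excluded but counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CATEGORIES

#: First year of the long-term series.
DEFAULT_YEAR_START = 1995
#: Last year of the long-term series.
DEFAULT_YEAR_END = 2022


@dataclass
class AreaSeries:
    """The area x category x year concentration grid.

    ``frame`` holds one row per cell with columns ``category``,
    ``marine_area``, ``year``, ``mean``, ``sd``, ``n_records`` and ``status``
    (observed / imputed / missing). Means and SDs are ng/g wet weight; means
    are NaN only for missing cells.
    """

    frame: pd.DataFrame
    areas: tuple[str, ...]
    categories: tuple[str, ...]
    years: tuple[int, ...]

    def pivot(self, category: str, value: str = "mean") -> pd.DataFrame:
        """Return one category's surface as an area x year table."""
        sub = self.frame[self.frame["category"] == category]
        return sub.pivot(index="marine_area", columns="year", values=value).reindex(
            index=list(self.areas), columns=list(self.years)
        )


def weighted_mean_cell(
    means, sds, ns
) -> tuple[float, float, int]:
    """Collapse the studies of one cell to (mean, pooled SD, record count).

    Weights are study sample sizes. The pooled SD combines within-study
    variance and squared deviation of study means from the cell mean, both
    weighted by sample size.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if means.size == 0:
        raise ValueError("cell has no records")
    w = ns / ns.sum()
    mean = float(np.sum(w * means))
    var = float(np.sum(w * (sds**2 + (means - mean) ** 2)))
    return mean, float(np.sqrt(max(var, 0.0))), int(means.size)


def build_area_series(
    records: pd.DataFrame,
    areas: tuple[str, ...] | None = None,
    categories: tuple[str, ...] = CATEGORIES,
    year_start: int = DEFAULT_YEAR_START,
    year_end: int = DEFAULT_YEAR_END,
) -> tuple[AreaSeries, dict]:
    """Aggregate converted records into the complete area grid.

    Parameters
    ----------
    records
        Converted, standardized records (columns ``category``,
        ``marine_area``, ``year``, ``mean``, ``sd``, ``n``).
    areas
        Grid areas; defaults to the areas present in the records.

    Returns
    -------
    (series, coverage)
        ``coverage`` reports observed / missing cell counts and the number of
        record-rows dated before ``year_start`` (excluded from the grid).
    """
    if areas is None:
        areas = tuple(sorted(records["marine_area"].unique()))
    years = tuple(range(year_start, year_end + 1))

    in_window = records[(records["year"] >= year_start) & (records["year"] <= year_end)]
    pre_window = int((records["year"] < year_start).sum())

    cells = {}
    for key, grp in in_window.groupby(["category", "marine_area", "year"], sort=False):
        cells[key] = weighted_mean_cell(
            grp["mean"].to_numpy(), grp["sd"].to_numpy(), grp["n"].to_numpy()
        )

    rows = []
    for cat in categories:
        for area in areas:
            for year in years:
                cell = cells.get((cat, area, year))
                if cell is None:
                    rows.append((cat, area, year, np.nan, np.nan, 0, "missing"))
                else:
                    rows.append((cat, area, year, *cell, "observed"))
    frame = pd.DataFrame(
        rows,
        columns=["category", "marine_area", "year", "mean", "sd", "n_records", "status"],
    )
    coverage = {
        "observed_cells": int((frame["status"] == "observed").sum()),
        "missing_cells": int((frame["status"] == "missing").sum()),
        "pre_window_rows": pre_window,
    }
    return AreaSeries(frame=frame, areas=tuple(areas), categories=tuple(categories), years=years), coverage
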