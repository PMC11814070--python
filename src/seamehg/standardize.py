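"""Screening and standardization of literature concentration records.

Raw records arrive as one row per reported concentration (a study x species x
area x period observation) with heterogeneous units, weight bases and missing
metadata. This module applies the screening criteria — duplicates, point-source
pollution, non-muscle tissue, unidentified marine area, unspecified weight
basis, below-detection-limit values, and an interquartile-range outlier pass —
and standardizes every surviving record to ng/g wet weight with a complete
(mean, sd, n, year, area, category) tuple.

Standardization rules applied here:

* all units converted to ng/g (ppm = ug/g, ppb = ug/kg = ng/g);
* dry weight converted to wet weight assuming 80% tissue water content,
  ``WW = (1 - 0.8) * DW``;
* missing standard deviations imputed as 65% of the reported mean;
* missing sampling years imputed as publication year minus two;
* a record reporting one value for a multi-year period is expanded to one
  record per calendar year, each carrying the identical distribution;
* missing sample sizes default to 1 so poorly documented studies carry the
  minimum weight in the later sample-size-weighted aggregation.

Records are handled as pandas DataFrames in the ``records.csv`` schema
(:data:`RECORD_COLUMNS`); rejections are logged one row per record with the
first matching reason.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .classify import assign_trophic_category, validate_area

#: Canonical column order of the raw-records interchange schema.
RECORD_COLUMNS = (
    "study_id",
    "species_name",
    "trophic_level",
    "group",
    "marine_area",
    "sampling_year_start",
    "sampling_year_end",
    "publication_year",
    "tissue",
    "weight_basis",
    "unit",
    "analyte",
    "mean_value",
    "sd_value",
    "sample_size",
    "polluted_site",
    "below_lod",
)

#: Assumed water content of seafood tissue: wet weight = (1 - 0.8) x dry weight.
WATER_CONTENT = 0.8

#: Missing standard deviations are imputed as this fraction of the mean.
SD_IMPUTATION_FRACTION = 0.65

#: Missing sampling years are imputed as publication year minus this offset.
PUBLICATION_YEAR_OFFSET = 2

# Multiplicative factors to ng/g. ppm is synonymous with ug/g, ppb with ug/kg,
# and ug/kg with ng/g. Both the micro sign and plain "u" spellings parse.
_UNIT_FACTORS = {
    "ng/g": 1.0,
    "µg/g": 1000.0,
    "ug/g": 1000.0,
    "µg/kg": 1.0,
    "ug/kg": 1.0,
    "mg/kg": 1000.0,
    "ppm": 1000.0,
    "ppb": 1.0,
}

#: Units accepted on input records.
SUPPORTED_UNITS = tuple(_UNIT_FACTORS)

#: Rejection reasons in the order the filters run.
REJECTION_REASONS = (
    "duplicate",
    "polluted_site",
    "non_muscle",
    "unknown_area",
    "unspecified_weight",
    "below_lod",
    "missing_trophic",
    "outlier",
)


class UnitError(ValueError):
    """An input record carries a concentration unit outside the supported set."""


@dataclass(frozen=True)
class ConcentrationDistribution:
    """One study-level concentration estimate in ng/g wet weight.

    ``n`` is the study sample size, used downstream as the aggregation weight.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


def convert_units(value, unit: str):
    """Convert a concentration from ``unit`` to ng/g.

    Accepts scalars or numpy arrays. Raises :class:`UnitError` for units
    outside :data:`SUPPORTED_UNITS`.
    """
    try:
        factor = _UNIT_FACTORS[str(unit).strip()]
    except KeyError:
        raise UnitError(
            f"unrecognised concentration unit {unit!r}; supported: "
            + ", ".join(("ng/g", "µg/g", "µg/kg", "mg/kg", "ppm", "ppb"))
        ) from None
    return value * factor


def dry_to_wet(value_dw):
    """Convert ng/g dry weight to ng/g wet weight assuming 80% water content."""
    return (1.0 - WATER_CONTENT) * value_dw


def impute_sd(mean: float) -> float:
    """Impute a missing standard deviation as 65% of the mean."""
    return SD_IMPUTATION_FRACTION * mean


def impute_sampling_year(publication_year: int) -> int:
    """Impute a missing sampling year as two years before publication."""
    return int(publication_year) - PUBLICATION_YEAR_OFFSET


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and not x.strip():
        return True
    return pd.isna(x)


def _ensure_record_ids(records: pd.DataFrame) -> pd.DataFrame:
    if "record_id" not in records.columns:
        records = records.copy()
        records.insert(0, "record_id", np.arange(len(records)))
    return records


def apply_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the substantive screening criteria to raw records.

    Drops, in order: exact duplicates (same study, species, area, sampling
    period, analyte and value), records from point-source-polluted sites,
    non-muscle tissues, unidentifiable marine areas, unspecified weight basis,
    and below-detection-limit values. Each rejected record is logged once with
    the first reason that matched.

    Returns
    -------
    (kept, rejections)
        ``kept`` retains the input schema plus ``record_id``; ``rejections``
        has columns ``record_id`` and ``reason``. The two partition the input.
    """
    records = _ensure_record_ids(records)
    kept = records
    rejected: list[pd.DataFrame] = []

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal kept
        hit = kept.loc[mask, ["record_id"]].copy()
        hit["reason"] = reason
        rejected.append(hit)
        kept = kept.loc[~mask]

    dup_keys = [
        "study_id",
        "species_name",
        "marine_area",
        "sampling_year_start",
        "sampling_year_end",
        "analyte",
        "mean_value",
    ]
    _drop(kept.duplicated(subset=dup_keys, keep="first"), "duplicate")
    _drop(kept["polluted_site"].fillna(False).astype(bool), "polluted_site")
    _drop(kept["tissue"].astype("string").str.strip() == "non_muscle", "non_muscle")
    _drop(
        kept["marine_area"].map(lambda a: validate_area(a) is None),
        "unknown_area",
    )
    basis = kept["weight_basis"].astype("string").str.strip().fillna("")
    _drop(~basis.isin(["wet", "dry"]), "unspecified_weight")
    _drop(kept["below_lod"].fillna(False).astype(bool), "below_lod")

    log = (
        pd.concat(rejected, ignore_index=True)
        if rejected
        else pd.DataFrame(columns=["record_id", "reason"])
    )
    assert len(kept) + len(log) == len(records)
    return kept.reset_index(drop=True), log


def standardize_records(
    records: pd.DataFrame,
    trophic_lookup: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize filtered records to ng/g wet weight with complete fields.

    Each surviving input row yields one output row per calendar year of its
    sampling period (inclusive), all carrying the same distribution. Fish
    records missing a trophic level are resolved through the optional
    ``trophic_lookup`` (columns ``species_name``, ``trophic_level``); records
    that cannot be resolved either way are rejected with reason
    ``missing_trophic``.

    Returns
    -------
    (standardized, rejections)
        ``standardized`` columns: record_id, row_id, study_id, species_name,
        group, category, marine_area, year, mean, sd, n, sd_imputed,
        year_imputed, analyte.
    """
    records = _ensure_record_ids(records)
    lookup: dict[str, float] = {}
    if trophic_lookup is not None:
        lookup = dict(
            zip(trophic_lookup["species_name"], trophic_lookup["trophic_level"])
        )

    rows: list[dict] = []
    rejected: list[dict] = []
    for rec in records.itertuples(index=False):
        area = validate_area(rec.marine_area)
        if area is None:  # apply_filters should have caught this
            rejected.append({"record_id": rec.record_id, "reason": "unknown_area"})
            continue

        if rec.group == "other_seafood":
            category = "OSE"
        else:
            tl = rec.trophic_level
            if _is_missing(tl):
                tl = lookup.get(rec.species_name)
            if tl is None or _is_missing(tl):
                rejected.append(
                    {"record_id": rec.record_id, "reason": "missing_trophic"}
                )
                continue
            category = assign_trophic_category(float(tl))

        mean = convert_units(float(rec.mean_value), rec.unit)
        sd_missing = _is_missing(rec.sd_value)
        sd = impute_sd(mean) if sd_missing else convert_units(float(rec.sd_value), rec.unit)
        if str(rec.weight_basis).strip() == "dry":
            mean = dry_to_wet(mean)
            sd = dry_to_wet(sd)

        start_missing = _is_missing(rec.sampling_year_start)
        end_missing = _is_missing(rec.sampling_year_end)
        if start_missing and end_missing:
            year_start = year_end = impute_sampling_year(rec.publication_year)
            year_imputed = True
        else:
            year_start = int(rec.sampling_year_end if start_missing else rec.sampling_year_start)
            year_end = int(rec.sampling_year_start if end_missing else rec.sampling_year_end)
            year_imputed = False

        n = 1 if _is_missing(rec.sample_size) else int(rec.sample_size)
        for year in range(year_start, year_end + 1):
            rows.append(
                {
                    "record_id": rec.record_id,
                    "study_id": rec.study_id,
                    "species_name": rec.species_name,
                    "group": rec.group,
                    "category": category,
                    "marine_area": area,
                    "year": year,
                    "mean": mean,
                    "sd": sd,
                    "n": n,
                    "sd_imputed": sd_missing,
                    "year_imputed": year_imputed,
                    "analyte": rec.analyte,
                }
            )

    std = pd.DataFrame(rows)
    if not std.empty:
        std.insert(1, "row_id", np.arange(len(std)))
    rej = pd.DataFrame(rejected, columns=["record_id", "reason"])
    return std, rej


def expand_period(record: pd.Series) -> pd.DataFrame:
    """Expand one standardized-input row over its sampling period.

    Convenience wrapper over :func:`standardize_records` for a single record;
    returns one row per calendar year in the inclusive range.
    """
    std, rej = standardize_records(pd.DataFrame([record]))
    if len(rej):
        raise ValueError(f"record rejected during standardization: {rej.iloc[0]['reason']}")
    return std


def remove_outliers(
    standardized: pd.DataFrame,
    fraction: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove the configured fraction of outliers per (group, category) stratum.

    Within each stratum the interquartile-range rule defines an outlier score:
    the exceedance of a record's mean beyond the Tukey fences
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (zero inside the fences). Exactly
    ``floor(fraction * stratum size)`` records with the largest scores are
    removed; score ties break by larger absolute distance from the stratum
    median, then by row id — so the removal set is deterministic.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError(f"outlier fraction must be in [0, 0.5), got {fraction}")
    if standardized.empty:
        return standardized, pd.DataFrame(columns=["record_id", "reason"])

    drop_rows: list[int] = []
    for _, grp in standardized.groupby(["group", "category"], sort=False):
        k = int(math.floor(fraction * len(grp)))
        if k == 0:
            continue
        x = grp["mean"].to_numpy(float)
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        score = np.maximum(0.0, np.maximum(lo - x, x - hi))
        dist = np.abs(x - np.median(x))
        order = sorted(
            range(len(grp)),
            key=lambda i: (-score[i], -dist[i], grp["row_id"].iat[i]),
        )
        drop_rows.extend(grp.index[order[:k]])

    dropped = standardized.loc[drop_rows]
    log = pd.DataFrame(
        {"record_id": dropped["record_id"].to_numpy(), "reason": "outlier"},
        columns=["record_id", "reason"],
    )
    kept = standardized.drop(index=drop_rows).reset_index(drop=True)
    return kept, log
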