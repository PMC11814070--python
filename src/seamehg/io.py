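"""Reading and validating the delimited-text interchange files.

Canonical formats are UTF-8 CSV with a header row: ``records.csv`` (one raw
literature record per row, :data:`seamehg.standardize.RECORD_COLUMNS`),
``capture.csv`` (nation x area x category x year capture volumes,
:data:`seamehg.national.CAPTURE_COLUMNS`), an optional species-to-trophic
lookup, and an optional nation table with ISO3 codes and continents.
Spreadsheet (.xlsx) input is accepted read-only for records, for parity with
raw-data deposits.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .national import CAPTURE_COLUMNS
from .standardize import RECORD_COLUMNS


class SchemaError(ValueError):
    """An interchange file violates its schema."""


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_records(path) -> pd.DataFrame:
    """Read and validate a raw-records file.

    Empty strings become missing values. Mandatory per-row fields are
    ``publication_year`` and a positive ``mean_value`` (unless the record is
    below the detection limit); violations raise :class:`SchemaError` naming
    the offending line numbers (1-based, header = line 1). A header-only
    file returns an empty frame with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = _read_table(path)
    missing_cols = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns: {missing_cols}")
    if frame.empty:
        warnings.warn(f"{path}: no records (header only)", stacklevel=2)
        return frame

    bad_lines: list[str] = []
    no_pub = frame["publication_year"].isna()
    for idx in frame.index[no_pub]:
        bad_lines.append(f"line {idx + 2}: missing publication_year")
    below = frame["below_lod"].fillna(False).astype(bool)
    bad_value = ~below & ~(frame["mean_value"] > 0)
    for idx in frame.index[bad_value]:
        bad_lines.append(f"line {idx + 2}: mean_value must be positive")
    both_years = frame["sampling_year_start"].notna() & frame["sampling_year_end"].notna()
    inverted = both_years & (frame["sampling_year_start"] > frame["sampling_year_end"])
    for idx in frame.index[inverted]:
        bad_lines.append(f"line {idx + 2}: sampling_year_start > sampling_year_end")
    if bad_lines:
        raise SchemaError(f"{path}: malformed rows:\n  " + "\n  ".join(bad_lines))
    return frame


def read_capture(path) -> pd.DataFrame:
    """Read and validate a capture-volume file (volumes must be >= 0)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = _read_table(path)
    missing_cols = [c for c in CAPTURE_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns: {missing_cols}")
    if (frame["volume"] < 0).any():
        raise SchemaError(f"{path}: capture volumes must be non-negative")
    return frame


def read_trophic_lookup(path) -> pd.DataFrame:
    """Read an optional species -> trophic level lookup table."""
    frame = _read_table(Path(path))
    for col in ("species_name", "trophic_level"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return frame


def read_nation_table(path) -> pd.DataFrame:
    """Read a nation table (nation, iso3, optionally continent)."""
    frame = _read_table(Path(path))
    for col in ("nation", "iso3"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return frame
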