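"""Synthetic literature records and capture tables with known ground truth.

Every pipeline stage is exercised against data generated from a latent truth
surface: one log-linear MeHg trajectory per (FAO area, seafood category),
with higher trophic categories receiving higher baselines by construction
(Level 4 > Level 3 > Level 2 > Level 1 > OSE), mirroring biomagnification.
Study-level records perturb the truth with log-normal between-study noise and
are then deliberately "messied" the way real literature records are: reported
on a dry-weight basis, in mixed units, as total mercury rather than
methylmercury, with missing SDs / sample sizes / sampling years, from
polluted sites, from non-muscle tissue, below detection limits, or with
unidentifiable areas. Each corruption is exactly invertible or exactly
detectable, so downstream recovery can be checked against the truth.

Dry-weight rendering multiplies the wet-weight value by 5 (the inverse of the
80%-water-content conversion); THg rendering inverts the group's log-log
conversion, so the conversion stage recovers MeHg exactly in the noiseless
limit. The five corruptions targeted by the screening filters (pollution,
non-muscle tissue, unknown area, unspecified weight basis, below-LOD) are
mutually exclusive per record, so each filter's rejection set can be compared
one-to-one with the corrupted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import CATEGORIES, FAO_AREAS, FISH_LEVELS
from .convert import DEFAULT_COEFFICIENTS
from .standardize import RECORD_COLUMNS, WATER_CONTENT

#: Default (geometric) baseline concentrations, ng/g wet weight, ordered by
#: bioaccumulation: apex predators carry roughly an order of magnitude more
#: MeHg than low-trophic fish and invertebrates.
DEFAULT_BASELINES = {
    "OSE": 30.0,
    "Level 1": 50.0,
    "Level 2": 80.0,
    "Level 3": 150.0,
    "Level 4": 300.0,
}

_CONTINENT_CYCLE = (
    "Asia",
    "Europe",
    "Africa",
    "North America",
    "South America",
    "Oceania",
)

#: Trophic mid-bin used when sampling a species' level for each fish category.
_TROPHIC_RANGES = {
    "Level 1": (1.5, 2.5),
    "Level 2": (2.5, 3.5),
    "Level 3": (3.5, 4.5),
    "Level 4": (4.5, 5.5),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Corruption rates are per-record probabilities; the five substantive ones
    (polluted / non-muscle / unknown-area / unspecified-weight / below-LOD)
    are drawn exclusively, the rest independently. ``noise_sd`` is the
    log-scale between-study SD and also sets the reported within-study
    coefficient of variation, so ``noise_sd = 0`` yields an exactly
    noise-free corpus. The seed fully determines the output.
    """

    n_studies: int = 500
    areas: tuple[str, ...] = FAO_AREAS[:5]
    categories: tuple[str, ...] = CATEGORIES
    year_start: int = 1995
    year_end: int = 2022
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    slope: float | None = None  # fixed annual log-slope; None draws per cell
    slope_mean: float = -0.01
    slope_sd: float = 0.008
    area_effect_sd: float = 0.2
    noise_sd: float = 0.3
    thg_fraction: float = 0.7
    period_rate: float = 0.15
    period_max_len: int = 5
    missing_sd_rate: float = 0.2
    missing_n_rate: float = 0.25
    missing_year_rate: float = 0.1
    dry_weight_rate: float = 0.15
    polluted_rate: float = 0.03
    non_muscle_rate: float = 0.03
    unknown_area_rate: float = 0.03
    unspecified_weight_rate: float = 0.02
    below_lod_rate: float = 0.02
    unit_mix: dict = field(
        default_factory=lambda: {
            "ng/g": 0.4,
            "µg/g": 0.15,
            "µg/kg": 0.15,
            "mg/kg": 0.1,
            "ppm": 0.1,
            "ppb": 0.1,
        }
    )
    n_nations: int = 8
    ensure_coverage: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not self.areas or not self.categories:
            raise ValueError("areas and categories must be non-empty")
        unknown_areas = set(self.areas) - set(FAO_AREAS)
        if unknown_areas:
            raise ValueError(f"unknown FAO areas: {sorted(unknown_areas)}")
        unknown_cats = set(self.categories) - set(CATEGORIES)
        if unknown_cats:
            raise ValueError(f"unknown categories: {sorted(unknown_cats)}")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        rates = {
            "thg_fraction": self.thg_fraction,
            "period_rate": self.period_rate,
            "missing_sd_rate": self.missing_sd_rate,
            "missing_n_rate": self.missing_n_rate,
            "missing_year_rate": self.missing_year_rate,
            "dry_weight_rate": self.dry_weight_rate,
            "polluted_rate": self.polluted_rate,
            "non_muscle_rate": self.non_muscle_rate,
            "unknown_area_rate": self.unknown_area_rate,
            "unspecified_weight_rate": self.unspecified_weight_rate,
            "below_lod_rate": self.below_lod_rate,
        }
        for name, rate in rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        exclusive = (
            self.polluted_rate
            + self.non_muscle_rate
            + self.unknown_area_rate
            + self.unspecified_weight_rate
            + self.below_lod_rate
        )
        if exclusive > 1.0:
            raise ValueError("exclusive corruption rates must sum to <= 1")
        if not self.unit_mix or any(w < 0 for w in self.unit_mix.values()):
            raise ValueError("unit_mix weights must be non-negative and non-empty")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.year_start, self.year_end + 1))


def clean_config(**overrides) -> SimulationConfig:
    """A noise-free, corruption-free configuration for exact-recovery tests.

    All corruption rates, the between-study noise, and period reporting are
    zero; units are pure ng/g; coverage of every grid cell is guaranteed.
    """
    defaults = dict(
        noise_sd=0.0,
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
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class TruthSurface:
    """The latent true MeHg surface the generator samples from.

    ``frame`` holds one row per (marine_area, category, year) with the true
    concentration in ng/g wet weight; ``trend`` holds the per-(area,
    category) log-intercept and annual log-slope.
    """

    frame: pd.DataFrame
    trend: pd.DataFrame
    noise_sd: float
    year_start: int

    def value(self, area: str, category: str, year: int) -> float:
        row = self.frame[
            (self.frame["marine_area"] == area)
            & (self.frame["category"] == category)
            & (self.frame["year"] == year)
        ]
        if row.empty:
            raise KeyError((area, category, year))
        return float(row["true_mehg"].iloc[0])


def generate_truth(config: SimulationConfig) -> TruthSurface:
    """Build one log-linear trajectory per (area, category).

    ln C(area, cat, year) = ln baseline[cat] + area_offset + slope * (year -
    year_start). Area offsets are shared across categories and centred at
    zero, so the trophic baseline ordering holds in every area (and a single
    -area config reproduces the baselines exactly).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    offsets = rng.normal(0.0, config.area_effect_sd, len(config.areas))
    offsets -= offsets.mean()

    trend_rows = []
    for offset, area in zip(offsets, config.areas):
        for cat in config.categories:
            if config.slope is not None:
                slope = float(config.slope)
            else:
                slope = float(rng.normal(config.slope_mean, config.slope_sd))
            trend_rows.append(
                {
                    "marine_area": area,
                    "category": cat,
                    "log_intercept": float(np.log(config.baselines[cat]) + offset),
                    "slope": slope,
                }
            )
    trend = pd.DataFrame(trend_rows)

    years = np.array(config.years)
    rows = []
    for t in trend.itertuples(index=False):
        values = np.exp(t.log_intercept + t.slope * (years - config.year_start))
        for year, v in zip(years, values):
            rows.append((t.marine_area, t.category, int(year), float(v)))
    frame = pd.DataFrame(rows, columns=["marine_area", "category", "year", "true_mehg"])
    assert (frame["true_mehg"] > 0).all()
    return TruthSurface(
        frame=frame, trend=trend, noise_sd=config.noise_sd, year_start=config.year_start
    )


def _mehg_to_thg(mehg: float, group_key: str) -> float:
    """Invert the group's log-log conversion (exact in the noiseless limit)."""
    slope, intercept = DEFAULT_COEFFICIENTS[group_key]
    return float(np.exp((np.log(mehg) - intercept) / slope))


def generate_literature_records(
    truth: TruthSurface, config: SimulationConfig
) -> pd.DataFrame:
    """Sample a literature-style record corpus from the truth surface.

    Returns a DataFrame in the records.csv schema. With
    ``config.ensure_coverage`` records cycle through the grid cells in order
    (so the corpus size is ``max(n_studies, n_cells)`` and coverage per cell
    is as even as possible); otherwise cells are sampled uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lookup = truth.frame.set_index(["marine_area", "category", "year"])["true_mehg"]
    cells = list(lookup.index)
    unit_names = list(config.unit_mix)
    unit_p = np.array([config.unit_mix[u] for u in unit_names], dtype=float)
    unit_p /= unit_p.sum()
    unit_factor = {"ng/g": 1.0, "µg/g": 1000.0, "µg/kg": 1.0, "mg/kg": 1000.0, "ppm": 1000.0, "ppb": 1.0}

    n_records = max(config.n_studies, len(cells)) if config.ensure_coverage else config.n_studies
    records = []
    for i in range(n_records):
        if config.ensure_coverage:
            area, cat, year = cells[i % len(cells)]
        else:
            area, cat, year = cells[rng.integers(len(cells))]
        is_fish = cat in FISH_LEVELS
        group = "marine_fish" if is_fish else "other_seafood"
        group_key = "FISH" if is_fish else "OSE"

        # Sampling period: a fraction of studies report one value for a span
        # of years (geometric-mean truth over the span).
        if config.period_rate > 0 and rng.random() < config.period_rate:
            length = int(rng.integers(2, config.period_max_len + 1))
            year_end = min(year + length - 1, config.year_end)
            span = [lookup[(area, cat, y)] for y in range(year, year_end + 1)]
            true_value = float(np.exp(np.mean(np.log(span))))
        else:
            year_end = year
            true_value = float(lookup[(area, cat, year)])

        noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        mehg_mean = true_value * float(np.exp(noise))
        mehg_sd = config.noise_sd * mehg_mean

        # Analyte: most studies report THg; render by inverting the group's
        # conversion so the downstream conversion recovers MeHg exactly.
        if rng.random() < config.thg_fraction:
            analyte = "THg"
            value = _mehg_to_thg(mehg_mean, group_key)
            slope, _ = DEFAULT_COEFFICIENTS[group_key]
            sd = mehg_sd * value / (slope * mehg_mean)  # local derivative scaling
        else:
            analyte = "MeHg"
            value, sd = mehg_mean, mehg_sd

        tissue, basis, rec_area, below_lod, polluted = "muscle", "wet", area, False, False
        u = rng.random()
        edge = config.polluted_rate
        if u < edge:
            polluted = True
            value *= float(rng.uniform(3.0, 10.0))
        elif u < (edge := edge + config.non_muscle_rate):
            tissue = "non_muscle"
        elif u < (edge := edge + config.unknown_area_rate):
            rec_area = ""
        elif u < (edge := edge + config.unspecified_weight_rate):
            basis = "unspecified"
        elif u < edge + config.below_lod_rate:
            below_lod = True
            value = 0.01

        if basis == "wet" and config.dry_weight_rate > 0 and rng.random() < config.dry_weight_rate:
            basis = "dry"
            factor = 1.0 / (1.0 - WATER_CONTENT)
            value *= factor
            sd *= factor

        unit = unit_names[rng.choice(len(unit_names), p=unit_p)]
        value /= unit_factor[unit]
        sd /= unit_factor[unit]

        missing_year = config.missing_year_rate > 0 and rng.random() < config.missing_year_rate
        if missing_year:
            year_end = year  # period information is lost with the year
            start_field = end_field = None
            publication_year = year + 2
        else:
            start_field, end_field = year, year_end
            publication_year = year_end + 2

        if is_fish:
            lo, hi = _TROPHIC_RANGES[cat]
            trophic = float(rng.uniform(lo, hi))
            # keep strictly inside the bin so binning is unambiguous
            trophic = min(max(trophic, lo + 1e-6), hi - 1e-6)
        else:
            trophic = None

        records.append(
            {
                "study_id": f"S{i:05d}",
                "species_name": f"{'Fish' if is_fish else 'Shellfish'}_{cat.replace(' ', '')}_{int(rng.integers(10))}",
                "trophic_level": trophic,
                "group": group,
                "marine_area": rec_area,
                "sampling_year_start": start_field,
                "sampling_year_end": end_field,
                "publication_year": publication_year,
                "tissue": tissue,
                "weight_basis": basis,
                "unit": unit,
                "analyte": analyte,
                "mean_value": value,
                "sd_value": None if (config.missing_sd_rate > 0 and rng.random() < config.missing_sd_rate) else sd,
                "sample_size": None if (config.missing_n_rate > 0 and rng.random() < config.missing_n_rate) else int(rng.integers(1, 51)),
                "polluted_site": polluted,
                "below_lod": below_lod,
            }
        )
    frame = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
    frame.insert(0, "record_id", np.arange(len(frame)))
    return frame


def _iso3(i: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return "Z" + letters[(i // 26) % 26] + letters[i % 26]


def generate_catch_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate nation x area x category x year capture volumes.

    Returns ``(capture, nations)`` where ``capture`` follows the capture.csv
    schema and ``nations`` maps nation name to synthetic ISO3 code and
    continent. By construction the first nation fishes a single area (its
    national value must equal that area's value) and the second nation
    reports all-zero catch (exercising the geometric-mean fallback).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    nations = pd.DataFrame(
        {
            "nation": [f"Nation_{i:02d}" for i in range(config.n_nations)],
            "iso3": [_iso3(i) for i in range(config.n_nations)],
            "continent": [
                _CONTINENT_CYCLE[i % len(_CONTINENT_CYCLE)]
                for i in range(config.n_nations)
            ],
        }
    )

    rows = []
    for i, (nation, iso3, _) in enumerate(nations.itertuples(index=False)):
        if i == 0:
            fished = [config.areas[0]]
        elif i == 1:
            fished = list(config.areas)  # rows present, volumes all zero
        else:
            k = int(rng.integers(1, len(config.areas) + 1))
            fished = list(rng.choice(config.areas, size=k, replace=False))
        for cat in config.categories:
            base = {area: float(np.exp(rng.normal(9.0, 1.0))) for area in fished}
            for year in config.years:
                for area in fished:
                    volume = 0.0 if i == 1 else base[area] * float(
                        np.exp(rng.normal(0.0, 0.2))
                    )
                    rows.append((nation, iso3, area, cat, year, volume))
    capture = pd.DataFrame(
        rows, columns=["nation", "iso3", "marine_area", "category", "year", "volume"]
    )
    return capture, nations


def write_fixtures(
    records: pd.DataFrame,
    capture: pd.DataFrame,
    nations: pd.DataFrame,
    truth: TruthSurface,
    directory,
) -> dict[str, Path]:
    """Write the fixture file set (records, capture, nation ids, truth).

    The truth file is not a pipeline input; it exists so recovery tests can
    compare pipeline output against the latent surface.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": directory / "records.csv",
        "capture": directory / "capture.csv",
        "nation_id": directory / "nation_id.csv",
        "truth": directory / "truth.csv",
    }
    records.to_csv(paths["records"], index=False)
    capture.to_csv(paths["capture"], index=False)
    nations.to_csv(paths["nation_id"], index=False)
    truth.frame.to_csv(paths["truth"], index=False)
    return paths
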