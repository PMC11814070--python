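"""THg-to-MeHg conversion with Monte Carlo uncertainty propagation.

Most literature records report total mercury (THg) rather than methylmercury.
The pipeline converts them with group-specific log-log regressions,

    marine fishes (FISH):   MeHg = exp(ln(THg) - 0.23)
    other seafoods (OSE):   MeHg = exp(0.94 * ln(THg) - 0.47)

i.e. a power law ``MeHg = e^intercept * THg^slope`` with the printed default
coefficients above. Because only (mean, SD) summaries are available per study,
uncertainty is propagated by Monte Carlo: THg is drawn 10,000 times from a
positive-support distribution moment-matched to the reported (mean, SD), each
draw is mapped through the regression, and the converted distribution is
summarised by the sample mean and SD of the mapped draws.

The module also refits the conversion coefficients from paired (THg, MeHg)
data — ordinary least squares of ln(MeHg) on ln(THg), with the FISH slope
constrained to 1 to preserve the proportional form — and provides residual
diagnostics on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .standardize import ConcentrationDistribution

#: Default log-log coefficients: FISH slope 1, intercept -0.23; OSE slope 0.94,
#: intercept -0.47.
DEFAULT_COEFFICIENTS = {"FISH": (1.0, -0.23), "OSE": (0.94, -0.47)}


@dataclass
class ConversionModel:
    """A log-log THg-to-MeHg regression for one seafood group.

    ``MeHg = exp(slope * ln(THg) + intercept)``. ``fitted`` marks models
    re-estimated from paired data (defaults carry the published coefficients);
    ``residual_sd`` and the standard errors are populated on refit.
    """

    group: str
    slope: float
    intercept: float
    fitted: bool = False
    residual_sd: Optional[float] = None
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("FISH", "OSE"):
            raise ValueError(f"group must be FISH or OSE, got {self.group!r}")
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


def default_model(group: str) -> ConversionModel:
    """Return the default conversion model for ``group`` (FISH or OSE)."""
    try:
        slope, intercept = DEFAULT_COEFFICIENTS[group]
    except KeyError:
        raise ValueError(f"group must be FISH or OSE, got {group!r}") from None
    return ConversionModel(group=group, slope=slope, intercept=intercept)


@dataclass
class MonteCarloSettings:
    """Monte Carlo configuration shared by the conversion and national stages.

    ``distribution_family`` selects the positive-support sampling distribution
    moment-matched to each (mean, SD): ``lognormal_moment_matched`` (default;
    guarantees positive draws) or ``truncated_normal`` (normal truncated at
    zero; note truncation shifts its mean slightly above the target).
    """

    n_draws: int = 10_000
    seed: int = 0
    distribution_family: str = "lognormal_moment_matched"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.distribution_family not in (
            "lognormal_moment_matched",
            "truncated_normal",
        ):
            raise ValueError(
                f"unknown distribution family {self.distribution_family!r}"
            )


def thg_to_mehg(thg, model: ConversionModel):
    """Apply the log-log conversion; accepts scalars or arrays, THg in ng/g.

    Strictly increasing for slope > 0; for the default FISH model (slope 1)
    the map is linear: MeHg = e^{-0.23} * THg.
    """
    x = np.asarray(thg, dtype=float)
    if np.any(x <= 0):
        raise ValueError("THg concentrations must be strictly positive")
    out = np.exp(model.slope * np.log(x) + model.intercept)
    return out if out.ndim else float(out)


def sample_positive(
    rng: np.random.Generator,
    mean,
    sd,
    size,
    family: str = "lognormal_moment_matched",
) -> np.ndarray:
    """Draw from a positive-support distribution moment-matched to (mean, sd).

    ``mean`` and ``sd`` may be scalars or arrays broadcast against ``size``.
    For the log-normal family the (mu, sigma) parameters are chosen so the
    draws have exactly the target mean and SD; the truncated-normal family
    truncates N(mean, sd) at zero.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if family == "lognormal_moment_matched":
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
        draws = rng.lognormal(np.where(sd > 0, mu, 0.0), np.sqrt(sigma2), size)
        return np.where(sd > 0, draws, mean)
    if family == "truncated_normal":
        u = rng.random(size)
        a = stats.norm.cdf(0.0, loc=mean, scale=np.where(sd > 0, sd, 1.0))
        draws = stats.norm.ppf(a + u * (1.0 - a), loc=mean, scale=np.where(sd > 0, sd, 1.0))
        return np.where(sd > 0, draws, mean)
    raise ValueError(f"unknown distribution family {family!r}")


def monte_carlo_convert(
    dist: ConcentrationDistribution,
    model: ConversionModel,
    settings: MonteCarloSettings,
    rng: np.random.Generator | None = None,
) -> ConcentrationDistribution:
    """Convert a THg (mean, SD, n) summary to MeHg by Monte Carlo.

    Draws ``settings.n_draws`` THg values from the configured positive-support
    distribution, maps each through the model, and returns the sample mean and
    SD of the converted draws. The sample size ``n`` is carried through
    unchanged. Deterministic under a fixed seed. A zero-SD input is treated as
    degenerate: the mean passes through the closed form exactly.
    """
    if dist.sd < 0:
        raise ValueError("sd must be non-negative")
    if dist.sd == 0:
        return ConcentrationDistribution(
            mean=thg_to_mehg(dist.mean, model), sd=0.0, n=dist.n
        )
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    draws = sample_positive(
        rng, dist.mean, dist.sd, settings.n_draws, settings.distribution_family
    )
    converted = thg_to_mehg(draws, model)
    return ConcentrationDistribution(
        mean=float(np.mean(converted)),
        sd=float(np.std(converted, ddof=1)) if settings.n_draws > 1 else 0.0,
        n=dist.n,
    )


def fit_conversion(
    thg,
    mehg,
    group: str,
    constrain_fish_slope: bool = True,
) -> ConversionModel:
    """Refit the log-log conversion from paired (THg, MeHg) data in ng/g.

    Ordinary least squares of ln(MeHg) on ln(THg). For FISH the slope is
    constrained to 1 by default (the intercept is then the mean log ratio),
    preserving the proportional form of the default model; pass
    ``constrain_fish_slope=False`` for a free slope. OSE always fits a free
    slope and requires a non-degenerate design (not all THg equal).
    """
    x = np.asarray(thg, dtype=float)
    y = np.asarray(mehg, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need at least 3 (THg, MeHg) pairs of equal length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("concentration pairs must be strictly positive")
    lx, ly = np.log(x), np.log(y)

    if group == "FISH" and constrain_fish_slope:
        ratios = ly - lx
        intercept = float(np.mean(ratios))
        resid_sd = float(np.std(ratios, ddof=1))
        return ConversionModel(
            group=group,
            slope=1.0,
            intercept=intercept,
            fitted=True,
            residual_sd=resid_sd,
            slope_se=0.0,
            intercept_se=resid_sd / np.sqrt(x.size),
        )

    if np.ptp(lx) == 0:
        raise ValueError("degenerate design: all THg values identical")
    fit = stats.linregress(lx, ly)
    resid = ly - (fit.slope * lx + fit.intercept)
    return ConversionModel(
        group=group,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fitted=True,
        residual_sd=float(np.std(resid, ddof=2)) if x.size > 2 else 0.0,
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
    )


@dataclass
class ResidualSummary:
    """Log-scale residual diagnostics for a conversion model."""

    residuals: np.ndarray
    median: float
    tail_fraction: float  # fraction of residuals beyond +/- 2 residual SD
    grid: Optional[np.ndarray] = None
    density: Optional[np.ndarray] = None


def residual_analysis(
    model: ConversionModel,
    thg,
    mehg,
    grid_size: int = 256,
) -> ResidualSummary:
    """Residual diagnostics on held-out (THg, MeHg) pairs.

    Residuals are ``ln(observed MeHg) - ln(predicted MeHg)``. A Gaussian
    kernel density is evaluated on a regular grid spanning the residual range
    padded by three bandwidths; degenerate (zero-spread) residual sets skip
    the density. A well-behaved conversion shows a sharp, near-symmetric
    density centred at zero.
    """
    pred = thg_to_mehg(np.asarray(thg, dtype=float), model)
    resid = np.log(np.asarray(mehg, dtype=float)) - np.log(pred)
    sd = float(np.std(resid, ddof=1)) if resid.size > 1 else 0.0
    tail = float(np.mean(np.abs(resid) > 2 * sd)) if sd > 0 else 0.0
    summary = ResidualSummary(
        residuals=resid, median=float(np.median(resid)), tail_fraction=tail
    )
    if sd > 0 and resid.size > 2:
        kde = stats.gaussian_kde(resid)
        bw = kde.factor * sd
        grid = np.linspace(resid.min() - 3 * bw, resid.max() + 3 * bw, grid_size)
        summary.grid = grid
        summary.density = kde(grid)
    return summary


def convert_records(
    standardized: pd.DataFrame,
    models: dict[str, ConversionModel] | None = None,
    settings: MonteCarloSettings | None = None,
    chunk_rows: int = 512,
) -> pd.DataFrame:
    """Convert all THg rows of a standardized record table to MeHg.

    MeHg-reporting rows pass through unchanged (provenance ``reported``); THg
    rows are converted with the group's model and Monte Carlo propagation
    (provenance ``converted_fish`` / ``converted_ose``). Zero-SD THg rows use
    the exact closed form. Vectorised in chunks of ``chunk_rows`` records to
    bound memory; deterministic for a given seed and chunk size.
    """
    models = models or {"FISH": default_model("FISH"), "OSE": default_model("OSE")}
    settings = settings or MonteCarloSettings()
    out = standardized.copy()
    out["conversion"] = "reported"
    is_thg = out["analyte"].astype(str).str.upper() == "THG"
    if not is_thg.any():
        return out

    rng = np.random.default_rng(settings.seed)
    idx = out.index[is_thg]
    group_key = np.where(out.loc[idx, "group"].to_numpy() == "other_seafood", "OSE", "FISH")
    for key in ("FISH", "OSE"):
        sub = idx[group_key == key]
        if len(sub) == 0:
            continue
        model = models[key]
        means = out.loc[sub, "mean"].to_numpy(float)
        sds = out.loc[sub, "sd"].to_numpy(float)
        new_mean = thg_to_mehg(means, model)
        new_sd = np.zeros_like(means)
        stochastic = sds > 0
        pos = np.flatnonzero(stochastic)
        for start in range(0, len(pos), chunk_rows):
            block = pos[start : start + chunk_rows]
            draws = sample_positive(
                rng,
                means[block][None, :],
                sds[block][None, :],
                (settings.n_draws, len(block)),
                settings.distribution_family,
            )
            conv = thg_to_mehg(draws, model)
            new_mean[block] = conv.mean(axis=0)
            new_sd[block] = conv.std(axis=0, ddof=1)
        out.loc[sub, "mean"] = new_mean
        out.loc[sub, "sd"] = new_sd
        out.loc[sub, "conversion"] = "converted_fish" if key == "FISH" else "converted_ose"
    out["analyte"] = "MeHg"
    return out
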