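"""Synthetic data generation for the whole pipeline.

Real rearing data for the two fruit-fly species are not deposited anywhere,
so every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes:

* **Cohort observations** — per stage × temperature × replicate, survival
  drawn Binomial(n, 1−M(T)) and development durations for survivors drawn
  log-logistic with median 1/r(T) and the stage's dispersion slope b.  The
  default design mirrors the constant-temperature experiment: 7
  temperatures (10, 15, 20, 25, 30, 33, 35 °C), 100 individuals × 5
  replicates per stage.
* **Adult observations** — 15 pairs per temperature; female lifespan from
  the senescence-quantile mechanism and daily egg counts Poisson with mean
  f(T)·ΔO(x), so lifetime totals average f(T)·O(x_death).
* **Annual temperature series** — constant, sinusoidal, or "outdoor-like"
  profiles; the outdoor-like profile confines daily minima to
  [9.14, 16.68] °C and maxima to [18.84, 37.66] °C (the range logged during
  the year-long outdoor validation experiment) with a seasonal sinusoid
  plus day-to-day noise.
* **Climate rasters** — 12 monthly tmin/tmax grids with a latitudinal
  gradient, a seasonal cycle and optional nodata speckle.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .rasters import RasterGrid
from .simulate import PhenologyModel, _log_logistic_quantiles
from .temperature import DAYS_PER_YEAR, TemperatureSeries
from . import thermal

__all__ = [
    "DESIGN_TEMPERATURES",
    "OUTDOOR_TMIN_RANGE",
    "OUTDOOR_TMAX_RANGE",
    "GeneratorConfig",
    "generate_cohort_observations",
    "generate_adult_observations",
    "generate_annual_temperatures",
    "generate_temperature_raster",
    "reference_models",
]

#: constant rearing temperatures of the experimental design (°C)
DESIGN_TEMPERATURES = (10.0, 15.0, 20.0, 25.0, 30.0, 33.0, 35.0)
#: daily extremes logged during the outdoor validation year (°C)
OUTDOOR_TMIN_RANGE = (9.14, 16.68)
OUTDOOR_TMAX_RANGE = (18.84, 37.66)


@dataclass
class GeneratorConfig:
    """True model plus experimental design for synthetic data generation."""

    model: PhenologyModel
    seed: int
    temperatures: tuple = DESIGN_TEMPERATURES
    n_per_cohort: int = 100
    n_replicates: int = 5
    n_pairs: int = 15

    def __post_init__(self) -> None:
        if min(self.n_per_cohort, self.n_replicates, self.n_pairs) < 1:
            raise ValueError("design sizes must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def generate_cohort_observations(config: GeneratorConfig) -> pd.DataFrame:
    """Long-format per-individual immature cohort table.

    Columns: stage, temperature_C, replicate, individual_id, survived,
    duration_days (NaN for non-survivors and at non-viable temperatures,
    where every individual dies).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for stage in config.model.stages:
        for T in config.temperatures:
            r = float(thermal.eval_development_rate(stage.dev_rate, T))
            m = float(thermal.eval_mortality(stage.mortality, T))
            if r <= 0:
                m = 1.0  # non-viable: the stage is never completed
            for rep in range(1, config.n_replicates + 1):
                survived = rng.uniform(size=config.n_per_cohort) >= m
                dur = np.full(config.n_per_cohort, np.nan)
                ns = int(survived.sum())
                if ns and r > 0:
                    u = rng.uniform(1e-12, 1 - 1e-12, ns)
                    dur[survived] = (1.0 / r) * _log_logistic_quantiles(
                        u, stage.devtime_slope
                    )
                for i in range(config.n_per_cohort):
                    rows.append(
                        (stage.name, T, rep, i + 1, bool(survived[i]), dur[i])
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "stage", "temperature_C", "replicate", "individual_id",
            "survived", "duration_days",
        ],
    )


def generate_adult_observations(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily per-female egg counts and adult longevities.

    Returns ``(eggs, longevity)``: eggs has one row per female per day of
    life with a Poisson egg count of mean f(T)·ΔO(x); longevity has one row
    per adult (both sexes) with the realized lifespan in days.
    """
    model = config.model
    rng = np.random.default_rng(config.seed + 1)
    egg_rows, lon_rows = [], []
    for T in config.temperatures:
        fec = float(thermal.eval_total_fecundity(model.fecundity, T))
        s_f = float(thermal.eval_senescence(model.senescence_female, T))
        s_m = float(thermal.eval_senescence(model.senescence_male, T))
        for j in range(1, config.n_pairs + 1):
            thr_f = float(
                _log_logistic_quantiles(
                    rng.uniform(1e-12, 1 - 1e-12, 1), model.adult_slope
                )[0]
            )
            x = 0.0
            day = 0
            while x < thr_f and day < 5 * DAYS_PER_YEAR:
                day += 1
                x_new = min(x + s_f, thr_f)
                d_o = float(
                    thermal.eval_oviposition_cdf(model.oviposition, x_new)
                    - thermal.eval_oviposition_cdf(model.oviposition, x)
                )
                eggs = int(rng.poisson(max(fec * d_o, 0.0)))
                egg_rows.append((T, j, day, eggs))
                x += s_f
            lon_rows.append((T, "female", j, day))
            thr_m = float(
                _log_logistic_quantiles(
                    rng.uniform(1e-12, 1 - 1e-12, 1), model.adult_slope
                )[0]
            )
            lon_rows.append((T, "male", j, math.ceil(thr_m / s_m) if s_m > 0 else 0))
    eggs = pd.DataFrame(egg_rows, columns=["temperature_C", "female_id", "day", "eggs"])
    longevity = pd.DataFrame(
        lon_rows, columns=["temperature_C", "sex", "individual_id", "longevity_days"]
    )
    return eggs, longevity


def generate_annual_temperatures(
    profile: str = "outdoor_like",
    seed: int = 0,
    *,
    constant: float = 25.0,
    mean: float = 20.0,
    amplitude: float = 8.0,
    diurnal_range: float = 10.0,
    n_days: int = DAYS_PER_YEAR,
) -> TemperatureSeries:
    """Annual daily tmin/tmax series from a named profile.

    ``constant`` gives tmin = tmax = T every day; ``sinusoid`` a seasonal
    sine of the daily mean with the given diurnal range; ``outdoor_like``
    a seasonal cycle plus noise confined to the logged outdoor ranges.
    """
    rng = np.random.default_rng(seed)
    d = np.arange(n_days)
    if profile == "constant":
        return TemperatureSeries.constant(constant, n_days)
    if profile == "sinusoid":
        tmean = mean + amplitude * np.sin(2 * np.pi * d / n_days)
        return TemperatureSeries(tmean - diurnal_range / 2, tmean + diurnal_range / 2)
    if profile == "outdoor_like":
        lo_min, hi_min = OUTDOOR_TMIN_RANGE
        lo_max, hi_max = OUTDOOR_TMAX_RANGE
        season = np.cos(2 * np.pi * (d - 15) / n_days)
        tmin = (
            0.5 * (lo_min + hi_min)
            + 0.4 * (hi_min - lo_min) * season
            + rng.normal(0, 0.6, n_days)
        )
        tmax = (
            0.5 * (lo_max + hi_max)
            + 0.4 * (hi_max - lo_max) * season
            + rng.normal(0, 1.2, n_days)
        )
        tmin = np.clip(tmin, lo_min, hi_min)
        tmax = np.clip(tmax, lo_max, hi_max)
        return TemperatureSeries(tmin, np.maximum(tmin, tmax))
    raise ValueError(f"unknown profile {profile!r}")


def generate_temperature_raster(
    n_rows: int,
    n_cols: int,
    seed: int = 0,
    *,
    north_temp: float = 8.0,
    south_temp: float = 28.0,
    seasonal_amplitude: float = 6.0,
    diurnal_range: float = 10.0,
    nodata_fraction: float = 0.0,
    cellsize: float = 0.5,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999.0,
) -> tuple[list[RasterGrid], list[RasterGrid]]:
    """12 monthly tmin and tmax grids with a north→south gradient.

    Row 0 (north) has mean annual temperature ``north_temp`` rising
    linearly to ``south_temp`` at the last row; each month adds a seasonal
    cosine of the given amplitude; tmin/tmax sit half the diurnal range
    below/above the mean.  ``nodata_fraction`` of cells are masked
    identically across all months and both variables.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    if n_rows > 1:
        lat_mean = np.linspace(north_temp, south_temp, n_rows)
    else:
        lat_mean = np.array([0.5 * (north_temp + south_temp)])
    base = np.repeat(lat_mean[:, None], n_cols, axis=1)
    mask = rng.uniform(size=(n_rows, n_cols)) < nodata_fraction
    tmin_list, tmax_list = [], []
    for m in range(12):
        season = seasonal_amplitude * math.cos(2 * math.pi * (m - 6.5) / 12.0)
        tmean = base + season
        tmin = np.where(mask, nodata, tmean - diurnal_range / 2)
        tmax = np.where(mask, nodata, tmean + diurnal_range / 2)
        tmin_list.append(RasterGrid(tmin, xllcorner, yllcorner, cellsize, nodata))
        tmax_list.append(RasterGrid(tmax, xllcorner, yllcorner, cellsize, nodata))
    return tmin_list, tmax_list


def reference_models() -> dict[str, PhenologyModel]:
    """Packaged phenology-model fixtures.

    ``rosa_like`` and ``quilicii_like`` archive the published parameter
    sets verbatim (with synthetic development-rate parameters, which were
    never published); ``synthetic_viable`` is a fully invented model that
    is viable across 15-35 °C and is the workhorse for simulation tests.
    """
    import yaml

    out = {}
    for name in ("rosa_like", "quilicii_like", "synthetic_viable"):
        text = (
            resources.files("phenorisk").joinpath("data", f"{name}.yaml").read_text()
        )
        out[name] = PhenologyModel.from_dict(yaml.safe_load(text))
    return out
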