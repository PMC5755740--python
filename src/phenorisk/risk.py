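"""Pest risk indices over annual temperature series and raster grids.

Three indices summarize what an annual temperature regime means for the
species:

* **ERI** (establishment risk index): the fraction of the 365 days on which
  every immature stage has positive survival (M(T̄) < 1) at the daily mean
  temperature; 1 means year-round establishment is possible.  An optional
  stricter mode additionally requires positive fecundity on the day.
* **GI** (generation index): the mean over all Julian start days x of
  365/T_x, where T_x is the generation length — the days a median
  individual starting as an egg on day x needs to complete egg, larva and
  pupa by rate summation and then, as an adult female, reach the age of 50%
  cumulative oviposition.
* **AI** (activity index): log10 of the product of daily finite rates of
  increase λ(T̄_x) taken from a quadratic fitted to life-table runs; every
  unit of AI is a 10-fold annual population increase.

Grid application evaluates the three indices per raster cell after
expanding 12 monthly tmin/tmax values to 365 daily values; nodata cells
propagate to nodata.
"""

from __future__ import annotations

import math

import numpy as np

from .forms import ThermalFunctionSpec
from .rasters import RasterGrid
from .simulate import PhenologyModel, _daily_rates
from .temperature import DAYS_PER_YEAR, TemperatureSeries, monthly_to_daily
from . import thermal

__all__ = [
    "compute_eri",
    "compute_generation_length",
    "compute_gi",
    "compute_ai",
    "compute_indices_for_grid",
    "classify_establishment",
]

GENERATION_CAP_DAYS = 5 * 365
_EPS = 1e-9


def _require_year(temps: TemperatureSeries) -> None:
    if len(temps) != DAYS_PER_YEAR:
        raise ValueError(f"need exactly {DAYS_PER_YEAR} daily temperatures")


def compute_eri(
    model: PhenologyModel,
    temps: TemperatureSeries,
    require_reproduction: bool = False,
) -> float:
    """Fraction of days on which all immature stages can survive."""
    _require_year(temps)
    tmean = temps.tmean
    ok = np.ones(DAYS_PER_YEAR, dtype=bool)
    for s in model.stages:
        ok &= np.asarray(thermal.eval_mortality(s.mortality, tmean)) < 1.0
    if require_reproduction:
        ok &= np.asarray(thermal.eval_total_fecundity(model.fecundity, tmean)) > 0.0
    return float(ok.mean())


def _generation_cumsums(model: PhenologyModel, temps: TemperatureSeries):
    """Extended prefix sums of daily development and senescence increments."""
    _require_year(temps)
    dev, _, sen_f, _, _ = _daily_rates(model, temps)
    n_cycles = GENERATION_CAP_DAYS // DAYS_PER_YEAR + 2
    ext_dev = np.tile(dev, (1, n_cycles))
    ext_sen = np.tile(sen_f, n_cycles)
    c_dev = [np.concatenate([[0.0], np.cumsum(row)]) for row in ext_dev]
    c_sen = np.concatenate([[0.0], np.cumsum(ext_sen)])
    return c_dev, c_sen


def _generation_lengths(model, temps, start_days: np.ndarray) -> np.ndarray:
    """Vectorized T_x for 0-based start day indices; inf when not completed."""
    c_dev, c_sen = _generation_cumsums(model, temps)
    x50 = thermal.oviposition_median_age(model.oviposition)
    p = start_days.astype(np.int64)
    alive = np.ones(p.shape, dtype=bool)
    for c in c_dev:
        target = c[np.minimum(p, len(c) - 1)] + 1.0 - _EPS
        nxt = np.searchsorted(c, target, side="left")
        alive &= nxt < len(c)
        p = np.minimum(nxt, len(c) - 1)
    target = c_sen[np.minimum(p, len(c_sen) - 1)] + x50 - _EPS
    nxt = np.searchsorted(c_sen, target, side="left")
    alive &= nxt < len(c_sen)
    p = np.minimum(nxt, len(c_sen) - 1)
    tx = (p - start_days).astype(float)
    tx[~alive | (tx > GENERATION_CAP_DAYS)] = math.inf
    return tx


def compute_generation_length(
    model: PhenologyModel, temps: TemperatureSeries, start_day: int
) -> float:
    """Generation length T_x in days from Julian start day (1..365).

    Deterministic median-individual forward simulation: rate summation
    through egg → larva → pupa, then senescence-rate summation of the adult
    female to the age of 50% cumulative oviposition.  Returns inf when the
    generation cannot complete within the cap (default 5 years).
    """
    if not 1 <= start_day <= DAYS_PER_YEAR:
        raise ValueError("start_day must be in 1..365")
    return float(_generation_lengths(model, temps, np.array([start_day - 1]))[0])


def compute_gi(model: PhenologyModel, temps: TemperatureSeries) -> float:
    """Mean generations per year over all Julian start days."""
    tx = _generation_lengths(model, temps, np.arange(DAYS_PER_YEAR))
    with np.errstate(divide="ignore"):
        per_start = np.where(np.isfinite(tx), DAYS_PER_YEAR / tx, 0.0)
    return float(per_start.mean())


def compute_ai(
    lambda_fn: ThermalFunctionSpec,
    temps: TemperatureSeries,
    lambda_floor: float = 0.5,
) -> float:
    """log10 of the product of daily finite rates of increase.

    λ is evaluated from the quadratic life-table fit at each daily mean
    temperature and floored at ``lambda_floor`` so that days outside the
    viable range bound AI below without driving it to −inf.
    """
    if lambda_fn.form_id != "lifetable_quadratic":
        raise ValueError("lambda_fn must be a lifetable_quadratic spec")
    if lambda_floor <= 0:
        raise ValueError("lambda_floor must be positive")
    _require_year(temps)
    a, b, c = (lambda_fn.params[k] for k in ("a", "b", "c"))
    t = temps.tmean
    lam = np.maximum(a + b * t + c * t**2, lambda_floor)
    return float(np.sum(np.log10(lam)))


def compute_indices_for_grid(
    model: PhenologyModel,
    lambda_fn: ThermalFunctionSpec,
    tmin_rasters: list[RasterGrid],
    tmax_rasters: list[RasterGrid],
    require_reproduction: bool = False,
    lambda_floor: float = 0.5,
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Per-cell ERI, GI and AI from 12 monthly tmin and tmax rasters.

    Monthly values are interpolated linearly between month midpoints
    (wrapped across the year) to a 365-day series per cell.  A nodata cell
    in any input is nodata in all three outputs.
    """
    if len(tmin_rasters) != 12 or len(tmax_rasters) != 12:
        raise ValueError("need 12 monthly tmin and 12 monthly tmax rasters")
    ref = tmin_rasters[0]
    for g in (*tmin_rasters, *tmax_rasters):
        if not ref.same_geometry(g):
            raise ValueError("raster geometry mismatch")
    tmin_stack = np.stack([g.values for g in tmin_rasters])  # (12, r, c)
    tmax_stack = np.stack([g.values for g in tmax_rasters])
    mask = np.zeros(ref.values.shape, dtype=bool)
    for g in (*tmin_rasters, *tmax_rasters):
        mask |= g.mask

    eri = np.full(ref.values.shape, ref.nodata)
    gi = np.full(ref.values.shape, ref.nodata)
    ai = np.full(ref.values.shape, ref.nodata)
    for r in range(ref.n_rows):
        for c in range(ref.n_cols):
            if mask[r, c]:
                continue
            tmin_d = monthly_to_daily(tmin_stack[:, r, c])
            tmax_d = monthly_to_daily(tmax_stack[:, r, c])
            series = TemperatureSeries(tmin_d, np.maximum(tmin_d, tmax_d))
            eri[r, c] = compute_eri(model, series, require_reproduction)
            gi[r, c] = compute_gi(model, series)
            ai[r, c] = compute_ai(lambda_fn, series, lambda_floor)
    make = lambda v: RasterGrid(
        np.where(mask, ref.nodata, v), ref.xllcorner, ref.yllcorner,
        ref.cellsize, ref.nodata,
    )
    return make(eri), make(gi), make(ai)


def classify_establishment(eri_grid: RasterGrid, cutoff: float = 0.6) -> RasterGrid:
    """Binary establishment layer: 1 where ERI > cutoff, else 0 (nodata kept)."""
    cls = (eri_grid.values > cutoff).astype(float)
    return eri_grid.like(cls)
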