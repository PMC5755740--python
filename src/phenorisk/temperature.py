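"""Daily temperature series and sub-daily interpolation.

Rate summation works on short time steps, but weather inputs are daily
minimum/maximum pairs.  The within-day cycle is reconstructed with the
standard degree-day cosine interpolation (minimum at midnight, maximum at
midday, mean equal to (tmin+tmax)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TemperatureSeries", "interpolate_daily_cycle", "monthly_to_daily"]

DAYS_PER_YEAR = 365
#: mid-month day-of-year anchors used when expanding monthly values to daily
_MONTH_MIDPOINTS = np.array(
    [15.5, 45.0, 74.5, 105.0, 135.5, 166.0, 196.5, 227.5, 258.0, 288.5, 319.0, 349.5]
)


@dataclass
class TemperatureSeries:
    """Daily minimum and maximum temperatures for day indices 1..N."""

    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self) -> None:
        self.tmin = np.atleast_1d(np.asarray(self.tmin, float))
        self.tmax = np.atleast_1d(np.asarray(self.tmax, float))
        if self.tmin.shape != self.tmax.shape or self.tmin.size < 1:
            raise ValueError("tmin/tmax must be equal-length, non-empty")
        if np.any(self.tmin > self.tmax):
            raise ValueError("tmin must be <= tmax on every day")

    def __len__(self) -> int:
        return self.tmin.size

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    @classmethod
    def constant(cls, T: float, n_days: int = DAYS_PER_YEAR) -> "TemperatureSeries":
        t = np.full(n_days, float(T))
        return cls(t, t.copy())

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        try:
            tmin = df[cols["tmin_c"]].to_numpy(float)
            tmax = df[cols["tmax_c"]].to_numpy(float)
        except KeyError as e:
            raise ValueError(f"temperature CSV needs tmin_C/tmax_C columns: {e}")
        return cls(tmin, tmax)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": np.arange(1, len(self) + 1), "tmin_C": self.tmin, "tmax_C": self.tmax}
        )


def interpolate_daily_cycle(
    tmin: float, tmax: float, steps_per_day: int = 24
) -> np.ndarray:
    """Cosine within-day temperature cycle.

    T(h) = (tmax+tmin)/2 − (tmax−tmin)/2 · cos(2πh/H) for h = 0..H−1, so the
    daily minimum occurs at h = 0, the maximum at mid-day, and the mean over
    the H steps equals (tmin+tmax)/2 exactly.
    """
    if tmin > tmax:
        raise ValueError("tmin must be <= tmax")
    if steps_per_day < 1:
        raise ValueError("steps_per_day must be >= 1")
    h = np.arange(steps_per_day)
    return (tmax + tmin) / 2.0 - (tmax - tmin) / 2.0 * np.cos(
        2.0 * np.pi * h / steps_per_day
    )


def monthly_to_daily(monthly: np.ndarray) -> np.ndarray:
    """Linear interpolation of 12 monthly values to 365 daily values.

    Values are anchored at mid-month day-of-year positions and wrapped
    across the year boundary (December interpolates into January).
    """
    monthly = np.asarray(monthly, float)
    if monthly.shape != (12,):
        raise ValueError("expected exactly 12 monthly values")
    xp = np.concatenate([_MONTH_MIDPOINTS - DAYS_PER_YEAR, _MONTH_MIDPOINTS,
                         _MONTH_MIDPOINTS + DAYS_PER_YEAR])
    fp = np.tile(monthly, 3)
    return np.interp(np.arange(1, DAYS_PER_YEAR + 1), xp, fp)
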