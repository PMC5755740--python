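"""Closed-form evaluation of the thermal response functions.

The functions here are the building blocks of the phenology model:

* Brière-1 development rate ``r(T) = a·T·(T−Tmin)·sqrt(Tmax−T)`` with hard
  zero outside the (Tmin, Tmax) window, and its closed-form optimum.
* Exponential-quadratic immature mortality ``M(T) = exp(b1+b2·T+b3·T²)``
  clipped to [0, 1].
* Adult senescence as either a simple exponential ``b1·exp(b2·T)`` or a
  double-logistic (Stinner) curve; expected adult longevity is 1/rate.
* Lifetime fecundity as an exponential polynomial or a Gaussian peak.
* Cumulative oviposition over normalized female age (age / mean survival
  time) as a cubic-exponential, logistic, or gamma CDF.
* The logit development-time distribution with per-temperature intercepts
  and a common slope on ln(time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .forms import ThermalFunctionSpec

__all__ = [
    "eval_development_rate",
    "optimum_temperature",
    "eval_mortality",
    "eval_senescence",
    "eval_total_fecundity",
    "eval_oviposition_cdf",
    "eval_devtime_cdf",
    "oviposition_median_age",
    "LethalTemperatures",
    "mortality_level_crossings",
    "lethal_temperatures",
    "linear_lower_threshold",
]

_SEARCH_LO, _SEARCH_HI = -20.0, 60.0  # °C bracket for lethal-temperature roots


def _check_finite(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature input must be finite")
    return T


def eval_development_rate(spec: ThermalFunctionSpec, T) -> np.ndarray | float:
    """Brière-1 development rate (1/day), zero outside (Tmin, Tmax)."""
    if spec.form_id != "briere1":
        raise ValueError(f"expected briere1, got {spec.form_id}")
    a, tmin, tmax = (spec.params[k] for k in ("a", "Tmin", "Tmax"))
    T = _check_finite(T)
    inside = (T > tmin) & (T < tmax)
    r = np.zeros_like(T, dtype=float)
    Ti = T[inside]
    r[inside] = a * Ti * (Ti - tmin) * np.sqrt(tmax - Ti)
    np.clip(r, 0.0, None, out=r)  # a<0 would otherwise go negative
    return r if r.ndim else float(r)


def optimum_temperature(spec: ThermalFunctionSpec) -> float:
    """Temperature maximizing the Brière-1 rate (closed form)."""
    if spec.form_id != "briere1":
        raise ValueError(f"expected briere1, got {spec.form_id}")
    tmin, tmax = spec.params["Tmin"], spec.params["Tmax"]
    if not tmin < tmax:
        raise ValueError("degenerate interval: Tmin must be < Tmax")
    disc = 16 * tmax**2 + 9 * tmin**2 - 16 * tmin * tmax
    return (4 * tmax + 3 * tmin + math.sqrt(disc)) / 10.0


def _mortality_exponent(spec: ThermalFunctionSpec, T: np.ndarray) -> np.ndarray:
    b1, b2, b3 = (spec.params[k] for k in ("b1", "b2", "b3"))
    return b1 + b2 * T + b3 * T**2


def eval_mortality(spec: ThermalFunctionSpec, T) -> np.ndarray | float:
    """Whole-stage mortality fraction exp(b1+b2·T+b3·T²), clipped to [0, 1]."""
    if spec.form_id != "mortality_expquad":
        raise ValueError(f"expected mortality_expquad, got {spec.form_id}")
    T = _check_finite(T)
    m = np.exp(np.minimum(_mortality_exponent(spec, T), 0.0))
    return m if m.ndim else float(m)


def eval_senescence(spec: ThermalFunctionSpec, T) -> np.ndarray | float:
    """Adult senescence rate (1/day); expected longevity is 1/rate."""
    T = _check_finite(T)
    if spec.form_id == "senescence_exponential":
        b1, b2 = spec.params["b1"], spec.params["b2"]
        s = b1 * np.exp(b2 * T)
    elif spec.form_id == "senescence_stinner":
        c1, c2, k1, k2, t0 = (spec.params[k] for k in ("C1", "C2", "k1", "k2", "T0"))
        s = c1 / (1.0 + np.exp(k1 + k2 * T)) + c2 / (1.0 + np.exp(k1 + k2 * (t0 - T)))
    else:
        raise ValueError(f"expected a senescence form, got {spec.form_id}")
    return s if s.ndim else float(s)


def eval_total_fecundity(spec: ThermalFunctionSpec, T) -> np.ndarray | float:
    """Lifetime eggs per female at temperature T (floored at 0)."""
    T = _check_finite(T)
    if spec.form_id == "fecundity_exppoly":
        b1, b2, b3 = (spec.params[k] for k in ("b1", "b2", "b3"))
        f = np.exp(b1 + b2 * T + b3 * T**2)
    elif spec.form_id == "fecundity_gaussian":
        y0, a, b, x0 = (spec.params[k] for k in ("y0", "a", "b", "x0"))
        f = y0 + a * np.exp(-0.5 * ((T - x0) / b) ** 2)
        f = np.maximum(f, 0.0)  # large-negative baseline: only the peak is meaningful
    else:
        raise ValueError(f"expected a fecundity form, got {spec.form_id}")
    return f if f.ndim else float(f)


def eval_oviposition_cdf(spec: ThermalFunctionSpec, x) -> np.ndarray | float:
    """Cumulative fraction of lifetime eggs laid by normalized age x ≥ 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("normalized age must be finite and >= 0")
    if spec.form_id == "ovip_cubic_exponential":
        a, b, c = (spec.params[k] for k in ("a", "b", "c"))
        y = 1.0 - np.exp(-(a * x + b * x**2 + c * x**3))
        y = np.clip(y, 0.0, 1.0)
    elif spec.form_id == "ovip_logistic":
        a, b = spec.params["a"], spec.params["b"]
        y = np.minimum(1.0 / (1.0 + np.exp(a + b * x)), 1.0)
    elif spec.form_id == "ovip_gamma":
        y = stats.gamma.cdf(x, a=spec.params["a"], scale=1.0 / spec.params["b"])
    else:
        raise ValueError(f"expected an oviposition form, got {spec.form_id}")
    return y if y.ndim else float(y)


def eval_devtime_cdf(
    spec: ThermalFunctionSpec, x, temperature_index: int
) -> np.ndarray | float:
    """P(development completed by time x days) at one rearing temperature.

    F(x) = 1 / (1 + exp(−(a_i + b·ln x))); the slope b is shared across
    temperatures, so the distribution has the same shape everywhere and the
    median at temperature i is exp(−a_i / b).
    """
    if spec.form_id != "devtime_logit":
        raise ValueError(f"expected devtime_logit, got {spec.form_id}")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("development time must be finite and > 0")
    a_i = spec.params["intercepts"][temperature_index]
    b = spec.params["b"]
    f = 1.0 / (1.0 + np.exp(-(a_i + b * np.log(x))))
    return f if f.ndim else float(f)


def oviposition_median_age(spec: ThermalFunctionSpec) -> float:
    """Normalized age x at which half the lifetime eggs have been laid."""
    if spec.form_id == "ovip_logistic":
        return -spec.params["a"] / spec.params["b"]
    if spec.form_id == "ovip_gamma":
        return float(stats.gamma.ppf(0.5, a=spec.params["a"], scale=1.0 / spec.params["b"]))
    if spec.form_id == "ovip_cubic_exponential":
        f = lambda x: eval_oviposition_cdf(spec, x) - 0.5
        hi = 1.0
        while f(hi) < 0 and hi < 1e6:
            hi *= 2
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))
    raise ValueError(f"expected an oviposition form, got {spec.form_id}")


@dataclass
class LethalTemperatures:
    """Temperatures where the fitted mortality curve crosses 50% / 100%.

    Any slot is ``None`` when that mortality level is never crossed on the
    searched interval.  When all are present they nest:
    lt100_lower <= lt50_lower <= lt50_upper <= lt100_upper.
    """

    lt50_lower: float | None = None
    lt50_upper: float | None = None
    lt100_lower: float | None = None
    lt100_upper: float | None = None


def mortality_level_crossings(
    spec: ThermalFunctionSpec, level: float
) -> tuple[float | None, float | None]:
    """Lower/upper temperatures where M(T) crosses ``level``.

    The exp-quadratic with b3 > 0 is U-shaped upside down in survival terms:
    mortality is high at both extremes with a single interior minimum.  Roots
    are found by bracketed root-finding on [-20, 60] °C.  For level == 1 the
    crossings are the boundaries of the clipped region where the raw
    exponential reaches 1 (exponent >= 0).
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    if spec.form_id != "mortality_expquad":
        raise ValueError(f"expected mortality_expquad, got {spec.form_id}")
    b2, b3 = spec.params["b2"], spec.params["b3"]
    if b3 <= 0:
        raise ValueError("crossings require a U-shaped curve (b3 > 0)")
    t_vertex = float(np.clip(-b2 / (2 * b3), _SEARCH_LO, _SEARCH_HI))
    target = math.log(level)

    def g(T: float) -> float:
        return _mortality_exponent(spec, np.asarray(T)).item() - target

    lower = upper = None
    if g(t_vertex) < 0:  # minimum below the level: interior crossings possible
        if g(_SEARCH_LO) > 0:
            lower = float(optimize.brentq(g, _SEARCH_LO, t_vertex, xtol=1e-9))
        if g(_SEARCH_HI) > 0:
            upper = float(optimize.brentq(g, t_vertex, _SEARCH_HI, xtol=1e-9))
    return lower, upper


def lethal_temperatures(spec: ThermalFunctionSpec) -> LethalTemperatures:
    """LT50 and LT100 thresholds of an exp-quadratic mortality curve."""
    lo50, hi50 = mortality_level_crossings(spec, 0.5)
    lo100, hi100 = mortality_level_crossings(spec, 1.0)
    return LethalTemperatures(lo50, hi50, lo100, hi100)


def linear_lower_threshold(intercept: float, slope: float) -> float:
    """Zero-rate temperature −a/b of the linear rate regression r(T)=a+b·T."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    return -intercept / slope
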