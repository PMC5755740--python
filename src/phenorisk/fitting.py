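"""Nonlinear least-squares fitting of thermal response curves.

Each functional form is fitted to observed (temperature, response) pairs by
multi-start Levenberg-Marquardt / trust-region least squares, with starting
values derived deterministically from the data (log/logit-transformed linear
fits where the form allows it, plus a coarse grid otherwise).  Goodness of
fit is summarized by the Gaussian least-squares AIC, n·ln(RSS/n) + 2k, and
R²; model selection takes the lowest AIC with ties broken by higher R² and
then by fewer parameters.

The development-time distribution is fitted separately: individual
development durations at two or more temperatures are pooled into a single
binomial logit regression of the empirical cumulative completion fraction
on ln(time), with one intercept per temperature and a single common slope
(the "same shape" assumption).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .forms import FORM_PARAMS, ThermalFunctionSpec
from . import thermal

__all__ = [
    "ObservedResponse",
    "FitResult",
    "fit_response",
    "compute_aic",
    "compute_r2",
    "select_best_model",
    "fit_devtime_common_slope",
    "responses_from_cohort",
    "fit_lifetable_quadratic",
    "FEMALE_RATIO",
]

#: Female fraction assigned at every temperature.
FEMALE_RATIO = 0.5


@dataclass
class ObservedResponse:
    """Paired (temperature, response) observations, optionally weighted."""

    temperatures: np.ndarray
    responses: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        self.responses = np.asarray(self.responses, float)
        if self.temperatures.shape != self.responses.shape:
            raise ValueError("temperatures and responses must have equal length")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != self.responses.shape:
                raise ValueError("weights must match responses")


@dataclass
class FitResult:
    spec: ThermalFunctionSpec
    aic: float
    r2: float
    rss: float
    n_obs: int
    converged: bool
    form_id: str = field(init=False)

    def __post_init__(self) -> None:
        self.form_id = self.spec.form_id


def compute_aic(rss: float, n_obs: int, k_params: int) -> float:
    """Gaussian least-squares AIC, n·ln(RSS/n) + 2k.

    A perfect fit (rss == 0) returns -inf so that it always wins selection.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        return float("-inf")
    return n_obs * math.log(rss / n_obs) + 2 * k_params


def compute_r2(observed, predicted) -> float:
    """Coefficient of determination 1 − RSS/TSS."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero total variance: R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / tss


def select_best_model(candidates: list[FitResult]) -> FitResult:
    """Lowest AIC; ties broken by higher R², then fewer parameters."""
    usable = [c for c in candidates if c.converged]
    if not usable:
        raise ValueError("no converged candidates to select from")
    return min(
        usable, key=lambda c: (c.aic, -c.r2, len(FORM_PARAMS[c.spec.form_id]))
    )


# ---------------------------------------------------------------------------
# form evaluation for fitting (unclipped where clipping would kill gradients)

def _model_fn(form_id: str):
    if form_id == "briere1":
        def f(T, a, tmin, tmax):
            T = np.asarray(T, float)
            inside = (T > tmin) & (T < tmax)
            out = np.zeros_like(T)
            out[inside] = a * T[inside] * (T[inside] - tmin) * np.sqrt(tmax - T[inside])
            return out
    elif form_id == "linear_rate":
        def f(T, a, b):
            return a + b * np.asarray(T, float)
    elif form_id in ("mortality_expquad", "fecundity_exppoly"):
        def f(T, b1, b2, b3):
            T = np.asarray(T, float)
            return np.exp(np.minimum(b1 + b2 * T + b3 * T**2, 50.0))
    elif form_id == "senescence_exponential":
        def f(T, b1, b2):
            return b1 * np.exp(b2 * np.asarray(T, float))
    elif form_id == "senescence_stinner":
        def f(T, c1, c2, k1, k2, t0):
            T = np.asarray(T, float)
            return c1 / (1 + np.exp(k1 + k2 * T)) + c2 / (1 + np.exp(k1 + k2 * (t0 - T)))
    elif form_id == "fecundity_gaussian":
        def f(T, y0, a, b, x0):
            return y0 + a * np.exp(-0.5 * ((np.asarray(T, float) - x0) / b) ** 2)
    elif form_id == "ovip_cubic_exponential":
        def f(x, a, b, c):
            x = np.asarray(x, float)
            return 1.0 - np.exp(-(a * x + b * x**2 + c * x**3))
    elif form_id == "ovip_logistic":
        def f(x, a, b):
            return 1.0 / (1.0 + np.exp(a + b * np.asarray(x, float)))
    elif form_id == "ovip_gamma":
        from scipy import stats
        def f(x, a, b):
            return stats.gamma.cdf(np.asarray(x, float), a=a, scale=1.0 / b)
    elif form_id == "lifetable_quadratic":
        def f(T, a, b, c):
            T = np.asarray(T, float)
            return a + b * T + c * T**2
    else:
        raise ValueError(f"no fittable model for form {form_id!r}")
    return f


def _poly_seed(x, y, deg):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.polyfit(x, y, deg)


def _initial_values(form_id: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid of initial parameter vectors."""
    starts: list[np.ndarray] = []
    if form_id == "briere1":
        # thresholds seeded just outside the observed range (Brière fits are
        # sensitive to the threshold starts)
        tpk = float(x[np.argmax(y)])
        for dlo in (2.0, 0.5):
            for dhi in (2.0, 5.0):
                tmin0, tmax0 = x.min() - dlo, x.max() + dhi
                denom = tpk * max(tpk - tmin0, 1e-6) * math.sqrt(max(tmax0 - tpk, 1e-6))
                starts.append(np.array([max(y.max(), 1e-8) / denom, tmin0, tmax0]))
    elif form_id == "linear_rate":
        starts.append(_poly_seed(x, y, 1)[::-1])
    elif form_id in ("mortality_expquad", "fecundity_exppoly"):
        ylog = np.log(np.clip(y, 1e-8, None))
        c2, c1, c0 = _poly_seed(x, ylog, 2)
        starts.append(np.array([c0, c1, c2]))
        starts.append(np.array([c0 * 0.5, c1 * 0.5, c2 * 0.5]))
    elif form_id == "senescence_exponential":
        c1, c0 = _poly_seed(x, np.log(np.clip(y, 1e-10, None)), 1)
        starts.append(np.array([math.exp(c0), c1]))
    elif form_id == "senescence_stinner":
        for k2 in (-0.1, -0.3):
            starts.append(np.array([y.max(), y.max() / 2, 3.0, k2, x.max()]))
            starts.append(np.array([y.max() / 2, y.max(), 1.0, k2, x.mean()]))
    elif form_id == "fecundity_gaussian":
        x0 = float(x[np.argmax(y)])
        for b0 in (3.0, 8.0, 30.0):
            starts.append(np.array([float(y.min()), float(y.max() - y.min()), b0, x0]))
    elif form_id == "ovip_cubic_exponential":
        z = -np.log(np.clip(1 - y, 1e-8, 1.0))
        coef, *_ = np.linalg.lstsq(
            np.column_stack([x, x**2, x**3]), z, rcond=None
        )
        starts.append(coef)
        starts.append(np.array([1.0, 1.0, 0.1]))
    elif form_id == "ovip_logistic":
        yc = np.clip(y, 1e-6, 1 - 1e-6)
        c1, c0 = _poly_seed(x, np.log(1 / yc - 1), 1)
        starts.append(np.array([c0, c1]))
    elif form_id == "ovip_gamma":
        starts += [np.array(s) for s in ((2.0, 2.0), (3.0, 4.0), (1.0, 1.0), (5.0, 5.0))]
    elif form_id == "lifetable_quadratic":
        c2, c1, c0 = _poly_seed(x, y, 2)
        starts.append(np.array([c0, c1, c2]))
    return starts


_BOUNDS = {
    "briere1": ([0.0, -50.0, -40.0], [np.inf, 60.0, 90.0]),
    "ovip_gamma": ([1e-6, 1e-6], [np.inf, np.inf]),
    "senescence_exponential": ([1e-12, -np.inf], [np.inf, np.inf]),
}


def fit_response(data: ObservedResponse, form_id: str) -> FitResult:
    """Fit one functional form to observed responses by least squares.

    Raises if the fit is under-determined; a fit that never converges from
    any start is returned with ``converged=False`` rather than raising.
    """
    if form_id == "devtime_logit":
        raise ValueError("use fit_devtime_common_slope for the devtime distribution")
    names = FORM_PARAMS[form_id]
    x, y = data.temperatures, data.responses
    n = x.size
    if n <= len(names):
        raise ValueError(
            f"under-determined: {n} observations for {len(names)} parameters"
        )
    fn = _model_fn(form_id)
    sigma = None
    if data.weights is not None:
        sigma = 1.0 / np.sqrt(np.clip(data.weights, 1e-12, None))
    bounds = _BOUNDS.get(form_id, (-np.inf, np.inf))

    best: tuple[float, np.ndarray, np.ndarray | None] | None = None
    for p0 in _initial_values(form_id, x, y):
        if not np.isscalar(bounds[0]):  # keep starts strictly inside box bounds
            lo, hi = (np.asarray(b, float) for b in bounds)
            p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    fn, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - fn(x, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)

    if best is None:
        spec = ThermalFunctionSpec(
            form_id, dict(zip(names, _initial_values(form_id, x, y)[0]))
        )
        return FitResult(spec, math.inf, -math.inf, math.inf, n, converged=False)

    rss, popt, pcov = best
    se = None
    if pcov is not None and np.all(np.isfinite(pcov)):
        diag = np.diag(pcov)
        if np.all(diag >= 0):
            se = dict(zip(names, np.sqrt(diag)))
    spec = ThermalFunctionSpec(form_id, dict(zip(names, popt)), param_se=se)
    pred = fn(x, *popt)
    try:
        r2 = compute_r2(y, pred)
    except ValueError:
        r2 = float("nan")
    return FitResult(spec, compute_aic(rss, n, len(names)), r2, rss, n, converged=True)


def fit_devtime_common_slope(
    durations: dict[float, np.ndarray]
) -> ThermalFunctionSpec:
    """Common-slope logit fit of development-time distributions.

    ``durations`` maps rearing temperature to the individual development
    times (days) observed there.  The empirical cumulative completion
    fraction at each distinct duration is regressed on ln(time) in a single
    pooled binomial GLM with temperature-indexed intercepts and one shared
    slope b > 0.
    """
    temps = sorted(durations)
    if len(temps) < 2:
        raise ValueError("need at least 2 temperatures")
    rows_logx, rows_temp, succ, tot = [], [], [], []
    for ti, t in enumerate(temps):
        d = np.asarray(durations[t], float)
        if d.size < 10:
            raise ValueError(f"need >= 10 individuals per temperature (T={t})")
        if np.ptp(d) == 0:
            raise ValueError(f"all durations identical at T={t}: zero spread")
        days = np.unique(d)
        for day in days:
            rows_logx.append(math.log(day))
            rows_temp.append(ti)
            succ.append(int(np.sum(d <= day)))
            tot.append(d.size)
    k = len(temps)
    X = np.zeros((len(rows_logx), k + 1))
    X[np.arange(len(rows_temp)), np.asarray(rows_temp)] = 1.0
    X[:, k] = rows_logx
    endog = np.column_stack([succ, np.asarray(tot) - np.asarray(succ)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    b = float(res.params[k])
    if b <= 0:
        raise ValueError("fitted common slope is not positive")
    return ThermalFunctionSpec(
        "devtime_logit",
        {
            "b": b,
            "intercepts": [float(v) for v in res.params[:k]],
            "temperatures": [float(t) for t in temps],
        },
    )


def responses_from_cohort(df, stage: str):
    """Summarize a long-format cohort table into fit-ready responses.

    From the per-individual table (columns stage, temperature_C, replicate,
    survived, duration_days) build, for one stage:

    * a mortality :class:`ObservedResponse` — the fraction dying per
      temperature × replicate,
    * a development-rate :class:`ObservedResponse` — 1/median duration of
      the survivors per temperature × replicate (replicates with no
      survivors contribute no rate point),
    * a durations dict (temperature → survivor durations) for
      :func:`fit_devtime_common_slope`.
    """
    sub = df[df["stage"] == stage]
    if sub.empty:
        raise ValueError(f"no observations for stage {stage!r}")
    mort_t, mort_y, rate_t, rate_y = [], [], [], []
    durations: dict[float, np.ndarray] = {}
    for (T, _rep), grp in sub.groupby(["temperature_C", "replicate"]):
        mort_t.append(T)
        mort_y.append(1.0 - grp["survived"].mean())
        d = grp.loc[grp["survived"], "duration_days"].dropna().to_numpy()
        if d.size:
            rate_t.append(T)
            rate_y.append(1.0 / float(np.median(d)))
    for T, grp in sub.groupby("temperature_C"):
        d = grp.loc[grp["survived"], "duration_days"].dropna().to_numpy()
        if d.size >= 10:
            durations[float(T)] = d
    mortality = ObservedResponse(np.array(mort_t), np.array(mort_y))
    rate = ObservedResponse(np.array(rate_t), np.array(rate_y))
    return mortality, rate, durations


def fit_lifetable_quadratic(params_by_temperature) -> ThermalFunctionSpec:
    """OLS quadratic L_p(T) = a + b·T + c·T² through (T, parameter) pairs."""
    pts = np.asarray(params_by_temperature, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(np.unique(pts[:, 0])) < 3:
        raise ValueError("need >= 3 distinct temperatures as (T, value) pairs")
    c2, c1, c0 = np.polyfit(pts[:, 0], pts[:, 1], 2)
    return ThermalFunctionSpec(
        "lifetable_quadratic", {"a": float(c0), "b": float(c1), "c": float(c2)}
    )
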