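"""Independent oracles: brute-force / closed-form computations kept
deliberately separate from the package's implementation paths."""

import math

import numpy as np
from scipy import stats


def briere_rate(a, tmin, tmax, T):
    if T <= tmin or T >= tmax:
        return 0.0
    return a * T * (T - tmin) * math.sqrt(tmax - T)


def brute_force_briere_argmax(a, tmin, tmax, resolution=1e-4):
    """Grid-search argmax of the Brière-1 curve."""
    T = np.arange(tmin, tmax, resolution)
    r = a * T * (T - tmin) * np.sqrt(np.maximum(tmax - T, 0.0))
    return float(T[np.argmax(r)])


def dense_grid_euler_lotka(ages, lxmx, tol=1e-6):
    """Two-level dense-grid root of Σ e^(−r(x+0.5))·lxmx = 1 on [−1, 2]."""
    ages = np.asarray(ages, float)
    lxmx = np.asarray(lxmx, float)
    xm = (ages + 0.5)[lxmx > 0]
    w = lxmx[lxmx > 0]

    def f(r):
        with np.errstate(over="ignore"):
            return np.exp(-np.outer(r, xm)) @ w - 1.0

    lo, hi = -1.0, 2.0
    for step in (1e-3, tol / 2):
        r = np.arange(lo, hi + step, step)
        v = f(r)
        sign = np.signbit(v)
        idx = np.flatnonzero(sign[1:] != sign[:-1])
        if idx.size == 0:  # boundary root
            return lo if abs(v[0]) < abs(v[-1]) else hi
        lo, hi = r[idx[0]], r[idx[0] + 1]
    return 0.5 * (lo + hi)


def expected_cohort_R0_GRR(model, T):
    """Deterministic expected-cohort R0 and GRR at constant temperature.

    Direct arithmetic from the model parameters: immature survival is the
    product of (1−M_i(T)); every adult female lays her full lifetime
    complement f(T)·O(x_death) with x_death = 1 (deterministic senescence
    threshold); female eggs scale by the female ratio.
    """
    s = 1.0
    for st in model.stages:
        p = st.mortality.params
        s *= 1.0 - min(1.0, math.exp(p["b1"] + p["b2"] * T + p["b3"] * T * T))
    fp = model.fecundity.params
    if model.fecundity.form_id == "fecundity_gaussian":
        f = max(0.0, fp["y0"] + fp["a"] * math.exp(-0.5 * ((T - fp["x0"]) / fp["b"]) ** 2))
    else:
        f = math.exp(fp["b1"] + fp["b2"] * T + fp["b3"] * T * T)
    op = model.oviposition.params
    if model.oviposition.form_id == "ovip_gamma":
        o1 = stats.gamma.cdf(1.0, a=op["a"], scale=1.0 / op["b"])
    elif model.oviposition.form_id == "ovip_logistic":
        o1 = 1.0 / (1.0 + math.exp(op["a"] + op["b"]))
    else:
        o1 = 1.0 - math.exp(-(op["a"] + op["b"] + op["c"]))
    grr = model.female_ratio * f * o1
    return s * grr, grr
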