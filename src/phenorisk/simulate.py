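"""Stochastic cohort simulation by rate summation and cohort updating.

A compiled phenology model drives a same-aged cohort of individuals from
the egg stage through larva, pupa and adulthood under a (possibly
fluctuating) daily temperature series:

* **Rate summation** — within each immature stage, physiological age
  accumulates hourly as Σ r(T_h)·Δt using the cosine within-day cycle.
* **Individual variability** — each individual draws a stage-completion
  threshold q = exp(logit(u)/b) at stage entry, the median-1 log-logistic
  quantile implied by the common-slope logit development-time distribution.
* **Mortality** — a daily within-stage death probability
  1 − (1−M(T̄_day))^(Δdev) is applied, where Δdev is the fraction of the
  stage completed that day, so that whole-stage survival at constant
  temperature equals 1 − M(T) (the scale on which M was measured).
* **Adults** — sex is assigned with probability ``female_ratio``; adult age
  is the normalized physiological age x = Σ S(T_h)·Δt (senescence-rate
  summation).  A female lays f(T̄_day)·[O(x_end) − O(x_start)] eggs per day
  and dies when x reaches her senescence threshold (deterministic 1 by
  default, or a log-logistic quantile when an adult slope is configured).

The output is an age-classified life table: l_x (surviving female
fraction) and m_x (female eggs per living female per day), plus a
stage-transition event log and per-stage realized durations/mortalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .forms import ThermalFunctionSpec
from .temperature import TemperatureSeries
from . import thermal

__all__ = ["ImmatureStage", "PhenologyModel", "SimulatedLifeTable", "simulate_cohort"]

IMMATURE_STAGES = ("egg", "larva", "pupa")
STEPS_PER_DAY = 24
MAX_YEARS = 5  # hard cap on cohort lifetime


@dataclass
class ImmatureStage:
    """Development rate, development-time spread and mortality of one stage."""

    name: str
    dev_rate: ThermalFunctionSpec  # briere1
    devtime_slope: float  # common-slope b of the logit distribution; inf = deterministic
    mortality: ThermalFunctionSpec  # mortality_expquad

    def __post_init__(self) -> None:
        if self.dev_rate.form_id != "briere1":
            raise ValueError(f"{self.name}: dev_rate must be briere1")
        if self.mortality.form_id != "mortality_expquad":
            raise ValueError(f"{self.name}: mortality must be mortality_expquad")
        if not self.devtime_slope > 0:
            raise ValueError(f"{self.name}: devtime_slope must be positive")


@dataclass
class PhenologyModel:
    """The compiled per-stage set of thermal functions driving simulation."""

    stages: list[ImmatureStage]
    senescence_female: ThermalFunctionSpec
    senescence_male: ThermalFunctionSpec
    fecundity: ThermalFunctionSpec
    oviposition: ThermalFunctionSpec
    female_ratio: float = 0.5
    adult_slope: float = math.inf  # inf => every adult dies at normalized age 1
    name: str = "unnamed"
    notes: str = ""

    def __post_init__(self) -> None:
        if [s.name for s in self.stages] != list(IMMATURE_STAGES):
            raise ValueError(f"stages must be {IMMATURE_STAGES} in order")
        if not 0.0 <= self.female_ratio <= 1.0:
            raise ValueError("female_ratio must be in [0, 1]")
        for attr, allowed in (
            ("senescence_female", ("senescence_exponential", "senescence_stinner")),
            ("senescence_male", ("senescence_exponential", "senescence_stinner")),
            ("fecundity", ("fecundity_exppoly", "fecundity_gaussian")),
            ("oviposition", ("ovip_cubic_exponential", "ovip_logistic", "ovip_gamma")),
        ):
            spec = getattr(self, attr)
            if spec.form_id not in allowed:
                raise ValueError(f"{attr}: form {spec.form_id!r} not allowed")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "notes": self.notes,
            "female_ratio": self.female_ratio,
            "adult_slope": None if math.isinf(self.adult_slope) else self.adult_slope,
            "stages": {
                s.name: {
                    "dev_rate": s.dev_rate.to_dict(),
                    "devtime_slope": None
                    if math.isinf(s.devtime_slope)
                    else s.devtime_slope,
                    "mortality": s.mortality.to_dict(),
                }
                for s in self.stages
            },
            "senescence_female": self.senescence_female.to_dict(),
            "senescence_male": self.senescence_male.to_dict(),
            "fecundity": self.fecundity.to_dict(),
            "oviposition": self.oviposition.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenologyModel":
        stages = []
        for name in IMMATURE_STAGES:
            s = d["stages"][name]
            slope = s.get("devtime_slope")
            stages.append(
                ImmatureStage(
                    name=name,
                    dev_rate=ThermalFunctionSpec.from_dict(s["dev_rate"]),
                    devtime_slope=math.inf if slope is None else float(slope),
                    mortality=ThermalFunctionSpec.from_dict(s["mortality"]),
                )
            )
        adult_slope = d.get("adult_slope")
        return cls(
            stages=stages,
            senescence_female=ThermalFunctionSpec.from_dict(d["senescence_female"]),
            senescence_male=ThermalFunctionSpec.from_dict(d["senescence_male"]),
            fecundity=ThermalFunctionSpec.from_dict(d["fecundity"]),
            oviposition=ThermalFunctionSpec.from_dict(d["oviposition"]),
            female_ratio=float(d.get("female_ratio", 0.5)),
            adult_slope=math.inf if adult_slope is None else float(adult_slope),
            name=d.get("name", "unnamed"),
            notes=d.get("notes", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PhenologyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedLifeTable:
    """Age-classified life table from one cohort run."""

    ages: np.ndarray  # days since egg, 0..D-1
    lx: np.ndarray  # surviving female fraction, starts at 1, non-increasing
    mx: np.ndarray  # female eggs per living female per day
    viable: bool
    stage_log: dict  # per-individual entry days, death day/stage, sex
    stage_durations: dict[str, float]  # mean realized duration among completers
    stage_mortality: dict[str, float]  # fraction of entrants dying in the stage
    n_individuals: int
    n_females: int
    total_female_eggs: float = 0.0  # female eggs laid by the whole cohort
    n_adult_females: int = 0  # females that reached adulthood

    @property
    def R0(self) -> float:
        """Net reproductive rate Σ l_x·m_x (female eggs per newborn female)."""
        return float(np.sum(self.lx * self.mx))

    @property
    def GRR(self) -> float:
        """Gross reproductive rate: lifetime female eggs per adult female.

        Estimated as the mean realized lifetime female fecundity of the
        females that reached adulthood — the "reproduction ignoring
        immature mortality" quantity.  In a perfectly synchronized cohort
        this equals Σ m_x; the per-adult mean avoids the small-cohort ratio
        bias that the population m_x curve carries when development is
        staggered across individuals.
        """
        if self.n_adult_females == 0:
            return 0.0
        return float(self.total_female_eggs / self.n_adult_females)


def _log_logistic_quantiles(u: np.ndarray, slope: float) -> np.ndarray:
    """Median-1 log-logistic quantile exp(logit(u)/b); slope=inf is the
    deterministic limit (all thresholds exactly 1)."""
    if math.isinf(slope):
        return np.ones_like(u)
    return np.exp(np.log(u / (1.0 - u)) / slope)


def _daily_rates(model: PhenologyModel, temps: TemperatureSeries):
    """Hourly rate summation collapsed to per-day increments.

    Returns per-day development increments for each immature stage, per-day
    mean-temperature mortality per stage, per-day senescence increments for
    each sex, and per-day fecundity f(T̄).
    """
    n = len(temps)
    cosv = np.cos(2.0 * np.pi * np.arange(STEPS_PER_DAY) / STEPS_PER_DAY)
    hourly = (
        0.5 * (temps.tmax + temps.tmin)[:, None]
        - 0.5 * (temps.tmax - temps.tmin)[:, None] * cosv[None, :]
    )
    flat = hourly.ravel()
    dev = np.stack(
        [
            np.asarray(thermal.eval_development_rate(s.dev_rate, flat))
            .reshape(n, STEPS_PER_DAY)
            .mean(axis=1)
            for s in model.stages
        ]
    )
    tmean = temps.tmean
    mort = np.stack(
        [np.asarray(thermal.eval_mortality(s.mortality, tmean)) for s in model.stages]
    )
    sen_f = (
        np.asarray(thermal.eval_senescence(model.senescence_female, flat))
        .reshape(n, STEPS_PER_DAY)
        .mean(axis=1)
    )
    sen_m = (
        np.asarray(thermal.eval_senescence(model.senescence_male, flat))
        .reshape(n, STEPS_PER_DAY)
        .mean(axis=1)
    )
    fec = np.asarray(thermal.eval_total_fecundity(model.fecundity, tmean))
    return dev, mort, sen_f, sen_m, fec


def simulate_cohort(
    model: PhenologyModel,
    temps: TemperatureSeries,
    n_individuals: int = 100,
    seed: int | np.random.Generator = 0,
) -> SimulatedLifeTable:
    """Simulate one cohort of ``n_individuals`` eggs from day 0.

    The temperature series is cycled when the cohort outlives it.  Identical
    seeds produce identical output.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_individuals
    n_days_series = len(temps)
    cap = MAX_YEARS * 365

    dev, mort, sen_f, sen_m, fec = _daily_rates(model, temps)

    # viability short-circuit: a stage that cannot develop anywhere in the
    # series can never be completed
    viable = bool(np.all(dev.max(axis=1) > 0))

    # pre-draw all individual-level randomness so that trajectories are
    # coupled under parameter perturbations (same seed, same draws)
    q = np.stack(
        [
            _log_logistic_quantiles(rng.uniform(1e-12, 1 - 1e-12, n), s.devtime_slope)
            for s in model.stages
        ]
    )  # (3, n) stage thresholds
    is_female = rng.uniform(size=n) < model.female_ratio
    s_adult = _log_logistic_quantiles(rng.uniform(1e-12, 1 - 1e-12, n), model.adult_slope)
    u_die = rng.uniform(size=(cap, n))

    n_females = int(is_female.sum())

    stage = np.zeros(n, dtype=int)  # 0..2 immature, 3 adult
    alive = np.ones(n, dtype=bool)
    age_in_stage = np.zeros(n)
    x_adult = np.zeros(n)  # normalized adult physiological age
    entry_day = np.full((4, n), -1, dtype=int)
    entry_day[0] = 0
    death_day = np.full(n, -1, dtype=int)
    death_stage = np.full(n, -1, dtype=int)

    lx: list[float] = []
    mx: list[float] = []
    total_eggs = 0.0

    if not viable:
        # nobody can complete development; still age the cohort one step so
        # downstream estimators see an explicit non-viable table
        return SimulatedLifeTable(
            ages=np.array([0]),
            lx=np.array([1.0]),
            mx=np.array([0.0]),
            viable=False,
            stage_log={
                "entry_day": entry_day,
                "death_day": death_day,
                "death_stage": death_stage,
                "is_female": is_female,
            },
            stage_durations={s.name: math.nan for s in model.stages},
            stage_mortality={s.name: 1.0 for s in model.stages},
            n_individuals=n,
            n_females=n_females,
        )

    ovip = model.oviposition

    day = 0
    while alive.any() and day < cap:
        d = day % n_days_series
        females_alive = alive & is_female
        lx.append(females_alive.sum() / n_females if n_females else 0.0)
        eggs_today = 0.0
        promoted_today = np.zeros(n, dtype=bool)  # no same-day double processing

        # --- immatures: death, then development, then transition ---------
        for si in range(3):
            sel = alive & (stage == si) & ~promoted_today
            if not sel.any():
                continue
            delta = dev[si, d]
            # fraction of the stage completed today, capped at completion so
            # the per-day exponents sum to exactly 1 over the whole stage
            remaining = q[si, sel] - age_in_stage[sel]
            frac = np.minimum(delta, remaining) / q[si, sel]
            p_die = 1.0 - (1.0 - mort[si, d]) ** frac
            dies = u_die[day, sel] < p_die
            idx = np.flatnonzero(sel)
            dead_idx = idx[dies]
            alive[dead_idx] = False
            death_day[dead_idx] = day
            death_stage[dead_idx] = si
            surv_idx = idx[~dies]
            age_in_stage[surv_idx] += delta
            done = surv_idx[age_in_stage[surv_idx] >= q[si, surv_idx]]
            if done.size:
                stage[done] = si + 1
                age_in_stage[done] = 0.0
                entry_day[si + 1, done] = day + 1
                promoted_today[done] = True

        # --- adults -------------------------------------------------------
        ad = alive & (stage == 3) & ~promoted_today
        if ad.any():
            fem = ad & is_female
            if fem.any():
                x0 = x_adult[fem]
                x1 = np.minimum(x0 + sen_f[d], s_adult[fem])
                if fec[d] > 0:
                    o0 = np.asarray(thermal.eval_oviposition_cdf(ovip, x0))
                    o1 = np.asarray(thermal.eval_oviposition_cdf(ovip, x1))
                    eggs_today = float(fec[d] * np.sum(o1 - o0))
                x_adult[fem] = x0 + sen_f[d]
                dead = np.flatnonzero(fem)[x_adult[fem] >= s_adult[fem]]
                alive[dead] = False
                death_day[dead] = day
                death_stage[dead] = 3
            male = ad & ~is_female
            if male.any():
                x_adult[male] += sen_m[d]
                dead = np.flatnonzero(male)[x_adult[male] >= s_adult[male]]
                alive[dead] = False
                death_day[dead] = day
                death_stage[dead] = 3

        fem_count = females_alive.sum()
        mx.append(model.female_ratio * eggs_today / fem_count if fem_count else 0.0)
        total_eggs += eggs_today
        day += 1

    lx_arr = np.asarray(lx)
    mx_arr = np.asarray(mx)

    durations: dict[str, float] = {}
    mortality: dict[str, float] = {}
    for si, s in enumerate(model.stages):
        entered = entry_day[si] >= 0
        completed = entered & (entry_day[si + 1] >= 0)
        died_in = entered & (death_stage == si)
        durations[s.name] = (
            float(np.mean(entry_day[si + 1, completed] - entry_day[si, completed]))
            if completed.any()
            else math.nan
        )
        mortality[s.name] = (
            float(died_in.sum() / entered.sum()) if entered.any() else math.nan
        )

    return SimulatedLifeTable(
        ages=np.arange(lx_arr.size),
        lx=lx_arr,
        mx=mx_arr,
        viable=True,
        stage_log={
            "entry_day": entry_day,
            "death_day": death_day,
            "death_stage": death_stage,
            "is_female": is_female,
        },
        stage_durations=durations,
        stage_mortality=mortality,
        n_individuals=n,
        n_females=n_females,
        total_female_eggs=model.female_ratio * total_eggs,
        n_adult_females=int(np.sum(is_female & (entry_day[3] >= 0))),
    )
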