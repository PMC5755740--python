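"""End-to-end orchestration: synth → fit → simulate → validate → map.

Each stage reads files written by the previous one (or user-supplied
inputs), writes its outputs into the run directory, and the whole run is
described by a manifest (package version, seeds, config hash, artifact
paths) so that re-running with an identical config reproduces identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .fitting import (
    ObservedResponse,
    fit_devtime_common_slope,
    fit_lifetable_quadratic,
    fit_response,
    responses_from_cohort,
    select_best_model,
)
from .lifetable import estimate_life_table_parameters, validate_against_observed
from .rasters import write_ascii_grid
from .risk import classify_establishment, compute_indices_for_grid
from .simulate import IMMATURE_STAGES, ImmatureStage, PhenologyModel, simulate_cohort
from .synthetic import (
    DESIGN_TEMPERATURES,
    GeneratorConfig,
    generate_adult_observations,
    generate_annual_temperatures,
    generate_cohort_observations,
    generate_temperature_raster,
    reference_models,
)
from .temperature import TemperatureSeries

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "fit_model_from_tables",
           "simulate_constant_temperatures"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str
    seed: int = 1
    model: str = "synthetic_viable"  # fixture name or path to a model YAML
    temperatures: tuple = DESIGN_TEMPERATURES
    n_individuals: int = 100
    n_reps: int = 50
    eri_require_reproduction: bool = False
    lambda_floor: float = 0.5
    establishment_cutoff: float = 0.6
    grid_shape: tuple = (20, 20)
    stages: tuple = ("synth", "fit", "simulate", "validate", "map")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_model(name_or_path: str) -> PhenologyModel:
    fixtures = reference_models()
    if name_or_path in fixtures:
        return fixtures[name_or_path]
    p = Path(name_or_path)
    if not p.exists():
        raise PipelineError(f"model fixture or file not found: {name_or_path}")
    return PhenologyModel.load(p)


# ---------------------------------------------------------------------------
# fit stage

def fit_model_from_tables(
    cohort: pd.DataFrame, eggs: pd.DataFrame, longevity: pd.DataFrame
) -> PhenologyModel:
    """Rebuild a phenology model from observation tables.

    Per immature stage the Brière-1 development rate and exp-quadratic
    mortality are fitted, plus the common-slope development-time logit.
    Adult senescence is fitted to 1/mean-longevity per temperature and sex;
    lifetime fecundity and the cumulative-oviposition curve are fitted with
    the candidate forms and the best AIC wins.
    """
    stages = []
    for name in IMMATURE_STAGES:
        mort, rate, durations = responses_from_cohort(cohort, name)
        rate_fit = fit_response(rate, "briere1")
        mort_fit = fit_response(mort, "mortality_expquad")
        slope = fit_devtime_common_slope(durations).params["b"]
        stages.append(
            ImmatureStage(name, rate_fit.spec, slope, mort_fit.spec)
        )

    sen = {}
    for sex in ("female", "male"):
        sub = longevity[longevity["sex"] == sex]
        by_t = sub.groupby("temperature_C")["longevity_days"].mean()
        resp = ObservedResponse(by_t.index.to_numpy(float), 1.0 / by_t.to_numpy(float))
        sen[sex] = fit_response(resp, "senescence_exponential").spec

    totals = eggs.groupby(["temperature_C", "female_id"])["eggs"].sum().reset_index()
    fec_resp = ObservedResponse(
        totals["temperature_C"].to_numpy(float), totals["eggs"].to_numpy(float)
    )
    fec_fit = select_best_model(
        [fit_response(fec_resp, f) for f in ("fecundity_exppoly", "fecundity_gaussian")]
    )

    mean_lon = longevity[longevity["sex"] == "female"].groupby("temperature_C")[
        "longevity_days"
    ].mean()
    xs, ys = [], []
    for (T, fid), grp in eggs.groupby(["temperature_C", "female_id"]):
        total = grp["eggs"].sum()
        if total <= 0 or T not in mean_lon.index or mean_lon[T] <= 0:
            continue
        grp = grp.sort_values("day")
        xs.append(grp["day"].to_numpy(float) / float(mean_lon[T]))
        ys.append(np.cumsum(grp["eggs"].to_numpy(float)) / total)
    ox = np.concatenate(xs)
    oy = np.concatenate(ys)
    ovip_resp = ObservedResponse(ox, oy)
    ovip_fit = select_best_model(
        [
            fit_response(ovip_resp, f)
            for f in ("ovip_logistic", "ovip_gamma", "ovip_cubic_exponential")
        ]
    )

    return PhenologyModel(
        stages=stages,
        senescence_female=sen["female"],
        senescence_male=sen["male"],
        fecundity=fec_fit.spec,
        oviposition=ovip_fit.spec,
        name="fitted",
        notes="fitted from observation tables",
    )


# ---------------------------------------------------------------------------
# simulate stage

def simulate_constant_temperatures(
    model: PhenologyModel,
    temperatures,
    n_individuals: int,
    n_reps: int,
    seed: int,
) -> pd.DataFrame:
    """Life-table parameter summary over constant-temperature regimes."""
    rows = []
    rng = np.random.default_rng(seed)
    for T in temperatures:
        temps = TemperatureSeries.constant(T)
        tables = [
            simulate_cohort(model, temps, n_individuals, rng)
            for _ in range(n_reps)
        ]
        params = estimate_life_table_parameters(tables)
        row = {"temperature_C": T, **params.as_row()}
        lt = tables[0]
        for st in IMMATURE_STAGES:
            durs = [t.stage_durations[st] for t in tables]
            morts = [t.stage_mortality[st] for t in tables]
            row[f"{st}_duration_days"] = float(np.nanmean(durs))
            row[f"{st}_mortality"] = float(np.nanmean(morts))
        del lt
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full pipeline

def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write a run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }
    artifacts: dict[str, str] = {}

    def _stage(name):
        return name in config.stages

    try:
        model = load_model(config.model)
    except Exception as e:
        raise PipelineError(f"stage config: {e}") from e

    try:
        if _stage("synth"):
            gc = GeneratorConfig(model=model, seed=config.seed,
                                 temperatures=tuple(config.temperatures),
                                 n_per_cohort=config.n_individuals)
            cohort = generate_cohort_observations(gc)
            eggs, longevity = generate_adult_observations(gc)
            series = generate_annual_temperatures("outdoor_like", seed=config.seed)
            cohort.to_csv(out / "cohort_observations.csv", index=False)
            eggs.to_csv(out / "adult_eggs.csv", index=False)
            longevity.to_csv(out / "adult_longevity.csv", index=False)
            series.to_frame().to_csv(out / "annual_temperatures.csv", index=False)
            artifacts["cohort"] = str(out / "cohort_observations.csv")
            manifest["stages"]["synth"] = "ok"
    except Exception as e:
        raise PipelineError(f"stage synth: {e}") from e

    fitted = model
    try:
        if _stage("fit"):
            cohort = pd.read_csv(out / "cohort_observations.csv")
            eggs = pd.read_csv(out / "adult_eggs.csv")
            longevity = pd.read_csv(out / "adult_longevity.csv")
            fitted = fit_model_from_tables(cohort, eggs, longevity)
            fitted.save(out / "fitted_model.yaml")
            artifacts["fitted_model"] = str(out / "fitted_model.yaml")
            manifest["stages"]["fit"] = "ok"
    except FileNotFoundError as e:
        raise PipelineError(f"stage fit: missing input {e.filename}") from e
    except Exception as e:
        raise PipelineError(f"stage fit: {e}") from e

    lambda_fn = None
    try:
        if _stage("simulate"):
            summary = simulate_constant_temperatures(
                fitted, config.temperatures, config.n_individuals,
                config.n_reps, config.seed,
            )
            summary.to_csv(out / "life_table_parameters.csv", index=False)
            artifacts["life_table_parameters"] = str(out / "life_table_parameters.csv")
            viable = summary[summary["viable"].astype(bool)]
            if len(viable) >= 3:
                lambda_fn = fit_lifetable_quadratic(
                    viable[["temperature_C", "lambda"]].to_numpy(float)
                )
                with open(out / "lambda_quadratic.yaml", "w") as fh:
                    yaml.safe_dump(lambda_fn.to_dict(), fh)
            manifest["stages"]["simulate"] = "ok"
    except Exception as e:
        raise PipelineError(f"stage simulate: {e}") from e

    try:
        if _stage("validate"):
            cohort = pd.read_csv(out / "cohort_observations.csv")
            summary = pd.read_csv(out / "life_table_parameters.csv")
            observed, simulated = {}, {}
            for st in IMMATURE_STAGES:
                obs_d, obs_m = [], []
                sim_d, sim_m = [], []
                for T in config.temperatures:
                    sub = cohort[(cohort["stage"] == st)
                                 & (cohort["temperature_C"] == T)]
                    row = summary[summary["temperature_C"] == T]
                    d = sub.loc[sub["survived"], "duration_days"].dropna()
                    if d.empty or row.empty or not math.isfinite(
                        float(row[f"{st}_duration_days"].iloc[0])
                    ):
                        continue
                    obs_d.append(float(d.mean()))
                    obs_m.append(1.0 - float(sub["survived"].mean()))
                    sim_d.append(float(row[f"{st}_duration_days"].iloc[0]))
                    sim_m.append(float(row[f"{st}_mortality"].iloc[0]))
                observed[f"{st}_duration"] = obs_d
                simulated[f"{st}_duration"] = sim_d
                observed[f"{st}_mortality"] = obs_m
                simulated[f"{st}_mortality"] = sim_m
            dist = validate_against_observed(observed, simulated)
            with open(out / "validation_distances.json", "w") as fh:
                json.dump(dist, fh, indent=2)
            artifacts["validation"] = str(out / "validation_distances.json")
            manifest["stages"]["validate"] = "ok"
    except Exception as e:
        raise PipelineError(f"stage validate: {e}") from e

    try:
        if _stage("map"):
            if lambda_fn is None:
                lam_path = out / "lambda_quadratic.yaml"
                if lam_path.exists():
                    from .forms import ThermalFunctionSpec

                    with open(lam_path) as fh:
                        lambda_fn = ThermalFunctionSpec.from_dict(yaml.safe_load(fh))
                else:
                    raise PipelineError(
                        "stage map: no lambda quadratic available (run simulate first)"
                    )
            nr, nc = config.grid_shape
            tmins, tmaxs = generate_temperature_raster(nr, nc, seed=config.seed)
            eri, gi, ai = compute_indices_for_grid(
                fitted, lambda_fn, tmins, tmaxs,
                require_reproduction=config.eri_require_reproduction,
                lambda_floor=config.lambda_floor,
            )
            write_ascii_grid(eri, out / "eri.asc")
            write_ascii_grid(gi, out / "gi.asc")
            write_ascii_grid(ai, out / "ai.asc")
            write_ascii_grid(
                classify_establishment(eri, config.establishment_cutoff),
                out / "establishment.asc",
            )
            artifacts["maps"] = str(out)
            manifest["stages"]["map"] = "ok"
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage map: {e}") from e

    manifest["artifacts"] = artifacts
    manifest["complete"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
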