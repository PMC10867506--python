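"""CSV / YAML readers and writers, run configuration and orchestration.

All tables travel as plain CSV with fixed column schemas; floating-point
values are written with 12 significant digits so a write-read round trip is
value-identical.  Malformed rows are rejected with their line number (1-based,
header = line 1).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import ScenarioComparison, WeightAtAge, compare
from .energy_density import EnergyDensityModel, PiecewiseFit, default_models, fit_piecewise
from .errors import SchemaError
from .params import DietItem, DietSchedule, SpeciesParams, load_species
from .scenarios import (
    NODE_DAYS,
    TagTemperatureSet,
    TemperatureScenario,
    build_assumed,
    nodes_from_daily,
)
from . import synthetic

FLOAT_FMT = "%.12g"


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what}: missing required column {col!r}")


# ---------------------------------------------------------------------------
# Tag temperature CSV: individual_id,date,temp_C

def read_tags(path: str | Path, species: str = "") -> TagTemperatureSet:
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "date", "temp_C"], f"tag file {path}")
    temps = pd.to_numeric(df["temp_C"], errors="coerce")
    bad = temps.isna() | (temps < -1.0) | (temps > 35.0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
        raise SchemaError(
            f"tag file {path}: temperature {df['temp_C'].iloc[line - 2]!r} at "
            f"line {line} outside plausible range [-1, 35] degC"
        )
    df = df.assign(temp_C=temps, date=pd.to_datetime(df["date"]))
    return TagTemperatureSet(records=df, species=species)


def write_tags(tags: TagTemperatureSet, path: str | Path) -> None:
    out = tags.records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Scenario CSV: sim_day,node_flag,temp_C

def write_scenario(scenario: TemperatureScenario, path: str | Path) -> None:
    scenario.to_dataframe().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_scenario(
    path: str | Path, label: str, start: tuple[int, int]
) -> TemperatureScenario:
    df = pd.read_csv(path)
    _require_columns(df, ["sim_day", "node_flag", "temp_C"], f"scenario file {path}")
    if len(df) != 365:
        raise SchemaError(f"scenario file {path}: expected 365 rows, got {len(df)}")
    df = df.sort_values("sim_day")
    daily = df["temp_C"].to_numpy(dtype=float)
    nodes = daily[np.array(NODE_DAYS) - 1]
    return TemperatureScenario(label=label, start=start, nodes=nodes, daily=daily)


# ---------------------------------------------------------------------------
# Diet CSV: prey,proportion,energy_density_J_g,indigestible_fraction

def read_diet(path: str | Path) -> DietSchedule:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["prey", "proportion", "energy_density_J_g", "indigestible_fraction"],
        f"diet file {path}",
    )
    items = tuple(
        DietItem(
            prey=str(r.prey),
            proportion=float(r.proportion),
            energy_density=float(r.energy_density_J_g),
            indigestible_fraction=float(r.indigestible_fraction),
        )
        for r in df.itertuples()
    )
    return DietSchedule(items=items)


def write_diet(diet: DietSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "prey": [i.prey for i in diet.items],
            "proportion": [i.proportion for i in diet.items],
            "energy_density_J_g": [i.energy_density for i in diet.items],
            "indigestible_fraction": [i.indigestible_fraction for i in diet.items],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def packaged_diet(species: str) -> DietSchedule:
    """Diet schedule shipped for a packaged species name."""
    ref = resources.files("thermoniche.data") / f"diet_{species}.csv"
    with resources.as_file(ref) as p:
        return read_diet(p)


# ---------------------------------------------------------------------------
# Weight-at-age CSV: age,weight_g

def read_weight_at_age(path: str | Path) -> WeightAtAge:
    df = pd.read_csv(path)
    _require_columns(df, ["age", "weight_g"], f"weight-at-age file {path}")
    df = df.sort_values("age")
    return WeightAtAge(
        ages=tuple(int(a) for a in df["age"]),
        weights=tuple(float(w) for w in df["weight_g"]),
    )


def write_weight_at_age(waa: WeightAtAge, path: str | Path) -> None:
    pd.DataFrame({"age": waa.ages, "weight_g": waa.weights}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Lipid CSV: weight_g,lipid_mg_g,source[,ed_kJ_g]

def read_lipid(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["weight_g", "lipid_mg_g", "source"], f"lipid file {path}")
    bad = (df["weight_g"] <= 0) | (df["lipid_mg_g"] < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(f"lipid file {path}: invalid record at line {line}")
    return df


def write_lipid(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Energy-density model YAML

def save_ed_model(model: EnergyDensityModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))


def load_ed_model(path: str | Path) -> EnergyDensityModel:
    return EnergyDensityModel.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Trajectory CSV

TRAJ_COLUMNS = [
    "day", "date", "age", "temp_C", "weight_g", "p",
    "C_ggd", "EC", "EF", "EU", "ER", "ES", "dE",
]


def trajectory_to_csv(traj, params: SpeciesParams, path: str | Path) -> None:
    """Write a daily trajectory with calendar dates cycled from the species'
    simulation start on a fixed non-leap reference year."""
    df = traj.to_dataframe()
    m, d = params.sim_start
    anchor = dt.date(2001, m, d)
    dates = [
        (anchor + dt.timedelta(days=int((day - 1) % 365))).strftime("%m-%d")
        for day in df["day"]
    ]
    df.insert(1, "date", dates)
    df = df.rename(columns={"temp_C": "temp_C"})[TRAJ_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# Run configuration and orchestration

@dataclass
class SpeciesRunConfig:
    """Configuration of one species' synthetic end-to-end run."""

    species: str                      # packaged name or path to YAML
    ed_source: str = "fit"            # "fit" or "default"
    diet: str | None = None           # path; None = packaged diet
    lipid_n: int = 1200
    lipid_noise_sd: float = 1.0
    ed_iterations: int = 200
    ed_alpha: float = 0.001
    waa_noise_sd: float = 0.0


@dataclass
class RunConfig:
    """Full demo-run configuration (synthetic inputs, both species)."""

    runs: list[SpeciesRunConfig]
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        runs = [SpeciesRunConfig(**r) for r in doc["runs"]]
        return cls(
            runs=runs,
            seed=int(doc.get("seed", 0)),
            make_plots=bool(doc.get("make_plots", True)),
        )


def demo_config(seed: int = 0) -> RunConfig:
    """The packaged two-species demo configuration."""
    ref = resources.files("thermoniche.data") / "demo_config.yaml"
    with resources.as_file(ref) as p:
        cfg = RunConfig.from_yaml(p)
    cfg.seed = seed
    return cfg


_PROFILES = {
    "lake trout": synthetic.lake_trout_profile,
    "chinook salmon": synthetic.chinook_profile,
}


def _slug(name: str) -> str:
    return name.replace(" ", "_")


@dataclass
class SpeciesRunResult:
    params: SpeciesParams
    diet: DietSchedule
    ed_model: EnergyDensityModel
    ed_fit: PiecewiseFit | None
    observed: TemperatureScenario
    assumed: TemperatureScenario
    waa: WeightAtAge
    comparison: ScenarioComparison


def run_species(
    cfg: SpeciesRunConfig, seed: int, outdir: Path | None = None
) -> SpeciesRunResult:
    """Generate synthetic inputs for one species, build both scenarios, fit
    or load the energy-density model and run the comparison.  If ``outdir``
    is given, every intermediate table is written there as CSV/YAML."""
    params = load_species(cfg.species)
    slug = _slug(params.name)
    diet = read_diet(cfg.diet) if cfg.diet else packaged_diet(slug)

    profile = _PROFILES[params.name](seed=seed)
    tags = synthetic.synth_tags(profile)

    observed = TemperatureScenario.from_tags(tags, params.sim_start, "observed")
    surface = synthetic.synth_surface_daily()
    warmest = nodes_from_daily(surface, params.sim_start)
    assumed = build_assumed(params.optimum_temp, warmest, params.sim_start)

    truth = default_models()[slug]
    ed_fit = None
    if cfg.ed_source == "fit":
        lipid = synthetic.synth_lipid_weight(
            truth, n=cfg.lipid_n, noise_sd=cfg.lipid_noise_sd, seed=seed + 1
        )
        ed_fit = fit_piecewise(
            lipid["weight_g"],
            lipid["ed_kJ_g"],
            iterations=cfg.ed_iterations,
            alpha=cfg.ed_alpha,
            rng=seed + 2,
        )
        ed_model = ed_fit.model
    elif cfg.ed_source == "default":
        lipid = None
        ed_model = truth
    else:
        raise SchemaError(f"ed_source must be 'fit' or 'default', got {cfg.ed_source!r}")

    first, last = params.age_span
    growth = (
        synthetic.LAKE_TROUT_GROWTH
        if params.name == "lake trout"
        else synthetic.CHINOOK_GROWTH
    )
    waa = synthetic.synth_weight_at_age(
        growth,
        range(first, last + 1),
        noise_sd=cfg.waa_noise_sd,
        seed=seed + 3,
        anchor_first=params.start_weight,
    )

    comparison = compare(observed, assumed, waa, diet, ed_model, params)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tags(tags, outdir / f"{slug}_tags.csv")
        write_scenario(observed, outdir / f"{slug}_scenario_observed.csv")
        write_scenario(assumed, outdir / f"{slug}_scenario_assumed.csv")
        write_weight_at_age(waa, outdir / f"{slug}_weight_at_age.csv")
        save_ed_model(ed_model, outdir / f"{slug}_ed_model.yaml")
        if lipid is not None:
            write_lipid(lipid, outdir / f"{slug}_lipid.csv")
        trajectory_to_csv(
            comparison.observed_trajectory, params, outdir / f"{slug}_traj_observed.csv"
        )
        trajectory_to_csv(
            comparison.projected_trajectory,
            params,
            outdir / f"{slug}_traj_assumed_projected.csv",
        )

    return SpeciesRunResult(
        params=params,
        diet=diet,
        ed_model=ed_model,
        ed_fit=ed_fit,
        observed=observed,
        assumed=assumed,
        waa=waa,
        comparison=comparison,
    )


def summary_frame(results: list[SpeciesRunResult]) -> pd.DataFrame:
    """One-row-per-species summary of the comparison metrics.

    Percent columns use the convention positive = assumed-occupancy value
    exceeds the observed-scenario reference.
    """
    rows = []
    for r in results:
        c = r.comparison
        mean_p_asm, mean_p_obs = c.mean_p()
        rows.append(
            {
                "species": c.species,
                "final_weight_observed_g": c.final_weight_observed,
                "final_weight_assumed_g": c.final_weight_projected,
                "final_weight_pct_bias_assumed_minus_observed": c.final_weight_pct_bias,
                "mean_p_assumed": mean_p_asm,
                "mean_p_observed": mean_p_obs,
                "p_ttest_t": c.p_ttest.t,
                "p_ttest_df": c.p_ttest.df,
                "p_ttest_pvalue": c.p_ttest.pvalue,
                "daily_C_pct_bias_assumed_minus_observed": c.daily_C_pct_bias,
                "daily_C_ttest_t": c.daily_C_ttest.t,
                "daily_C_ttest_pvalue": c.daily_C_ttest.pvalue,
                "lifetime_consumption_assumed_kg": c.lifetime_consumption_assumed_kg,
                "lifetime_consumption_observed_kg": c.lifetime_consumption_observed_kg,
                "lifetime_consumption_pct_bias": c.lifetime_consumption_pct_bias,
                "ed_breakpoint_g": r.ed_model.breakpoint,
            }
        )
    return pd.DataFrame(rows)


def run_full(config: RunConfig, outdir: str | Path) -> list[SpeciesRunResult]:
    """End-to-end demo: synthetic data -> ED fit -> scenarios -> comparison,
    writing all tables, the summary CSV and (optionally) three figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = [run_species(cfg, config.seed, outdir) for cfg in config.runs]
    summary_frame(results).to_csv(
        outdir / "comparison_summary.csv", index=False, float_format=FLOAT_FMT
    )
    if config.make_plots:
        from . import plots

        plots.growth_figure(results, outdir / "fig_growth.png")
        plots.feeding_rate_figure(results, outdir / "fig_feeding_rates.png")
        plots.consumption_figure(results, outdir / "fig_consumption.png")
    return results
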