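"""Worldwide projection of prevalence and attack frequency under warming.

Applies the calibrated prevalence line and the Poisson severity model,
cell by cell, to the mean temperature of a one-week Christmas window
(Dec 22-28 by default) computed from a baseline climate file and from one
gridded projection per emission scenario (RCP2.6/4.5/6.0/8.5).  Scenario
maps carry cellwise deltas against the baseline, and area-weighted
(cos-latitude) global summaries support regression testing.

``run_pipeline`` drives the whole analysis from a single JSON config:
read inputs -> assign winter temperatures -> fit both models -> project
baseline and scenarios -> write maps (NetCDF + CSV), fits (JSON), a
summary table (CSV) and a run log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import (
    CHRISTMAS_WINDOW,
    DEFAULT_MAX_RADIUS,
    DEFAULT_VARIABLE,
    CalendarWindow,
    Field2D,
    read_temperature_grid,
    window_mean,
)
from .exceptions import AlignmentError, ConfigError
from .prevalence import (
    LinearPrevalenceFit,
    assign_winter_temps,
    fit_prevalence,
    predict_prevalence,
    read_study_table,
)
from .severity import (
    PoissonSeverityFit,
    fit_poisson,
    predict_weekly_attacks,
    read_diaries,
    weekly_temperature_effect,
)

SCENARIO_NAMES = ("historical", "RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5")


@dataclass
class ScenarioSpec:
    """One climate realisation to project onto."""

    name: str
    climate_path: Path
    target_year: int
    window: CalendarWindow = CHRISTMAS_WINDOW
    variable_name: str = DEFAULT_VARIABLE

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ConfigError(
                f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}"
            )
        self.climate_path = Path(self.climate_path)


@dataclass
class ProjectionMaps:
    """Per-scenario 2D fields; deltas are filled by ``compare_to_baseline``."""

    scenario: ScenarioSpec
    mean_temp: Field2D
    prevalence: Field2D
    weekly_attacks: Field2D
    delta_prevalence: Field2D | None = None
    delta_weekly: Field2D | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form per-cell table (daily attacks included as weekly/7)."""
        df = self.mean_temp.to_dataframe()
        df["prevalence"] = self.prevalence.to_dataframe()["prevalence"].to_numpy()
        weekly = self.weekly_attacks.to_dataframe()["weekly_attacks"].to_numpy()
        df["weekly_attacks"] = weekly
        df["daily_attacks"] = weekly / 7.0
        if self.delta_prevalence is not None:
            df["delta_prevalence"] = self.delta_prevalence.to_dataframe()[
                "delta_prevalence"
            ].to_numpy()
        if self.delta_weekly is not None:
            df["delta_weekly"] = self.delta_weekly.to_dataframe()[
                "delta_weekly"
            ].to_numpy()
        return df

    def to_netcdf(self, path) -> None:
        import xarray as xr

        fields = {
            "mean_temp": self.mean_temp,
            "prevalence": self.prevalence,
            "weekly_attacks": self.weekly_attacks,
        }
        if self.delta_prevalence is not None:
            fields["delta_prevalence"] = self.delta_prevalence
        if self.delta_weekly is not None:
            fields["delta_weekly"] = self.delta_weekly
        ds = xr.Dataset({k: f.to_dataarray() for k, f in fields.items()})
        ds.attrs["scenario"] = self.scenario.name
        ds.attrs["target_year"] = self.scenario.target_year
        ds.to_netcdf(path)


def project_scenario(
    scenario: ScenarioSpec,
    prevalence_fit: LinearPrevalenceFit,
    severity_fit: PoissonSeverityFit,
    apply_threshold: bool = True,
) -> ProjectionMaps:
    """Project both models onto one scenario's Christmas-window climate.

    ``mean_temp`` is the window mean for the scenario's target year;
    prevalence and weekly attacks are evaluated cellwise from the fits.
    Masked (ocean) cells stay NaN in every output field.
    """
    grid = read_temperature_grid(scenario.climate_path, scenario.variable_name)
    mean_temp = window_mean(grid, scenario.window, scenario.target_year)
    prevalence = predict_prevalence(prevalence_fit, mean_temp.values)
    weekly = predict_weekly_attacks(
        severity_fit, mean_temp.values, apply_threshold=apply_threshold
    )
    lat, lon = mean_temp.lat, mean_temp.lon
    return ProjectionMaps(
        scenario=scenario,
        mean_temp=mean_temp,
        prevalence=Field2D(lat, lon, prevalence, name="prevalence", units="%"),
        weekly_attacks=Field2D(
            lat, lon, weekly, name="weekly_attacks", units="attacks/week"
        ),
    )


def compare_to_baseline(
    baseline: ProjectionMaps, scenario: ProjectionMaps
) -> ProjectionMaps:
    """Fill scenario-minus-baseline delta fields (cellwise, exact)."""
    if not baseline.mean_temp.same_grid_as(scenario.mean_temp):
        raise AlignmentError(
            f"scenario {scenario.scenario.name!r} grid does not match baseline grid"
        )
    lat, lon = baseline.mean_temp.lat, baseline.mean_temp.lon
    d_prev = scenario.prevalence.values - baseline.prevalence.values
    d_week = scenario.weekly_attacks.values - baseline.weekly_attacks.values
    scenario.delta_prevalence = Field2D(
        lat, lon, d_prev, name="delta_prevalence", units="percentage points"
    )
    scenario.delta_weekly = Field2D(
        lat, lon, d_week, name="delta_weekly", units="attacks/week"
    )
    return scenario


def area_weighted_mean(fld: Field2D) -> float:
    """cos(latitude)-weighted mean over unmasked cells."""
    w = np.cos(np.radians(fld.lat))[:, None] * np.ones((1, fld.lon.size))
    ok = ~fld.mask
    if not ok.any():
        return float("nan")
    return float(np.average(fld.values[ok], weights=w[ok]))


def summarize_scenarios(maps: list[ProjectionMaps]) -> pd.DataFrame:
    """Area-weighted global summary, one row per scenario."""
    rows = []
    for m in maps:
        row = {
            "scenario": m.scenario.name,
            "target_year": m.scenario.target_year,
            "mean_temp": area_weighted_mean(m.mean_temp),
            "prevalence": area_weighted_mean(m.prevalence),
            "weekly_attacks": area_weighted_mean(m.weekly_attacks),
        }
        if m.delta_prevalence is not None:
            row["delta_prevalence"] = area_weighted_mean(m.delta_prevalence)
            row["delta_weekly"] = area_weighted_mean(m.delta_weekly)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration of a full run (see ``load_config``)."""

    study_table: Path
    climate: dict[str, Path]
    output_dir: Path
    diaries: Path | None = None
    severity_coefficients: Path | None = None
    baseline_year: int = 1999
    target_year: int = 2099
    winter_window: CalendarWindow = field(
        default_factory=lambda: CalendarWindow((11, 1), (3, 31))
    )
    christmas_window: CalendarWindow = field(
        default_factory=lambda: CalendarWindow((12, 22), (12, 28))
    )
    weighting: str = "none"
    attack_threshold_temp: float = 13.0
    threshold_enabled: bool = True
    max_radius: int = DEFAULT_MAX_RADIUS
    variable_name: str = DEFAULT_VARIABLE
    seed: int = 0

    def validate(self) -> None:
        if "historical" not in self.climate:
            raise ConfigError("climate must include a 'historical' file")
        for name, path in self.climate.items():
            if name not in SCENARIO_NAMES:
                raise ConfigError(f"unknown scenario name {name!r} in climate")
            if not Path(path).exists():
                raise ConfigError(f"climate file for {name!r} not found: {path}")
        if not Path(self.study_table).exists():
            raise ConfigError(f"study table not found: {self.study_table}")
        if self.diaries is None and self.severity_coefficients is None:
            raise ConfigError("need either 'diaries' or 'severity_coefficients'")
        for label, path in (
            ("diaries", self.diaries),
            ("severity_coefficients", self.severity_coefficients),
        ):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{label} file not found: {path}")


def _window_from_json(value) -> CalendarWindow:
    (sm, sd), (em, ed) = value
    return CalendarWindow((int(sm), int(sd)), (int(em), int(ed)))


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON pipeline config.

    Keys mirror :class:`PipelineConfig`; windows are written as
    ``[[month, day], [month, day]]``.  All paths are resolved relative to
    the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    base = path.parent

    def _resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    kwargs = dict(raw)
    kwargs["study_table"] = _resolve(raw.get("study_table"))
    kwargs["climate"] = {k: _resolve(v) for k, v in raw.get("climate", {}).items()}
    kwargs["output_dir"] = _resolve(raw.get("output_dir"))
    kwargs["diaries"] = _resolve(raw.get("diaries"))
    kwargs["severity_coefficients"] = _resolve(raw.get("severity_coefficients"))
    if "winter_window" in raw:
        kwargs["winter_window"] = _window_from_json(raw["winter_window"])
    if "christmas_window" in raw:
        kwargs["christmas_window"] = _window_from_json(raw["christmas_window"])
    try:
        cfg = PipelineConfig(**kwargs)
    except TypeError as err:
        raise ConfigError(f"bad config key: {err}") from err
    cfg.validate()
    return cfg


def run_pipeline(config) -> dict:
    """Execute the full analysis described by a config (path or object).

    Writes per-scenario maps (``maps_<scenario>.nc`` / ``.csv``), both fit
    JSONs, ``summary.csv`` and ``run_log.json`` into the output directory
    and returns ``{"maps": [...], "summary": DataFrame, "prevalence_fit":
    ..., "severity_fit": ...}``.  Any stage failure is re-raised with the
    stage name prepended.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as err:
            raise type(err)(f"[stage {name}] {err}") from err

    records = _stage("read_studies", lambda: read_study_table(cfg.study_table))
    hist_grid = _stage(
        "read_baseline_climate",
        lambda: read_temperature_grid(cfg.climate["historical"], cfg.variable_name),
    )
    records = _stage(
        "assign_winter_temps",
        lambda: assign_winter_temps(
            records, hist_grid, cfg.winter_window, cfg.max_radius
        ),
    )
    prevalence_fit = _stage(
        "fit_prevalence", lambda: fit_prevalence(records, cfg.weighting)
    )

    if cfg.diaries is not None:
        severity_fit = _stage(
            "fit_severity",
            lambda: fit_poisson(
                read_diaries(cfg.diaries),
                attack_threshold_temp=cfg.attack_threshold_temp,
            ),
        )
    else:
        severity_fit = _stage(
            "load_severity_coefficients",
            lambda: PoissonSeverityFit.from_json(cfg.severity_coefficients),
        )

    baseline_spec = ScenarioSpec(
        "historical",
        cfg.climate["historical"],
        cfg.baseline_year,
        cfg.christmas_window,
        cfg.variable_name,
    )
    baseline = _stage(
        "project_baseline",
        lambda: project_scenario(
            baseline_spec, prevalence_fit, severity_fit, cfg.threshold_enabled
        ),
    )

    all_maps = [baseline]
    for name in SCENARIO_NAMES[1:]:
        if name not in cfg.climate:
            continue
        spec = ScenarioSpec(
            name, cfg.climate[name], cfg.target_year, cfg.christmas_window,
            cfg.variable_name,
        )
        maps = _stage(
            f"project_{name}",
            lambda spec=spec: compare_to_baseline(
                baseline,
                project_scenario(
                    spec, prevalence_fit, severity_fit, cfg.threshold_enabled
                ),
            ),
        )
        all_maps.append(maps)

    summary = summarize_scenarios(all_maps)
    effect = weekly_temperature_effect(
        severity_fit, apply_threshold=cfg.threshold_enabled
    )

    # --- outputs ---
    prevalence_fit.to_json(out / "prevalence_fit.json")
    severity_fit.to_json(out / "severity_fit.json")
    for m in all_maps:
        tag = m.scenario.name.lower().replace(".", "")
        m.to_netcdf(out / f"maps_{tag}.nc")
        m.to_dataframe().to_csv(
            out / f"maps_{tag}.csv", index=False, float_format="%.10g"
        )
    summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")

    import raynaud

    log = {
        "package_version": raynaud.__version__,
        "python_version": platform.python_version(),
        "seed": cfg.seed,
        "weighting": cfg.weighting,
        "attack_threshold_temp": cfg.attack_threshold_temp,
        "threshold_enabled": cfg.threshold_enabled,
        "baseline_year": cfg.baseline_year,
        "target_year": cfg.target_year,
        "winter_window": [
            list(cfg.winter_window.start_month_day),
            list(cfg.winter_window.end_month_day),
        ],
        "christmas_window": [
            list(cfg.christmas_window.start_month_day),
            list(cfg.christmas_window.end_month_day),
        ],
        "max_radius": cfg.max_radius,
        "variable_name": cfg.variable_name,
        "n_studies": len(records),
        "prevalence_slope": prevalence_fit.slope,
        "prevalence_zero_crossing": (
            prevalence_fit.zero_crossing_temp if prevalence_fit.slope < 0 else None
        ),
        "weekly_effect": {
            "mean_slope": effect.mean_slope,
            "degrees_per_one_fewer_attack": effect.degrees_per_one_fewer_attack,
        },
        "climate_files": {k: str(v) for k, v in cfg.climate.items()},
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "maps": all_maps,
        "summary": summary,
        "prevalence_fit": prevalence_fit,
        "severity_fit": severity_fit,
        "weekly_effect": effect,
        "output_dir": out,
    }


def plot_field(fld: Field2D, ax=None, **kwargs):
    """Optional quick-look pcolormesh of a projected field (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(fld.lon, fld.lat, fld.values, shading="auto", **kwargs)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(f"{fld.name} [{fld.units}]")
    plt.colorbar(mesh, ax=ax)
    return ax
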