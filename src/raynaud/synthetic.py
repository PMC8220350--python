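"""Synthetic climate grids, survey tables and attack diaries with known truth.

Every pipeline stage can be exercised offline: the generators here emulate
the three external inputs — bias-adjusted gridded daily temperature
(CF NetCDF, Kelvin on disk, land-only), a multi-study prevalence survey
table, and pooled n-of-1 attack diaries — each driven by a known ground
truth so that parameter recovery can be checked end to end.

The synthetic climate is deliberately simple: a latitudinal gradient, a
sinusoidal seasonal cycle phased so the northern-hemisphere minimum falls
in mid-January (making the Nov-Mar window the cold season), i.i.d. daily
Gaussian noise, and a uniform warming offset per emission scenario.  It
makes no attempt to mimic real spatial covariance or weather
autocorrelation.

Each generator draws from its own seed-derived stream, so adding one
generator call never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .climate import (
    CalendarWindow,
    Field2D,
    TemperatureGrid,
    WINTER_WINDOW,
    extract_at,
    window_mean,
)
from .exceptions import PlacementError, ValidationError

#: Canonical scenario names and their default uniform end-of-century warming
#: offsets (degC) relative to the historical baseline.
DEFAULT_SCENARIO_OFFSETS: dict[str, float] = {
    "RCP2.6": 1.0,
    "RCP4.5": 2.0,
    "RCP6.0": 3.0,
    "RCP8.5": 4.5,
}

#: Survey sample-size extremes observed across the 20 published studies.
SAMPLE_SIZE_RANGE = (67, 4182)

# Sub-stream tags so each generator has an independent RNG for a given seed.
_STREAM_CLIMATE = 101
_STREAM_STUDIES = 202
_STREAM_DIARIES = 303


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

@dataclass
class ClimateSimParams:
    """Parameters of the synthetic daily temperature fields.

    Defaults give a 5-degree-resolution global grid whose mid-latitude
    winters sit a few degrees below zero — comparable to the winter-mean
    temperatures of the survey sites the prevalence model is calibrated on.
    """

    n_lat: int = 36
    n_lon: int = 72
    equator_temp: float = 27.0  # degC annual mean at the equator
    lat_gradient: float = 0.5  # degC lost per degree of |latitude|
    seasonal_amplitude: float = 8.0  # degC half peak-to-trough seasonal swing
    daily_noise_sd: float = 2.0  # degC i.i.d. daily weather noise
    scenario_offsets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_OFFSETS)
    )
    land_fraction: float = 0.7
    hist_years: tuple[int, int] = (1991, 2000)
    scen_years: tuple[int, int] = (2091, 2100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.daily_noise_sd < 0:
            raise ValidationError("daily_noise_sd must be >= 0")
        if not 0 < self.land_fraction <= 1:
            raise ValidationError("land_fraction must be in (0, 1]")
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValidationError("grid must be at least 2x2")


def _grid_axes(params: ClimateSimParams) -> tuple[np.ndarray, np.ndarray]:
    dlat = 180.0 / params.n_lat
    dlon = 360.0 / params.n_lon
    lat = -90.0 + dlat / 2.0 + dlat * np.arange(params.n_lat)
    lon = -180.0 + dlon / 2.0 + dlon * np.arange(params.n_lon)
    return lat, lon


def _seasonal_cycle(day_of_year: np.ndarray, lat: np.ndarray, amplitude: float):
    """Seasonal term, phased so the NH minimum falls around Jan 15."""
    phase = np.cos(2.0 * np.pi * (day_of_year[:, None] - 15.0) / 365.25)
    hemisphere = np.where(lat >= 0.0, 1.0, -1.0)
    return -amplitude * phase * hemisphere[None, :]


def simulate_temperature_grid(
    params: ClimateSimParams,
    years: tuple[int, int],
    offset: float = 0.0,
    land_mask: np.ndarray | None = None,
) -> TemperatureGrid:
    """Build one in-memory daily grid for [years[0], years[1]] inclusive."""
    lat, lon = _grid_axes(params)
    time = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = time.dayofyear.to_numpy(dtype=float)

    base = params.equator_temp - params.lat_gradient * np.abs(lat)
    seasonal = _seasonal_cycle(doy, lat, params.seasonal_amplitude)
    values = base[None, :, None] + seasonal[:, :, None] + offset
    values = np.broadcast_to(values, (time.size, lat.size, lon.size)).copy()

    rng = _rng(params.seed, _STREAM_CLIMATE)
    if land_mask is None:
        land_mask = rng.random((lat.size, lon.size)) < params.land_fraction
        if not land_mask.any():
            land_mask.flat[0] = True
    if params.daily_noise_sd > 0:
        values += rng.normal(0.0, params.daily_noise_sd, size=values.shape)
    values[:, ~land_mask] = np.nan
    return TemperatureGrid(lat, lon, time, values, land_mask=land_mask)


def write_temperature_grid(grid: TemperatureGrid, path, variable="tasAdjust") -> None:
    """Write a grid as CF NetCDF in Kelvin with NaN-filled ocean cells."""
    da = xr.DataArray(
        grid.values + 273.15,
        coords={"time": grid.time, "lat": grid.lat, "lon": grid.lon},
        dims=("time", "lat", "lon"),
        name=variable,
        attrs={"units": "K", "long_name": "Near-Surface Air Temperature"},
    )
    ds = da.to_dataset()
    ds.to_netcdf(path, encoding={variable: {"_FillValue": 1.0e20}})


def gen_climate(params: ClimateSimParams, out_dir) -> dict[str, Path]:
    """Write one historical plus four scenario NetCDF files.

    The five files share the grid, land mask and daily noise realisation;
    each scenario adds its uniform warming offset, so scenario-minus-
    historical differences are exact at every cell and time step.  Returns
    a mapping ``{"historical": path, "RCP2.6": path, ...}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hist = simulate_temperature_grid(params, params.hist_years)
    paths: dict[str, Path] = {}

    hist_path = out_dir / "tas_day_synthetic_historical.nc"
    write_temperature_grid(hist, hist_path)
    paths["historical"] = hist_path

    # Scenario fields reuse the historical noise (same stream, same draw)
    # shifted to the scenario years and offset uniformly.
    n_hist_days = hist.time.size
    for name, offset in params.scenario_offsets.items():
        scen_time = pd.date_range(
            f"{params.scen_years[0]}-01-01", f"{params.scen_years[1]}-12-31", freq="D"
        )
        doy = scen_time.dayofyear.to_numpy(dtype=float)
        base = params.equator_temp - params.lat_gradient * np.abs(hist.lat)
        seasonal = _seasonal_cycle(doy, hist.lat, params.seasonal_amplitude)
        values = base[None, :, None] + seasonal[:, :, None] + offset
        values = np.broadcast_to(
            values, (scen_time.size, hist.lat.size, hist.lon.size)
        ).copy()
        noise_src = hist.values - (
            base[None, :, None]
            + _seasonal_cycle(
                hist.time.dayofyear.to_numpy(dtype=float),
                hist.lat,
                params.seasonal_amplitude,
            )[:, :, None]
        )
        n = min(n_hist_days, scen_time.size)
        values[:n] += np.nan_to_num(noise_src[:n])
        values[:, ~hist.land_mask] = np.nan
        scen = TemperatureGrid(
            hist.lat, hist.lon, scen_time, values, land_mask=hist.land_mask
        )
        tag = name.lower().replace(".", "")
        path = out_dir / f"tas_day_synthetic_{tag}.nc"
        write_temperature_grid(scen, path)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Survey tables
# ---------------------------------------------------------------------------

@dataclass
class StudySimParams:
    """Ground truth of the synthetic prevalence surveys.

    The default line (slope -0.5 % per degC, intercept 6.5 %) crosses zero
    at 13 degC, the empirical ceiling above which attacks are not observed.
    """

    true_slope: float = -0.5  # % prevalence per degC winter mean
    true_intercept: float = 6.5  # % prevalence at 0 degC
    noise_sd: float = 1.0  # % survey-level noise
    n_sites: int = 20
    latitude_range: tuple[float, float] = (30.0, 60.0)  # degrees north
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValidationError("n_sites must be >= 3")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def gen_studies(
    params: StudySimParams,
    climate: TemperatureGrid,
    window: CalendarWindow = WINTER_WINDOW,
    out_path=None,
) -> pd.DataFrame:
    """Generate a survey table from known prevalence-temperature truth.

    Sites are drawn (with replacement across sites, without within a draw)
    from land cells whose latitude lies inside ``latitude_range``; each is
    assigned a publication year whose preceding winter the climate grid
    covers, and a prevalence
    ``clamp(intercept + slope * winter_mean + noise, 0, 100)``.  Sample
    sizes are log-uniform over the published surveys' extremes [67, 4182].
    """
    rng = _rng(params.seed, _STREAM_STUDIES)
    lo, hi = params.latitude_range
    lat_ok = (climate.lat >= lo) & (climate.lat <= hi)
    ii, jj = np.nonzero(climate.land_mask & lat_ok[:, None])
    if ii.size < 1:
        raise PlacementError(
            f"no land cells with latitude in [{lo}, {hi}] to place sites on"
        )
    if ii.size < params.n_sites:
        raise PlacementError(
            f"only {ii.size} eligible land cells for {params.n_sites} sites"
        )
    pick = rng.choice(ii.size, size=params.n_sites, replace=False)

    first_year = int(climate.time[0].year)
    last_year = int(climate.time[-1].year)
    years_avail = [
        y
        for y in range(first_year, last_year + 1)
        if climate.covers(window.dates(y))
    ]
    if not years_avail:
        raise PlacementError("climate grid covers no complete winter window")
    years = rng.choice(years_avail, size=params.n_sites, replace=True)

    fields: dict[int, Field2D] = {}
    rows = []
    for k, (cell, year) in enumerate(zip(pick, years)):
        i, j = int(ii[cell]), int(jj[cell])
        year = int(year)
        if year not in fields:
            fields[year] = window_mean(climate, window, year)
        lat_c, lon_c = float(climate.lat[i]), float(climate.lon[j])
        wtemp = extract_at(fields[year], lat_c, lon_c, max_radius=0)
        prevalence = np.clip(
            params.true_intercept
            + params.true_slope * wtemp
            + rng.normal(0.0, params.noise_sd),
            0.0,
            100.0,
        )
        log_lo, log_hi = np.log(SAMPLE_SIZE_RANGE)
        sample_size = int(round(np.exp(rng.uniform(log_lo, log_hi))))
        rows.append(
            {
                "study": f"Sim{k + 1:02d}",
                "year": year,
                "country": "Synthetica",
                "city": f"site_{i:02d}_{j:02d}",
                "latitude": lat_c,
                "longitude": lon_c,
                "sample_size": sample_size,
                "prevalence": float(prevalence),
            }
        )
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


# ---------------------------------------------------------------------------
# Attack diaries
# ---------------------------------------------------------------------------

@dataclass
class DiarySimParams:
    """Ground truth of the synthetic n-of-1 attack diaries.

    Defaults produce 4 patients x 550 days = 2200 patient-days, matching
    the scale of the pooled n-of-1 series the severity model class was
    estimated on (over 2000 days of exposure).
    """

    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {"intercept": 0.3, "temperature": -0.12}
    )
    n_patients: int = 4
    n_days: int = 550
    temperature_range: tuple[float, float] = (-5.0, 15.0)
    start_day: str = "1999-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients * self.n_days < 10:
            raise ValidationError("need n_patients * n_days >= 10")
        if "intercept" not in self.true_coefficients:
            raise ValidationError("true_coefficients must include 'intercept'")


def gen_diaries(params: DiarySimParams, out_path=None) -> pd.DataFrame:
    """Generate daily attack diaries from a known log-linear Poisson rate.

    Daily temperatures are uniform on ``temperature_range``; counts are
    Poisson with rate ``exp(b0 + b_T * temperature + ...)`` (extra named
    coefficients draw standard-normal covariate columns of the same name).
    """
    rng = _rng(params.seed, _STREAM_DIARIES)
    n = params.n_patients * params.n_days
    lo, hi = params.temperature_range
    temps = rng.uniform(lo, hi, size=n)
    eta = np.full(n, params.true_coefficients["intercept"], dtype=float)
    extra_cols: dict[str, np.ndarray] = {}
    for name, coef in params.true_coefficients.items():
        if name == "intercept":
            continue
        if name == "temperature":
            eta += coef * temps
        else:
            col = rng.normal(0.0, 1.0, size=n)
            extra_cols[name] = col
            eta += coef * col
    counts = rng.poisson(np.exp(eta))

    days = pd.to_datetime(params.start_day) + pd.to_timedelta(
        np.tile(np.arange(params.n_days), params.n_patients), unit="D"
    )
    df = pd.DataFrame(
        {
            "patient_id": np.repeat(
                [f"P{i + 1:02d}" for i in range(params.n_patients)], params.n_days
            ),
            "day": days,
            "attack_count": counts,
            "temperature": temps,
            **extra_cols,
        }
    )
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df
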