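"""Linear model of Raynaud's phenomenon prevalence versus winter temperature.

Population surveys report the percentage of the general population with
Raynaud's phenomenon; prevalence rises toward colder climates.  This module
reads a survey table (one row per study: site, latitude, sample size,
prevalence %), assigns each study the mean temperature of the winter
(Nov 1 -> Mar 31) preceding its publication year from a gridded climate
dataset, and fits

    prevalence(%) = intercept + slope * winter_mean_temperature(degC)

by (optionally sample-size-weighted) least squares.  The fitted line is
applied on the raw percent scale, clamped to [0, 100]; its downward zero
crossing is the temperature above which predicted prevalence vanishes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate import (
    DEFAULT_MAX_RADIUS,
    CalendarWindow,
    Field2D,
    TemperatureGrid,
    extract_at,
    window_mean,
)
from .exceptions import (
    CoverageError,
    DegenerateDesignError,
    LinkageError,
    NoCrossingError,
    NoLandCellError,
    ValidationError,
)

# Longitudes for the survey sites; the published table gives only latitudes.
# Values are approximate city-centre coordinates (degrees east).
GAZETTEER: dict[str, tuple[float, float]] = {
    "Boston": (42.36, -71.06),
    "Ehime": (33.84, 132.77),
    "Valencia": (39.47, -0.38),
    "South Carolina": (33.84, -80.90),
    "Toulon": (43.12, 5.93),
    "Nyons": (44.36, 5.14),
    "Grenoble": (45.19, 5.72),
    "Tarentaise": (45.37, 6.80),
    "Van": (38.50, 43.38),
    "Southampton": (50.91, -1.40),
    "Wellington": (41.25, 174.78),
    "Vasteras": (59.61, 16.55),
    "Copenhagen": (55.68, 12.57),
    "Athens": (37.98, 23.73),
    "Edirne": (41.15, 26.56),
    "Milan": (45.46, 9.19),
    "Ioannina": (39.77, 20.85),
    "Manchester": (53.48, -2.24),
}


@dataclass
class StudyRecord:
    """One prevalence survey: site, year, size, prevalence, linked climate."""

    study: str
    year: int
    country: str
    city: str
    latitude: float
    longitude: float
    sample_size: int
    prevalence: float
    mean_age: str | None = None
    winter_temp: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 100.0:
            raise ValidationError(
                f"study {self.study!r} ({self.city}): prevalence "
                f"{self.prevalence} outside [0, 100]"
            )
        if self.sample_size < 1:
            raise ValidationError(
                f"study {self.study!r}: sample_size {self.sample_size} < 1"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"study {self.study!r}: latitude {self.latitude} outside [-90, 90]"
            )


def bundled_study_table_path():
    """Path to the packaged 20-study survey table."""
    return resources.files("raynaud.data") / "study_table.csv"


def read_study_table(path=None) -> list[StudyRecord]:
    """Read a survey CSV into validated records.

    Expected header ``study,year,country,city,latitude,sample_size,
    prevalence`` with optional ``longitude`` and ``mean_age`` columns.
    Missing longitudes are filled from the bundled gazetteer; an explicit
    longitude column overrides it.  With ``path=None`` the packaged
    20-study table is read.
    """
    if path is None:
        path = bundled_study_table_path()
    df = pd.read_csv(path)
    required = {"study", "year", "country", "city", "latitude", "sample_size", "prevalence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"study table missing columns: {sorted(missing)}")

    records: list[StudyRecord] = []
    for idx, row in df.iterrows():
        lon = row.get("longitude")
        if lon is None or (isinstance(lon, float) and np.isnan(lon)):
            city = str(row["city"])
            if city not in GAZETTEER:
                raise LinkageError(
                    f"row {idx}: unknown city {city!r} and no longitude column"
                )
            lon = GAZETTEER[city][1]
        try:
            records.append(
                StudyRecord(
                    study=str(row["study"]),
                    year=int(row["year"]),
                    country=str(row["country"]),
                    city=str(row["city"]),
                    latitude=float(row["latitude"]),
                    longitude=float(lon),
                    sample_size=int(row["sample_size"]),
                    prevalence=float(row["prevalence"]),
                    mean_age=str(row["mean_age"]) if "mean_age" in df.columns else None,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {idx}: {err}") from err
    return records


def assign_winter_temps(
    records: list[StudyRecord],
    grid: TemperatureGrid,
    window: CalendarWindow | None = None,
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> list[StudyRecord]:
    """Attach to each study the mean temperature of the winter preceding it.

    For a study published in year Y the window ends in Y (Nov 1 of Y-1
    through Mar 31 of Y by default).  Window means are computed once per
    distinct year and sampled at each site by nearest-land-cell extraction.
    """
    if window is None:
        window = CalendarWindow((11, 1), (3, 31))
    fields: dict[int, Field2D] = {}
    out: list[StudyRecord] = []
    for rec in records:
        try:
            if rec.year not in fields:
                fields[rec.year] = window_mean(grid, window, rec.year)
            temp = extract_at(fields[rec.year], rec.latitude, rec.longitude, max_radius)
        except (CoverageError, NoLandCellError) as err:
            raise type(err)(f"study {rec.study!r} ({rec.city}, {rec.year}): {err}") from err
        out.append(replace(rec, winter_temp=temp))
    return out


@dataclass
class LinearPrevalenceFit:
    """Least-squares line of prevalence (%) on winter temperature (degC)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    n_records: int
    p_value_slope: float
    weighting: str = "none"

    def predict(self, temperature) -> np.ndarray | float:
        return predict_prevalence(self, temperature)

    @property
    def zero_crossing_temp(self) -> float:
        return zero_crossing(self)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "LinearPrevalenceFit":
        if hasattr(source, "read"):
            data = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


def fit_prevalence(
    records: list[StudyRecord], weighting: str = "none"
) -> LinearPrevalenceFit:
    """Fit the prevalence-temperature line by (weighted) least squares.

    ``weighting="sample_size"`` weights each study by its number of
    participants; the default is the unweighted fit.  Requires at least
    three records with distinct winter temperatures.  The slope p-value is
    the two-sided t test with n-2 degrees of freedom.
    """
    if weighting not in ("none", "sample_size"):
        raise ValueError(f"unknown weighting {weighting!r}")
    temps = np.array([r.winter_temp for r in records], dtype=float)
    if np.any(np.isnan(temps)):
        raise ValueError("records must have winter_temp assigned before fitting")
    prev = np.array([r.prevalence for r in records], dtype=float)
    if temps.size < 2:
        raise DegenerateDesignError("need >= 2 records to fit a line")
    if np.unique(temps).size < 2:
        raise DegenerateDesignError("all winter temperatures identical")

    weights = (
        np.array([r.sample_size for r in records], dtype=float)
        if weighting == "sample_size"
        else np.ones_like(temps)
    )
    X = sm.add_constant(temps)
    # n=2 fits a line exactly; df_resid=0 makes SEs NaN without a warning.
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.WLS(prev, X, weights=weights).fit()
        return LinearPrevalenceFit(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            residual_sd=float(np.sqrt(res.scale)),
            n_records=int(temps.size),
            p_value_slope=float(res.pvalues[1]),
            weighting=weighting,
        )


def predict_prevalence(fit: LinearPrevalenceFit, temperature) -> np.ndarray | float:
    """Predicted prevalence (%) at a temperature, clamped to [0, 100].

    NaN inputs (masked grid cells) propagate as NaN.
    """
    t = np.asarray(temperature, dtype=float)
    pred = np.clip(fit.intercept + fit.slope * t, 0.0, 100.0)
    return float(pred) if np.isscalar(temperature) else pred


def zero_crossing(fit: LinearPrevalenceFit) -> float:
    """Temperature (degC) above which predicted prevalence is clamped to 0."""
    if fit.slope >= 0:
        raise NoCrossingError(
            f"slope {fit.slope:.4g} is not negative; prevalence never reaches 0"
        )
    return -fit.intercept / fit.slope


def latitude_fallback_fit(records: list[StudyRecord]) -> LinearPrevalenceFit:
    """Sensitivity fit of prevalence on |latitude| instead of temperature.

    Provided because extrapolating survey sites to the rest of the world can
    be read either as temperature-mediated prediction (the default
    throughout this package) or as a direct latitude regression.  The
    returned object reuses :class:`LinearPrevalenceFit` with ``slope`` in
    % per degree of absolute latitude.
    """
    lats = [abs(r.latitude) for r in records]
    proxied = [replace(r, winter_temp=lat) for r, lat in zip(records, lats)]
    fit = fit_prevalence(proxied)
    return replace(fit, weighting="none")
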