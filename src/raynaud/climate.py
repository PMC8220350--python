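"""Gridded daily temperature I/O and calendar-window statistics.

The pipeline consumes CF-convention NetCDF files of daily near-surface air
temperature on a regular latitude/longitude grid (the ISIMIP ``tasAdjust``
layout: land-only fields, Kelvin on disk, oceans as fill values).  This
module loads such files into :class:`TemperatureGrid`, averages them over
calendar windows (the Nov 1 -> Mar 31 winter used to characterise each
survey's cold-season exposure, or a one-week Christmas window for mapping),
and extracts values at point locations by nearest unmasked cell.

All temperatures are handled in degrees Celsius internally; Kelvin inputs
are converted at load time.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .exceptions import (
    CalendarError,
    CoverageError,
    NoLandCellError,
    UnitsError,
    VariableNotFoundError,
)

#: Default NetCDF variable name (ISIMIP bias-adjusted near-surface air temperature).
DEFAULT_VARIABLE = "tasAdjust"

#: Default search radius (grid rings) for nearest-land-cell point extraction.
DEFAULT_MAX_RADIUS = 3

#: Plausible range for daily near-surface air temperature in Celsius.
_VALID_RANGE_C = (-90.0, 60.0)

_KELVIN_UNITS = {"k", "kelvin", "degrees_kelvin"}
_CELSIUS_UNITS = {"degc", "deg_c", "c", "celsius", "degrees_celsius", "°c"}

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Calendar windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalendarWindow:
    """A recurring calendar window, possibly spanning the year boundary.

    Parameters
    ----------
    start_month_day, end_month_day:
        ``(month, day)`` tuples.  A window whose end precedes its start in
        calendar order (e.g. Nov 1 -> Mar 31) spans the year boundary: the
        window *ending* in year Y starts in year Y-1.
    """

    start_month_day: tuple[int, int] = (11, 1)
    end_month_day: tuple[int, int] = (3, 31)

    def __post_init__(self) -> None:
        for month, day in (self.start_month_day, self.end_month_day):
            # Validate against a leap year so (2, 29) is an acceptable endpoint.
            _dt.date(2000, month, day)

    @property
    def spans_year_boundary(self) -> bool:
        return self.end_month_day < self.start_month_day

    def dates(self, end_year: int) -> pd.DatetimeIndex:
        """All calendar days of the window ending in ``end_year``."""
        start_year = end_year - 1 if self.spans_year_boundary else end_year
        start = _dt.date(start_year, *self.start_month_day)
        end = _dt.date(end_year, *self.end_month_day)
        return pd.date_range(start, end, freq="D")

    def n_days(self, end_year: int) -> int:
        return len(self.dates(end_year))


#: The winter window the prevalence model is calibrated on.
WINTER_WINDOW = CalendarWindow((11, 1), (3, 31))

#: Austral-winter alternative for southern-hemisphere sites.
AUSTRAL_WINTER_WINDOW = CalendarWindow((5, 1), (9, 30))

#: One-week window centred on Christmas, used for the projection maps.
CHRISTMAS_WINDOW = CalendarWindow((12, 22), (12, 28))


# ---------------------------------------------------------------------------
# Grid containers
# ---------------------------------------------------------------------------

@dataclass
class Field2D:
    """A single 2D field on a lat/lon grid; masked cells are NaN."""

    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray
    name: str = "value"
    units: str = "degC"

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError(
                f"field shape {self.values.shape} does not match "
                f"({self.lat.size}, {self.lon.size}) lat/lon axes"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is masked (no value)."""
        return np.isnan(self.values)

    def same_grid_as(self, other: "Field2D") -> bool:
        return (
            self.lat.size == other.lat.size
            and self.lon.size == other.lon.size
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form (lat, lon, value) table, masked cells omitted."""
        lat2, lon2 = np.meshgrid(self.lat, self.lon, indexing="ij")
        df = pd.DataFrame(
            {"lat": lat2.ravel(), "lon": lon2.ravel(), self.name: self.values.ravel()}
        )
        return df.dropna(subset=[self.name]).reset_index(drop=True)

    def to_dataarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            coords={"lat": self.lat, "lon": self.lon},
            dims=("lat", "lon"),
            name=self.name,
            attrs={"units": self.units},
        )

    def to_netcdf(self, path) -> None:
        self.to_dataarray().to_netcdf(path)


@dataclass
class TemperatureGrid:
    """Daily gridded temperature in Celsius with a land mask.

    ``values`` has shape ``(time, lat, lon)``; ocean (or otherwise
    permanently missing) cells hold NaN at every time step and are False in
    ``land_mask``.
    """

    lat: np.ndarray
    lon: np.ndarray
    time: pd.DatetimeIndex
    values: np.ndarray
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_units: str = "degC"

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.time = pd.DatetimeIndex(self.time).normalize()
        self.values = np.asarray(self.values, dtype=float)

        if self.values.shape != (self.time.size, self.lat.size, self.lon.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(time={self.time.size}, lat={self.lat.size}, lon={self.lon.size})"
            )

        # Store days in chronological order regardless of storage order.
        if not self.time.is_monotonic_increasing:
            order = np.argsort(self.time.values, kind="stable")
            self.time = self.time[order]
            self.values = self.values[order]
        self._check_daily_axis()

        if self.land_mask is None:
            self.land_mask = ~np.all(np.isnan(self.values), axis=0)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)

    def check_plausible_celsius(self) -> None:
        """Raise if unmasked values fall outside a plausible Celsius range.

        Applied after loading files: values near +280 "degC" betray a
        missed Kelvin conversion.
        """
        finite = self.values[:, self.land_mask]
        finite = finite[np.isfinite(finite)]
        if finite.size and (
            finite.min() < _VALID_RANGE_C[0] or finite.max() > _VALID_RANGE_C[1]
        ):
            raise UnitsError(
                f"temperatures outside plausible Celsius range "
                f"{_VALID_RANGE_C}: [{finite.min():.2f}, {finite.max():.2f}] — "
                "check the file's units attribute"
            )

    def _check_daily_axis(self) -> None:
        if self.time.size == 0:
            raise CalendarError("empty time axis")
        if self.time.has_duplicates:
            raise CalendarError("time axis contains duplicate days")
        if self.time.size > 1:
            steps = np.diff(self.time.values).astype("timedelta64[D]")
            if not np.all(steps == np.timedelta64(1, "D")):
                raise CalendarError("time axis is not daily (gaps or sub-daily steps)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def covers(self, dates: pd.DatetimeIndex) -> bool:
        return dates.isin(self.time).all()


# ---------------------------------------------------------------------------
# Reading CF NetCDF
# ---------------------------------------------------------------------------

def _convert_units(values: np.ndarray, units: str) -> np.ndarray:
    key = str(units).strip().lower()
    if key in _KELVIN_UNITS:
        return values - 273.15
    if key in _CELSIUS_UNITS:
        return values
    raise UnitsError(f"unsupported temperature units {units!r}")


def read_temperature_grid(path, variable_name: str = DEFAULT_VARIABLE) -> TemperatureGrid:
    """Load a CF-convention daily temperature file into Celsius.

    Fill values declared by ``_FillValue``/``missing_value`` become NaN and
    define the land mask (a cell missing at every time step is ocean).

    Raises
    ------
    VariableNotFoundError
        if ``variable_name`` is absent from the file.
    UnitsError
        if the units attribute is missing or not a Kelvin/Celsius spelling.
    CalendarError
        if the time axis is not strictly daily.
    """
    with xr.open_dataset(path, decode_times=True) as ds:
        if variable_name not in ds.data_vars:
            raise VariableNotFoundError(
                f"variable {variable_name!r} not found in {path}; "
                f"available: {sorted(ds.data_vars)}"
            )
        da = ds[variable_name]
        dims = [d for d in ("time", "lat", "lon") if d in da.dims]
        if len(dims) != 3:
            raise CalendarError(
                f"variable {variable_name!r} must have (time, lat, lon) dims, "
                f"got {da.dims}"
            )
        da = da.transpose("time", "lat", "lon")
        units = da.attrs.get("units")
        if units is None:
            raise UnitsError(f"variable {variable_name!r} has no units attribute")
        values = _convert_units(da.values.astype(float), units)
        time = pd.DatetimeIndex(da["time"].values)
        grid = TemperatureGrid(
            lat=da["lat"].values,
            lon=da["lon"].values,
            time=time,
            values=values,
            source_units=str(units),
        )
        grid.check_plausible_celsius()
        return grid


# ---------------------------------------------------------------------------
# Window means
# ---------------------------------------------------------------------------

def window_mean(grid: TemperatureGrid, window: CalendarWindow, end_year: int) -> Field2D:
    """Per-cell arithmetic mean over every calendar day of the window.

    The window ending in ``end_year`` is resolved on the real (Gregorian)
    calendar, so a Nov 1 -> Mar 31 winter averages 151 days, or 152 when the
    February inside it is a leap February.  Masked cells stay masked.

    Raises
    ------
    CoverageError
        listing the missing dates, if the grid does not hold every day.
    """
    dates = window.dates(end_year)
    present = dates.isin(grid.time)
    if not present.all():
        missing = dates[~present]
        shown = ", ".join(str(d.date()) for d in missing[:10])
        raise CoverageError(
            f"time axis missing {missing.size} of {dates.size} window days "
            f"(window ending {end_year}): {shown}"
            + ("..." if missing.size > 10 else ""),
            missing_dates=missing,
        )
    idx = grid.time.get_indexer(dates)
    mean = grid.values[idx].mean(axis=0)
    mean = np.where(grid.land_mask, mean, np.nan)
    return Field2D(grid.lat, grid.lon, mean, name="mean_temp", units="degC")


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance in kilometres (array-broadcasting)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((p2 - p1) / 2.0) ** 2
        + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def extract_at(
    field: Field2D,
    latitude: float,
    longitude: float,
    max_radius: int = DEFAULT_MAX_RADIUS,
) -> float:
    """Value of the nearest unmasked cell centre to a point.

    Candidates are restricted to ``max_radius`` index rings (Chebyshev
    distance, with longitudinal wrap-around) around the index-nearest cell;
    among unmasked candidates the great-circle-nearest wins, with exact ties
    broken by smaller ``|lat|`` then smaller ``lon``.  Coastal cities on
    land-only grids typically sit over a masked sea cell, which is why a
    ring search rather than the single nearest cell is used.

    Raises
    ------
    NoLandCellError
        if every candidate cell within ``max_radius`` rings is masked.
    """
    if np.isnan(field.values).all():
        raise NoLandCellError("field has no unmasked cell")

    i0 = int(np.argmin(np.abs(field.lat - latitude)))
    dlon = np.abs(field.lon - longitude)
    dlon = np.minimum(dlon, 360.0 - dlon)
    j0 = int(np.argmin(dlon))

    nlat, nlon = field.values.shape
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    dj = np.abs(jj - j0)
    ring = np.maximum(np.abs(ii - i0), np.minimum(dj, nlon - dj))
    candidate = (ring <= max_radius) & ~field.mask
    if not candidate.any():
        raise NoLandCellError(
            f"no unmasked cell within {max_radius} rings of "
            f"({latitude:.2f}, {longitude:.2f})"
        )

    ci, cj = np.nonzero(candidate)
    clat, clon = field.lat[ci], field.lon[cj]
    dist = great_circle_km(latitude, longitude, clat, clon)
    order = np.lexsort((clon, np.abs(clat), dist))
    best = order[0]
    return float(field.values[ci[best], cj[best]])
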