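"""Shared fixtures: tiny in-memory grids and synthetic NetCDF files."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from raynaud import TemperatureGrid


def make_grid(
    lat=None,
    lon=None,
    start="1998-11-01",
    end="1999-03-31",
    fill=0.0,
    land_mask=None,
):
    """Small constant-valued daily grid for unit tests."""
    lat = np.asarray(lat if lat is not None else [40.0, 45.0, 50.0], dtype=float)
    lon = np.asarray(lon if lon is not None else [0.0, 5.0, 10.0], dtype=float)
    time = pd.date_range(start, end, freq="D")
    values = np.full((time.size, lat.size, lon.size), float(fill))
    if land_mask is not None:
        values[:, ~np.asarray(land_mask, dtype=bool)] = np.nan
    return TemperatureGrid(lat, lon, time, values, land_mask=land_mask)


def write_netcdf(path, values, lat, lon, time, variable="tasAdjust", units="K"):
    """Write a raw CF file without any package code (independent of the reader)."""
    da = xr.DataArray(
        np.asarray(values, dtype=float),
        coords={"time": pd.DatetimeIndex(time), "lat": lat, "lon": lon},
        dims=("time", "lat", "lon"),
        name=variable,
        attrs={"units": units},
    )
    da.to_dataset().to_netcdf(path)
    return path


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def netcdf_writer(tmp_path):
    def _write(name="synthetic.nc", **kwargs):
        return write_netcdf(tmp_path / name, **kwargs)

    return _write
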