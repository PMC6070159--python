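"""File formats for gridded fields, station series and population grids.

Gridded fields are written as CF-style NetCDF (dimensions ``time``/``lat``/
``lon``; attributes ``pollutant``, ``units``, ``member_id``, ``scenario_id``)
through xarray, with a plain-CSV fallback (``time,lat,lon,value`` plus
metadata header comments). Stations use a single CSV with one row per
station-hour; missing observations have an empty value field. Population
grids are CSV ``lat,lon,count`` with the age shares in a JSON sidecar block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .core import (
    ConcentrationField,
    DomainSpec,
    POLLUTANTS,
    PopulationGrid,
    StationSeries,
)


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


def _parse_times(values) -> pd.DatetimeIndex | pd.Series:
    """Parse timestamps as UTC and return them timezone-naive (internal
    convention: all times are UTC)."""
    t = pd.to_datetime(values, utc=True)
    if isinstance(t, pd.Series):
        return t.dt.tz_localize(None)
    return t.tz_localize(None)


def _domain_from_axes(
    lats: np.ndarray, lons: np.ndarray, times: pd.DatetimeIndex
) -> DomainSpec:
    if len(lats) < 1 or len(lons) < 1:
        raise ParseError("empty spatial axes")
    res_candidates = []
    for ax in (lats, lons):
        if len(ax) > 1:
            steps = np.diff(ax)
            if np.any(steps <= 0):
                raise ParseError("non-monotone spatial axis")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ParseError("irregular spatial axis")
            res_candidates.append(steps[0])
    if not res_candidates:
        raise ParseError("cannot infer resolution from a 1x1 grid")
    res = float(res_candidates[0])
    times = pd.DatetimeIndex(times)
    if len(times) > 1:
        dt = np.diff(times.values)
        if np.any(dt.astype("timedelta64[s]").astype(int) <= 0):
            raise ParseError("non-monotone time axis")
        if not np.all(dt == np.timedelta64(1, "h")):
            raise ParseError("time axis is not hourly")
    return DomainSpec(
        lon_min=float(lons[0] - res / 2),
        lon_max=float(lons[-1] + res / 2),
        lat_min=float(lats[0] - res / 2),
        lat_max=float(lats[-1] + res / 2),
        resolution=res,
        time_start=times[0],
        time_end=times[-1] + pd.Timedelta(hours=1),
    )


# ---------------------------------------------------------------- fields


def field_to_dataset(field: ConcentrationField) -> xr.Dataset:
    d = field.domain
    da = xr.DataArray(
        field.values,
        dims=("time", "lat", "lon"),
        coords={"time": d.times, "lat": d.lat_centers, "lon": d.lon_centers},
        name="concentration",
        attrs={"units": field.units, "long_name": f"{field.pollutant} concentration"},
    )
    ds = da.to_dataset()
    ds.attrs = {
        "pollutant": field.pollutant,
        "units": field.units,
        "member_id": field.member_id,
        "scenario_id": field.scenario_id,
        "Conventions": "CF-1.8",
    }
    return ds


def write_field(field: ConcentrationField, path: str | Path) -> None:
    """Write a field as NetCDF (``.nc``) or CSV (anything else)."""
    path = Path(path)
    if path.suffix == ".nc":
        field_to_dataset(field).to_netcdf(path, engine="scipy")
    else:
        _write_field_csv(field, path)


def read_field(path: str | Path) -> ConcentrationField:
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        da = ds["concentration"]
        times = pd.DatetimeIndex(da["time"].values)
        domain = _domain_from_axes(
            np.asarray(da["lat"].values), np.asarray(da["lon"].values), times
        )
        pollutant = str(ds.attrs.get("pollutant", ""))
        if pollutant not in POLLUTANTS:
            raise ParseError(f"unknown pollutant code {pollutant!r} in {path.name}")
        return ConcentrationField(
            domain=domain,
            pollutant=pollutant,
            values=np.asarray(da.values, dtype=float),
            units=str(ds.attrs.get("units", "ug/m3")),
            member_id=str(ds.attrs.get("member_id", "unknown")),
            scenario_id=str(ds.attrs.get("scenario_id", "base")),
        )
    return _read_field_csv(path)


def _write_field_csv(field: ConcentrationField, path: Path) -> None:
    d = field.domain
    meta = {
        "pollutant": field.pollutant,
        "units": field.units,
        "member_id": field.member_id,
        "scenario_id": field.scenario_id,
    }
    times = d.times
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time,lat,lon,value\n")
        for it, t in enumerate(times):
            ts = t.strftime("%Y-%m-%dT%H:%M:%SZ")
            for ilat, lat in enumerate(d.lat_centers):
                row = field.values[it, ilat]
                for ilon, lon in enumerate(d.lon_centers):
                    fh.write(f"{ts},{lat:.6f},{lon:.6f},{row[ilon]:.10g}\n")


def _read_field_csv(path: Path) -> ConcentrationField:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    required = {"time", "lat", "lon", "value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path.name}: missing columns {sorted(required - set(df.columns))}")
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ParseError(
            f"{path.name}: negative concentration at data row {int(neg[0]) + 1}"
        )
    pollutant = meta.get("pollutant", "")
    if pollutant not in POLLUTANTS:
        raise ParseError(f"unknown pollutant code {pollutant!r} in {path.name}")
    times = pd.DatetimeIndex(sorted(_parse_times(df["time"].unique())))
    lats = np.array(sorted(df["lat"].unique()))
    lons = np.array(sorted(df["lon"].unique()))
    domain = _domain_from_axes(lats, lons, times)
    n_t, n_lat, n_lon = len(times), len(lats), len(lons)
    if len(df) != n_t * n_lat * n_lon:
        raise ParseError(
            f"{path.name}: {len(df)} rows cannot tile a "
            f"{n_t}x{n_lat}x{n_lon} grid"
        )
    t_idx = times.get_indexer(_parse_times(df["time"]))
    lat_idx = np.searchsorted(lats, df["lat"].values)
    lon_idx = np.searchsorted(lons, df["lon"].values)
    values = np.full((n_t, n_lat, n_lon), np.nan)
    values[t_idx, lat_idx, lon_idx] = df["value"].values
    if np.any(np.isnan(values)):
        raise ParseError(f"{path.name}: grid not fully tiled (duplicate rows?)")
    return ConcentrationField(
        domain=domain,
        pollutant=pollutant,
        values=values,
        units=meta.get("units", "ug/m3"),
        member_id=meta.get("member_id", "unknown"),
        scenario_id=meta.get("scenario_id", "base"),
    )


# ---------------------------------------------------------------- stations


def write_stations(stations: list[StationSeries], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("station_id,lon,lat,pollutant,timestamp_utc,value,units\n")
        for st in stations:
            times = st.domain.times
            for t, v in zip(times, st.values):
                ts = t.strftime("%Y-%m-%dT%H:%M:%SZ")
                sval = "" if np.isnan(v) else f"{v:.10g}"
                fh.write(
                    f"{st.station_id},{st.lon:.6f},{st.lat:.6f},"
                    f"{st.pollutant},{ts},{sval},{st.units}\n"
                )


def read_stations(path: str | Path, domain: DomainSpec) -> list[StationSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"station_id", "lon", "lat", "pollutant", "timestamp_utc", "value", "units"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path.name}: missing columns {sorted(required - set(df.columns))}"
        )
    if len(df) and df["value"].dropna().lt(0).any():
        bad = df.index[df["value"] < 0][0]
        raise ParseError(f"{path.name}: negative observation at data row {int(bad) + 1}")
    times = domain.times
    out: list[StationSeries] = []
    df["timestamp_utc"] = _parse_times(df["timestamp_utc"])
    for (sid, pollutant), grp in df.groupby(["station_id", "pollutant"], sort=True):
        if pollutant not in POLLUTANTS:
            raise ParseError(f"unknown pollutant code {pollutant!r} in {path.name}")
        series = pd.Series(np.nan, index=times)
        idx = grp.set_index("timestamp_utc")["value"]
        inside = idx.index.intersection(times)
        series.loc[inside] = idx.loc[inside]
        out.append(
            StationSeries(
                station_id=str(sid),
                lon=float(grp["lon"].iloc[0]),
                lat=float(grp["lat"].iloc[0]),
                pollutant=str(pollutant),
                values=series.values,
                domain=domain,
                units=str(grp["units"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------- population


def write_population(pop: PopulationGrid, path: str | Path) -> None:
    """CSV ``lat,lon,count`` with age shares embedded as a JSON header comment."""
    path = Path(path)
    d = pop.domain
    with open(path, "w") as fh:
        fh.write(f"# age_shares: {json.dumps(dict(pop.age_shares))}\n")
        fh.write("lat,lon,count\n")
        for ilat, lat in enumerate(d.lat_centers):
            for ilon, lon in enumerate(d.lon_centers):
                fh.write(f"{lat:.6f},{lon:.6f},{pop.counts[ilat, ilon]:.10g}\n")


def read_population(path: str | Path, domain: DomainSpec) -> PopulationGrid:
    path = Path(path)
    age_shares = None
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                if key.strip() == "age_shares":
                    age_shares = json.loads(val)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    if not {"lat", "lon", "count"}.issubset(df.columns):
        raise ParseError(f"{path.name}: expected columns lat,lon,count")
    counts = np.zeros((domain.n_lat, domain.n_lon))
    lat_idx = np.rint((df["lat"].values - domain.lat_min) / domain.resolution - 0.5)
    lon_idx = np.rint((df["lon"].values - domain.lon_min) / domain.resolution - 0.5)
    if (
        lat_idx.min() < 0
        or lon_idx.min() < 0
        or lat_idx.max() >= domain.n_lat
        or lon_idx.max() >= domain.n_lon
    ):
        raise ParseError(f"{path.name}: population cell outside domain grid")
    counts[lat_idx.astype(int), lon_idx.astype(int)] = df["count"].values
    kwargs = {"age_shares": age_shares} if age_shares else {}
    return PopulationGrid(domain=domain, counts=counts, **kwargs)


__all__ = [
    "ParseError",
    "read_field",
    "read_population",
    "read_stations",
    "write_field",
    "write_population",
    "write_stations",
]
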