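"""Shared domain types and grid/time/unit conventions.

The analysis chain operates on hourly pollutant concentration fields on a
regular latitude--longitude grid (the common multi-model grid onto which all
participating models are interpolated, 0.25 degrees by default), sparse hourly
station observations, and a gridded population with age-group shares.

Conventions
-----------
* Grid cells are addressed by 0-based ``(row, col)`` with latitude ascending;
  the center of cell ``(i, j)`` sits at ``min + (index + 0.5) * resolution``.
* The time axis is hourly, UTC, half-open ``[time_start, time_end)``.
* The canonical internal concentration unit is ug/m3 for every pollutant
  (all exposure--response coefficients are expressed per ug/m3); gaseous
  fields given in ppb are converted at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

POLLUTANTS = ("O3", "CO", "SO2", "PM25")

UG_M3 = "ug/m3"
PPB = "ppb"

#: ppb -> ug/m3 molar conversion factors at 20 degC / 1013 hPa.
#: PM25 is a mass concentration and has no ppb representation.
DEFAULT_PPB_TO_UGM3 = {"O3": 2.00, "SO2": 2.66, "CO": 1.16}

AGE_GROUPS = ("infant_lt9mo", "child_lt15", "adult_ge15", "adult_ge30", "adult_ge65")


class UnitError(ValueError):
    """Raised for impossible or unknown unit conversions."""


class OutOfDomainError(ValueError):
    """Raised when a point falls outside the domain bounds."""


def _normalize_units(units: str) -> str:
    u = units.strip().lower().replace("µ", "u").replace("³", "3").replace(" ", "")
    if u in {"ug/m3", "ugm-3", "ugm3"}:
        return UG_M3
    if u == "ppb":
        return PPB
    raise UnitError(f"unknown concentration units {units!r}")


@dataclass(frozen=True)
class DomainSpec:
    """Regular lat-lon grid and hourly UTC period shared by all fields."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    time_start: pd.Timestamp
    time_end: pd.Timestamp
    resolution: float = 0.25
    pollutants: tuple[str, ...] = POLLUTANTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_start", pd.Timestamp(self.time_start))
        object.__setattr__(self, "time_end", pd.Timestamp(self.time_end))
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max")
        if not self.lat_min < self.lat_max:
            raise ValueError("lat_min must be < lat_max")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for lo, hi, name in (
            (self.lon_min, self.lon_max, "lon"),
            (self.lat_min, self.lat_max, "lat"),
        ):
            n = (hi - lo) / self.resolution
            if abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(f"{name} span is not a positive multiple of resolution")
        span_h = (self.time_end - self.time_start) / pd.Timedelta(hours=1)
        if abs(span_h - round(span_h)) > 1e-9 or span_h < 24:
            raise ValueError("time span must cover a whole number of hours, >= 24")
        unknown = set(self.pollutants) - set(POLLUTANTS)
        if unknown:
            raise ValueError(f"unknown pollutants: {sorted(unknown)}")

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_hours(self) -> int:
        return round((self.time_end - self.time_start) / pd.Timedelta(hours=1))

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.time_start, self.time_end, freq="h", inclusive="left")

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min <= lon <= self.lon_max and self.lat_min <= lat <= self.lat_max
        )


def cell_index_for(domain: DomainSpec, lon: float, lat: float) -> tuple[int, int]:
    """0-based (row, col) of the grid cell whose center is nearest the point.

    Points exactly on a shared cell edge are assigned to the lower-index cell.
    """
    if not domain.contains(lon, lat):
        raise OutOfDomainError(f"point (lon={lon}, lat={lat}) outside domain bounds")

    def axis_index(x: float, lo: float, n: int) -> int:
        f = (x - lo) / domain.resolution
        i = int(np.floor(f + 1e-12))
        # a point exactly on an interior edge is equidistant from the two
        # neighbouring centers; the tie goes to the lower index
        if abs(f - round(f)) < 1e-9 and round(f) == i and i > 0:
            i -= 1
        return min(max(i, 0), n - 1)

    return axis_index(lat, domain.lat_min, domain.n_lat), axis_index(
        lon, domain.lon_min, domain.n_lon
    )


@dataclass
class ConcentrationField:
    """Hourly gridded concentrations for one pollutant / member / scenario.

    ``values`` has shape ``(n_hours, n_lat, n_lon)``. Model fields are
    complete (no missing values) and non-negative.
    """

    domain: DomainSpec
    pollutant: str
    values: np.ndarray
    units: str = UG_M3
    member_id: str = "truth"
    scenario_id: str = "base"

    def __post_init__(self) -> None:
        self.units = _normalize_units(self.units)
        if self.pollutant not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.domain.n_hours, self.domain.n_lat, self.domain.n_lon)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match domain {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("model concentration fields must be finite")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def copy_with(self, **kwargs) -> "ConcentrationField":
        out = dict(
            domain=self.domain,
            pollutant=self.pollutant,
            values=self.values.copy(),
            units=self.units,
            member_id=self.member_id,
            scenario_id=self.scenario_id,
        )
        out.update(kwargs)
        return ConcentrationField(**out)


def convert_units(
    field: ConcentrationField,
    target_units: str,
    factors: Mapping[str, float] | None = None,
) -> ConcentrationField:
    """Convert a gaseous concentration field between ppb and ug/m3.

    The conversion is a pollutant-specific multiplicative molar factor
    (20 degC / 1013 hPa defaults), so it is exactly invertible.
    """
    target = _normalize_units(target_units)
    if target == field.units:
        return field.copy_with()
    if field.pollutant == "PM25":
        raise UnitError("PM25 is a mass concentration; ppb is undefined")
    factors = dict(DEFAULT_PPB_TO_UGM3, **(factors or {}))
    if field.pollutant not in factors:
        raise UnitError(f"no conversion factor for pollutant {field.pollutant!r}")
    k = factors[field.pollutant]
    scale = k if target == UG_M3 else 1.0 / k
    return field.copy_with(values=field.values * scale, units=target)


@dataclass
class StationSeries:
    """Hourly observations at a point; NaN marks missing hours."""

    station_id: str
    lon: float
    lat: float
    pollutant: str
    values: np.ndarray
    domain: DomainSpec
    units: str = UG_M3

    def __post_init__(self) -> None:
        self.units = _normalize_units(self.units)
        if not self.domain.contains(self.lon, self.lat):
            raise OutOfDomainError(
                f"station {self.station_id!r} at (lon={self.lon}, lat={self.lat}) "
                "outside domain"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.domain.n_hours,):
            raise ValueError(
                f"station {self.station_id!r}: series length {self.values.shape} "
                f"does not match domain hours ({self.domain.n_hours},)"
            )
        if not np.any(np.isfinite(self.values)):
            raise ValueError(f"station {self.station_id!r} has no valid observations")
        if np.nanmin(self.values) < 0:
            raise ValueError(f"station {self.station_id!r} has negative observations")

    @property
    def cell(self) -> tuple[int, int]:
        return cell_index_for(self.domain, self.lon, self.lat)

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass
class PopulationGrid:
    """Persons per grid cell plus domain-wide age-group shares.

    Age groups overlap by construction: ``adult_ge65 <= adult_ge30 <=
    adult_ge15`` and the three disjoint groups (infants under 9 months,
    children under 15, adults 15+) partition the population.
    """

    domain: DomainSpec
    counts: np.ndarray
    age_shares: Mapping[str, float] = dc_field(
        default_factory=lambda: DEFAULT_AGE_SHARES.copy()
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.domain.n_lat, self.domain.n_lon):
            raise ValueError("population counts shape does not match domain grid")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("population counts must be finite and non-negative")
        s = dict(self.age_shares)
        missing = set(AGE_GROUPS) - set(s)
        if missing:
            raise ValueError(f"missing age-group shares: {sorted(missing)}")
        for g, v in s.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"age share {g}={v} outside [0, 1]")
        if not s["adult_ge65"] <= s["adult_ge30"] + 1e-12 or not s[
            "adult_ge30"
        ] <= s["adult_ge15"] + 1e-12:
            raise ValueError("adult age shares must be nested (ge65 <= ge30 <= ge15)")
        part = s["infant_lt9mo"] + s["child_lt15"] + s["adult_ge15"]
        if abs(part - 1.0) > 1e-9:
            raise ValueError(
                f"infant + child + adult(15+) shares must sum to 1, got {part}"
            )
        self.age_shares = s

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def share(self, age_group: str) -> float:
        if age_group == "all":
            return 1.0
        try:
            return self.age_shares[age_group]
        except KeyError:
            raise ValueError(f"unknown age group {age_group!r}") from None


#: A European-like age structure: ~1 % infants under 9 months, ~16 % children
#: under 15, the rest adults, of whom most are 30+ and ~18 % of the total 65+.
DEFAULT_AGE_SHARES = {
    "infant_lt9mo": 0.01,
    "child_lt15": 0.155,
    "adult_ge15": 0.835,
    "adult_ge30": 0.62,
    "adult_ge65": 0.18,
}


def _check_same_grid(fields) -> None:
    first = fields[0]
    for f in fields[1:]:
        if f.values.shape != first.values.shape:
            raise ValueError("fields have mismatching grid/time shapes")
        if f.pollutant != first.pollutant:
            raise ValueError(
                f"pollutant mismatch: {f.pollutant!r} vs {first.pollutant!r}"
            )
        if f.units != first.units:
            raise ValueError("fields have mismatching units")


__all__ = [
    "AGE_GROUPS",
    "DEFAULT_AGE_SHARES",
    "DEFAULT_PPB_TO_UGM3",
    "POLLUTANTS",
    "PPB",
    "UG_M3",
    "ConcentrationField",
    "DomainSpec",
    "OutOfDomainError",
    "PopulationGrid",
    "StationSeries",
    "UnitError",
    "cell_index_for",
    "convert_units",
]
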