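"""Synthetic study-shaped inputs: truth fields, pseudo-model ensembles,
station observations, population grids and concentration scenarios.

The generators emulate the statistical shape of the real study inputs — a
regular 0.25-degree grid, one year of hourly concentrations with seasonal and
diurnal structure, an ensemble of biased and noisy models scattered around an
unknown truth, a sparse station network concentrated where people live, and
emission-perturbation scenarios — without any chemistry or meteorology. The
emission-to-concentration response of a scenario is modelled as a direct
multiplicative concentration scaling (a linear atmosphere); real responses
are non-linear, which this module deliberately does not emulate.

Every generator is a pure function of its inputs and an explicit integer
seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    ConcentrationField,
    DEFAULT_AGE_SHARES,
    DomainSpec,
    PopulationGrid,
    StationSeries,
)


@dataclass(frozen=True)
class PseudoModelSpec:
    """Bias/noise recipe turning the truth into one ensemble member.

    mult_bias and add_bias mimic systematic model error (e.g. members that
    underestimate PM2.5 by tens of percent), noise_sd the random error, and
    smoothing_cells the loss of spatial detail of coarse models.
    """

    member_id: str
    mult_bias: float = 1.0
    add_bias: float = 0.0
    noise_sd: float = 0.0
    smoothing_cells: int = 0

    def __post_init__(self) -> None:
        if self.mult_bias <= 0:
            raise ValueError("mult_bias must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.smoothing_cells < 0:
            raise ValueError("smoothing_cells must be >= 0")


@dataclass(frozen=True)
class TruthParams:
    """Statistical structure of a generated truth field (all in ug/m3)."""

    mean_level: float
    seasonal_amp: float = 0.0
    diurnal_amp: float = 0.0
    spatial_gradient: float = 0.0
    population_coupling: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_level < 0:
            raise ValueError("mean_level must be non-negative")
        for name in ("seasonal_amp", "diurnal_amp", "spatial_gradient",
                     "population_coupling", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Default truth parameters per pollutant, loosely European-scale annual
#: means: winter-peaking PM2.5/CO/SO2, summer-peaking O3 with a pronounced
#: afternoon diurnal cycle.
DEFAULT_TRUTH_PARAMS: dict[str, TruthParams] = {
    "O3": TruthParams(mean_level=60.0, seasonal_amp=15.0, diurnal_amp=20.0,
                      spatial_gradient=5.0, population_coupling=-0.0, noise_sd=6.0),
    "CO": TruthParams(mean_level=300.0, seasonal_amp=80.0, diurnal_amp=30.0,
                      spatial_gradient=20.0, population_coupling=150.0, noise_sd=25.0),
    "SO2": TruthParams(mean_level=5.0, seasonal_amp=2.0, diurnal_amp=1.0,
                       spatial_gradient=1.0, population_coupling=3.0, noise_sd=0.8),
    "PM25": TruthParams(mean_level=12.0, seasonal_amp=4.0, diurnal_amp=2.0,
                        spatial_gradient=2.0, population_coupling=8.0, noise_sd=1.5),
}

#: Day-of-year at which the seasonal cycle peaks.
SEASONAL_PEAK_DOY = {"O3": 196, "CO": 15, "SO2": 15, "PM25": 15}
#: Hour (UTC) at which the diurnal cycle peaks; mid-afternoon for O3.
DIURNAL_PEAK_HOUR = {"O3": 14, "CO": 8, "SO2": 10, "PM25": 8}


def generate_population(
    domain: DomainSpec,
    total_population: float,
    age_shares: Mapping[str, float] | None = None,
    n_hotspots: int = 5,
    seed: int = 0,
    decay_scale: float = 1.0,
    background: float = 0.05,
) -> PopulationGrid:
    """Population clustered around ``n_hotspots`` centers with exponential
    decay (scale ``decay_scale`` degrees) over a uniform rural background.

    Cell counts are integers obtained by largest-remainder rounding, so they
    sum to ``total_population`` exactly.
    """
    if n_hotspots < 1:
        raise ValueError("n_hotspots must be >= 1")
    if total_population <= 0:
        raise ValueError("total_population must be positive")
    rng = np.random.default_rng(seed)
    lon_c, lat_c = np.meshgrid(domain.lon_centers, domain.lat_centers)
    weight = np.full(lon_c.shape, background)
    for _ in range(n_hotspots):
        hx = rng.uniform(domain.lon_min, domain.lon_max)
        hy = rng.uniform(domain.lat_min, domain.lat_max)
        size = rng.uniform(0.5, 1.5)
        dist = np.hypot(lon_c - hx, lat_c - hy)
        w_h = size * np.exp(-dist / max(decay_scale, 1e-300))
        if w_h.sum() == 0.0:  # decay -> 0 limit: everything in the nearest cell
            w_h = np.zeros_like(dist)
            w_h[np.unravel_index(np.argmin(dist), dist.shape)] = size
        weight += w_h
    raw = weight / weight.sum() * total_population
    floor = np.floor(raw)
    remainder = int(round(total_population - floor.sum()))
    counts = floor
    if remainder > 0:
        frac = (raw - floor).ravel()
        top = np.argsort(frac)[::-1][:remainder]
        counts = floor.ravel()
        counts[top] += 1
        counts = counts.reshape(raw.shape)
    return PopulationGrid(
        domain=domain,
        counts=counts,
        age_shares=dict(age_shares) if age_shares else DEFAULT_AGE_SHARES.copy(),
    )


def generate_truth(
    domain: DomainSpec,
    pollutant: str,
    params: TruthParams | None = None,
    population: PopulationGrid | None = None,
    seed: int = 0,
) -> ConcentrationField:
    """Hourly truth field: mean + annual sinusoid + diurnal sinusoid +
    fixed spatial gradient + population-coupled hotspots + smooth noise,
    clipped at zero."""
    params = params or DEFAULT_TRUTH_PARAMS[pollutant]
    times = domain.times
    doy = times.dayofyear.values + times.hour.values / 24.0
    seasonal = params.seasonal_amp * np.cos(
        2 * np.pi * (doy - SEASONAL_PEAK_DOY[pollutant]) / 365.25
    )
    diurnal = params.diurnal_amp * np.cos(
        2 * np.pi * (times.hour.values - DIURNAL_PEAK_HOUR[pollutant]) / 24.0
    )
    temporal = params.mean_level + seasonal + diurnal  # (T,)

    n_lat, n_lon = domain.n_lat, domain.n_lon
    # gentle south-north gradient plus population coupling
    grad = params.spatial_gradient * (
        np.linspace(-0.5, 0.5, n_lat)[:, None] * np.ones((1, n_lon))
    )
    spatial = grad
    if population is not None and params.population_coupling:
        peak = population.counts.max()
        if peak > 0:
            spatial = spatial + params.population_coupling * (
                population.counts / peak
            )
    values = temporal[:, None, None] + spatial[None, :, :]
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, params.noise_sd, size=values.shape)
        # correlated in space and time so it looks like weather, not static
        noise = ndimage.gaussian_filter(noise, sigma=(6.0, 1.0, 1.0), mode="nearest")
        # renormalize so the requested sd survives the smoothing
        s = noise.std()
        if s > 0:
            noise *= params.noise_sd / s
        values = values + noise
    return ConcentrationField(
        domain=domain,
        pollutant=pollutant,
        values=np.clip(values, 0.0, None),
        member_id="truth",
    )


def perturb_to_member(
    truth: ConcentrationField, spec: PseudoModelSpec, seed: int = 0
) -> ConcentrationField:
    """member = smooth(mult_bias * truth + add_bias) + noise, clipped at 0."""
    values = spec.mult_bias * truth.values + spec.add_bias
    if spec.smoothing_cells > 0:
        size = 2 * spec.smoothing_cells + 1
        values = ndimage.uniform_filter(
            values, size=(1, size, size), mode="nearest"
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return truth.copy_with(
        values=np.clip(values, 0.0, None), member_id=spec.member_id
    )


def sample_observations(
    truth: ConcentrationField,
    n_stations: int,
    obs_noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    population: PopulationGrid | None = None,
    population_weighted: bool = True,
) -> list[StationSeries]:
    """Place stations (preferentially in populated cells) and observe the
    truth at the nearest cell with Gaussian noise and random missing hours."""
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    d = truth.domain
    n_cells = d.n_lat * d.n_lon
    if n_stations > n_cells:
        raise ValueError(f"n_stations={n_stations} exceeds {n_cells} grid cells")
    rng = np.random.default_rng(seed)
    if population is not None and population_weighted:
        w = population.counts.ravel().astype(float)
        w = w + w.sum() / n_cells * 0.01  # small floor: rural stations exist
        p = w / w.sum()
    else:
        p = None
    flat = rng.choice(n_cells, size=n_stations, replace=False, p=p)
    out: list[StationSeries] = []
    for k, cell in enumerate(sorted(flat.tolist())):
        ilat, ilon = divmod(cell, d.n_lon)
        series = truth.values[:, ilat, ilon].copy()
        if obs_noise_sd > 0:
            series = series + rng.normal(0.0, obs_noise_sd, size=series.shape)
            series = np.clip(series, 0.0, None)
        if missing_rate > 0:
            miss = rng.random(series.shape) < missing_rate
            series = series.copy()
            series[miss] = np.nan
        out.append(
            StationSeries(
                station_id=f"ST{k:04d}",
                lon=float(d.lon_centers[ilon]),
                lat=float(d.lat_centers[ilat]),
                pollutant=truth.pollutant,
                values=series,
                domain=d,
                units=truth.units,
            )
        )
    return out


def make_scenario(
    fields: Mapping[str, ConcentrationField],
    response: Mapping[str, float],
    region_mask: np.ndarray | None = None,
    scenario_id: str = "scenario",
) -> dict[str, ConcentrationField]:
    """Scale concentrations inside a region mask (default: whole domain).

    ``response`` maps pollutant -> multiplicative factor in (0, 1]; a 20 %
    emission reduction under the linear-atmosphere assumption is a factor
    of 0.8 on every pollutant.
    """
    out: dict[str, ConcentrationField] = {}
    for pollutant, field in fields.items():
        scale = float(response.get(pollutant, 1.0))
        if not 0.0 < scale <= 1.0:
            raise ValueError(f"scale for {pollutant} must be in (0, 1], got {scale}")
        if region_mask is None:
            values = field.values * scale
        else:
            mask = np.asarray(region_mask, dtype=bool)
            if mask.shape != (field.domain.n_lat, field.domain.n_lon):
                raise ValueError(
                    f"region mask shape {mask.shape} does not match grid "
                    f"({field.domain.n_lat}, {field.domain.n_lon})"
                )
            values = field.values.copy()
            values[:, mask] *= scale
        out[pollutant] = field.copy_with(values=values, scenario_id=scenario_id)
    return out


__all__ = [
    "DEFAULT_TRUTH_PARAMS",
    "PseudoModelSpec",
    "TruthParams",
    "generate_population",
    "generate_truth",
    "make_scenario",
    "perturb_to_member",
    "sample_observations",
]
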