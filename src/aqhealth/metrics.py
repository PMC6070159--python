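"""Concentration metrics consumed by the health-impact stage.

* ``annual_mean`` — per-cell arithmetic mean over the period (CO, SO2, PM2.5).
* ``daily_max_8h`` — per calendar day, the maximum of the 24 running 8-hour
  means whose window *ends* in that day (ozone).
* ``somo35`` — yearly sum of daily-max-8h ozone exceedances above 35 ppb
  (70 ug/m3 at the default molar factor); units ug/m3 * days.

Data-capture rules follow common European reporting practice: an 8-hour
window is valid with at least 6 of its 8 hours present, and a day is valid
with at least 75 % of its available in-period windows valid (18 of 24 for a
full day). Windows reaching before the start of the period are skipped, so
the first day offers only 17 windows. Complete model fields always satisfy
these rules; they only bite for observation-derived series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConcentrationField

#: 35 ppb expressed in ug/m3 with the default O3 molar factor (2.00).
SOMO35_THRESHOLD_UGM3 = 70.0


@dataclass
class MetricField:
    """A reduced concentration metric on the (lat, lon) grid.

    ``values`` is (lat, lon) for annual_mean and somo35, (day, lat, lon)
    for dm8h.
    """

    pollutant: str
    metric: str  # annual_mean | dm8h | somo35
    values: np.ndarray
    units: str


def annual_mean(field: ConcentrationField) -> MetricField:
    """Per-cell arithmetic mean over all hours of the period."""
    if field.values.shape[0] == 0:
        raise ValueError("empty time axis")
    return MetricField(
        pollutant=field.pollutant,
        metric="annual_mean",
        values=field.values.mean(axis=0),
        units=field.units,
    )


def _running_8h_means(values: np.ndarray, min_valid: int = 6) -> np.ndarray:
    """8-hour running means ending at each hour t (hours t-7..t).

    NaN-aware: a window with fewer than ``min_valid`` valid hours is NaN;
    otherwise the mean of its valid hours. Windows with t < 7 (reaching
    before the period) are NaN.
    """
    v = np.asarray(values, dtype=float)
    valid = np.isfinite(v)
    filled = np.where(valid, v, 0.0)
    # prepend a zero slab so window sums are cumsum[t+1] - cumsum[t-7]
    pad = [(1, 0)] + [(0, 0)] * (v.ndim - 1)
    csum = np.cumsum(np.pad(filled, pad), axis=0)
    ccnt = np.cumsum(np.pad(valid.astype(np.int64), pad), axis=0)
    t = v.shape[0]
    out = np.full(v.shape, np.nan)
    if t < 8:
        return out
    wsum = csum[8:] - csum[:-8]
    wcnt = ccnt[8:] - ccnt[:-8]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(wcnt >= min_valid, wsum / wcnt, np.nan)
    out[7:] = means
    return out


def daily_max_8h(
    field: ConcentrationField,
    min_valid_hours: int = 6,
    day_capture: float = 0.75,
) -> MetricField:
    """Daily maximum of the running 8-hour means, per calendar day (UTC)."""
    t = field.values.shape[0]
    if t % 24 != 0 or t == 0:
        raise ValueError("period must cover whole days for daily metrics")
    n_days = t // 24
    win = _running_8h_means(field.values, min_valid=min_valid_hours)
    by_day = win.reshape(n_days, 24, *field.values.shape[1:])
    valid = np.isfinite(by_day)
    n_valid = valid.sum(axis=1)
    available = np.full((n_days,) + (1,) * (by_day.ndim - 2), 24, dtype=float)
    available[0] = 17  # day 1: the 7 windows reaching before the period are skipped
    with np.errstate(invalid="ignore"):
        dmax = np.nanmax(np.where(valid, by_day, -np.inf), axis=1)
    dmax = np.where(n_valid >= np.ceil(day_capture * available), dmax, np.nan)
    dmax = np.where(np.isfinite(dmax), dmax, np.nan)
    return MetricField(
        pollutant=field.pollutant, metric="dm8h", values=dmax, units=field.units
    )


def somo35(
    dm8h: MetricField, threshold: float = SOMO35_THRESHOLD_UGM3
) -> MetricField:
    """Sum of positive daily-max-8h exceedances above ``threshold``.

    Invalid (NaN) days contribute zero exceedance.
    """
    if dm8h.metric != "dm8h":
        raise ValueError("somo35 expects a dm8h metric field")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    exceed = np.clip(dm8h.values - threshold, 0.0, None)
    values = np.nansum(np.where(np.isfinite(dm8h.values), exceed, 0.0), axis=0)
    return MetricField(
        pollutant=dm8h.pollutant,
        metric="somo35",
        values=values,
        units=f"{dm8h.units} days",
    )


def compute_metric_set(
    fields: dict[str, ConcentrationField],
    somo35_threshold: float = SOMO35_THRESHOLD_UGM3,
) -> dict[tuple[str, str], MetricField]:
    """All metrics the outcome catalog can reference, keyed (pollutant, metric).

    Annual means for every pollutant; SOMO35 (via DM8H) for O3.
    """
    out: dict[tuple[str, str], MetricField] = {}
    for pollutant, field in fields.items():
        out[(pollutant, "annual_mean")] = annual_mean(field)
        if pollutant == "O3":
            out[("O3", "somo35")] = somo35(
                daily_max_8h(field), threshold=somo35_threshold
            )
    return out


__all__ = [
    "MetricField",
    "SOMO35_THRESHOLD_UGM3",
    "annual_mean",
    "compute_metric_set",
    "daily_max_8h",
    "somo35",
]
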