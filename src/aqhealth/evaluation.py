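"""Model skill against station observations.

Hourly model values are sampled at the grid cell nearest each station and
filtered on observation availability; statistics can be computed on the
hourly pairs directly or on monthly means of the pairs. The four skill
scores are Pearson correlation r, normalized mean bias NMB = sum(M-O)/sum(O),
normalized mean gross error NMGE = sum|M-O|/sum(O), and RMSE (with MSE =
RMSE^2 retained for ensemble subset selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConcentrationField, StationSeries


@dataclass
class PairedSeries:
    """Model/observation values at one station, valid hours only."""

    station_id: str
    pollutant: str
    model: np.ndarray
    obs: np.ndarray
    hours: pd.DatetimeIndex  # timestamps of the retained pairs

    def __post_init__(self) -> None:
        if len(self.model) != len(self.obs) or len(self.model) != len(self.hours):
            raise ValueError("model/obs/hours must have equal lengths")
        if len(self.model) < 1:
            raise ValueError("paired series must contain at least one pair")
        if not (np.all(np.isfinite(self.model)) and np.all(np.isfinite(self.obs))):
            raise ValueError("paired series must contain no missing entries")


@dataclass
class EvalStats:
    member_id: str
    pollutant: str
    period: str  # "hourly" | "monthly"
    n_pairs: int
    r: float  # NaN when undefined (constant series)
    nmb: float
    nmge: float
    rmse: float

    @property
    def mse(self) -> float:
        return self.rmse**2


def pair_model_obs(
    field: ConcentrationField, stations: list[StationSeries]
) -> list[PairedSeries]:
    """Sample the model at each station's nearest cell and drop hours with
    missing observations. Stations with no valid overlap are excluded with
    a warning."""
    times = field.domain.times
    out: list[PairedSeries] = []
    for st in stations:
        if st.pollutant != field.pollutant:
            raise ValueError(
                f"station {st.station_id!r} observes {st.pollutant}, "
                f"field is {field.pollutant}"
            )
        if st.units != field.units:
            raise ValueError(f"station {st.station_id!r} units differ from field")
        ilat, ilon = st.cell
        model = field.values[:, ilat, ilon]
        mask = np.isfinite(st.values)
        if not mask.any():
            warnings.warn(
                f"station {st.station_id!r}: no valid observation hours; excluded",
                stacklevel=2,
            )
            continue
        out.append(
            PairedSeries(
                station_id=st.station_id,
                pollutant=st.pollutant,
                model=model[mask].astype(float),
                obs=st.values[mask].astype(float),
                hours=times[mask],
            )
        )
    return out


def monthly_series(
    pairs: PairedSeries, min_valid_frac: float = 0.25
) -> PairedSeries:
    """Average a station's pairs to calendar months.

    Months where fewer than ``min_valid_frac`` of the month's hours have
    valid pairs are dropped. The returned ``hours`` hold the first day of
    each retained month.
    """
    df = pd.DataFrame(
        {"model": pairs.model, "obs": pairs.obs}, index=pairs.hours
    )
    grouped = df.groupby(pd.Grouper(freq="MS"))
    rows = []
    idx = []
    for month_start, grp in grouped:
        hours_in_month = pd.Period(month_start, freq="M").days_in_month * 24
        if len(grp) >= min_valid_frac * hours_in_month and len(grp) > 0:
            rows.append((grp["model"].mean(), grp["obs"].mean()))
            idx.append(month_start)
    if not rows:
        raise ValueError(
            f"station {pairs.station_id!r}: all months fall below the "
            f"{min_valid_frac:.0%} validity floor"
        )
    model, obs = map(np.array, zip(*rows))
    return PairedSeries(
        station_id=pairs.station_id,
        pollutant=pairs.pollutant,
        model=model,
        obs=obs,
        hours=pd.DatetimeIndex(idx),
    )


def _concat(pairs: PairedSeries | list[PairedSeries]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, PairedSeries):
        pairs = [pairs]
    if not pairs:
        raise ValueError("no paired series to evaluate")
    m = np.concatenate([p.model for p in pairs])
    o = np.concatenate([p.obs for p in pairs])
    return m, o


def evaluate(
    pairs: PairedSeries | list[PairedSeries],
    member_id: str = "member",
    period: str = "hourly",
) -> EvalStats:
    """Skill statistics over the pooled pairs of one or more stations.

    r is NaN (undefined, not zero) when either series is constant; NMB and
    NMGE are NaN when the observations sum to zero.
    """
    m, o = _concat(pairs)
    pollutant = (pairs[0] if isinstance(pairs, list) else pairs).pollutant
    diff = m - o
    rmse = float(np.sqrt(np.mean(diff**2)))
    so = o.sum()
    if so > 0:
        nmb = float(diff.sum() / so)
        nmge = float(np.abs(diff).sum() / so)
    else:
        nmb = nmge = float("nan")
    if len(m) >= 2 and np.std(m) > 0 and np.std(o) > 0:
        r = float(np.corrcoef(m, o)[0, 1])
    else:
        r = float("nan")
    return EvalStats(
        member_id=member_id,
        pollutant=pollutant,
        period=period,
        n_pairs=len(m),
        r=r,
        nmb=nmb,
        nmge=nmge,
        rmse=rmse,
    )


def station_annual_bias(pairs: list[PairedSeries]) -> dict[str, float]:
    """Signed per-station bias (model mean - obs mean) in field units."""
    return {
        p.station_id: float(p.model.mean() - p.obs.mean()) for p in pairs
    }


def stats_to_frame(stats: list[EvalStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "member": s.member_id,
                "pollutant": s.pollutant,
                "period": s.period,
                "n": s.n_pairs,
                "r": s.r,
                "NMB": s.nmb,
                "NMGE": s.nmge,
                "RMSE": s.rmse,
            }
            for s in stats
        ]
    )


__all__ = [
    "EvalStats",
    "PairedSeries",
    "evaluate",
    "monthly_series",
    "pair_model_obs",
    "station_annual_bias",
    "stats_to_frame",
]
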