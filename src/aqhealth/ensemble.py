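"""Multi-model ensemble construction.

Three combinations of the member fields are supported:

* the equal-weight all-member mean (the classic multi-model mean),
* the per-cell, per-hour median,
* the *optimal* reduced ensemble: the non-empty member subset whose mean
  minimizes the mean squared error against the station observations. The
  MSE is evaluated on the hourly valid station pairs and the winning subset
  mean is then extended to the whole domain. One static subset is selected
  per pollutant.

The subset search is exhaustive (2^N - 1 candidates; capped at N = 15 by
default, i.e. 32 767 subsets), which is exact and cheap at study scale.
Ties are broken toward the smaller subset, then lexicographic member order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import ConcentrationField, StationSeries, _check_same_grid
from .evaluation import pair_model_obs


def combine_mean(fields: list[ConcentrationField]) -> ConcentrationField:
    """Per-cell, per-hour arithmetic mean of the members."""
    if not fields:
        raise ValueError("need at least one field")
    _check_same_grid(fields)
    values = np.mean([f.values for f in fields], axis=0)
    return fields[0].copy_with(values=values, member_id="MM_mean")


def combine_median(fields: list[ConcentrationField]) -> ConcentrationField:
    """Per-cell, per-hour median (mean of the central two for even counts)."""
    if not fields:
        raise ValueError("need at least one field")
    _check_same_grid(fields)
    values = np.median([f.values for f in fields], axis=0)
    return fields[0].copy_with(values=values, member_id="MM_median")


@dataclass
class EnsembleSelection:
    pollutant: str
    member_ids: tuple[str, ...]
    station_mse: float
    candidate_count: int
    all_member_mse: float
    per_subset_mse: dict[tuple[str, ...], float] | None = None


def _station_matrix(
    fields: list[ConcentrationField], stations: list[StationSeries]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack each member's station-hour values (rows) against the pooled
    valid observations (columns follow station, then hour order)."""
    per_member = []
    obs_ref: np.ndarray | None = None
    for f in fields:
        pairs = pair_model_obs(f, stations)
        if not pairs:
            raise ValueError("no station has valid pairs with the model fields")
        m = np.concatenate([p.model for p in pairs])
        o = np.concatenate([p.obs for p in pairs])
        if obs_ref is None:
            obs_ref = o
        per_member.append(m)
    return np.vstack(per_member), obs_ref


def select_optimal_subset(
    fields: list[ConcentrationField],
    stations: list[StationSeries],
    max_members: int = 15,
    keep_subset_mses: bool = False,
) -> tuple[EnsembleSelection, ConcentrationField]:
    """Exhaustively search all non-empty member subsets for the minimum
    station MSE and return the winning subset plus its domain-wide mean."""
    if not fields:
        raise ValueError("need at least one field")
    _check_same_grid(fields)
    n = len(fields)
    if n > max_members:
        raise ValueError(
            f"{n} members exceed the exhaustive-search cap of {max_members}; "
            "raise max_members to proceed"
        )
    matrix, obs = _station_matrix(fields, stations)
    member_ids = [f.member_id for f in fields]

    best_mse = np.inf
    best_subset: tuple[int, ...] | None = None
    count = 0
    per_subset: dict[tuple[str, ...], float] = {}
    # sizes ascending + lexicographic order inside a size = the stated tie rule,
    # combined with a strict improvement test
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            count += 1
            pred = matrix[list(subset)].mean(axis=0)
            mse = float(np.mean((pred - obs) ** 2))
            if keep_subset_mses:
                per_subset[tuple(member_ids[i] for i in subset)] = mse
            if mse < best_mse:
                best_mse = mse
                best_subset = subset
    assert best_subset is not None
    all_mse = float(np.mean((matrix.mean(axis=0) - obs) ** 2))
    chosen = [fields[i] for i in best_subset]
    combined = combine_mean(chosen)
    combined.member_id = "MM_opt"
    selection = EnsembleSelection(
        pollutant=fields[0].pollutant,
        member_ids=tuple(member_ids[i] for i in best_subset),
        station_mse=best_mse,
        candidate_count=count,
        all_member_mse=all_mse,
        per_subset_mse=per_subset if keep_subset_mses else None,
    )
    return selection, combined


__all__ = [
    "EnsembleSelection",
    "combine_mean",
    "combine_median",
    "select_optimal_subset",
]
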