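"""Base-vs-perturbation scenario differencing.

A perturbation scenario (e.g. a 20 % anthropogenic emission reduction,
represented here as alternative concentration fields) is assessed with the
same catalog and population as the base case; differencing the two gives
avoided responses, avoided premature deaths and avoided external costs
(negative deltas = avoided). Percent changes aggregated over cells are
population-weighted: the ratio of summed deltas to summed base responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .health import HealthImpactTable
from .valuation import CostTable


@dataclass
class ScenarioDelta:
    scenario_id: str
    member_id: str
    outcome_delta: dict[str, float]  # perturbed - base responses
    outcome_percent: dict[str, float]  # 100*delta/base; NaN when base == 0
    delta_pd: float  # premature deaths
    delta_cost: float  # EUR
    delta_pd_grid: np.ndarray | None = None


def delta_assessment(
    base_impacts: HealthImpactTable,
    base_costs: CostTable,
    scen_impacts: HealthImpactTable,
    scen_costs: CostTable,
    scenario_id: str = "scenario",
) -> ScenarioDelta:
    """Per-outcome, premature-death and cost differences (scenario - base)."""
    if set(base_impacts.outcomes) != set(scen_impacts.outcomes):
        raise ValueError("base and scenario assessments use different catalogs")
    if base_impacts.lifetable_factor != scen_impacts.lifetable_factor:
        raise ValueError("base and scenario use different lifetable factors")
    outcome_delta: dict[str, float] = {}
    outcome_percent: dict[str, float] = {}
    for code, base_r in base_impacts.outcomes.items():
        scen_r = scen_impacts.outcomes[code]
        d = scen_r.total - base_r.total
        outcome_delta[code] = d
        outcome_percent[code] = (
            100.0 * d / base_r.total if base_r.total != 0 else float("nan")
        )
    delta_pd = scen_impacts.total_premature_deaths - base_impacts.total_premature_deaths
    pd_grid = None
    if base_impacts.pd_grid is not None and scen_impacts.pd_grid is not None:
        pd_grid = scen_impacts.pd_grid - base_impacts.pd_grid
    return ScenarioDelta(
        scenario_id=scenario_id,
        member_id=base_impacts.member_id,
        outcome_delta=outcome_delta,
        outcome_percent=outcome_percent,
        delta_pd=delta_pd,
        delta_cost=scen_costs.total - base_costs.total,
        delta_pd_grid=pd_grid,
    )


def delta_map(base_grid: np.ndarray, scen_grid: np.ndarray) -> np.ndarray:
    """Cell-wise percent change 100*(scen-base)/base; NaN where base == 0."""
    base = np.asarray(base_grid, dtype=float)
    scen = np.asarray(scen_grid, dtype=float)
    if base.shape != scen.shape:
        raise ValueError(f"grid shapes differ: {base.shape} vs {scen.shape}")
    out = np.full(base.shape, np.nan)
    nz = base != 0
    out[nz] = 100.0 * (scen[nz] - base[nz]) / base[nz]
    return out


def multi_model_delta_summary(deltas: list[ScenarioDelta]) -> pd.DataFrame:
    """Mean and sample standard deviation of member deltas per scenario.

    With a single member the sd is reported as NaN (undefined).
    """
    if not deltas:
        raise ValueError("need at least one scenario delta")
    df = pd.DataFrame(
        {
            "scenario": [d.scenario_id for d in deltas],
            "member": [d.member_id for d in deltas],
            "delta_pd": [d.delta_pd for d in deltas],
            "delta_cost": [d.delta_cost for d in deltas],
        }
    )
    grouped = df.groupby("scenario")[["delta_pd", "delta_cost"]]
    summary = grouped.agg(["mean", lambda x: x.std(ddof=1), "count"])
    summary.columns = [
        "delta_pd_mean", "delta_pd_sd", "n",
        "delta_cost_mean", "delta_cost_sd", "n2",
    ]
    summary = summary.drop(columns="n2")
    return summary


__all__ = [
    "ScenarioDelta",
    "delta_assessment",
    "delta_map",
    "multi_model_delta_summary",
]
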