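"""Economic valuation of health responses (EUR, 2013 prices).

Each outcome's cost is its response times the catalog unit value: chronic
mortality is valued per year of life lost (VOLY, EUR 57 510), acute and
infant deaths per case prevented (EUR 1 532 099 and EUR 2 298 148), and
morbidity per case/day/episode. Costs are attributed to pollutants by
splitting multi-component outcomes (heart failure, hospital admissions,
restricted activity days) according to their component-wise cost shares,
so the pollutant columns always sum to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .core import POLLUTANTS
from .health import HealthImpactTable, OutcomeSpec


@dataclass
class CostTable:
    member_id: str
    outcome_costs: dict[str, float]  # EUR per outcome code
    pollutant_costs: dict[str, float] = dc_field(default_factory=dict)

    @property
    def total(self) -> float:
        if self.outcome_costs:
            return float(sum(self.outcome_costs.values()))
        return float(sum(self.pollutant_costs.values()))


def value_impacts(
    impacts: HealthImpactTable, catalog: list[OutcomeSpec] | None = None
) -> CostTable:
    """cost_outcome = response * unit_value, plus pollutant attribution."""
    outcome_costs: dict[str, float] = {}
    pollutant_costs: dict[str, float] = {p: 0.0 for p in POLLUTANTS}
    for code, result in impacts.outcomes.items():
        spec = result.spec
        cost = result.total * spec.unit_value_eur
        outcome_costs[code] = cost
        # component responses carry the pollutant attribution
        for comp, comp_total in zip(spec.components, result.component_totals):
            pollutant_costs[comp.pollutant] += comp_total * spec.unit_value_eur
    return CostTable(
        member_id=impacts.member_id,
        outcome_costs=outcome_costs,
        pollutant_costs=pollutant_costs,
    )


def attribute_by_pollutant(cost: CostTable) -> dict[str, float]:
    """Per-pollutant cost totals; columns sum to the table total."""
    if not cost.pollutant_costs:
        raise ValueError("cost table carries no pollutant attribution")
    total = sum(cost.pollutant_costs.values())
    if cost.outcome_costs and not np.isclose(
        total, cost.total, rtol=1e-6, atol=1e-6
    ):
        raise ValueError(
            f"pollutant attribution ({total}) does not conserve the total "
            f"({cost.total})"
        )
    return dict(cost.pollutant_costs)


def ensemble_cost_summary(tables: list[CostTable]) -> pd.DataFrame:
    """Member rows plus column-wise Mean and Median rows (unrounded EUR).

    Columns are the four pollutants and Total, one row per member, shaped
    like the per-model external-cost tables of multi-model valuation
    studies.
    """
    if not tables:
        raise ValueError("need at least one cost table")
    cols = list(POLLUTANTS)
    rows = {}
    for t in tables:
        attribution = attribute_by_pollutant(t) if t.pollutant_costs else {}
        rows[t.member_id] = [attribution.get(p, np.nan) for p in cols] + [t.total]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols + ["Total"])
    return summarize_cost_matrix(df)


def summarize_cost_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Append column-wise Mean and Median rows to a member-by-column cost
    frame (any consistent units)."""
    if df.empty:
        raise ValueError("empty cost matrix")
    members = [i for i in df.index if i not in ("Mean", "Median")]
    out = df.loc[members].copy()
    out.loc["Mean"] = out.loc[members].mean()
    out.loc["Median"] = out.loc[members].median()
    return out


def round_costs_for_report(df: pd.DataFrame, unit: float = 1e6) -> pd.DataFrame:
    """Emulate published-table rounding, in million EUR by default.

    The CO column is rounded to the nearest million; the other columns to
    the nearest 1000 million, except that exact half-thousand values (as
    produced by even-count medians) are kept at 500-million granularity.
    Used only for reporting, never internally.
    """
    out = df.copy() / unit

    def round_large(v: float) -> float:
        if not np.isfinite(v):
            return v
        r500 = round(v / 500.0) * 500.0
        if abs(v - r500) < 1e-9 * max(1.0, abs(v)):
            return r500
        return round(v / 1000.0) * 1000.0

    for col in out.columns:
        if col == "CO":
            out[col] = out[col].map(lambda v: round(v) if np.isfinite(v) else v)
        else:
            out[col] = out[col].map(round_large)
    return out


__all__ = [
    "CostTable",
    "attribute_by_pollutant",
    "ensemble_cost_summary",
    "round_costs_for_report",
    "summarize_cost_matrix",
    "value_impacts",
]
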