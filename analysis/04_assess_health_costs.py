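#!/usr/bin/env python
"""Run the health-impact and valuation chain for every member and ensemble
product: annual means (SOMO35 for ozone) -> exposure-response catalog ->
per-outcome responses, premature deaths (chronic YOLL/10.6 + acute), and
external costs in EUR with pollutant attribution.

Reads scratch/demo/ (members and ensembles); writes
results/health_impacts.csv and results/external_costs_meur.csv.
"""

import sys
from collections import defaultdict
from pathlib import Path

import pandas as pd

from aqhealth import health, io, metrics, valuation

ROOT = Path(__file__).resolve().parents[1]
IN = ROOT / "scratch" / "demo"
RESULTS = ROOT / "results"


def main() -> None:
    if not IN.exists():
        sys.exit("run analysis/01_simulate.py (and 03) first")
    RESULTS.mkdir(exist_ok=True)
    by_member = defaultdict(dict)
    for path in sorted(IN.glob("field_*.nc")):
        field = io.read_field(path)
        if field.member_id != "truth":
            by_member[field.member_id][field.pollutant] = field
    domain = next(iter(next(iter(by_member.values())).values())).domain
    population = io.read_population(IN / "population.csv", domain)

    impact_rows, cost_tables = [], []
    for member_id, fields in sorted(by_member.items()):
        mset = metrics.compute_metric_set(fields)
        impacts = health.assess(mset, population, member_id=member_id)
        costs = valuation.value_impacts(impacts)
        cost_tables.append(costs)
        row = {"member": member_id}
        row.update({code: r.total for code, r in impacts.outcomes.items()})
        row.update({
            "chronic_deaths": impacts.chronic_deaths,
            "acute_deaths": impacts.acute_deaths,
            "infant_deaths": impacts.infant_deaths,
            "total_premature_deaths": impacts.total_premature_deaths,
            "total_cost_meur": costs.total / 1e6,
        })
        impact_rows.append(row)
        print(f"{member_id}: PD {impacts.total_premature_deaths:,.0f} "
              f"(chronic {impacts.chronic_deaths:,.0f} + acute "
              f"{impacts.acute_deaths:,.0f}), cost {costs.total / 1e9:,.2f} bn EUR")

    pd.DataFrame(impact_rows).to_csv(RESULTS / "health_impacts.csv", index=False)
    summary = valuation.ensemble_cost_summary(
        [t for t in cost_tables if t.member_id.startswith("M")
         and not t.member_id.startswith("MM_")]
    )
    valuation.round_costs_for_report(summary).to_csv(
        RESULTS / "external_costs_meur.csv"
    )
    print(f"\nwrote {RESULTS / 'health_impacts.csv'} and "
          f"{RESULTS / 'external_costs_meur.csv'}")


if __name__ == "__main__":
    sys.exit(main())
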