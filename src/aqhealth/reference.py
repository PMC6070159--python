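"""Published reference numbers from a continental multi-model valuation
assessment (12 European and 3 North American regional modeling systems,
year 2010).

These are *inputs*, not results of this package: the per-model external-cost
rows (million EUR, 2013 prices) for the European and North American
ensembles, and the ensemble-mean mortality building blocks (thousands of
chronic years of life lost and acute deaths). They feed consistency checks
that the summary and mortality arithmetic implemented here reproduces the
published ensemble rows.
"""

from __future__ import annotations

import pandas as pd

#: Per-model external costs over Europe, million EUR: columns CO, SO2, O3,
#: PM2.5, Total; 12 regional modeling systems.
EU_MODEL_COSTS_MEUR = pd.DataFrame(
    {
        "CO": [70, 80, 70, 90, 90, 80, 70, 70, 110, 80, 80, 80],
        "SO2": [19000, 13000, 8000, 18000, 15000, 17000, 11000, 12000,
                30000, 28000, 34000, 47000],
        "O3": [22000, 24000, 6000, 5000, 13000, 21000, 6000, 18000,
               35000, 25000, 27000, 25000],
        "PM25": [155000, 237000, 339000, 335000, 305000, 413000, 253000,
                 215000, 376000, 280000, 340000, 279000],
        "Total": [196000, 274000, 353000, 358000, 333000, 451000, 270000,
                  245000, 441000, 333000, 401000, 351000],
    },
    index=["DE1", "DK1", "ES1", "FI1", "FRES1", "IT1", "IT2", "NL1",
           "TR1", "UK1", "UK2", "UK3"],
)

#: Per-model external costs over the United States, million EUR.
US_MODEL_COSTS_MEUR = pd.DataFrame(
    {
        "CO": [30, 55, 60],
        "SO2": [9000, 11000, 14000],
        "O3": [21000, 39000, 22000],
        "PM25": [46000, 123000, 155000],
        "Total": [76000, 172000, 191000],
    },
    index=["DE1", "DK1", "US3"],
)

#: Ensemble mortality building blocks, thousands: chronic years of life
#: lost and acute deaths, for the mean-of-individual-models ensemble over
#: Europe and the all-model-mean ensemble over North America.
EU_MMI_CHRONIC_YOLL_THOUSANDS = 4111.0
EU_MMI_ACUTE_DEATHS_THOUSANDS = 26.0
NA_MMM_CHRONIC_YOLL_THOUSANDS = 1481.0
NA_MMM_ACUTE_DEATHS_THOUSANDS = 9.0

#: Total populations of the two receptor regions (persons).
EU_TOTAL_POPULATION = 532_000_000
US_TOTAL_POPULATION = 307_000_000

__all__ = [
    "EU_MMI_ACUTE_DEATHS_THOUSANDS",
    "EU_MMI_CHRONIC_YOLL_THOUSANDS",
    "EU_MODEL_COSTS_MEUR",
    "EU_TOTAL_POPULATION",
    "NA_MMM_ACUTE_DEATHS_THOUSANDS",
    "NA_MMM_CHRONIC_YOLL_THOUSANDS",
    "US_MODEL_COSTS_MEUR",
    "US_TOTAL_POPULATION",
]
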