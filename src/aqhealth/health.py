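"""Exposure--response functions and health-impact assessment.

Every outcome follows the linear exposure--response form

    R = alpha * dc * P

where ``alpha`` is the empirically determined coefficient for the outcome,
``dc`` the concentration metric above a counterfactual of zero (annual mean
for CO, SO2 and PM2.5; SOMO35 for O3), and ``P`` the exposed population
(cell count x age-group share x prevalence). Chronic PM2.5 mortality is
expressed in years of life lost (YOLL) and converted to premature deaths
with a lifetable factor of 10.6 years per death; acute deaths (O3, SO2)
are added to give total premature deaths, while infant mortality is always
reported as its own line.

The default catalog carries the full valuation study table: morbidity
(chronic bronchitis, restricted activity days, congestive heart failure,
lung cancer, hospital admissions, child and adult asthma symptom days),
acute mortality for SO2 and O3, chronic mortality YOLL, and infant
mortality, with unit values in EUR (2013 prices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .core import AGE_GROUPS, PopulationGrid
from .metrics import MetricField

LIFETABLE_FACTOR = 10.6  # years of life lost per chronic premature death

VALID_AGE_GROUPS = AGE_GROUPS + ("all",)


@dataclass(frozen=True)
class OutcomeComponent:
    """One additive term of an outcome's response.

    ``alpha`` is in response units per (ug/m3) per exposed person for
    annual-mean metrics, or per (ug/m3 day) per person for SOMO35.
    """

    alpha: float
    pollutant: str
    metric: str  # annual_mean | somo35
    age_group: str = "all"
    prevalence: float = 1.0

    def __post_init__(self) -> None:
        if self.metric not in ("annual_mean", "somo35"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "somo35" and self.pollutant != "O3":
            raise ValueError("somo35 applies to O3 only")
        if self.age_group not in VALID_AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if not 0.0 < self.prevalence <= 1.0:
            raise ValueError("prevalence must be in (0, 1]")


@dataclass(frozen=True)
class OutcomeSpec:
    code: str
    name: str
    components: tuple[OutcomeComponent, ...]
    response_unit: str  # cases | days | episodes | YOLL
    category: str  # morbidity | mortality_acute | mortality_chronic_yoll | mortality_infant
    unit_value_eur: float
    rr_note: str = ""  # provenance only, never computed from

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError(f"outcome {self.code}: needs at least one component")
        if self.unit_value_eur < 0:
            raise ValueError(f"outcome {self.code}: unit value must be >= 0")


CHILD_ASTHMA_PREVALENCE = 0.076
ADULT_ASTHMA_PREVALENCE = 0.059


def default_catalog(
    chf_age_group: str = "adult_ge65",
    infant_group: str = "infant_lt9mo",
) -> list[OutcomeSpec]:
    """The shipped exposure--response and valuation catalog (16 outcomes).

    ``chf_age_group`` and ``infant_group`` expose the two genuinely
    ambiguous age assignments (congestive heart failure and infant
    mortality) without touching the coefficients.
    """

    def c(alpha, pollutant, metric="annual_mean", age="all", prev=1.0):
        return OutcomeComponent(alpha, pollutant, metric, age, prev)

    return [
        OutcomeSpec(
            "CB", "Chronic bronchitis",
            (c(8.2e-5, "PM25", age="adult_ge15"),),
            "cases", "morbidity", 38_578, rr_note="RR 1.007 per ug/m3 basis",
        ),
        OutcomeSpec(
            "RAD", "Restricted activity days",
            (
                c(8.4e-4, "PM25", age="adult_ge15"),
                c(-3.46e-5, "PM25", age="adult_ge15"),
                c(-2.47e-4, "PM25", age="adult_ge65"),
                c(-8.42e-5, "PM25", age="adult_ge15"),
            ),
            "days", "morbidity", 98,
            rr_note="negative terms deduct hospital admissions to avoid double counting; 40% are work-loss days",
        ),
        OutcomeSpec(
            "CHF", "Congestive heart failure",
            (
                c(3.09e-5, "PM25", age=chf_age_group),
                c(5.64e-7, "CO", age=chf_age_group),
            ),
            "cases", "morbidity", 10_998,
        ),
        OutcomeSpec(
            "LC", "Lung cancer",
            (c(1.26e-5, "PM25", age="adult_ge30"),),
            "cases", "morbidity", 16_022, rr_note="RR 1.08 per 10 ug/m3",
        ),
        OutcomeSpec(
            "RHA", "Respiratory hospital admissions",
            (c(3.46e-6, "PM25"), c(2.04e-6, "SO2")),
            "cases", "morbidity", 5_315,
        ),
        OutcomeSpec(
            "CHA", "Cerebrovascular hospital admissions",
            (c(8.42e-6, "PM25"),),
            "cases", "morbidity", 6_734,
        ),
        OutcomeSpec(
            "BUC", "Bronchodilator use, asthmatic children",
            (c(1.29e-1, "PM25", age="child_lt15", prev=CHILD_ASTHMA_PREVALENCE),),
            "cases", "morbidity", 16,
        ),
        OutcomeSpec(
            "COUC", "Cough days, asthmatic children",
            (c(4.46e-1, "PM25", age="child_lt15", prev=CHILD_ASTHMA_PREVALENCE),),
            "days", "morbidity", 30,
        ),
        OutcomeSpec(
            "LRSC", "Lower respiratory symptom days, asthmatic children",
            (c(1.72e-1, "PM25", age="child_lt15", prev=CHILD_ASTHMA_PREVALENCE),),
            "days", "morbidity", 9,
        ),
        OutcomeSpec(
            "BUA", "Bronchodilator use, asthmatic adults",
            (c(2.72e-1, "PM25", age="adult_ge15", prev=ADULT_ASTHMA_PREVALENCE),),
            "cases", "morbidity", 16,
        ),
        OutcomeSpec(
            "COUA", "Cough days, asthmatic adults",
            (c(2.8e-1, "PM25", age="adult_ge15", prev=ADULT_ASTHMA_PREVALENCE),),
            "days", "morbidity", 30,
        ),
        OutcomeSpec(
            "LRSA", "Lower respiratory symptom days, asthmatic adults",
            (c(1.01e-1, "PM25", age="adult_ge15", prev=ADULT_ASTHMA_PREVALENCE),),
            "days", "morbidity", 9,
        ),
        OutcomeSpec(
            "AM_SO2", "Acute mortality (SO2)",
            (c(7.85e-6, "SO2"),),
            "cases", "mortality_acute", 1_532_099,
        ),
        OutcomeSpec(
            "AM_O3", "Acute mortality (O3)",
            (c(3.27e-6, "O3", metric="somo35"),),
            "cases", "mortality_acute", 1_532_099,
        ),
        OutcomeSpec(
            "CM_YOLL", "Chronic mortality (PM2.5), years of life lost",
            (c(1.138e-3, "PM25", age="adult_ge30"),),
            "YOLL", "mortality_chronic_yoll", 57_510,
            rr_note="RR 1.062 (1.040-1.083) per 10 ug/m3; 1138 YOLL per 100 000 per 10 ug/m3",
        ),
        OutcomeSpec(
            "IM", "Infant mortality (PM2.5)",
            (c(6.68e-6, "PM25", age=infant_group),),
            "cases", "mortality_infant", 2_298_148,
        ),
    ]


# ----------------------------------------------------------- catalog I/O


def catalog_to_yaml(catalog: list[OutcomeSpec], path) -> None:
    data = [
        {
            "code": o.code,
            "name": o.name,
            "response_unit": o.response_unit,
            "category": o.category,
            "unit_value_eur": o.unit_value_eur,
            "rr_note": o.rr_note,
            "components": [
                {
                    "alpha": comp.alpha,
                    "pollutant": comp.pollutant,
                    "metric": comp.metric,
                    "age_group": comp.age_group,
                    "prevalence": comp.prevalence,
                }
                for comp in o.components
            ],
        }
        for o in catalog
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def catalog_from_yaml(path) -> list[OutcomeSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        OutcomeSpec(
            code=o["code"],
            name=o.get("name", o["code"]),
            components=tuple(
                OutcomeComponent(
                    alpha=float(comp["alpha"]),
                    pollutant=comp["pollutant"],
                    metric=comp.get("metric", "annual_mean"),
                    age_group=comp.get("age_group", "all"),
                    prevalence=float(comp.get("prevalence", 1.0)),
                )
                for comp in o["components"]
            ),
            response_unit=o.get("response_unit", "cases"),
            category=o.get("category", "morbidity"),
            unit_value_eur=float(o["unit_value_eur"]),
            rr_note=o.get("rr_note", ""),
        )
        for o in data
    ]


# ----------------------------------------------------------- assessment


@dataclass
class OutcomeResult:
    spec: OutcomeSpec
    grid: np.ndarray  # (lat, lon) response per cell
    total: float
    component_totals: tuple[float, ...]  # aligned with spec.components


@dataclass
class HealthImpactTable:
    member_id: str
    outcomes: dict[str, OutcomeResult]
    lifetable_factor: float = LIFETABLE_FACTOR
    pd_grid: np.ndarray | None = None  # premature deaths per cell

    @property
    def chronic_yoll(self) -> float:
        return self.outcomes["CM_YOLL"].total if "CM_YOLL" in self.outcomes else 0.0

    @property
    def chronic_deaths(self) -> float:
        return self.chronic_yoll / self.lifetable_factor

    @property
    def acute_deaths(self) -> float:
        return sum(
            r.total
            for r in self.outcomes.values()
            if r.spec.category == "mortality_acute"
        )

    @property
    def infant_deaths(self) -> float:
        return sum(
            r.total
            for r in self.outcomes.values()
            if r.spec.category == "mortality_infant"
        )

    @property
    def total_premature_deaths(self) -> float:
        """Chronic plus acute deaths; infant mortality reported separately."""
        return self.chronic_deaths + self.acute_deaths


MetricSet = dict[tuple[str, str], MetricField]


def compute_outcome(
    spec: OutcomeSpec, metrics: MetricSet, population: PopulationGrid
) -> OutcomeResult:
    """Apply R = alpha * dc * P for each component and sum over components."""
    grid = np.zeros_like(population.counts, dtype=float)
    comp_totals = []
    for comp in spec.components:
        key = (comp.pollutant, comp.metric)
        if key not in metrics:
            raise ValueError(
                f"outcome {spec.code}: missing metric {comp.metric!r} for "
                f"pollutant {comp.pollutant!r}"
            )
        exposed = population.counts * population.share(comp.age_group) * comp.prevalence
        comp_grid = comp.alpha * metrics[key].values * exposed
        comp_totals.append(float(comp_grid.sum()))
        grid = grid + comp_grid
    total = float(grid.sum())
    if np.any(grid < 0):
        warnings.warn(
            f"outcome {spec.code}: negative cell responses (composite with "
            "deduction terms); reported as computed",
            stacklevel=2,
        )
    return OutcomeResult(
        spec=spec, grid=grid, total=total, component_totals=tuple(comp_totals)
    )


def assess(
    metrics: MetricSet,
    population: PopulationGrid,
    catalog: list[OutcomeSpec] | None = None,
    lifetable_factor: float = LIFETABLE_FACTOR,
    member_id: str = "member",
) -> HealthImpactTable:
    """Compute every catalog outcome and the derived mortality scalars."""
    if lifetable_factor <= 0:
        raise ValueError("lifetable_factor must be positive")
    catalog = catalog if catalog is not None else default_catalog()
    outcomes = {spec.code: compute_outcome(spec, metrics, population) for spec in catalog}
    pd_grid = np.zeros_like(population.counts, dtype=float)
    for r in outcomes.values():
        if r.spec.category == "mortality_chronic_yoll":
            pd_grid += r.grid / lifetable_factor
        elif r.spec.category == "mortality_acute":
            pd_grid += r.grid
    return HealthImpactTable(
        member_id=member_id,
        outcomes=outcomes,
        lifetable_factor=lifetable_factor,
        pd_grid=pd_grid,
    )


def yoll_to_deaths(yoll: float, lifetable_factor: float = LIFETABLE_FACTOR) -> float:
    """Convert years of life lost to premature deaths."""
    if lifetable_factor <= 0:
        raise ValueError("lifetable_factor must be positive")
    if yoll < 0:
        raise ValueError("yoll must be non-negative")
    return yoll / lifetable_factor


__all__ = [
    "ADULT_ASTHMA_PREVALENCE",
    "CHILD_ASTHMA_PREVALENCE",
    "HealthImpactTable",
    "LIFETABLE_FACTOR",
    "MetricSet",
    "OutcomeComponent",
    "OutcomeResult",
    "OutcomeSpec",
    "assess",
    "catalog_from_yaml",
    "catalog_to_yaml",
    "compute_outcome",
    "default_catalog",
    "yoll_to_deaths",
]
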