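"""End-to-end orchestration: simulate -> metrics -> evaluate -> ensemble ->
assess -> value -> scenario, with a YAML config and a reproducibility
manifest.

The pipeline is deterministic under a fixed seed: every stage seed is
derived from the run seed, all parameters land in the manifest together
with SHA-256 checksums of every output file, and a rerun with the same
config reproduces the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import evaluation as ev
from . import health, io, metrics, synth, valuation
from .core import ConcentrationField, DomainSpec
from .scenario import delta_assessment, multi_model_delta_summary

log = logging.getLogger("aqhealth")


@dataclass
class RunConfig:
    """Everything needed to reproduce a demo study run."""

    # domain
    lon_min: float = 0.0
    lon_max: float = 5.0
    lat_min: float = 45.0
    lat_max: float = 50.0
    resolution: float = 0.25
    time_start: str = "2010-01-01"
    time_end: str = "2011-01-01"
    # population
    total_population: int = 50_000_000
    n_hotspots: int = 5
    age_shares: dict[str, float] | None = None
    # ensemble members: multiplicative bias, additive bias, noise sd, smoothing
    members: list[dict[str, Any]] = dc_field(
        default_factory=lambda: [
            {"member_id": "M1", "mult_bias": 0.85, "noise_sd": 2.0, "smoothing_cells": 1},
            {"member_id": "M2", "mult_bias": 1.10, "noise_sd": 3.0},
            {"member_id": "M3", "mult_bias": 0.70, "add_bias": 1.0, "noise_sd": 2.5},
            {"member_id": "M4", "mult_bias": 1.00, "noise_sd": 4.0, "smoothing_cells": 2},
            {"member_id": "M5", "mult_bias": 0.95, "add_bias": -0.5, "noise_sd": 2.0},
        ]
    )
    # stations
    n_stations: int = 20
    obs_noise_sd: float = 1.0
    missing_rate: float = 0.1
    # health / valuation
    somo35_threshold: float = metrics.SOMO35_THRESHOLD_UGM3
    lifetable_factor: float = health.LIFETABLE_FACTOR
    catalog_path: str | None = None
    # scenarios: id -> pollutant scale factors (default: 20 % global cut,
    # linear-atmosphere concentration response)
    scenarios: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {
            "GLO20": {"O3": 0.8, "CO": 0.8, "SO2": 0.8, "PM25": 0.8}
        }
    )
    seed: int = 1
    write_fields: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def domain(self) -> DomainSpec:
        return DomainSpec(
            lon_min=self.lon_min,
            lon_max=self.lon_max,
            lat_min=self.lat_min,
            lat_max=self.lat_max,
            resolution=self.resolution,
            time_start=pd.Timestamp(self.time_start),
            time_end=pd.Timestamp(self.time_end),
        )

    def member_specs(self) -> list[synth.PseudoModelSpec]:
        return [synth.PseudoModelSpec(**m) for m in self.members]

    def to_dict(self) -> dict[str, Any]:
        return {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in self.__dict__.items()
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sub_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full chain and write stage outputs plus a manifest.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    domain = config.domain()
    catalog = (
        health.catalog_from_yaml(config.catalog_path)
        if config.catalog_path
        else health.default_catalog()
    )
    specs = config.member_specs()
    pollutants = list(domain.pollutants)
    # stage seeds: population, then per-pollutant blocks
    seeds = _sub_seeds(config.seed, 1 + len(pollutants) * (2 + len(specs)))
    seed_iter = iter(seeds)

    log.info("stage simulate: population grid")
    population = synth.generate_population(
        domain,
        total_population=config.total_population,
        age_shares=config.age_shares,
        n_hotspots=config.n_hotspots,
        seed=next(seed_iter),
    )
    io.write_population(population, out / "population.csv")

    eval_rows: list[ev.EvalStats] = []
    impact_tables: list[health.HealthImpactTable] = []
    cost_tables: list[valuation.CostTable] = []
    deltas = []
    selections: dict[str, dict[str, Any]] = {}
    member_metrics: dict[str, health.MetricSet] = {}
    scen_member_metrics: dict[str, dict[str, health.MetricSet]] = {
        sid: {} for sid in config.scenarios
    }

    for pollutant in pollutants:
        log.info("stage simulate: %s truth, members, stations", pollutant)
        truth = synth.generate_truth(
            domain, pollutant, population=population, seed=next(seed_iter)
        )
        stations = synth.sample_observations(
            truth,
            n_stations=config.n_stations,
            obs_noise_sd=config.obs_noise_sd,
            missing_rate=config.missing_rate,
            seed=next(seed_iter),
            population=population,
        )
        io.write_stations(stations, out / f"stations_{pollutant}.csv")
        members = [
            synth.perturb_to_member(truth, spec, seed=next(seed_iter))
            for spec in specs
        ]
        if config.write_fields:
            for m in members:
                io.write_field(m, out / f"field_{pollutant}_{m.member_id}.nc")

        log.info("stage evaluate: %s", pollutant)
        for m in members:
            pairs = ev.pair_model_obs(m, stations)
            eval_rows.append(ev.evaluate(pairs, member_id=m.member_id))
            monthly = [ev.monthly_series(p) for p in pairs]
            eval_rows.append(
                ev.evaluate(monthly, member_id=m.member_id, period="monthly")
            )

        log.info("stage ensemble: %s", pollutant)
        mm_mean = ens.combine_mean(members)
        mm_median = ens.combine_median(members)
        selection, mm_opt = ens.select_optimal_subset(members, stations)
        selections[pollutant] = {
            "members": list(selection.member_ids),
            "station_mse": selection.station_mse,
            "all_member_mse": selection.all_member_mse,
            "candidates": selection.candidate_count,
        }
        for e in (mm_mean, mm_median, mm_opt):
            pairs = ev.pair_model_obs(e, stations)
            eval_rows.append(ev.evaluate(pairs, member_id=e.member_id))

        for f in members + [mm_mean, mm_median, mm_opt]:
            member_metrics.setdefault(f.member_id, {}).update(
                _pollutant_metrics(f, config.somo35_threshold)
            )
        for sid, response in config.scenarios.items():
            scen_fields = synth.make_scenario(
                {pollutant: mm_mean}, response, scenario_id=sid
            )
            scen_member_metrics[sid].setdefault("MM_mean", {}).update(
                _pollutant_metrics(scen_fields[pollutant], config.somo35_threshold)
            )
            for m in members:
                scen_m = synth.make_scenario(
                    {pollutant: m}, response, scenario_id=sid
                )[pollutant]
                scen_member_metrics[sid].setdefault(m.member_id, {}).update(
                    _pollutant_metrics(scen_m, config.somo35_threshold)
                )

    ev.stats_to_frame(eval_rows).to_csv(out / "eval_stats.csv", index=False)
    with open(out / "ensemble_selection.json", "w") as fh:
        json.dump(selections, fh, indent=2, sort_keys=True)

    log.info("stage assess + value")
    member_order = [s.member_id for s in specs] + ["MM_mean", "MM_median", "MM_opt"]
    for mid in member_order:
        impacts = health.assess(
            member_metrics[mid],
            population,
            catalog,
            lifetable_factor=config.lifetable_factor,
            member_id=mid,
        )
        impact_tables.append(impacts)
        cost_tables.append(valuation.value_impacts(impacts, catalog))
    _write_impact_table(impact_tables, out / "health_impacts.csv")
    cost_df = valuation.ensemble_cost_summary(
        [t for t in cost_tables if t.member_id in {s.member_id for s in specs}]
    )
    cost_df.to_csv(out / "costs.csv")
    valuation.round_costs_for_report(cost_df).to_csv(out / "costs_meur_rounded.csv")

    log.info("stage scenario")
    base_by_id = {t.member_id: t for t in impact_tables}
    base_costs_by_id = {t.member_id: t for t in cost_tables}
    for sid in config.scenarios:
        for mid, mset in scen_member_metrics[sid].items():
            scen_impacts = health.assess(
                mset,
                population,
                catalog,
                lifetable_factor=config.lifetable_factor,
                member_id=mid,
            )
            scen_costs = valuation.value_impacts(scen_impacts, catalog)
            deltas.append(
                delta_assessment(
                    base_by_id[mid],
                    base_costs_by_id[mid],
                    scen_impacts,
                    scen_costs,
                    scenario_id=sid,
                )
            )
    member_deltas = [d for d in deltas if d.member_id != "MM_mean"]
    if member_deltas:
        multi_model_delta_summary(member_deltas).to_csv(out / "scenario_deltas.csv")
    pd.DataFrame(
        [
            {
                "scenario": d.scenario_id,
                "member": d.member_id,
                "delta_pd": d.delta_pd,
                "delta_cost_eur": d.delta_cost,
            }
            for d in deltas
        ]
    ).to_csv(out / "scenario_deltas_members.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "ensemble_selection": selections,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out)
    return manifest


def _pollutant_metrics(
    field: ConcentrationField, somo35_threshold: float
) -> health.MetricSet:
    out: health.MetricSet = {
        (field.pollutant, "annual_mean"): metrics.annual_mean(field)
    }
    if field.pollutant == "O3":
        out[("O3", "somo35")] = metrics.somo35(
            metrics.daily_max_8h(field), threshold=somo35_threshold
        )
    return out


def _write_impact_table(tables: list[health.HealthImpactTable], path: Path) -> None:
    rows = []
    for t in tables:
        row: dict[str, Any] = {"member": t.member_id}
        row.update({code: r.total for code, r in t.outcomes.items()})
        row["chronic_deaths"] = t.chronic_deaths
        row["acute_deaths"] = t.acute_deaths
        row["infant_deaths"] = t.infant_deaths
        row["total_premature_deaths"] = t.total_premature_deaths
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


__all__ = ["RunConfig", "run_pipeline"]
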