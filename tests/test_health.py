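"""Exposure-response catalog and health-impact arithmetic."""

import numpy as np
import pandas as pd
import pytest

from aqhealth import health
from aqhealth.core import DomainSpec, PopulationGrid
from aqhealth.metrics import MetricField


def one_cell_domain():
    return DomainSpec(
        lon_min=0.0, lon_max=0.25, lat_min=45.0, lat_max=45.25,
        resolution=0.25, time_start=pd.Timestamp("2010-01-01"),
        time_end=pd.Timestamp("2010-01-02"),
    )


def single_cohort_population(domain, persons, group="adult_ge30"):
    """Everyone in one cell; the whole population counted in ``group``."""
    shares = {
        "infant_lt9mo": 0.0, "child_lt15": 0.0, "adult_ge15": 1.0,
        "adult_ge30": 0.0, "adult_ge65": 0.0,
    }
    if group in ("adult_ge30", "adult_ge65"):
        shares["adult_ge30"] = 1.0 if group == "adult_ge30" else 0.0
        shares[group] = 1.0
        if group == "adult_ge65":
            shares["adult_ge30"] = 1.0
    elif group == "infant_lt9mo":
        shares = {"infant_lt9mo": 1.0, "child_lt15": 0.0, "adult_ge15": 0.0,
                  "adult_ge30": 0.0, "adult_ge65": 0.0}
    counts = np.full((domain.n_lat, domain.n_lon), float(persons))
    return PopulationGrid(domain, counts, shares)


def metric(pollutant, name, value, domain):
    return MetricField(pollutant, name,
                       np.full((domain.n_lat, domain.n_lon), float(value)),
                       "ug/m3")


def metric_set(domain, pm=0.0, so2=0.0, co=0.0, o3_somo=0.0):
    return {
        ("PM25", "annual_mean"): metric("PM25", "annual_mean", pm, domain),
        ("SO2", "annual_mean"): metric("SO2", "annual_mean", so2, domain),
        ("CO", "annual_mean"): metric("CO", "annual_mean", co, domain),
        ("O3", "somo35"): metric("O3", "somo35", o3_somo, domain),
    }


class TestCatalog:
    def test_sixteen_outcome_codes(self):
        catalog = health.default_catalog()
        codes = [o.code for o in catalog]
        assert len(codes) == 16 and len(set(codes)) == 16
        assert {"CB", "RAD", "CHF", "LC", "RHA", "CHA", "BUC", "COUC", "LRSC",
                "BUA", "COUA", "LRSA", "AM_SO2", "AM_O3", "CM_YOLL", "IM"} == set(codes)

    def test_chronic_mortality_component(self):
        cm = next(o for o in health.default_catalog() if o.code == "CM_YOLL")
        comp = cm.components[0]
        assert comp.alpha == pytest.approx(1.138e-3)
        assert comp.metric == "annual_mean"
        assert comp.pollutant == "PM25"
        assert comp.age_group == "adult_ge30"
        assert cm.unit_value_eur == 57_510

    def test_acute_o3_uses_somo35(self):
        am = next(o for o in health.default_catalog() if o.code == "AM_O3")
        assert am.components[0].metric == "somo35"

    def test_yaml_round_trip(self, tmp_path):
        catalog = health.default_catalog()
        health.catalog_to_yaml(catalog, tmp_path / "cat.yaml")
        back = health.catalog_from_yaml(tmp_path / "cat.yaml")
        assert back == catalog

    def test_infant_group_selectable(self):
        # both readings of the infant age annotation are supported
        alt = health.default_catalog(infant_group="child_lt15")
        im = next(o for o in alt if o.code == "IM")
        assert im.components[0].age_group == "child_lt15"


class TestComputeOutcome:
    def test_chronic_mortality_worked_example(self):
        """10 ug/m3 annual PM2.5 over 100 000 persons aged 30+ -> 1138 YOLL."""
        domain = one_cell_domain()
        pop = single_cohort_population(domain, 100_000, "adult_ge30")
        cm = next(o for o in health.default_catalog() if o.code == "CM_YOLL")
        result = health.compute_outcome(cm, metric_set(domain, pm=10.0), pop)
        assert result.total == pytest.approx(1138.0)

    def test_zero_metric_gives_zero(self):
        domain = one_cell_domain()
        pop = single_cohort_population(domain, 100_000)
        for spec in health.default_catalog():
            r = health.compute_outcome(spec, metric_set(domain), pop)
            assert r.total == 0.0

    def test_acute_o3_hand_evaluation(self):
        """alpha * SOMO35 * P = 3.27e-6 * 4000 * 1e6 = 13 080 cases."""
        domain = one_cell_domain()
        pop = single_cohort_population(domain, 1_000_000)
        am = next(o for o in health.default_catalog() if o.code == "AM_O3")
        r = health.compute_outcome(am, metric_set(domain, o3_somo=4000.0), pop)
        assert r.total == pytest.approx(13_080.0)

    def test_missing_metric_named_in_error(self):
        domain = one_cell_domain()
        pop = single_cohort_population(domain, 1000)
        am = next(o for o in health.default_catalog() if o.code == "AM_O3")
        with pytest.raises(ValueError, match="somo35.*O3|O3.*somo35"):
            health.compute_outcome(am, {}, pop)


class TestAssess:
    def _assess(self, pm=10.0, so2=5.0, co=200.0, o3=3000.0, persons=1e6):
        domain = one_cell_domain()
        pop = single_cohort_population(domain, persons, "adult_ge30")
        return health.assess(metric_set(domain, pm, so2, co, o3), pop)

    def test_scaling_all_metrics_scales_outcomes(self):
        base = self._assess()
        scaled = self._assess(pm=8.0, so2=4.0, co=160.0, o3=2400.0)
        for code, r in base.outcomes.items():
            assert scaled.outcomes[code].total == pytest.approx(0.8 * r.total)

    def test_derived_mortality_scalars(self):
        t = self._assess()
        assert t.chronic_deaths * t.lifetable_factor == pytest.approx(
            t.chronic_yoll, rel=1e-15
        )
        am_o3 = t.outcomes["AM_O3"].total
        am_so2 = t.outcomes["AM_SO2"].total
        assert t.acute_deaths == pytest.approx(am_o3 + am_so2)
        assert t.total_premature_deaths == pytest.approx(
            t.chronic_yoll / 10.6 + t.acute_deaths
        )
        # infant deaths reported separately, never inside total PD
        assert t.infant_deaths == pytest.approx(t.outcomes["IM"].total)

    def test_additivity_over_spatial_partition(self):
        domain = DomainSpec(
            lon_min=0.0, lon_max=1.0, lat_min=45.0, lat_max=45.5,
            resolution=0.25, time_start=pd.Timestamp("2010-01-01"),
            time_end=pd.Timestamp("2010-01-02"),
        )
        rng = np.random.default_rng(5)
        counts = rng.uniform(0, 1e5, (domain.n_lat, domain.n_lon))
        pop = PopulationGrid(domain, counts)
        pm = MetricField("PM25", "annual_mean",
                         rng.uniform(5, 25, counts.shape), "ug/m3")
        mset = {("PM25", "annual_mean"): pm}
        cm = next(o for o in health.default_catalog() if o.code == "CM_YOLL")
        whole = health.compute_outcome(cm, mset, pop)
        # split domain into left/right halves, mask populations
        left = PopulationGrid(domain, np.where([[True, True, False, False]] * 2,
                                               counts, 0.0), pop.age_shares)
        right = PopulationGrid(domain, np.where([[False, False, True, True]] * 2,
                                                counts, 0.0), pop.age_shares)
        t_left = health.compute_outcome(cm, mset, left).total
        t_right = health.compute_outcome(cm, mset, right).total
        assert whole.total == pytest.approx(t_left + t_right, rel=1e-12)
        assert whole.total == pytest.approx(whole.grid.sum(), rel=1e-9)

    def test_table3_premature_death_arithmetic(self):
        """Published ensemble building blocks reproduce the printed totals."""
        eu = health.yoll_to_deaths(4111.0) + 26.0
        assert round(eu) == 414
        na = health.yoll_to_deaths(1481.0) + 9.0
        assert round(na) == 149


class TestYollToDeaths:
    @pytest.mark.parametrize("yoll,expected", [(0.0, 0.0), (106.0, 10.0),
                                               (4111.0, 4111.0 / 10.6)])
    def test_conversion(self, yoll, expected):
        assert health.yoll_to_deaths(yoll) == pytest.approx(expected)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            health.yoll_to_deaths(10.0, lifetable_factor=0.0)
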