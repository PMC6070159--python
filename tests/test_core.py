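"""Domain types, unit conversion, grid addressing and file round trips."""

import numpy as np
import pandas as pd
import pytest

from aqhealth import io
from aqhealth.core import (
    ConcentrationField,
    DomainSpec,
    OutOfDomainError,
    UnitError,
    cell_index_for,
    convert_units,
)
from tests.conftest import make_field


class TestDomainSpec:
    def test_grid_geometry(self, small_domain):
        assert small_domain.n_lon == 5
        assert small_domain.n_lat == 4
        assert small_domain.n_hours == 72
        # cell centers at min + (i + 0.5) * resolution
        assert small_domain.lon_centers[0] == pytest.approx(0.25)
        assert small_domain.lat_centers[-1] == pytest.approx(46.75)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lon_min": 2.0, "lon_max": 1.0},
            {"resolution": -0.25},
            {"lon_max": 1.13},  # not a multiple of resolution
            {"time_end": pd.Timestamp("2010-01-01T12")},  # < 24 h
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(
            lon_min=0.0, lon_max=2.0, lat_min=45.0, lat_max=47.0,
            resolution=0.25, time_start=pd.Timestamp("2010-01-01"),
            time_end=pd.Timestamp("2010-01-03"),
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            DomainSpec(**base)


class TestUnitConversion:
    def test_o3_35ppb_is_70ugm3(self, small_domain):
        field = make_field(small_domain, "O3", 35.0, units="ppb")
        out = convert_units(field, "ug/m3")
        assert np.allclose(out.values, 70.0)
        assert out.units == "ug/m3"

    def test_identity_when_target_equals_current(self, small_domain):
        field = make_field(small_domain, "SO2", 12.0)
        out = convert_units(field, "ug/m3")
        assert np.array_equal(out.values, field.values)

    @pytest.mark.parametrize("pollutant", ["O3", "SO2", "CO"])
    def test_round_trip_identity(self, small_domain, pollutant, rng):
        vals = rng.uniform(0, 50, (small_domain.n_hours, small_domain.n_lat,
                                   small_domain.n_lon))
        field = make_field(small_domain, pollutant, values=vals, units="ppb")
        back = convert_units(convert_units(field, "ug/m3"), "ppb")
        assert np.allclose(back.values, vals, rtol=1e-9)

    def test_so2_example_value(self, small_domain):
        field = make_field(small_domain, "SO2", 10.0, units="ppb")
        assert np.allclose(convert_units(field, "ug/m3").values, 26.6)

    def test_pm25_has_no_ppb(self, small_domain):
        field = make_field(small_domain, "PM25", 10.0)
        with pytest.raises(UnitError):
            convert_units(field, "ppb")


class TestCellIndex:
    def test_point_at_cell_center(self, small_domain):
        assert cell_index_for(small_domain, 0.25, 45.25) == (0, 0)
        assert cell_index_for(small_domain, 2.25, 46.75) == (3, 4)

    def test_shared_edge_goes_to_lower_index(self, small_domain):
        # 0.5 is the edge between columns 0 and 1; 46.0 between rows 1 and 2
        assert cell_index_for(small_domain, 0.5, 46.0) == (1, 0)

    def test_outside_domain_raises(self, small_domain):
        with pytest.raises(OutOfDomainError):
            cell_index_for(small_domain, -1.0, 46.0)

    def test_agrees_with_exhaustive_nearest_center_search(self, small_domain, rng):
        lons = small_domain.lon_centers
        lats = small_domain.lat_centers
        for _ in range(100):
            lon = rng.uniform(small_domain.lon_min, small_domain.lon_max)
            lat = rng.uniform(small_domain.lat_min, small_domain.lat_max)
            row, col = cell_index_for(small_domain, lon, lat)
            # independent brute force over all cell centers
            dists = np.hypot(lats[:, None] - lat, lons[None, :] - lon)
            assert dists[row, col] == pytest.approx(dists.min())


class TestFieldIO:
    def _random_field(self, domain, rng, fmt_units="ug/m3"):
        vals = rng.uniform(0, 40, (domain.n_hours, domain.n_lat, domain.n_lon))
        return make_field(domain, "SO2", values=np.round(vals, 6),
                          units=fmt_units, member_id="M7", scenario_id="GLO")

    @pytest.mark.parametrize("suffix", [".nc", ".csv"])
    def test_round_trip(self, small_domain, tmp_path, rng, suffix):
        field = self._random_field(small_domain, rng)
        path = tmp_path / f"f{suffix}"
        io.write_field(field, path)
        back = io.read_field(path)
        assert np.allclose(back.values, field.values, rtol=1e-12)
        assert (back.pollutant, back.units) == ("SO2", "ug/m3")
        assert (back.member_id, back.scenario_id) == ("M7", "GLO")
        assert back.domain.n_hours == small_domain.n_hours

    def test_csv_and_netcdf_agree(self, small_domain, tmp_path, rng):
        field = self._random_field(small_domain, rng)
        io.write_field(field, tmp_path / "f.nc")
        io.write_field(field, tmp_path / "f.csv")
        a = io.read_field(tmp_path / "f.nc")
        b = io.read_field(tmp_path / "f.csv")
        assert np.allclose(a.values, b.values, rtol=1e-9)

    def test_negative_concentration_rejected_with_row(self, small_domain, tmp_path):
        field = make_field(small_domain, "SO2", 5.0)
        path = tmp_path / "f.csv"
        io.write_field(field, path)
        lines = path.read_text().splitlines()
        first_data = next(i for i, l in enumerate(lines) if l.startswith("2010"))
        lines[first_data + 2] = lines[first_data + 2].rsplit(",", 1)[0] + ",-4.0"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(io.ParseError, match="row 3"):
            io.read_field(path)

    def test_unknown_pollutant_code_rejected(self, small_domain, tmp_path):
        field = make_field(small_domain, "SO2", 5.0)
        path = tmp_path / "f.csv"
        io.write_field(field, path)
        path.write_text(path.read_text().replace("pollutant: SO2", "pollutant: XY"))
        with pytest.raises(io.ParseError, match="XY"):
            io.read_field(path)


class TestStationAndPopulationIO:
    def test_station_round_trip_with_missing(self, small_domain, tmp_path, rng):
        from aqhealth.core import StationSeries

        vals = rng.uniform(0, 30, small_domain.n_hours)
        vals[::5] = np.nan
        st = StationSeries("S1", 0.7, 45.8, "O3", vals, small_domain)
        io.write_stations([st], tmp_path / "st.csv")
        back = io.read_stations(tmp_path / "st.csv", small_domain)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].values, vals, rtol=1e-9)
        assert back[0].cell == st.cell

    def test_population_round_trip(self, small_domain, population, tmp_path):
        io.write_population(population, tmp_path / "pop.csv")
        back = io.read_population(tmp_path / "pop.csv", small_domain)
        np.testing.assert_allclose(back.counts, population.counts)
        assert back.age_shares == dict(population.age_shares)

    def test_inconsistent_age_shares_rejected(self, small_domain):
        from aqhealth.core import PopulationGrid

        counts = np.ones((small_domain.n_lat, small_domain.n_lon))
        bad = {"infant_lt9mo": 0.2, "child_lt15": 0.2, "adult_ge15": 0.2,
               "adult_ge30": 0.1, "adult_ge65": 0.05}
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationGrid(small_domain, counts, bad)
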