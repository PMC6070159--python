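"""Synthetic input generators: determinism, conservation, known-parameter
recovery."""

import numpy as np
import pytest

from aqhealth import synth
from aqhealth.evaluation import evaluate, pair_model_obs
from tests.conftest import make_field


class TestGeneratePopulation:
    def test_counts_conserve_total(self, small_domain):
        pop = synth.generate_population(small_domain, 532_000_000,
                                        n_hotspots=3, seed=5)
        assert pop.counts.sum() == pytest.approx(532_000_000, abs=0.5)
        assert np.all(pop.counts >= 0)

    def test_single_hotspot_zero_decay_limit(self, small_domain):
        pop = synth.generate_population(
            small_domain, 1000, n_hotspots=1, seed=9,
            decay_scale=1e-320, background=0.0,
        )
        assert pop.counts.max() == 1000
        assert (pop.counts > 0).sum() == 1

    def test_same_seed_identical(self, small_domain):
        a = synth.generate_population(small_domain, 10_000, n_hotspots=2, seed=3)
        b = synth.generate_population(small_domain, 10_000, n_hotspots=2, seed=3)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_hotspots(self, small_domain):
        with pytest.raises(ValueError):
            synth.generate_population(small_domain, 1000, n_hotspots=0, seed=1)


class TestGenerateTruth:
    def test_degenerate_constant_field(self, small_domain):
        params = synth.TruthParams(mean_level=42.0)
        truth = synth.generate_truth(small_domain, "PM25", params, seed=1)
        assert np.allclose(truth.values, 42.0)

    def test_o3_daily_max_exceeds_daily_mean(self, small_domain):
        params = synth.TruthParams(mean_level=60.0, diurnal_amp=20.0)
        truth = synth.generate_truth(small_domain, "O3", params, seed=1)
        days = truth.values.reshape(-1, 24, small_domain.n_lat, small_domain.n_lon)
        assert np.all(days.max(axis=1) > days.mean(axis=1))

    def test_empirical_mean_near_mean_level(self, small_domain):
        params = synth.TruthParams(mean_level=30.0, noise_sd=3.0)
        means = [
            synth.generate_truth(small_domain, "SO2", params, seed=s).values.mean()
            for s in (1, 2, 3)
        ]
        n = small_domain.n_hours * small_domain.n_lat * small_domain.n_lon
        se = 3.0 / np.sqrt(n / 50)  # generous for spatio-temporal correlation
        assert abs(np.mean(means) - 30.0) < 3 * se

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            synth.TruthParams(mean_level=-1.0)


class TestPerturbToMember:
    def test_identity_spec_reproduces_truth(self, small_domain):
        truth = make_field(small_domain, "PM25", 14.0)
        spec = synth.PseudoModelSpec("M0")
        member = synth.perturb_to_member(truth, spec, seed=1)
        assert np.array_equal(member.values, truth.values)
        assert member.member_id == "M0"

    def test_pure_multiplicative_bias(self, small_domain, rng):
        vals = rng.uniform(1, 30, (small_domain.n_hours, small_domain.n_lat,
                                   small_domain.n_lon))
        truth = make_field(small_domain, "PM25", values=vals)
        member = synth.perturb_to_member(
            truth, synth.PseudoModelSpec("M1", mult_bias=0.8), seed=1
        )
        assert np.allclose(member.values, 0.8 * vals)

    def test_nmb_recovers_mult_bias_with_noise(self, small_domain):
        params = synth.TruthParams(mean_level=20.0, seasonal_amp=3.0,
                                   diurnal_amp=3.0, noise_sd=2.0)
        truth = synth.generate_truth(small_domain, "PM25", params, seed=7)
        member = synth.perturb_to_member(
            truth, synth.PseudoModelSpec("M1", mult_bias=0.8, noise_sd=0.5), seed=8
        )
        obs = synth.sample_observations(truth, n_stations=15, seed=9)
        stats = evaluate(pair_model_obs(member, obs))
        assert stats.nmb == pytest.approx(-0.20, abs=0.02)


class TestSampleObservations:
    def test_noiseless_equals_truth_at_cells(self, small_domain, rng):
        vals = rng.uniform(0, 25, (small_domain.n_hours, small_domain.n_lat,
                                   small_domain.n_lon))
        truth = make_field(small_domain, "O3", values=vals)
        obs = synth.sample_observations(truth, n_stations=5, seed=2)
        for st in obs:
            ilat, ilon = st.cell
            assert np.array_equal(st.values, vals[:, ilat, ilon])

    def test_missing_rate_within_binomial_bounds(self, small_domain):
        truth = make_field(small_domain, "O3", 20.0)
        obs = synth.sample_observations(
            truth, n_stations=10, missing_rate=0.3, seed=4
        )
        n = sum(st.values.size for st in obs)
        missing = sum(int(np.isnan(st.values).sum()) for st in obs)
        # 99 % binomial CI around 0.3
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(missing / n - 0.3) < 2.58 * se

    def test_same_seed_identical_placement_and_series(self, small_domain):
        truth = make_field(small_domain, "O3", 20.0)
        a = synth.sample_observations(truth, 5, obs_noise_sd=1.0,
                                      missing_rate=0.2, seed=6)
        b = synth.sample_observations(truth, 5, obs_noise_sd=1.0,
                                      missing_rate=0.2, seed=6)
        for x, y in zip(a, b):
            assert (x.lon, x.lat) == (y.lon, y.lat)
            np.testing.assert_array_equal(x.values, y.values)

    def test_too_many_stations_rejected(self, small_domain):
        truth = make_field(small_domain, "O3", 20.0)
        with pytest.raises(ValueError):
            synth.sample_observations(truth, n_stations=10_000, seed=1)


class TestMakeScenario:
    def test_unit_scale_is_identity(self, small_domain, rng):
        vals = rng.uniform(0, 25, (small_domain.n_hours, small_domain.n_lat,
                                   small_domain.n_lon))
        base = {"PM25": make_field(small_domain, "PM25", values=vals)}
        scen = synth.make_scenario(base, {"PM25": 1.0})
        assert np.array_equal(scen["PM25"].values, vals)

    def test_uniform_scaling_exact(self, small_domain, rng):
        vals = rng.uniform(0, 25, (small_domain.n_hours, small_domain.n_lat,
                                   small_domain.n_lon))
        base = {"PM25": make_field(small_domain, "PM25", values=vals)}
        scen = synth.make_scenario(base, {"PM25": 0.8})
        assert np.array_equal(scen["PM25"].values, vals * 0.8)

    def test_mask_locality(self, small_domain, rng):
        vals = rng.uniform(1, 25, (small_domain.n_hours, small_domain.n_lat,
                                   small_domain.n_lon))
        base = {"PM25": make_field(small_domain, "PM25", values=vals)}
        mask = np.zeros((small_domain.n_lat, small_domain.n_lon), dtype=bool)
        mask[:, : small_domain.n_lon // 2] = True
        scen = synth.make_scenario(base, {"PM25": 0.8}, region_mask=mask)
        out = scen["PM25"].values
        assert np.array_equal(out[:, ~mask], vals[:, ~mask])  # bit-identical
        assert np.allclose(out[:, mask], 0.8 * vals[:, mask])

    def test_bad_mask_shape_rejected(self, small_domain):
        base = {"PM25": make_field(small_domain, "PM25", 10.0)}
        with pytest.raises(ValueError, match="mask shape"):
            synth.make_scenario(base, {"PM25": 0.8},
                                region_mask=np.ones((2, 2), dtype=bool))
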