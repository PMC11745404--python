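"""Euler–Maruyama ensemble projection."""

import numpy as np
import pytest

import openstate as osx


def const_noise(level):
    return osx.NoiseModel(
        process=lambda x: np.full_like(np.asarray(x, float), level),
        observation=lambda x: np.zeros_like(np.asarray(x, float)))


def single_model(fn, bin_index=0):
    return {(bin_index, ()): osx.ChangeModel(bin_index=bin_index, smooth=fn)}


class TestEmStep:
    def test_deterministic_accumulation(self):
        x = 10.0
        for _ in range(5):
            x = osx.em_step(x, lambda v: np.full_like(v, 2.0),
                            lambda v: np.zeros_like(v), 0.1, 0.0)
        assert x == pytest.approx(11.0)

    def test_fixed_point_unchanged(self):
        f = lambda v: 0.3 * v * (1 - v / 60.0)
        out = osx.em_step(np.array([60.0]), f, lambda v: np.zeros_like(v),
                          0.1, np.array([0.0]))
        assert out[0] == 60.0

    def test_clipped_to_bounds(self):
        out = osx.em_step(np.array([99.0, 1.0]),
                          lambda v: np.array([50.0, -50.0]),
                          lambda v: np.zeros_like(v), 1.0, 0.0)
        assert out.tolist() == [100.0, 0.0]


class TestSimulateEnsemble:
    def test_ou_stationary_sd_closed_form(self, bins):
        """OU drift θ=0.5, σ=3: stationary SD = σ/√(2θ) = 3.0."""
        models = single_model(lambda x: -0.5 * (x - 50.0))
        cfg = osx.SimulationConfig(n_steps=2000, seed=3, record_every=200)
        ens = osx.simulate_ensemble(np.full(10_000, 50.0),
                                    np.full(10_000, -13.9), models,
                                    const_noise(3.0), bins, cfg)
        sd = ens.snapshot(int(ens.snapshot_years[-1])).std()
        assert sd == pytest.approx(3.0, rel=0.05)

    def test_zero_noise_deterministic_and_dt_stable(self, bins):
        models = single_model(lambda x: 0.3 * x * (1 - x / 60.0))
        x0 = np.array([5.0, 30.0, 80.0])
        mats = np.full(3, -13.9)
        finals = {}
        for dt in (0.1, 0.05):
            cfg = osx.SimulationConfig(dt=dt, n_steps=int(99 / dt), seed=1)
            ens = osx.simulate_ensemble(x0, mats, models, const_noise(0.0),
                                        bins, cfg)
            finals[dt] = ens.snapshot(int(ens.snapshot_years[-1]))
        assert np.max(np.abs(finals[0.1] - finals[0.05])) < 0.1

    def test_zero_noise_converges_to_stable_equilibria(self, bins):
        drift = lambda x: 0.3 * x * (1 - x / 60.0) * (x / 20.0 - 1.0)
        models = single_model(drift)
        eq = osx.find_equilibria(drift)
        x0 = np.array([5.0, 15.0, 25.0, 50.0, 95.0])
        cfg = osx.SimulationConfig(n_steps=5000, seed=1, record_every=100)
        ens = osx.simulate_ensemble(x0, np.full(5, -13.9), models,
                                    const_noise(0.0), bins, cfg)
        final = ens.snapshot(int(ens.snapshot_years[-1]))
        for val in final:
            assert np.min(np.abs(eq.stable_roots - val)) < 0.5

    def test_single_attractor_density_mode(self, bins):
        models = single_model(lambda x: 0.3 * x * (1 - x / 60.0))
        rng = np.random.default_rng(0)
        x0 = rng.uniform(5, 95, 4000)
        cfg = osx.SimulationConfig(n_steps=990, seed=2, record_every=99)
        ens = osx.simulate_ensemble(x0, np.full(4000, -13.9), models,
                                    const_noise(2.0), bins, cfg)
        d = osx.density(ens.snapshot(int(ens.snapshot_years[-1])))
        modes = d.modes()
        assert len(modes) == 1
        assert modes[0] == pytest.approx(60.0, abs=3.0)

    def test_warming_switches_bins_at_predicted_years(self, bins):
        models = {(b, ()): osx.ChangeModel(bin_index=b,
                                           smooth=lambda x: np.zeros_like(x))
                  for b in range(28, 34)}
        # base MAT exactly on the bin edge -0.0; +0.04 °C/y crosses a
        # 0.5 °C edge every 12.5 years
        warming = 0.04 * np.arange(100)
        cfg = osx.SimulationConfig(n_steps=990, seed=4)
        ens = osx.simulate_ensemble(np.array([50.0]), np.array([0.0]), models,
                                    const_noise(0.0), bins, cfg,
                                    warming=warming)
        path = ens.bin_path[0]
        years = np.arange(path.size)
        expected = 28 + np.minimum((0.04 * years) // 0.5, 5).astype(int)
        np.testing.assert_array_equal(path, expected)

    def test_beyond_warmest_bin_uses_warmest_model(self, bins):
        # drift differs per bin; plot warms far past the last fitted bin
        models = {(38, ()): osx.ChangeModel(bin_index=38,
                                            smooth=lambda x: np.full_like(x, -1.0)),
                  (39, ()): osx.ChangeModel(bin_index=39,
                                            smooth=lambda x: np.full_like(x, 1.0))}
        cfg = osx.SimulationConfig(n_steps=100, seed=5)
        ens = osx.simulate_ensemble(np.array([50.0]), np.array([20.0]), models,
                                    const_noise(0.0), bins, cfg)
        # MAT 20 °C is far above the 6 °C top edge -> warmest bin's +1 %/y
        assert ens.snapshot(int(ens.snapshot_years[-1]))[0] \
            == pytest.approx(60.0)

    def test_missing_interior_bin_is_an_error(self, bins):
        models = {(10, ()): osx.ChangeModel(bin_index=10,
                                            smooth=lambda x: np.zeros_like(x)),
                  (12, ()): osx.ChangeModel(bin_index=12,
                                            smooth=lambda x: np.zeros_like(x))}
        cfg = osx.SimulationConfig(n_steps=10, seed=6)
        with pytest.raises(KeyError, match="bin"):
            osx.simulate_ensemble(np.array([50.0]),
                                  np.array([bins.center(11)]), models,
                                  const_noise(0.0), bins, cfg)

    def test_reproducible_from_seed(self, bins):
        models = single_model(lambda x: 0.3 * x * (1 - x / 60.0))
        cfg = osx.SimulationConfig(n_steps=200, seed=7)
        args = (np.full(100, 40.0), np.full(100, -13.9), models,
                const_noise(2.0), bins, cfg)
        a = osx.simulate_ensemble(*args)
        b = osx.simulate_ensemble(*args)
        np.testing.assert_array_equal(a.latent, b.latent)


class TestObservationNoise:
    def _flat_ensemble(self, n=100_000, value=50.0):
        return osx.TrajectoryEnsemble(
            snapshot_years=np.array([0]),
            latent=np.full((n, 1), value), mat=np.zeros(n))

    def test_zero_h_identity(self):
        ens = self._flat_ensemble(n=100)
        osx.add_observation_noise(ens, lambda x: np.zeros_like(x), seed=1)
        np.testing.assert_array_equal(ens.observed, ens.latent)

    def test_snapshot_sd_matches_nominal(self):
        ens = self._flat_ensemble()
        osx.add_observation_noise(ens, lambda x: np.full_like(x, 5.0), seed=2)
        assert ens.observed[:, 0].std() == pytest.approx(5.0, rel=0.02)

    def test_same_seed_identical(self):
        a = self._flat_ensemble(n=500)
        b = self._flat_ensemble(n=500)
        h = lambda x: np.full_like(x, 3.0)
        osx.add_observation_noise(a, h, seed=9)
        osx.add_observation_noise(b, h, seed=9)
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_observed_iqr_at_least_latent(self, bins):
        models = single_model(lambda x: 0.3 * x * (1 - x / 60.0))
        cfg = osx.SimulationConfig(n_steps=990, seed=10, record_every=99)
        rng = np.random.default_rng(1)
        ens = osx.simulate_ensemble(rng.uniform(10, 90, 3000),
                                    np.full(3000, -13.9), models,
                                    const_noise(2.0), bins, cfg)
        osx.add_observation_noise(ens, lambda x: np.full_like(x, 3.0), seed=11)
        y = int(ens.snapshot_years[-1])
        d_lat = osx.density(ens.snapshot(y, "latent"))
        d_obs = osx.density(ens.snapshot(y, "observed"))
        assert d_obs.iqr() >= d_lat.iqr()


class TestSelectInitial:
    def test_equal_allocation_ensemble_size(self, bins):
        rng = np.random.default_rng(2)
        n = 4000
        cover = np.tile(rng.uniform(0, 100, 100), 40)[:n]
        mat = np.repeat(bins.center(np.arange(40)), 100)[:n]
        panel = osx.Panel.from_arrays(cover[:, None], mat, [2000],
                                      plot_ids=[f"p{i}" for i in range(n)])
        cfg = osx.SimulationConfig(n_samples=80_000, seed=3)
        x0, mat0 = osx.select_initial(panel, bins, cfg)
        assert x0.size == 80_000
        counts = np.bincount(osx.assign_bin(mat0, bins), minlength=40)
        assert np.all(counts == 2000)
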