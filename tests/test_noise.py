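"""Process/observation noise separation via the lag-SD regression."""

import numpy as np
import pandas as pd
import pytest

import openstate as osx
from openstate.trend import FittingError


def _panel_from_cover(cover, mat=-1.8):
    n = cover.shape[0]
    return osx.Panel.from_arrays(cover, np.full(n, mat),
                                 np.arange(2000, 2000 + cover.shape[1]))


class TestBuildLagSD:
    def test_constant_series_zero_sd(self):
        cover = np.tile(np.linspace(10, 90, 50)[:, None], (1, 12))
        table = osx.build_lag_sd(_panel_from_cover(cover), min_n=2)
        assert np.allclose(table["sd"], 0.0)

    def test_two_point_spread_is_population_sd(self):
        # group at 50 whose lagged values are exactly {50-3, 50+3}
        cover = np.zeros((40, 11))
        cover[:, :] = 50.0
        cover[::2, 1:] = 47.0
        cover[1::2, 1:] = 53.0
        table = osx.build_lag_sd(_panel_from_cover(cover), min_n=2)
        first = table[(table.cover_group == 50.0) & (table.lag == 1)]
        # only year-2000 occurrences sit at 50; their lag-1 values are ±3
        assert first["sd"].iloc[0] == pytest.approx(3.0)

    def test_diffusion_sd_matches_sqrt_lag_oracle(self, pure_noise_panel):
        """f≡0, g≡1, h≡0: sd(Δt) ≈ √Δt per lag (Monte-Carlo vs closed form)."""
        table = osx.build_lag_sd(pure_noise_panel)
        mid = table[(table.cover_group >= 30) & (table.cover_group <= 70)]
        pooled = mid.groupby("lag").apply(
            lambda t: np.average(t["sd"], weights=t["n"]),
            include_groups=False)
        for lag, sd in pooled.items():
            assert sd == pytest.approx(np.sqrt(lag), rel=0.10)

    def test_sd_invariant_to_plot_relabeling(self, pure_noise_panel):
        table = osx.build_lag_sd(pure_noise_panel)
        df = pure_noise_panel.df.sample(frac=1.0, random_state=7)
        df = df.assign(plot_id=[f"x{i}" for i in range(len(df))])
        table2 = osx.build_lag_sd(osx.Panel(df))
        pd.testing.assert_frame_equal(
            table.reset_index(drop=True), table2.reset_index(drop=True))

    def test_short_panel_rejected(self):
        cover = np.full((50, 5), 40.0)
        with pytest.raises(FittingError):
            osx.build_lag_sd(_panel_from_cover(cover), max_lag=10)


class TestFitSqrtLag:
    def test_exact_line_in_sqrt_lag(self):
        table = pd.DataFrame({"cover_group": [40.0] * 3,
                              "lag": [1, 4, 9], "sd": [3.0, 4.0, 5.0],
                              "n": [100] * 3})
        out = osx.fit_sqrt_lag(table)
        assert out["a"].iloc[0] == pytest.approx(2.0)
        assert out["b"].iloc[0] == pytest.approx(1.0)

    def test_constant_sd_is_pure_observation_noise(self):
        table = pd.DataFrame({"cover_group": [40.0] * 10,
                              "lag": range(1, 11), "sd": [2.5] * 10,
                              "n": [100] * 10})
        out = osx.fit_sqrt_lag(table)
        assert out["a"].iloc[0] == pytest.approx(2.5)
        assert out["b"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_estimates_clipped_and_flagged(self):
        table = pd.DataFrame({"cover_group": [40.0] * 3,
                              "lag": [1, 4, 9], "sd": [0.5, 1.5, 2.5],
                              "n": [100] * 3})
        out = osx.fit_sqrt_lag(table)
        assert out["a"].iloc[0] == 0.0
        assert bool(out["clipped"].iloc[0])
        assert out["a_raw"].iloc[0] < 0

    def test_too_few_lags_skipped_with_warning(self):
        table = pd.DataFrame({"cover_group": [40.0, 40.0, 50.0, 50.0, 50.0],
                              "lag": [1, 2, 1, 2, 3],
                              "sd": [1.0, 1.1, 1.0, 1.1, 1.2],
                              "n": [100] * 5})
        with pytest.warns(UserWarning, match="skipped"):
            out = osx.fit_sqrt_lag(table)
        assert out["cover_group"].tolist() == [50.0]

    def test_pure_process_noise_recovered_without_bias(self, pure_noise_panel):
        """With h≡0 the additive decomposition is exact: a≈0, b≈g."""
        coeffs = osx.fit_sqrt_lag(osx.build_lag_sd(pure_noise_panel))
        mid = coeffs[(coeffs.cover_group >= 20) & (coeffs.cover_group <= 80)]
        assert abs(np.median(mid["a_raw"])) < 0.2
        assert np.mean(mid["b"]) == pytest.approx(1.0, abs=0.15)


class TestFitNoiseModels:
    def test_constant_coefficients_give_constant_smooths(self):
        coeffs = pd.DataFrame({"cover_group": np.arange(10, 91, 5.0),
                               "a": 2.0, "b": 1.0})
        nm = osx.fit_noise_models(coeffs)
        x = np.linspace(10, 90, 33)
        assert np.allclose(nm.observation(x), 2.0, atol=1e-9)
        assert np.allclose(nm.process(x), 1.0, atol=1e-9)

    def test_linear_profile_recovered(self):
        grid = np.arange(0, 101, 1.0)
        coeffs = pd.DataFrame({"cover_group": grid,
                               "a": np.zeros_like(grid),
                               "b": 0.5 + 0.02 * grid})
        nm = osx.fit_noise_models(coeffs)
        assert np.max(np.abs(nm.process(grid) - (0.5 + 0.02 * grid))) < 1e-3

    def test_outputs_never_negative(self):
        rng = np.random.default_rng(5)
        grid = np.arange(0, 101, 2.0)
        coeffs = pd.DataFrame({"cover_group": grid,
                               "a": np.clip(rng.normal(0, 0.05, grid.size), 0,
                                            None),
                               "b": np.clip(rng.normal(0, 0.05, grid.size), 0,
                                            None)})
        nm = osx.fit_noise_models(coeffs)
        x = np.linspace(0, 100, 501)
        assert nm.observation(x).min() >= 0.0
        assert nm.process(x).min() >= 0.0

    def test_insufficient_groups_rejected(self):
        coeffs = pd.DataFrame({"cover_group": np.arange(5.0), "a": 1.0,
                               "b": 1.0})
        with pytest.raises(FittingError):
            osx.fit_noise_models(coeffs)


class TestSeparationSensitivity:
    """Recovered a tracks h and recovered b tracks g.

    The diagonal response dominates: doubling one true noise source
    moves its own estimate far more than the other's.
    """

    @staticmethod
    def _recover(g, h, seed=61):
        truth = osx.GroundTruthModel(
            "custom", custom_drift=lambda x: np.zeros_like(x),
            process_noise=g, obs_noise=h)
        cfg = osx.SyntheticConfig(n_plots=2500, years=21, seed=seed)
        panel = osx.generate_panel(truth, cfg)
        coeffs = osx.fit_sqrt_lag(osx.build_lag_sd(panel))
        mid = coeffs[(coeffs.cover_group >= 20) & (coeffs.cover_group <= 80)]
        return float(mid["a"].mean()), float(mid["b"].mean())

    def test_observation_noise_drives_intercept(self):
        a_lo, b_lo = self._recover(g=1.0, h=1.0)
        a_hi, b_hi = self._recover(g=1.0, h=2.0)
        assert a_hi > a_lo * 1.3
        assert abs(a_hi - a_lo) > 2 * abs(b_hi - b_lo)

    def test_process_noise_drives_slope(self):
        a_lo, b_lo = self._recover(g=1.0, h=1.0)
        a_hi, b_hi = self._recover(g=2.0, h=1.0)
        assert b_hi > b_lo * 1.3
        assert abs(b_hi - b_lo) > 2 * abs(a_hi - a_lo)
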