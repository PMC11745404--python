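"""Synthetic tree-cover landscapes from known stochastic ground truth.

Generates plot-series panels from a Langevin model

    dX = f(X) dt + g(X) dW,        X^ = X + h(X) B,

with a chosen drift f (logistic, weak Allee, strong Allee, or custom),
process-noise amplitude g and observation-noise SD h.  Latent paths are
integrated with the Euler–Maruyama scheme at a sub-annual step, sampled
annually, and observation noise is superimposed on the annual samples.
Every downstream stage (trend fitting, noise separation, projection,
state analysis, biomass) can therefore be validated against dynamics
whose equilibria and noise levels are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Panel

__all__ = [
    "ConfigurationError",
    "GroundTruthModel",
    "SyntheticConfig",
    "drift_eval",
    "generate_panel",
    "generate_warming",
]

DRIFT_NAMES = ("logistic", "allee", "strong_allee", "custom")


class ConfigurationError(ValueError):
    """Invalid ground-truth or generator configuration."""


def _as_fn(noise_fn) -> Callable[[np.ndarray], np.ndarray]:
    """Coerce a scalar or callable noise description to a callable."""
    if callable(noise_fn):
        return noise_fn
    val = float(noise_fn)
    return lambda x: np.full_like(np.asarray(x, dtype=float), val)


@dataclass
class GroundTruthModel:
    """True drift/diffusion/observation-noise triple used for generation.

    drift_params uses the field's conventions: ``r`` intrinsic rate
    (% y⁻¹ scale), ``K`` carrying cover (%), ``A`` Allee threshold (%).
    ``process_noise`` maps cover % → diffusion amplitude (% · y^(−1/2));
    ``obs_noise`` maps cover % → observation SD (%); either may be given
    as a constant.
    """

    drift_name: str = "logistic"
    drift_params: dict = field(default_factory=dict)
    process_noise: object = 0.0
    obs_noise: object = 0.0
    custom_drift: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.drift_name not in DRIFT_NAMES:
            raise ConfigurationError(
                f"unknown drift_name {self.drift_name!r}; "
                f"expected one of {DRIFT_NAMES}")
        if self.drift_name == "custom" and self.custom_drift is None:
            raise ConfigurationError("custom drift requires custom_drift")
        p = self.drift_params
        if self.drift_name != "custom":
            K = p.get("K", 60.0)
            if not 0.0 < K <= 100.0:
                raise ConfigurationError(f"K={K} must be in (0, 100]")
            if self.drift_name == "strong_allee":
                A = p.get("A", 20.0)
                if not 0.0 < A < K:
                    raise ConfigurationError(f"need 0 < A={A} < K={K}")

    def drift(self, x, params: Mapping | None = None):
        x = np.asarray(x, dtype=float)
        p = dict(self.drift_params)
        if params:
            p.update(params)
        if self.drift_name == "custom":
            return np.asarray(self.custom_drift(x), dtype=float)
        r = np.asarray(p.get("r", 0.1), dtype=float)
        K = np.asarray(p.get("K", 60.0), dtype=float)
        logistic = r * x * (1.0 - x / K)
        if self.drift_name == "logistic":
            return logistic
        A = np.asarray(p.get("A", 20.0), dtype=float)
        if self.drift_name == "strong_allee":
            return logistic * (x / A - 1.0)
        # weak Allee: saturating multiplicative factor x/(x+A)
        return logistic * x / (x + A)

    def g(self, x):
        return np.maximum(_as_fn(self.process_noise)(np.asarray(x, float)), 0.0)

    def h(self, x):
        return np.maximum(_as_fn(self.obs_noise)(np.asarray(x, float)), 0.0)


def drift_eval(model: GroundTruthModel, cover):
    """Evaluate the true drift f(cover) in % y⁻¹; cover must lie in [0, 100]."""
    cover = np.asarray(cover, dtype=float)
    if np.any((cover < 0) | (cover > 100)):
        raise ValueError("cover outside [0, 100]")
    out = model.drift(cover)
    return float(out) if out.ndim == 0 else out


@dataclass
class SyntheticConfig:
    """Panel-generation settings.

    21 annual observations starting in 2000 emulate the two-decade
    satellite record; ``dt_internal`` is the Euler–Maruyama substep in
    years.  ``init_cover`` may be "uniform", an array of initial covers,
    or a callable ``(rng, n, mat) -> covers``.  ``param_gradient`` maps a
    drift parameter name to its (value at mat_range[0], value at
    mat_range[1]) pair, linearly interpolated per plot over MAT, which
    produces a cold-sparse / warm-dense landscape; ``strata_scheme``
    assigns categorical labels per plot and ``param_overrides`` may
    override drift parameters per (stratum column, label).
    """

    n_plots: int = 1000
    years: int = 21
    dt_internal: float = 0.1
    mat_range: tuple = (-14.0, 6.0)
    seed: int = 0
    start_year: int = 2000
    init_cover: object = "uniform"
    burn_in_years: float = 0.0
    param_gradient: Mapping[str, tuple] | None = None
    strata_scheme: Mapping[str, Sequence[str]] | None = None
    param_overrides: Mapping[tuple, Mapping[str, float]] | None = None

    def __post_init__(self):
        if self.n_plots < 1:
            raise ConfigurationError("n_plots must be >= 1")
        if self.years < 2:
            raise ConfigurationError("years must be >= 2")
        if not 0.0 < self.dt_internal <= 1.0:
            raise ConfigurationError("dt_internal must be in (0, 1]")
        if self.seed is None:
            raise ConfigurationError("seed must be set")


def _initial_covers(cfg: SyntheticConfig, rng, mat):
    init = cfg.init_cover
    if isinstance(init, str):
        if init == "uniform":
            return rng.uniform(0.0, 100.0, cfg.n_plots)
        raise ConfigurationError(f"unknown init_cover scheme {init!r}")
    if callable(init):
        return np.clip(np.asarray(init(rng, cfg.n_plots, mat), float), 0, 100)
    arr = np.asarray(init, dtype=float)
    if arr.shape != (cfg.n_plots,):
        raise ConfigurationError("init_cover array must have shape (n_plots,)")
    return np.clip(arr, 0.0, 100.0)


def _per_plot_params(truth, cfg, rng, mat, strata):
    params = {k: np.full(cfg.n_plots, float(v))
              for k, v in truth.drift_params.items()}
    if cfg.param_gradient:
        lo, hi = cfg.mat_range
        frac = (mat - lo) / (hi - lo) if hi > lo else np.zeros_like(mat)
        for name, (v_lo, v_hi) in cfg.param_gradient.items():
            params[name] = v_lo + (v_hi - v_lo) * frac
    if cfg.param_overrides:
        for (col, label), over in cfg.param_overrides.items():
            mask = np.asarray(strata[col]) == label
            for name, val in over.items():
                if name not in params:
                    params[name] = np.full(cfg.n_plots, np.nan)
                params[name][mask] = val
    return params


def generate_panel(truth: GroundTruthModel, cfg: SyntheticConfig) -> Panel:
    """Simulate a panel of annual plot series from known ground truth.

    Euler–Maruyama at ``cfg.dt_internal`` with clipping to [0, 100] after
    every substep, annual subsampling, then observation noise
    h(X)·B added to each annual latent value (also clipped).
    Bit-reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    mat = rng.uniform(*cfg.mat_range, cfg.n_plots)
    strata = {}
    if cfg.strata_scheme:
        for col, labels in cfg.strata_scheme.items():
            strata[col] = rng.choice(list(labels), cfg.n_plots)
    params = _per_plot_params(truth, cfg, rng, mat, strata)
    x = _initial_covers(cfg, rng, mat)

    substeps = max(1, int(round(1.0 / cfg.dt_internal)))
    dt = 1.0 / substeps
    sqrt_dt = np.sqrt(dt)

    def advance_one_year(x):
        for _ in range(substeps):
            f = truth.drift(x, params)
            g = truth.g(x)
            x = x + dt * f + sqrt_dt * g * rng.standard_normal(cfg.n_plots)
            x = np.clip(x, 0.0, 100.0)
        return x

    for _ in range(int(round(cfg.burn_in_years))):
        x = advance_one_year(x)

    latent = np.empty((cfg.n_plots, cfg.years))
    latent[:, 0] = x
    for j in range(1, cfg.years):
        x = advance_one_year(x)
        latent[:, j] = x

    h = truth.h(latent)
    observed = latent + h * rng.standard_normal(latent.shape)
    observed = np.clip(observed, 0.0, 100.0)

    years = cfg.start_year + np.arange(cfg.years)
    panel = Panel.from_arrays(observed, mat, years, strata=strata)
    panel.latent = latent  # kept for validation against the truth
    return panel


def generate_warming(start_mat: float, rate: float, years: int,
                     start_year: int = 2000) -> pd.Series:
    """Linear warming trajectory: MAT per calendar year.

    ``rate`` is in °C y⁻¹; entry ``i`` is ``start_mat + rate * i``.
    """
    if years < 1:
        raise ConfigurationError("years must be >= 1")
    idx = start_year + np.arange(int(years))
    return pd.Series(start_mat + rate * np.arange(int(years)),
                     index=idx, name="mat")
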