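"""Forward projection of tree-cover ensembles.

Integrates the fitted Langevin model with the Euler–Maruyama scheme

    X(t+Δt) = X(t) + Δt·f_bin(X) + √Δt·g(X)·ξ,   ξ ~ N(0, 1),

at Δt = 0.1 y by default, each plot using the drift of its current
temperature bin.  Under a warming trajectory the bin is re-resolved
once per simulated year; beyond the warmest fitted bin the warmest
bin's model applies (and symmetrically the coldest below).  Observation
noise h(X)·B is superimposed on stored snapshots only — it never feeds
back into the dynamics.  Covers are clipped to [0, 100] after every
step (a reflecting boundary is available behind ``boundary``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .noise import NoiseModel
from .trend import TemperatureBins, assign_bin

__all__ = ["SimulationConfig", "TrajectoryEnsemble", "em_step",
           "simulate_ensemble", "add_observation_noise", "select_initial"]

_GRID_STEP = 0.1
_GRID = np.arange(0.0, 100.0 + _GRID_STEP / 2, _GRID_STEP)


@dataclass
class SimulationConfig:
    """Euler–Maruyama ensemble settings.

    The default horizon is 990 steps of 0.1 y from the year 2000 (the
    headline projection's step count); ``n_samples`` with
    ``equal_allocation`` draws the same number of initial plots per
    temperature bin (2,000 per bin × 40 bins = 80,000 by default).
    ``record_every`` is in simulated years.
    """

    dt: float = 0.1
    n_steps: int = 990
    n_samples: int = 80_000
    seed: int = 0
    record_every: int = 1
    equal_allocation: bool = True
    boundary: str = "clip"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.boundary not in ("clip", "reflect"):
            raise ValueError("boundary must be 'clip' or 'reflect'")

    @property
    def n_years(self) -> int:
        return int(np.ceil(self.n_steps * self.dt - 1e-9))


@dataclass
class TrajectoryEnsemble:
    """Simulated cover paths for many plots.

    ``latent`` has shape (n_plots, n_snapshots); ``snapshot_years`` are
    offsets from the start year.  ``observed`` is latent plus
    superimposed observation noise (clipped), filled by
    :func:`add_observation_noise`.  ``bin_path`` records each plot's
    temperature bin per simulated year.
    """

    snapshot_years: np.ndarray
    latent: np.ndarray
    mat: np.ndarray
    bin_path: np.ndarray = None
    observed: np.ndarray = None
    start_year: int = 2000

    @property
    def n_plots(self) -> int:
        return self.latent.shape[0]

    def snapshot(self, year_offset: int, kind: str = "latent") -> np.ndarray:
        arr = getattr(self, kind)
        if arr is None:
            raise ValueError(f"{kind} paths not available")
        idx = np.where(self.snapshot_years == year_offset)[0]
        if idx.size == 0:
            raise KeyError(f"no snapshot at year offset {year_offset}")
        return arr[:, idx[0]]


def em_step(x, f, g, dt: float, draw, boundary: str = "clip"):
    """One Euler–Maruyama step; ``f`` and ``g`` are callables of cover."""
    x = np.asarray(x, dtype=float)
    out = x + dt * np.asarray(f(x), float) \
        + np.sqrt(dt) * np.asarray(g(x), float) * np.asarray(draw, float)
    if boundary == "reflect":
        out = np.where(out < 0, -out, out)
        out = np.where(out > 100, 200.0 - out, out)
    return np.clip(out, 0.0, 100.0)


def _bin_rows(models: dict, strata_key: tuple):
    """Map bin index -> model for one stratum, with edge fallback."""
    sub = {b: m for (b, key), m in models.items() if key == strata_key}
    if not sub:
        raise KeyError(f"no fitted models for strata {strata_key!r}")
    return sub


def _resolve_bins(bin_idx, fitted: dict, strata_key):
    """Apply the edge-fallback rule; error on missing interior bins."""
    fitted_bins = np.array(sorted(fitted))
    lo, hi = fitted_bins[0], fitted_bins[-1]
    resolved = np.clip(bin_idx, lo, hi)
    missing = ~np.isin(resolved, fitted_bins)
    if np.any(missing):
        bad = sorted(set(np.asarray(resolved)[missing].tolist()))
        raise KeyError(
            f"no fitted change model for interior temperature bin(s) {bad} "
            f"(strata {strata_key!r}) and no fallback applies")
    return resolved


def simulate_ensemble(init_cover, mat, models: dict, noise: NoiseModel,
                      bins: TemperatureBins, cfg: SimulationConfig,
                      warming=None, strata_key: tuple = ()) -> TrajectoryEnsemble:
    """Integrate an ensemble forward under per-bin drift and shared noise.

    ``models`` maps (bin_index, strata_key) → ChangeModel; ``warming``
    is either None, a 1-D sequence of MAT offsets per simulated year
    (added to every plot's base MAT), or a (n_plots, n_years+1) array of
    absolute MATs.  Reproducible from ``cfg.seed``.
    """
    x = np.clip(np.asarray(init_cover, dtype=float).copy(), 0.0, 100.0)
    mat = np.asarray(mat, dtype=float)
    n = x.size
    rng = np.random.default_rng(cfg.seed)
    fitted = _bin_rows(models, strata_key)
    fitted_bins = sorted(fitted)
    row_map = np.full(bins.count, -1, dtype=int)
    row_map[fitted_bins] = np.arange(len(fitted_bins))

    # dense drift lookup per fitted bin: linear interpolation on a 0.1 % grid
    drift_grid = np.vstack([np.asarray(fitted[b](_GRID), float)
                            for b in fitted_bins])
    g_grid = np.asarray(noise.process(_GRID), dtype=float)

    n_years = cfg.n_years
    substeps = max(1, int(round(1.0 / cfg.dt)))
    dt = 1.0 / substeps
    sqrt_dt = np.sqrt(dt)
    steps_left = cfg.n_steps

    def mat_at_year(y):
        if warming is None:
            return mat
        w = np.asarray(warming, dtype=float)
        if w.ndim == 1:
            return mat + w[min(y, w.size - 1)]
        return w[:, min(y, w.shape[1] - 1)]

    snap_years = [0]
    snaps = [x.copy()]
    bin_path = np.empty((n, n_years + 1), dtype=int)

    pos = np.empty(n)
    for y in range(n_years):
        b = _resolve_bins(assign_bin(mat_at_year(y), bins), fitted, strata_key)
        bin_path[:, y] = b
        rows = row_map[b]
        for _ in range(substeps):
            if steps_left <= 0:
                break
            np.divide(x, _GRID_STEP, out=pos)
            i0 = np.minimum(pos.astype(int), _GRID.size - 2)
            frac = pos - i0
            f = drift_grid[rows, i0] * (1 - frac) + drift_grid[rows, i0 + 1] * frac
            g = g_grid[i0] * (1 - frac) + g_grid[i0 + 1] * frac
            x = x + dt * f + sqrt_dt * g * rng.standard_normal(n)
            if cfg.boundary == "reflect":
                x = np.where(x < 0, -x, x)
                x = np.where(x > 100, 200.0 - x, x)
            np.clip(x, 0.0, 100.0, out=x)
            steps_left -= 1
        if (y + 1) % cfg.record_every == 0 or y == n_years - 1:
            snap_years.append(y + 1)
            snaps.append(x.copy())
    bin_path[:, n_years] = _resolve_bins(
        assign_bin(mat_at_year(n_years), bins), fitted, strata_key)

    return TrajectoryEnsemble(
        snapshot_years=np.asarray(snap_years), latent=np.column_stack(snaps),
        mat=mat, bin_path=bin_path)


def add_observation_noise(ens: TrajectoryEnsemble, h, seed: int) -> TrajectoryEnsemble:
    """Superimpose observation noise h(X)·B on every stored snapshot.

    ``h`` is a callable of cover (e.g. ``NoiseModel.observation``); B is
    standard normal per (plot, snapshot).  The latent paths are left
    untouched; a clipped ``observed`` array is attached and returned.
    """
    if isinstance(h, NoiseModel):
        h = h.observation
    rng = np.random.default_rng(seed)
    sd = np.asarray(h(ens.latent), dtype=float)
    ens.observed = np.clip(
        ens.latent + sd * rng.standard_normal(ens.latent.shape), 0.0, 100.0)
    return ens


def select_initial(panel, bins: TemperatureBins, cfg: SimulationConfig,
                   year_index: int = 0):
    """Draw the simulation's initial (cover, MAT) sample from a panel.

    With ``equal_allocation`` the same number of plots is drawn per
    fitted temperature bin (with replacement when a bin holds fewer
    plots than its quota), totalling ``cfg.n_samples``.
    """
    rng = np.random.default_rng(cfg.seed)
    cover = panel.cover[:, year_index]
    mat = panel.mat
    ok = np.isfinite(cover)
    cover, mat = cover[ok], mat[ok]
    if not cfg.equal_allocation:
        idx = rng.choice(cover.size, size=min(cfg.n_samples, cover.size),
                         replace=False)
        return cover[idx], mat[idx]
    b = assign_bin(mat, bins)
    present = np.unique(b)
    per_bin = cfg.n_samples // present.size
    picks = []
    for bi in present:
        pool = np.where(b == bi)[0]
        picks.append(rng.choice(pool, size=per_bin, replace=pool.size < per_bin))
    idx = np.concatenate(picks)
    return cover[idx], mat[idx]
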