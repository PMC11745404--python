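"""Separation of process noise from observation noise.

For small lags the SD of cover at t+Δt across plots that share the same
cover at t grows like

    σ(Δt) = a + b·√Δt,

because process noise accumulates like a diffusion (∝ √Δt) while
observation noise is lag-independent.  The procedure: pool every
plot-year occurrence into 1 %-wide cover groups, compute the SD of the
lagged cover per (group, lag) for Δt = 1…10 y, regress σ on √Δt per
group (intercept → observation noise a, slope → process noise b), then
smooth the per-group coefficients over cover into the temperature-
independent noise functions g(X) (process) and h(X) (observation).
No drift correction is applied to the SDs; for strongly drifting
groups this inflates b slightly (small-time-step assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .panel import Panel
from .smoothing import PenalizedSpline
from .trend import FittingError

__all__ = ["NoiseModel", "build_lag_sd", "fit_sqrt_lag", "fit_noise_models"]


def build_lag_sd(panel: Panel, max_lag: int = 10, group_width: float = 1.0,
                 min_n: int = 30) -> pd.DataFrame:
    """SD of lagged cover per (initial cover group, lag).

    Pools all plot-year occurrences 2000–2020: every observation with
    cover in group c and a value max_lag or fewer years later
    contributes.  Cover groups are the nearest multiple of
    ``group_width`` (1 % by default); SDs are population SDs.  Returns columns
    (cover_group, lag, sd, n); (group, lag) cells with fewer than
    ``min_n`` occurrences are omitted.
    """
    cover = panel.cover
    n_years = cover.shape[1]
    if n_years < max_lag + 1:
        raise FittingError(
            f"panel spans {n_years} years; need >= max_lag+1 = {max_lag + 1}")
    rows = []
    for lag in range(1, max_lag + 1):
        start = cover[:, : n_years - lag].ravel()
        future = cover[:, lag:].ravel()
        ok = np.isfinite(start) & np.isfinite(future)
        grp = np.round(start[ok] / group_width) * group_width
        agg = (pd.DataFrame({"cover_group": grp, "value": future[ok]})
               .groupby("cover_group")["value"]
               .agg(sd=lambda v: v.std(ddof=0), n="size")
               .reset_index())
        agg["lag"] = lag
        rows.append(agg)
    table = pd.concat(rows, ignore_index=True)
    table = table[table["n"] >= min_n].reset_index(drop=True)
    if table.empty:
        raise FittingError(
            f"no (cover group, lag) cell reaches min_n={min_n} occurrences")
    return table[["cover_group", "lag", "sd", "n"]]


def fit_sqrt_lag(table: pd.DataFrame, min_lags: int = 3,
                 weighted: bool = False) -> pd.DataFrame:
    """Per-cover-group OLS of sd on √lag: sd = a + b·√Δt.

    Intercept a is the observation noise, slope b the process noise.
    Negative estimates are clipped to 0 and flagged; the unclipped
    values are kept in ``a_raw``/``b_raw``.  Groups with fewer than
    ``min_lags`` lags are skipped with a warning.  ``weighted`` uses the
    occurrence counts as OLS weights (off by default).
    """
    out = []
    for grp, sub in table.groupby("cover_group"):
        if len(sub) < min_lags:
            warnings.warn(
                f"cover group {grp}: only {len(sub)} lags (< {min_lags}); "
                "skipped", stacklevel=2)
            continue
        x = np.sqrt(sub["lag"].to_numpy(dtype=float))
        y = sub["sd"].to_numpy(dtype=float)
        w = sub["n"].to_numpy(dtype=float) if weighted else None
        b_raw, a_raw = np.polyfit(x, y, 1, w=w)
        yhat = a_raw + b_raw * x
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        out.append({
            "cover_group": grp,
            "a": max(a_raw, 0.0), "b": max(b_raw, 0.0),
            "a_raw": a_raw, "b_raw": b_raw,
            "r2": r2, "n_lags": len(sub),
            "clipped": bool(a_raw < 0 or b_raw < 0),
        })
    if not out:
        raise FittingError("no cover group has enough lags to fit")
    return pd.DataFrame(out)


@dataclass
class NoiseModel:
    """Smoothed, temperature-independent noise functions.

    ``process(x)`` returns the diffusion amplitude g(x) in % · y^(−1/2);
    ``observation(x)`` returns the observation SD h(x) in %.  Both are
    clipped at zero.  ``coefficients`` keeps the per-cover-group (a, b)
    table with fit diagnostics.
    """

    process: Callable
    observation: Callable
    coefficients: pd.DataFrame = None
    strata_key: tuple = ()

    def __post_init__(self):
        raw_g, raw_h = self.process, self.observation
        self.process = lambda x: np.maximum(raw_g(x), 0.0)
        self.observation = lambda x: np.maximum(raw_h(x), 0.0)


def fit_noise_models(coeffs: pd.DataFrame, min_groups: int = 10,
                     basis_dim: int = 20, strata_key: tuple = ()) -> NoiseModel:
    """Smooth the per-cover-group (a, b) coefficients into h(X) and g(X).

    Uses the same penalized cubic regression spline contract as the
    drift fits; one temperature-independent model per stratum.
    """
    if len(coeffs) < min_groups:
        raise FittingError(
            f"{len(coeffs)} cover groups < required {min_groups}")
    x = coeffs["cover_group"].to_numpy(dtype=float)
    sp_b = PenalizedSpline(k=basis_dim).fit(x, coeffs["b"].to_numpy(float))
    sp_a = PenalizedSpline(k=basis_dim).fit(x, coeffs["a"].to_numpy(float))
    return NoiseModel(process=sp_b, observation=sp_a,
                      coefficients=coeffs.copy(), strata_key=strata_key)
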