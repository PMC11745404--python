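"""Equilibria, density landscapes and windowed density shifts.

Stable states of the fitted dynamics are the zero crossings of the
drift with negative local slope (attractors); positive-slope crossings
are repellers.  Cover distributions are summarized as Gaussian kernel
densities on [0, 100] with boundary reflection, and their modes (local
maxima above a prominence floor) diagnose unimodal vs bimodal — i.e.
single-state vs alternative-state — landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .panel import Panel
from .trend import TemperatureBins, assign_bin

__all__ = ["EquilibriumSet", "DensityLandscape", "find_equilibria",
           "density", "windowed_densities", "DEFAULT_WINDOWS"]

DEFAULT_WINDOWS = ((2000, 2004), (2005, 2009), (2010, 2014), (2015, 2020))


@dataclass
class EquilibriumSet:
    """Drift zeros on [0, 100], sorted ascending.

    ``stability[i]`` is "stable" where the drift slope is negative at
    the root and "unstable" where positive; tangential zeros (the drift
    touches zero without crossing) are listed separately.
    """

    roots: np.ndarray
    stability: list
    tangential: np.ndarray = field(default_factory=lambda: np.array([]))
    key: tuple = ()

    @property
    def stable_roots(self) -> np.ndarray:
        return self.roots[[s == "stable" for s in self.stability]]

    @property
    def unstable_roots(self) -> np.ndarray:
        return self.roots[[s == "unstable" for s in self.stability]]


def find_equilibria(model, grid_step: float = 0.1, tol: float = 1e-4,
                    zero_atol: float = 1e-12, key: tuple = ()) -> EquilibriumSet:
    """Locate and classify zero crossings of a drift function on [0, 100].

    Sign changes between grid points are refined by bisection
    (:func:`scipy.optimize.brentq`) to ``tol`` cover-%; classification
    uses the local slope (central difference at ``grid_step`` scale).
    Grid points where the drift is exactly zero without a sign change
    are reported as tangential.
    """
    f = model if callable(model) else model.smooth
    grid = np.arange(0.0, 100.0 + grid_step / 2, grid_step)
    vals = np.asarray(f(grid), dtype=float)

    roots = []
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0 and (i == 0 or vals[i - 1] != 0.0):
            roots.append(grid[i])
        elif v0 * v1 < 0:
            roots.append(brentq(lambda z: float(np.asarray(f(z))),
                                grid[i], grid[i + 1], xtol=tol))
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    def slope(x0):
        h = grid_step
        lo, hi = max(x0 - h, 0.0), min(x0 + h, 100.0)
        return (float(np.asarray(f(hi))) - float(np.asarray(f(lo)))) / (hi - lo)

    kept, stability, tangential = [], [], []
    for x0 in roots:
        s = slope(x0)
        if abs(s) <= zero_atol:
            tangential.append(x0)
        else:
            kept.append(x0)
            stability.append("stable" if s < 0 else "unstable")
    order = np.argsort(kept)
    return EquilibriumSet(
        roots=np.asarray(kept)[order],
        stability=[stability[i] for i in order],
        tangential=np.asarray(sorted(tangential)), key=key)


@dataclass
class DensityLandscape:
    """Probability density of tree cover on a regular [0, 100] grid."""

    grid: np.ndarray
    density: np.ndarray
    window: str = ""
    key: tuple = ()

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def modes(self, prominence_frac: float = 0.05) -> np.ndarray:
        """Local maxima with prominence ≥ ``prominence_frac`` of the peak."""
        d = self.density
        prom = prominence_frac * float(d.max())
        peaks, _ = find_peaks(d, prominence=prom)
        # boundary maxima are not seen by find_peaks; pad with edge dips
        padded = np.concatenate([[0.0], d, [0.0]])
        ppeaks, _ = find_peaks(padded, prominence=prom)
        peaks = np.unique(np.concatenate([peaks, ppeaks - 1]))
        peaks = peaks[(peaks >= 0) & (peaks < d.size)]
        return self.grid[peaks]

    def iqr(self) -> float:
        """Interquartile range of the density (via its CDF on the grid)."""
        cdf = np.concatenate([[0.0], np.cumsum(
            np.diff(self.grid) * 0.5 * (self.density[1:] + self.density[:-1]))])
        cdf /= cdf[-1]
        q25, q75 = np.interp([0.25, 0.75], cdf, self.grid)
        return float(q75 - q25)


def density(values, grid_n: int = 1001, bw_method: str = "silverman",
            window: str = "", key: tuple = ()) -> DensityLandscape:
    """Reflected Gaussian KDE of cover values, normalized on [0, 100].

    Boundary reflection at 0 and 100 removes the edge bias of a plain
    kernel estimate for a variable confined to a bounded percentage;
    Silverman's rule sets the bandwidth.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("density requires at least 2 values")
    kde = gaussian_kde(values, bw_method=bw_method)
    grid = np.linspace(0.0, 100.0, grid_n)
    d = kde(grid) + kde(-grid) + kde(200.0 - grid)
    d /= np.trapezoid(d, grid)
    return DensityLandscape(grid=grid, density=d, window=window, key=key)


def windowed_densities(panel: Panel, windows=DEFAULT_WINDOWS,
                       bins: TemperatureBins | None = None) -> list:
    """Pooled plot-year cover densities per time window (and per bin).

    Each window (y0, y1) pools every cover value observed in calendar
    years y0..y1 inclusive, optionally split by temperature bin,
    yielding one :class:`DensityLandscape` per (window, bin).
    """
    out = []
    cover = panel.cover
    years = panel.years
    if bins is not None:
        bin_idx = assign_bin(panel.mat, bins)
        groups = [(bi, cover[bin_idx == bi]) for bi in np.unique(bin_idx)]
    else:
        groups = [((), cover)]
    for (y0, y1) in windows:
        cols = np.where((years >= y0) & (years <= y1))[0]
        if cols.size == 0:
            raise ValueError(f"window {y0}-{y1} contains no observed years")
        for key, cov in groups:
            vals = cov[:, cols].ravel()
            out.append(density(vals, window=f"{y0}-{y1}",
                               key=key if isinstance(key, tuple) else (key,)))
    return out
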