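"""Per-plot trend estimation and per-bin deterministic drift fitting.

The deterministic part f(X) of the cover dynamics is estimated in two
steps: (1) each plot's annual change rate (% y⁻¹) by the Theil–Sen
estimator — the median of all pairwise slopes of its annual series,
robust to observation noise; (2) within each 0.5 °C mean-annual-
temperature bin (and optional categorical strata), a penalized cubic
regression spline of change rate against initial (first-year) cover.
The zero crossings of that smooth are the bin's cover equilibria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .panel import Panel, PlotSeries
from .smoothing import PenalizedSpline

__all__ = [
    "TemperatureBins",
    "ChangeModel",
    "FittingError",
    "UndefinedChangeError",
    "assign_bin",
    "theil_sen",
    "panel_theil_sen",
    "fit_change_model",
]


class FittingError(RuntimeError):
    """Model fitting could not proceed (empty panel, all groups skipped...)."""


class UndefinedChangeError(ValueError):
    """Theil–Sen change is undefined (fewer than 2 usable observations)."""


@dataclass(frozen=True)
class TemperatureBins:
    """Half-open 0.5 °C MAT bins [low+i·w, low+(i+1)·w); default −14…6 °C."""

    low: float = -14.0
    high: float = 6.0
    width: float = 0.5

    def __post_init__(self):
        n = (self.high - self.low) / self.width
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError(
                f"(high-low)/width must be a positive integer, got {n}")

    @property
    def count(self) -> int:
        return int(round((self.high - self.low) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.low + self.width * np.arange(self.count + 1)

    def label(self, i: int) -> str:
        e = self.edges
        return f"[{e[i]:g},{e[i + 1]:g})"

    def center(self, i) -> np.ndarray:
        return self.low + self.width * (np.asarray(i) + 0.5)


def assign_bin(mat, bins: TemperatureBins):
    """Bin index for a MAT value; out-of-range MATs map to the edge bins.

    Temperatures at or above the top edge use the warmest bin, mirroring
    the warmest-bin fallback applied when projected warming exceeds the
    fitted range; temperatures below the bottom edge use the coldest.
    """
    mat = np.asarray(mat, dtype=float)
    idx = np.floor((mat - bins.low) / bins.width).astype(int)
    idx = np.clip(idx, 0, bins.count - 1)
    return int(idx) if idx.ndim == 0 else idx


# -- Theil–Sen --------------------------------------------------------------

def theil_sen(series) -> float:
    """Median of all pairwise slopes (Δcover / Δyear) of one plot series.

    Pairs with zero year difference are excluded; years with missing
    cover are skipped.  An even number of pairwise slopes yields the
    midpoint of the two central ones (the ordinary median).
    """
    if isinstance(series, PlotSeries):
        years = np.asarray(series.cover.index, dtype=float)
        values = np.asarray(series.cover, dtype=float)
    else:
        values, years = series
        years = np.asarray(years, dtype=float)
        values = np.asarray(values, dtype=float)
    ok = np.isfinite(values) & np.isfinite(years)
    years, values = years[ok], values[ok]
    if values.size < 2:
        raise UndefinedChangeError(
            f"need >= 2 observations, got {values.size}")
    j, k = np.triu_indices(values.size, 1)
    dy = years[k] - years[j]
    keep = dy != 0
    if not np.any(keep):
        raise UndefinedChangeError("all observation pairs share a year")
    slopes = (values[k] - values[j])[keep] / dy[keep]
    return float(np.median(slopes))


def panel_theil_sen(cover: np.ndarray, years) -> np.ndarray:
    """Vectorized Theil–Sen over a (n_plots, n_years) cover matrix.

    Missing values are masked pairwise; plots with < 2 observations get
    NaN.  Matches :func:`theil_sen` row by row.
    """
    cover = np.asarray(cover, dtype=float)
    years = np.asarray(years, dtype=float)
    j, k = np.triu_indices(cover.shape[1], 1)
    dy = years[k] - years[j]
    keep = dy != 0
    j, k, dy = j[keep], k[keep], dy[keep]
    slopes = (cover[:, k] - cover[:, j]) / dy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmedian(slopes, axis=1)


# -- drift models ------------------------------------------------------------

@dataclass
class ChangeModel:
    """Fitted drift f(X) for one (temperature bin, stratum) group.

    ``support`` is the cover range observed in the fit; outside it the
    smooth continues linearly from the boundary (needed when warming
    moves plots into bins fitted on different cover ranges).
    """

    bin_index: int
    strata_key: tuple = ()
    smooth: Callable = None
    support: tuple = (0.0, 100.0)
    n_fit: int = 0
    bin_label: str = ""

    def __call__(self, cover):
        return self.smooth(cover)

    GRID = np.arange(0.0, 100.0 + 1e-9, 0.5)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"cover": self.GRID,
                             "change": self.smooth(self.GRID)})

    @classmethod
    def from_grid(cls, cover, change, **meta) -> "ChangeModel":
        cover = np.asarray(cover, dtype=float)
        change = np.asarray(change, dtype=float)

        def interp(x):
            return np.interp(np.asarray(x, dtype=float), cover, change)

        return cls(smooth=interp, **meta)


def fit_change_model(panel: Panel, bins: TemperatureBins,
                     strata_keys: tuple = (), min_group: int = 50,
                     basis_dim: int = 20,
                     pool_start_years: bool = False) -> dict:
    """Fit a drift smooth per (temperature bin, stratum) group.

    Response: per-plot Theil–Sen change rate.  Predictor: the plot's
    first-year cover — or, with ``pool_start_years``, each start year's
    cover paired with the change rate, pooled.  Groups with fewer than
    ``min_group`` plots are skipped with a warning; a mapping
    ``{(bin_index, strata_key): ChangeModel}`` is returned with the
    skipped groups listed in its ``.skipped`` attribute.
    """
    if len(panel) == 0:
        raise FittingError("empty panel")
    cover = panel.cover
    changes = panel_theil_sen(cover, panel.years)
    bin_idx = assign_bin(panel.mat, bins)
    if strata_keys:
        strata = panel.df[list(strata_keys)].astype(str)
        group_keys = [tuple(t) for t in strata.itertuples(index=False)]
    else:
        group_keys = [()] * len(panel)

    frame = pd.DataFrame({"bin": bin_idx, "key": group_keys,
                          "x0": cover[:, 0], "change": changes})
    frame = frame.dropna(subset=["x0", "change"])

    models: dict = {}
    skipped = []
    for (b, key), grp in frame.groupby(["bin", "key"], sort=True):
        if len(grp) < min_group:
            skipped.append((int(b), key, len(grp)))
            warnings.warn(
                f"group bin={b} strata={key}: {len(grp)} < {min_group} "
                "plots; skipped", stacklevel=2)
            continue
        x, y = grp["x0"].to_numpy(), grp["change"].to_numpy()
        if pool_start_years:
            xs, ys = [], []
            for j in range(cover.shape[1]):
                sel = grp.index.to_numpy()
                xs.append(cover[sel, j])
                ys.append(changes[sel])
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            ok = np.isfinite(x)
            x, y = x[ok], y[ok]
        sp = PenalizedSpline(k=basis_dim).fit(x, y)
        models[(int(b), key)] = ChangeModel(
            bin_index=int(b), strata_key=key, smooth=sp,
            support=sp.support_, n_fit=len(grp), bin_label=bins.label(int(b)))
    if not models:
        raise FittingError(
            f"all groups below min_group={min_group}: {skipped}")
    models = dict(sorted(models.items()))
    out = _ModelSet(models)
    out.skipped = skipped
    return out


class _ModelSet(dict):
    """dict of ChangeModels keyed (bin_index, strata_key), + skip metadata."""

    skipped: list = []
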