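"""Plot-series panel container.

A *panel* is the package's central in-memory object: one row per sample
plot, with the plot's mean annual temperature (MAT, °C), optional
categorical strata (region, fire, management, ...) and one column of
tree cover (%) per calendar year.  Internally it wraps a wide pandas
DataFrame whose year columns are named ``tc_<year>`` (e.g. ``tc_2000``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PlotSeries", "Panel", "PanelFormatError", "YEAR_COLUMN_PREFIX"]

YEAR_COLUMN_PREFIX = "tc_"
_YEAR_RE = re.compile(rf"^{YEAR_COLUMN_PREFIX}(\d{{4}})$")


class PanelFormatError(ValueError):
    """A panel table violates the wide-format schema or value contracts."""


@dataclass
class PlotSeries:
    """One plot's annual tree-cover series with its covariates.

    ``cover`` is indexed by calendar year (strictly increasing, annual
    spacing); values are percent cover in [0, 100], NaN for missing.
    """

    plot_id: str
    mat: float
    cover: pd.Series
    strata: dict = field(default_factory=dict)

    def __post_init__(self):
        years = np.asarray(self.cover.index, dtype=int)
        if len(years) >= 2 and not np.all(np.diff(years) == 1):
            raise PanelFormatError(
                f"plot {self.plot_id}: years must be strictly increasing with "
                f"annual spacing, got {years.tolist()}")
        vals = np.asarray(self.cover, dtype=float)
        bad = (vals < 0) | (vals > 100)
        if np.any(bad & np.isfinite(vals)):
            raise PanelFormatError(
                f"plot {self.plot_id}: cover values outside [0, 100]")


class Panel:
    """Collection of :class:`PlotSeries` in wide tabular form."""

    def __init__(self, df: pd.DataFrame):
        year_cols = [c for c in df.columns if _YEAR_RE.match(str(c))]
        if "plot_id" not in df.columns or "mat" not in df.columns:
            raise PanelFormatError("panel requires 'plot_id' and 'mat' columns")
        if not year_cols:
            raise PanelFormatError(
                f"panel has no '{YEAR_COLUMN_PREFIX}<year>' cover columns")
        years = sorted(int(_YEAR_RE.match(c).group(1)) for c in year_cols)
        if len(years) >= 2 and not np.all(np.diff(years) == 1):
            raise PanelFormatError(f"panel years not annually spaced: {years}")
        ordered = [f"{YEAR_COLUMN_PREFIX}{y}" for y in years]
        meta = [c for c in df.columns if c not in year_cols]
        self.df = df[meta + ordered].reset_index(drop=True)
        self.years = np.asarray(years, dtype=int)
        self._year_cols = ordered
        cover = self.df[ordered].to_numpy(dtype=float)
        bad = (cover < 0) | (cover > 100)
        if np.any(bad & np.isfinite(cover)):
            row = int(np.where((bad & np.isfinite(cover)).any(axis=1))[0][0])
            raise PanelFormatError(
                f"cover outside [0, 100] at panel row {row} "
                f"(plot_id={self.df['plot_id'].iloc[row]!r})")

    # -- accessors ---------------------------------------------------------

    @property
    def cover(self) -> np.ndarray:
        """(n_plots, n_years) float array of tree cover %."""
        return self.df[self._year_cols].to_numpy(dtype=float)

    @property
    def mat(self) -> np.ndarray:
        return self.df["mat"].to_numpy(dtype=float)

    @property
    def plot_ids(self) -> np.ndarray:
        return self.df["plot_id"].to_numpy()

    @property
    def strata_columns(self) -> list:
        return [c for c in self.df.columns
                if c not in ("plot_id", "mat") and c not in self._year_cols]

    def __len__(self) -> int:
        return len(self.df)

    def series(self, plot_id) -> PlotSeries:
        rows = self.df.index[self.df["plot_id"] == plot_id]
        if len(rows) == 0:
            raise KeyError(f"no plot with id {plot_id!r}")
        row = self.df.loc[rows[0]]
        cover = pd.Series(
            row[self._year_cols].to_numpy(dtype=float), index=self.years)
        strata = {c: row[c] for c in self.strata_columns}
        return PlotSeries(plot_id=row["plot_id"], mat=float(row["mat"]),
                          cover=cover, strata=strata)

    def __iter__(self):
        for pid in self.df["plot_id"]:
            yield self.series(pid)

    @classmethod
    def from_series(cls, series: list) -> "Panel":
        rows = []
        for s in series:
            row = {"plot_id": s.plot_id, "mat": s.mat, **s.strata}
            for year, val in s.cover.items():
                row[f"{YEAR_COLUMN_PREFIX}{int(year)}"] = val
            rows.append(row)
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_arrays(cls, cover: np.ndarray, mat: np.ndarray, years,
                    plot_ids=None, strata: dict | None = None) -> "Panel":
        cover = np.asarray(cover, dtype=float)
        n = cover.shape[0]
        if plot_ids is None:
            plot_ids = [f"p{i:06d}" for i in range(n)]
        data = {"plot_id": plot_ids, "mat": np.asarray(mat, dtype=float)}
        for key, vals in (strata or {}).items():
            data[key] = vals
        for j, y in enumerate(years):
            data[f"{YEAR_COLUMN_PREFIX}{int(y)}"] = cover[:, j]
        return cls(pd.DataFrame(data))

    def equals(self, other: "Panel") -> bool:
        return self.df.equals(other.df)
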