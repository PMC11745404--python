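"""Delimited-text round-tripping for every artifact in the pipeline.

Single interchange dialect: comma-separated UTF-8 with '.' decimals.
Panels are wide (plot_id, mat, strata..., tc_2000...tc_2020); change
models are dense prediction grids with a '#'-prefixed metadata header;
noise tables and coefficient tables carry their column headers.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .panel import Panel, PanelFormatError, YEAR_COLUMN_PREFIX
from .trend import ChangeModel

__all__ = ["read_panel", "write_panel", "read_warming", "write_warming",
           "write_change_models", "read_change_models",
           "write_table", "read_table"]


def read_panel(path) -> Panel:
    """Read a wide panel table, validating schema and value ranges."""
    if os.path.getsize(path) == 0:
        raise PanelFormatError(f"{path}: empty panel file")
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise PanelFormatError(f"{path}: panel has a header but no rows")
    year_cols = [c for c in df.columns if str(c).startswith(YEAR_COLUMN_PREFIX)]
    for c in year_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad_parse = vals.isna() & df[c].notna() & (df[c].astype(str) != "")
        if bad_parse.any():
            row = int(np.where(bad_parse)[0][0])
            raise PanelFormatError(
                f"{path}: non-numeric cover in column {c}, row {row}")
        out_of_range = vals.notna() & ((vals < 0) | (vals > 100))
        if out_of_range.any():
            row = int(np.where(out_of_range)[0][0])
            raise PanelFormatError(
                f"{path}: cover {vals.iloc[row]} outside [0, 100] "
                f"in column {c}, row {row}")
        df[c] = vals
    try:
        return Panel(df)
    except PanelFormatError as e:
        raise PanelFormatError(f"{path}: {e}") from e


def write_panel(panel: Panel, path) -> None:
    panel.df.to_csv(path, index=False)


def read_warming(path) -> pd.Series:
    df = pd.read_csv(path, float_precision="round_trip")
    if "year" not in df.columns or "mat" not in df.columns:
        raise PanelFormatError(f"{path}: warming table needs year,mat columns")
    return pd.Series(df["mat"].to_numpy(float),
                     index=df["year"].to_numpy(int), name="mat")


def write_warming(traj: pd.Series, path) -> None:
    pd.DataFrame({"year": traj.index, "mat": traj.to_numpy()}).to_csv(
        path, index=False)


def write_change_models(models: dict, directory) -> None:
    """One grid file per (bin, strata) model, with a metadata header."""
    os.makedirs(directory, exist_ok=True)
    for (b, key), model in models.items():
        tag = "_".join(str(k) for k in key) if key else "all"
        path = os.path.join(directory, f"change_bin{b:03d}_{tag}.csv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# bin_index={b}\n")
            fh.write(f"# strata_key={','.join(map(str, key))}\n")
            fh.write(f"# bin_label={model.bin_label}\n")
            fh.write(f"# n_fit={model.n_fit}\n")
            fh.write(f"# support={model.support[0]!r},{model.support[1]!r}\n")
            model.to_table().to_csv(fh, index=False)


def read_change_models(directory) -> dict:
    """Rebuild grid-interpolating ChangeModels; exact on the written grid."""
    models = {}
    for name in sorted(os.listdir(directory)):
        if not (name.startswith("change_bin") and name.endswith(".csv")):
            continue
        path = os.path.join(directory, name)
        meta = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k.strip()] = v
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, float_precision="round_trip")
        key = tuple(s for s in meta.get("strata_key", "").split(",") if s)
        sup = meta.get("support", "0.0,100.0").split(",")
        model = ChangeModel.from_grid(
            table["cover"], table["change"],
            bin_index=int(meta["bin_index"]), strata_key=key,
            support=(float(sup[0]), float(sup[1])),
            n_fit=int(meta.get("n_fit", 0)),
            bin_label=meta.get("bin_label", ""))
        models[(model.bin_index, key)] = model
    return models


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
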