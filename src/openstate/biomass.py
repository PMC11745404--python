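"""Tree cover → aboveground biomass models and projected biomass change.

A calibration set of (cover %, AGB t ha⁻¹) pairs is fit with three
candidate families — linear, power (α·xᵝ) and exponential (α·e^{βx}) —
each by least squares on the natural scale, and the family with the
lowest AIC under a common Gaussian-error likelihood is selected.
Comparing AICs across transformed scales would be invalid, hence the
shared natural-scale likelihood.  The selected model converts simulated
latent covers (observation noise is measurement artifact, not mass)
into per-temperature-bin biomass at the start and end of a projection,
and into relative (%) and area-weighted total (t) change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulate import TrajectoryEnsemble
from .trend import FittingError, TemperatureBins

__all__ = ["BiomassModel", "fit_biomass_model", "biomass_change",
           "FAMILIES"]

FAMILIES = ("linear", "power", "exponential")


def _linear(x, a, b):
    return a + b * x


def _power(x, a, b):
    return a * np.power(np.maximum(x, 1e-12), b)


def _exponential(x, a, b):
    return a * np.exp(b * x)


_FORMS = {"linear": _linear, "power": _power, "exponential": _exponential}


@dataclass
class BiomassModel:
    """Selected cover→AGB mapping with per-family AIC bookkeeping."""

    family: str
    coefficients: tuple
    aic: dict
    region: str = ""
    n_fit: int = 0

    def __call__(self, cover):
        return np.maximum(_FORMS[self.family](
            np.asarray(cover, dtype=float), *self.coefficients), 0.0)


def _gaussian_aic(y, yhat, n_params: int) -> float:
    n = y.size
    rss = float(np.sum((y - yhat) ** 2))
    # +1 parameter for the error variance; common across families
    return n * np.log(max(rss, 1e-300) / n) + 2 * (n_params + 1)


def _initial_guess(family, x, y):
    if family == "linear":
        return None
    pos = (y > 0) & (x > 0)
    if pos.sum() < 2:
        return (max(np.mean(y), 1e-3), 0.01)
    ly = np.log(y[pos])
    if family == "exponential":
        b, la = np.polyfit(x[pos], ly, 1)
    else:
        b, la = np.polyfit(np.log(x[pos]), ly, 1)
    return (float(np.exp(la)), float(b))


def fit_biomass_model(cover, agb, families=FAMILIES, region: str = "") -> BiomassModel:
    """Fit candidate families and select the lowest-AIC one.

    Requires ≥ 10 pairs spanning ≥ 30 cover-%.  Linear is solved
    directly; power and exponential are log-linearized for starting
    values and refined by nonlinear least squares on the natural scale.
    Families that fail to converge are excluded with a warning.
    """
    x = np.asarray(cover, dtype=float)
    y = np.asarray(agb, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise FittingError(f"need >= 10 calibration pairs, got {x.size}")
    if x.max() - x.min() < 30.0:
        raise FittingError(
            f"cover span {x.max() - x.min():.1f}% < required 30%")

    fits, aics = {}, {}
    for fam in families:
        try:
            if fam == "linear":
                b, a = np.polyfit(x, y, 1)
                coef = (float(a), float(b))
            else:
                p0 = _initial_guess(fam, x, y)
                coef, _ = curve_fit(_FORMS[fam], x, y, p0=p0, maxfev=10_000)
                coef = tuple(float(c) for c in coef)
            aics[fam] = _gaussian_aic(y, _FORMS[fam](x, *coef), len(coef))
            fits[fam] = coef
        except (RuntimeError, TypeError, np.linalg.LinAlgError) as e:
            warnings.warn(f"family {fam!r} failed to converge: {e}",
                          stacklevel=2)
    if not fits:
        raise FittingError("no candidate biomass family converged")
    best = min(aics, key=aics.get)
    return BiomassModel(family=best, coefficients=fits[best], aic=aics,
                        region=region, n_fit=x.size)


def biomass_change(ens: TrajectoryEnsemble, model: BiomassModel,
                   areas: dict, start_offset: int = 0,
                   end_offset: int | None = None) -> pd.DataFrame:
    """Per-temperature-bin biomass change between two snapshots.

    Plots are grouped by their temperature bin at the start of the
    projection.  ``areas`` maps bin index → represented area (ha).
    Columns: bin, area_ha, agb_start / agb_end (t ha⁻¹ means over
    latent covers), relative_change_pct and total_change_t
    (= Δmean × area); the last row aggregates the grand total, whose
    relative change is start-mass-weighted.
    """
    if end_offset is None:
        end_offset = int(ens.snapshot_years[-1])
    x0 = ens.snapshot(start_offset, "latent")
    x1 = ens.snapshot(end_offset, "latent")
    b0 = ens.bin_path[:, 0]
    rows = []
    for bi in np.unique(b0):
        if bi not in areas:
            raise KeyError(f"no area provided for temperature bin {bi}")
        sel = b0 == bi
        m0 = float(np.mean(model(x0[sel])))
        m1 = float(np.mean(model(x1[sel])))
        area = float(areas[bi])
        rows.append({
            "bin": int(bi), "n_plots": int(sel.sum()), "area_ha": area,
            "agb_start": m0, "agb_end": m1,
            "relative_change_pct": (m1 - m0) / m0 * 100.0 if m0 > 0 else np.nan,
            "total_change_t": (m1 - m0) * area,
        })
    table = pd.DataFrame(rows)
    start_mass = float((table["agb_start"] * table["area_ha"]).sum())
    total = float(table["total_change_t"].sum())
    grand = {
        "bin": -1, "n_plots": int(table["n_plots"].sum()),
        "area_ha": float(table["area_ha"].sum()),
        "agb_start": np.nan, "agb_end": np.nan,
        "relative_change_pct":
            total / start_mass * 100.0 if start_mass > 0 else np.nan,
        "total_change_t": total,
    }
    return pd.concat([table, pd.DataFrame([grand])], ignore_index=True)
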