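"""End-to-end pipeline: synthesize → trend → noise → project → analyze → biomass.

Configuration is a plain mapping (usually loaded from YAML).  Every
stochastic stage requires its own named seed — validated before any
computation — and a machine-readable run manifest (config hash, seeds,
package versions, outputs) is written alongside the result tables so a
run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as osio
from .biomass import biomass_change, fit_biomass_model
from .noise import build_lag_sd, fit_noise_models, fit_sqrt_lag
from .panel import Panel
from .simulate import (SimulationConfig, add_observation_noise,
                       select_initial, simulate_ensemble)
from .states import density, find_equilibria, windowed_densities
from .synthetic import GroundTruthModel, SyntheticConfig, generate_panel
from .trend import TemperatureBins, fit_change_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

_STOCHASTIC_STAGES = ("synthesize", "simulate", "observation")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see load_config for the YAML shape)."""

    out_dir: str
    seeds: dict
    panel_path: str | None = None
    synthesize: dict | None = None
    bins: dict = field(default_factory=dict)
    strata_keys: tuple = ()
    trend: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    warming: dict | str | None = None
    calibration_path: str | None = None
    area_per_bin_ha: float = 1.0

    def __post_init__(self):
        if self.panel_path is None and self.synthesize is None:
            raise ValueError("config needs either panel_path or synthesize")
        needed = ["simulate", "observation"]
        if self.synthesize is not None:
            needed.append("synthesize")
        missing = [s for s in needed if s not in (self.seeds or {})]
        if missing:
            raise ValueError(f"missing seeds for stochastic stages: {missing}")
        for path in (self.panel_path, self.calibration_path):
            if path is not None and not os.path.exists(path):
                raise ValueError(f"input path does not exist: {path}")
        if isinstance(self.warming, str) and not os.path.exists(self.warming):
            raise ValueError(f"warming path does not exist: {self.warming}")


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    raw["strata_keys"] = tuple(raw.get("strata_keys", ()))
    return PipelineConfig(**raw)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage, writing intermediate tables and a manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs = []

    def emit(name, writer, *args):
        path = os.path.join(cfg.out_dir, name)
        writer(*args, path)
        outputs.append(name)
        return path

    bins = TemperatureBins(**cfg.bins)

    # -- input panel -------------------------------------------------------
    try:
        if cfg.synthesize is not None:
            syn = dict(cfg.synthesize)
            truth = GroundTruthModel(**syn.pop("truth"))
            scfg = SyntheticConfig(seed=cfg.seeds["synthesize"], **syn)
            panel = generate_panel(truth, scfg)
            emit("panel.csv", osio.write_panel, panel)
        else:
            panel = osio.read_panel(cfg.panel_path)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("synthesize/read_panel", e) from e

    # -- deterministic part ------------------------------------------------
    try:
        models = fit_change_model(panel, bins, strata_keys=cfg.strata_keys,
                                  **cfg.trend)
        osio.write_change_models(models, os.path.join(cfg.out_dir, "models"))
        outputs.append("models/")
    except Exception as e:
        raise PipelineError("trend", e) from e

    # -- noise separation --------------------------------------------------
    try:
        lag_table = build_lag_sd(panel, **cfg.noise)
        coeffs = fit_sqrt_lag(lag_table)
        noise_model = fit_noise_models(coeffs)
        emit("lag_sd.csv", osio.write_table, lag_table)
        emit("noise_coefficients.csv", osio.write_table, coeffs)
    except Exception as e:
        raise PipelineError("noise", e) from e

    # -- projection --------------------------------------------------------
    try:
        sim_cfg = SimulationConfig(seed=cfg.seeds["simulate"], **cfg.simulate)
        warming = None
        if isinstance(cfg.warming, str):
            traj = osio.read_warming(cfg.warming)
            warming = traj.to_numpy() - traj.iloc[0]
        elif isinstance(cfg.warming, dict):
            warming = cfg.warming["rate"] * np.arange(sim_cfg.n_years + 1)
        x0, mat0 = select_initial(panel, bins, sim_cfg)
        ens = simulate_ensemble(x0, mat0, models, noise_model, bins, sim_cfg,
                                warming=warming)
        add_observation_noise(ens, noise_model, cfg.seeds["observation"])
        snap = pd.DataFrame({
            "plot": np.repeat(np.arange(ens.n_plots), ens.snapshot_years.size),
            "year": np.tile(panel.years[0] + ens.snapshot_years, ens.n_plots),
            "latent": ens.latent.ravel(),
            "observed": ens.observed.ravel(),
        })
        emit("trajectories.csv", osio.write_table, snap)
    except Exception as e:
        raise PipelineError("simulate", e) from e

    # -- state analysis ----------------------------------------------------
    try:
        eq_rows = []
        for (b, key), model in models.items():
            eq = find_equilibria(model, key=(b,) + key)
            for root, stab in zip(eq.roots, eq.stability):
                eq_rows.append({"bin": b, "strata": "/".join(key),
                                "root": root, "stability": stab})
        equilibria = pd.DataFrame(eq_rows)
        emit("equilibria.csv", osio.write_table, equilibria)

        final = ens.snapshot(int(ens.snapshot_years[-1]), "observed")
        final_density = density(final, window="final")
        dens_df = pd.DataFrame({"cover": final_density.grid,
                                "density": final_density.density})
        emit("final_density.csv", osio.write_table, dens_df)

        wins = [(int(panel.years[0]), int(panel.years[-1]))] \
            if len(panel.years) < 6 else None
        observed_windows = windowed_densities(panel, windows=wins or
                                              _windows_for(panel.years))
        wd = pd.concat([pd.DataFrame({"cover": d.grid, "density": d.density,
                                      "window": d.window})
                        for d in observed_windows], ignore_index=True)
        emit("windowed_densities.csv", osio.write_table, wd)
    except Exception as e:
        raise PipelineError("analyze", e) from e

    # -- biomass -----------------------------------------------------------
    biomass_table = None
    if cfg.calibration_path is not None:
        try:
            calib = osio.read_table(cfg.calibration_path)
            bm = fit_biomass_model(calib["cover"], calib["agb"])
            areas = {int(b): cfg.area_per_bin_ha
                     for b in np.unique(ens.bin_path[:, 0])}
            biomass_table = biomass_change(ens, bm, areas)
            emit("biomass_change.csv", osio.write_table, biomass_table)
        except Exception as e:
            raise PipelineError("biomass", e) from e

    manifest = {
        "config_hash": _config_hash(cfg),
        "config": asdict(cfg),
        "seeds": cfg.seeds,
        "versions": _versions(),
        "outputs": outputs,
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {"panel": panel, "models": models, "noise": noise_model,
            "ensemble": ens, "equilibria": equilibria,
            "final_density": final_density, "biomass": biomass_table,
            "manifest": manifest}


def _windows_for(years) -> tuple:
    """Split the observed span into up to four 5–6 year windows."""
    y0, y1 = int(years[0]), int(years[-1])
    n_win = max(1, min(4, (y1 - y0 + 1) // 5))
    edges = np.linspace(y0, y1 + 1, n_win + 1).astype(int)
    return tuple((int(edges[i]), int(edges[i + 1] - 1)) for i in range(n_win))


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"openstate": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
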