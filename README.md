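# openstate

Langevin reconstruction and projection of boreal tree-cover dynamics.

Boreal tree cover at a given site is well described as a noisy dynamical
system: a deterministic tendency to grow toward (or decay away from) a
temperature-dependent equilibrium cover, plus year-to-year stochastic
variation, observed through a satellite sensor that adds its own
measurement error.  `openstate` estimates that system from panels of
short (~21-point) annual tree-cover series and projects it forward:

    dX = f(X) dt + g(X) dW          (cover dynamics, Langevin form)
    X̂  = X + h(X)·B                 (observation model, B ~ N(0,1))

where X is tree cover (% of a 6.25 ha pixel), f is the drift (expected
annual change, % y⁻¹), g the process-noise amplitude (% · y^(−1/2)) and
h the observation-noise SD (%).  The workflow, aimed at ecosystem
modellers working with remote-sensing cover panels:

1. **Trend** — per-plot annual change by the Theil–Sen estimator
   (median of all pairwise slopes, robust to observation noise), then a
   penalized cubic regression spline of change against initial cover
   per 0.5 °C mean-annual-temperature bin: the estimate of f.  Zero
   crossings of f are cover equilibria (stable where f′ < 0).
2. **Noise separation** — for 1 %-wide cover groups, the SD of cover
   Δt = 1…10 years later is regressed on √Δt: the slope is process
   noise (diffusion grows like √Δt), the intercept observation noise
   (lag-independent).  Smoothing the per-group coefficients over cover
   gives g(X) and h(X).
3. **Projection** — Euler–Maruyama ensembles (Δt = 0.1 y) from the
   initial cover distribution to 2100, each plot using its current
   temperature bin's drift; warming trajectories switch bins once per
   simulated year (warmest fitted bin beyond the fitted range).
   Observation noise is superimposed on stored snapshots only.
4. **State analysis** — reflected-kernel densities of cover, mode
   detection, windowed density shifts, equilibrium tables.
5. **Biomass** — cover→aboveground-biomass model chosen by AIC among
   linear / power / exponential families; projected cover change
   aggregated to relative and total biomass change per temperature bin.

A synthetic-landscape module generates panels from known ground truth
(logistic, weak/strong Allee or custom drifts), so every stage is
validated against dynamics whose equilibria and noise levels are exact.

## Worked example

```python
import openstate as osx

# 1. synthetic panel: 5,000 plots, 21 annual observations, logistic truth
truth = osx.GroundTruthModel("logistic", {"r": 0.3, "K": 60.0},
                             process_noise=2.0, obs_noise=2.0)
cfg = osx.SyntheticConfig(n_plots=5000, years=21, seed=42,
                          mat_range=(-2.0, -1.6))
panel = osx.generate_panel(truth, cfg)

# 2. deterministic part: Theil-Sen change vs initial cover, per 0.5 degC bin
bins = osx.TemperatureBins()
models = osx.fit_change_model(panel, bins)
(_, model), = models.items()
eq = osx.find_equilibria(model)
for root, stab in zip(eq.roots, eq.stability):
    print(f"equilibrium at {root:5.1f}% cover ({stab})")

# 3. noise separation: sd(lag) = a + b*sqrt(lag) per 1% cover group
noise = osx.fit_noise_models(osx.fit_sqrt_lag(osx.build_lag_sd(panel)))
print(f"process noise g(50)     = {noise.process(50.0):.2f} % / sqrt(yr)")
print(f"observation noise h(50) = {noise.observation(50.0):.2f} %")

# 4. project 99 years forward and locate the year-2100 mode
sim = osx.SimulationConfig(n_steps=990, seed=7, n_samples=4000, record_every=99)
x0, mat0 = osx.select_initial(panel, bins, sim)
ens = osx.simulate_ensemble(x0, mat0, models, noise, bins, sim)
osx.add_observation_noise(ens, noise, seed=8)
d = osx.density(ens.snapshot(99, "observed"))
print(f"year-2100 density mode  = {d.modes()[0]:.1f}% cover")
```

Output:

```
equilibrium at  59.7% cover (stable)
process noise g(50)     = 0.02 % / sqrt(yr)
observation noise h(50) = 3.31 %
year-2100 density mode  = 60.0% cover
```

The drift fit recovers the true carrying cover K = 60 to within a
fraction of a percent, and the century-long projection concentrates the
ensemble at that attractor.  The noise split illustrates a real
limitation of the two-step lag-SD method: this panel sits mostly near
its attractor, where mean reversion absorbs the √Δt growth of the SD,
so the recovered process noise is biased toward zero while the
intercept absorbs the combined spread (true g = 2, h = 2; see
`docs/methods.md` for the bias analysis).

There is also a CLI mirroring the stages (`openstate synthesize | trend
| noise | simulate | analyze | biomass | run`); `openstate run --config
examples/pipeline.yaml` executes the whole pipeline on the shipped
fixture panel and writes every intermediate table plus a reproducibility
manifest.

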