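# Methods

## Model

Tree cover X(t) of a plot (percent of a 250 m × 250 m pixel) is modelled
as a one-dimensional Langevin system,

    dX = f(X) dt + g(X) dW,

with drift f (% y⁻¹), diffusion amplitude g (% · y^(−1/2)) and Wiener
increments dW, observed through

    X̂_t = X_t + h(X_t) · B_t,     B_t ~ N(0, 1) i.i.d.,

where h is the observation-noise SD of the satellite cover product.
The environment is held quasi-fixed by estimating f independently per
0.5 °C mean-annual-temperature (MAT) bin — by default 40 half-open bins
on [−14 °C, 6 °C), the span of the boreal biome; MATs outside the range
map to the edge bins — and optionally per categorical stratum (region,
fire, management).  g and h are treated as temperature-independent
(one pair per stratum): their cover profiles vary little across bins,
and pooling across temperature stabilizes the lag-SD estimates.

Assumptions worth keeping in mind: plots are independent (no spatial
interaction); the drift is autonomous within a bin (climate enters only
through bin membership); noise is Gaussian and state-dependent only
through cover; cover is confined to [0, 100] by clipping after every
step (the boundary is treated as sticky-reflecting; a true reflecting
boundary is available via `SimulationConfig(boundary="reflect")`).

## Estimating the drift

Each plot's annual change rate is the Theil–Sen estimator: the median
of all pairwise slopes of its annual series.  Pairs with zero year
difference are dropped; missing years are skipped; fewer than two
usable observations is an error.  The estimator's insensitivity to
outliers is what makes the short, noisy series usable at all.

Within each (bin, stratum) group with at least `min_group` plots
(default 50; below this spline fits destabilize), change rate is
regressed on first-year cover with a penalized cubic regression spline.
Regressing on the first year only — rather than pooling all start
years — keeps the response and predictor causally ordered over the full
window; pooled start years are available via `pool_start_years=True`.

### Smoother contract

The smoother is a P-spline: a cubic B-spline basis on equidistant
knots extended past the data support, a second-order difference penalty
on the coefficients, and penalty weight chosen by minimizing the GCV
score n·RSS/(n − edf)² over a log-spaced grid with bounded local
refinement.  Because the knots are equidistant, straight lines lie in
the penalty null space and are reproduced to machine precision at any
penalty — a property the test suite checks at 1e-6 — and the fit is a
small (k × k) linear solve, fast at any sample size.

The basis dimension defaults to k = 20.  With k = 10 the knot spacing
(~14 cover-%) cannot track drifts with strong cubic curvature: on
strong-Allee validation data the upper attractor is recovered ~3.6
cover-% too high purely from basis bias, while k = 20 recovers it
within 0.5 %.  GCV still selects the penalty, so the extra basis
freedom does not overfit gentler drifts (logistic, linear and constant
cases are unchanged).  One independent cross-check test compares the
smoother against R mgcv's GCV-selected cubic regression spline on a
common sample.

Outside the fitted cover support the smooth continues linearly from the
boundary value and slope.  This matters under warming: plots switch
into bins whose models were fitted on different cover ranges, and a
defined, monotone extrapolation avoids polynomial blow-up.

## Separating process from observation noise

For every 1 %-wide cover group (values rounded to the nearest percent —
the natural reading for an integer-valued cover product), pooled over
all plot-year occurrences, the package computes the population SD of
cover Δt = 1…10 years later, keeping (group, lag) cells with at least
30 occurrences.  Per group, OLS of SD on √Δt gives an intercept a
(observation noise) and slope b (process noise); negative estimates are
clipped to zero and flagged, with the raw values retained.  Smoothing a
and b over cover with the same spline contract yields h(X) and g(X),
clipped at zero.

Two biases of this two-step procedure are worth documenting rather than
hiding:

* **Quadrature bias.**  Grouping is necessarily on *observed* cover.
  The latent cover within an observed-cover group therefore has spread
  ≈ h, and the lagged SD follows σ(Δt) ≈ sqrt(2h² + g²Δt) — variance
  components add in quadrature, not linearly.  Fitting the additive
  form a + b√Δt to that curve overstates a and understates b as h/g
  grows: for g = 1, h = 2 the closed-form OLS values are a ≈ 2.33,
  b ≈ 0.59, and simulation reproduces them.  With h = 0 the additive
  form is exact and g is recovered without bias (a test asserts the
  intercept is then centred at 0 within ±0.2 %).  The additive
  regression is kept because it is this method's defining contract; the
  recovered a and b should be read as an upper bound on observation
  noise and a lower bound on process noise when both are present.
* **Drift contamination.**  No drift correction is applied to the SDs.
  Near a strong attractor, mean reversion caps the growth of the
  lagged SD, biasing b further toward zero.  The effect is visible in
  panels concentrated at their equilibrium (see the README example) and
  negligible for near-neutral dynamics.

## Forward projection

Ensembles are integrated with Euler–Maruyama at Δt = 0.1 y, each plot
using the drift of its current temperature bin, with covers clipped to
[0, 100] per step.  Drift and g are evaluated by linear interpolation
on a 0.1 % cover grid precomputed per bin — bit-equivalent to direct
spline evaluation to within interpolation error far below the noise
scale, and what makes 80,000-plot ensembles cheap.  The default
horizon is 990 steps (99 simulated years from 2000); the step count is
configurable, and the 1000-step variant reaches 2100 exactly.  The
default ensemble draws 2,000 initial plots per fitted bin (80,000 for
the full 40-bin design).

Warming enters as an annual MAT trajectory (global offsets or per-plot
absolute values).  Bins are re-resolved once per simulated year —
warming inputs are annual, so finer switching would be spurious —
and plots warming past the warmest fitted bin use that bin's model
(symmetrically the coldest below).  A missing *interior* bin is an
error naming the bin, never silently bridged.

Observation noise h(X)·B is added to stored snapshots only and never
fed back into the dynamics: it is a measurement artifact, not mass or
growth, and exists so simulated distributions are comparable with the
observed (noisy) panels.

## State analysis

Equilibria are zero crossings of the fitted drift located by bisection
to 1e-4 cover-% on a 0.1 % scan grid, classified stable/unstable by the
local slope; tangential (non-crossing) zeros are reported separately.
Cover densities are Gaussian KDEs with Silverman bandwidth and boundary
reflection at 0 and 100, normalized to integrate to one (checked at
1e-6).  Modes are KDE local maxima with prominence at least 5 % of the
peak — enough to suppress sampling ripples without hiding genuine
secondary modes.  Windowed densities pool all plot-year values per
calendar window, defaulting to the four 5–6-year periods
2000–04 / 2005–09 / 2010–14 / 2015–20.

## Biomass

Calibration pairs (cover %, AGB t ha⁻¹) are fit with linear, power
(α·xᵝ) and exponential (α·e^{βx}) candidates — log-linearized starting
values, nonlinear least squares on the natural scale — and the family
with the lowest AIC under a common Gaussian-error likelihood is
selected.  Keeping every family on the natural scale is essential:
AICs computed on different transformed responses are not comparable.
Projected biomass change uses *latent* covers, grouped by each plot's
temperature bin at the start of the projection, with per-bin mean AGB
at the start and end snapshots, relative change (%), and total change
(Δmean × area, t); the grand total is exactly the sum of per-bin
totals.

## Synthetic landscapes

The generator emulates the observable features of a satellite cover
panel: 21 annual values per plot, a MAT drawn per plot, latent dynamics
from a configurable drift (logistic, weak Allee with the saturating
factor x/(x+A), strong Allee, or custom) integrated at a 0.1 y substep,
state-dependent process noise, and superimposed state-dependent
observation noise, everything clipped to [0, 100] and bit-reproducible
from one seed.  An optional linear parameter gradient over MAT (e.g. K
rising with temperature) produces the cold-sparse / warm-dense pattern
of real panels, and categorical strata with parameter overrides exercise
the grouped-fitting paths.

Validation panels use one shared parameter set — r = 0.3, K = 60,
g ≡ 2, plus A = 20 for the Allee variants — so only the drift form
varies across the recovery tests.  What the generator does *not*
emulate, and what passing tests therefore do not certify: spatial
autocorrelation between plots, non-Gaussian or temporally correlated
sensor error, integer quantization of the cover product, fire/management
regimes with their own dynamics, and any real geographic sampling.  A
subtlety of clipped boundaries: an attractor at 0 with additive noise g
and local relaxation rate r is displaced upward by ≈ g·√(2/π)/√(2r)
(half-normal hovering), so boundary-attractor recovery is only as sharp
as that physical displacement.

## Numerical choices and limitations

* GCV penalty search: log₁₀λ ∈ [−6, 10], 33-point grid plus bounded
  refinement; fits are deterministic given the data.
* Theil–Sen ties: identical-year pairs are excluded (undefined slope);
  even pair counts use the ordinary median (midpoint of the central
  two).
* Duplicating a panel verbatim shifts the GCV optimum by O(edf/n), so
  fitted smooths are only near-invariant to duplication (exact
  invariance holds for plot reordering).
* Problem sizes in tests and in the acceptance script — 20,000-plot
  recovery panels, 5,000-plot noise panels, 4,000–10,000-plot
  ensembles, 100 biomass replicates — were chosen as the smallest sizes
  at which the Monte-Carlo spread is comfortably inside each stated
  tolerance.
* The pipeline writes every intermediate table as CSV plus a manifest
  (config hash, per-stage seeds, package versions); a run is
  reproducible bit-for-bit from the manifest.
* All tabular interchange is plain CSV; no raster, GIS or NetCDF
  handling is in scope.
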