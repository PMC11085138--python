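# Methods

This note records the models behind phycobatch, the defaults that matter,
and the choices made where the design was genuinely open.  Nothing here
states a number the test suite or `scripts/acceptance.py` does not itself
compute.

## Sensor correction

In-tube turbidity sensors saturate: the apparent OD falls progressively
below the true (spectrophotometer) OD as density rises.  We model the
ratio of the two signals as `OD_ref/OD_sensor = a·exp(b·OD_sensor)`.
Taking logs makes the model exactly linear in `(od_sensor, ln ratio)`, so
`fit_calibration` is ordinary least squares in that space — deterministic,
with no starting-value sensitivity — and `a = exp(intercept)` is positive
by construction.  `b` is unconstrained in sign.  Pairs with sensor OD
below 0.01 (configurable) are excluded because the ratio amplifies noise
near zero.  R² is reported in the linearised space.

Whether the original procedure fitted in ratio space or by direct
nonlinear least squares is not documented anywhere we can rely on; the
linearised fit is this package's choice.  Inversion (needed by the
simulator to emit sensor-space logs) uses the principal Lambert-W branch,
`x = W₀(b·y/a)/b`, which is exact for `y ≥ 0, b > 0`; a bisection oracle
confirms it to 1e-9 in the tests.  One calibration per species/condition
is the intended use; `compare_phase_fits` exposes per-phase fitting with a
contrast on (a, b) for checking that a pooled model is adequate.

## Growth-curve model and estimators

**Segmentation.**  The exponential window is the longest window that
starts after `lag_skip` (default 2 h), spans at least `min_exp_hours`
(default 5 h), and keeps the R² of a log-OD line fit at or above
`r2_threshold` (default 0.9995); ties are broken by higher R², then
earlier start.  The deceleration phase runs from the window's end to the
end of the series.

The R² threshold is the single most consequential default and was
calibrated on the package's own simulator: light limitation sets in
smoothly, so log-curvature accumulates gradually, and a lax threshold
(e.g. 0.995) lets the "exponential" window stretch ~10 h past the
shading onset, under-estimating µ by ~12% at a generating rate of
0.15 h⁻¹.  At 0.9995 the selected window (≈2–21 h under default
conditions) matches the classically reported log-linear region of such
curves (from ~5 h to 20–30 h), and µ is recovered within 5% across seeds
at 1% sensor noise.  A consequence worth knowing: with smooth light
limitation the window end still trails the strict "rate fell below 95% of
initial" onset by several hours at any noise-compatible threshold; µ from
the window is therefore biased slightly low (~4% under defaults), which
is inherent to slope-on-a-window estimation, not to the implementation.

**µ and doubling time.**  µ is the OLS slope of ln OD vs time on the
window; doubling time is ln 2/µ.  Non-positive OD inside the window is a
domain error (no clipping, no baseline subtraction).

**V_max.**  A window of `vmax_window_hours` slides across the
deceleration phase; the steepest OLS slope of OD vs time, times 24·k,
is V_max in g L⁻¹ day⁻¹ — a deterministic surrogate for visually picking
"the linear part".  The default window is 12 h: with 1% multiplicative
sensor noise a 6 h window takes the maximum over many noisy slopes and
inflates V_max by 10–16%, while 12 h reproduces the noiseless value
within ~5% and is still short against the 40+ h deceleration phases the
defaults produce.  All rates are computed in hours; the per-day factor
enters only at reporting.

**Pipeline convention.**  Replicate channels are corrected individually
and averaged before segmentation and estimation, matching the practice of
reporting means of three culture replicates; per-replicate estimation at
1% noise occasionally finds no window that clears the R² criterion.

## Yields

The endpoint method, `(X_final − X_initial)/S₀`, assumes the substrate is
exhausted when growth stops; if a measured residual above 5% of S₀ is
supplied, the estimator warns rather than errors.  The consumption method
regresses cumulative biomass increments on cumulative substrate consumed
through the origin (the mass-balance line passes through (0,0) by
definition), interpolating the substrate series to the biomass grid when
needed; R² is reported against the through-origin line.  In the pipeline
and acceptance runs the endpoint biomass is the replicate-mean corrected
OD averaged over the final 4 h (9 samples), which suppresses the
noise amplification of the sensor correction at high OD.

## Pigment statistics

Contents are % of dry weight.  `reference_percentage` expresses a
heterotrophic content as a percentage of the photoautotrophic
deceleration-phase reference — the across-intensity average of
per-intensity replicate means, over whichever intensities are present
(the set is recorded in reports).  Contrasts are two-sided two-sample
t-tests at a per-comparison α = 0.05 with no multiple-testing correction
by default (a Benjamini–Hochberg option exists).  The pooled-variance
test is the default rather than Welch: at n = 3 per group the Welch
approximation's true level is ≈0.035 at nominal 0.05 (measured by
simulation), which breaks type-I calibration, while the pooled test is
exact under normal equal-variance replicates — precisely the regime the
replicate generator produces.  Welch remains available
(`equal_var=False`) for genuinely heteroscedastic groups.

## Simulator

**Photoautotrophic.**  One-sided illumination of a culture of depth L
(default 0.03 m); Beer–Lambert attenuation with biomass attenuation
coefficient σ (default 100 m⁻¹ per g L⁻¹, i.e. 0.1 m² g⁻¹ — a typical
low-pigment value); local growth follows a saturating (Monod-form)
response in irradiance with K_I = 150 µmol m⁻² s⁻¹ (≈73% saturation at
400 µmol m⁻² s⁻¹, consistent with photosynthetic light curves of green
microalgae).  The depth-averaged rate has the closed form

```
µ̄(X) = µ_max/(σXL) · ln[(K_I + I0)/(K_I + I0·e^(−σXL))]
```

verified against 1000-point quadrature to 1e-8.  dX/dt = (µ̄ − m)·X with
maintenance m = 0.002 h⁻¹, integrated adaptively (relative tolerance
1e-10) with output on the fixed 0.5 h grid.  Ground truths exposed:
initial specific rate, light-limitation onset (first time µ̄ drops below
95% of its initial value), peak volumetric productivity.

**Heterotrophic.**  Monod kinetics in substrate with yield-coupled
drawdown; with zero dark decay the trajectory conserves
X − X₀ = Y·(S₀ − S) to integrator precision.  The optional dark-decay
factor `exp(−r·max(0, t − t_onset))` slows growth in darkness after
~50 h unless weak light is flagged — a phenomenological stand-in for the
observed weak-light growth effect, not a mechanistic claim.  Under the
`weak_light_glucose` preset the six-day endpoint densities are ≈0.39
(weak light) vs ≈0.15 g L⁻¹ (darkness), reproducing the reported
more-than-doubling.

**Observation model.**  Corrected OD is X/k (k default 0.40 g L⁻¹ per OD
unit); sensor OD is the exact inverse of the correction model;
multiplicative Gaussian noise (default 1% relative) is applied per
replicate (default n = 3) in sensor space, where the physical noise
arises.  Substrate replicates get their own noise streams.  All
randomness flows from one seed through `numpy` seed-sequence substreams,
so identical seeds give byte-identical outputs.

**Presets.**  `data/presets.yaml` holds the default study conditions and
scenario anchors: initial specific rate 0.15 h⁻¹ (fast strain near its
optimum intensity, I0 = 500), peak productivity 1.8 g L⁻¹ day⁻¹ (high
light, I0 = 700), yields 0.55 (glucose), 0.32 (acetate endpoint), 0.30
(acetate consumption), substrate loadings 15 and 2 g L⁻¹.  µ_max is
resolved from each anchor at load time (closed form for the rate anchor,
bisection on the noiseless simulator for the productivity anchor), so
generating ground truths equal the anchors exactly.  These are
calibration anchors chosen to land at the magnitudes printed for the
corresponding published experiments — not measurements.

**Pigment generator.**  Cell means are multiplicative:
base × acclimation(I) × phase × substrate × weak-light × suppression,
with `acclim(I) = c_min + (c_max − c_min)·K_A/(K_A + I)` (strictly
decreasing in irradiance).  Heterotrophic cells are anchored to the
photoautotrophic deceleration reference so a suppression factor of 0.23
yields a 23% reference percentage by construction.  Photoacclimation is
generated statically per phase (no lagged dynamics) — sufficient for
testing the statistics stage, and a known simplification.

## What passing tests do and do not show

The simulator reproduces the phenomenology the estimators assume —
smooth exponential-to-deceleration transition, Beer–Lambert shading,
stoichiometric substrate coupling, multiplicative sensor noise.  Real
cultures additionally show lag phases, CO₂/pH excursions, adaptive
pigment dynamics that feed back on attenuation, acetate pH toxicity, and
non-Gaussian sensor artefacts (bubbles, fouling) — none of which are
generated, so recovery results here bound estimator behaviour only under
the stated model.  Problem sizes throughout (72–143 h at 0.5 h sampling,
n = 3, ≤1000-rep null calibrations) were chosen as the smallest that make
the recovery tolerances meaningful.

## Degenerate inputs and numerical conventions

Constant series raise a no-exponential-phase error reporting the best R²
found; R² is defined 0 for zero-variance responses.  OD ≤ 0 inside an
estimation window is an error, never clipped.  Identical zero-variance
contrast groups get p = 1 by convention and a degenerate flag.  Substrate
concentrations are clipped at 0 only on simulator output (integrator
round-off).  Yield estimates are floored at 0.  Sampling grids must be
uniform within 1%; time is always hours.
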