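# Methods

## Model overview

`thetaplace` implements a feedforward model of the entorhinal-cortex
(EC) to hippocampus pathway in which hippocampal cells acquire both
spatial tuning (place fields) and temporal tuning (theta phase
precession) from their inputs through synaptic plasticity, with no
built-in spatial or temporal selectivity of their own.  The three
ingredients are:

1. a virtual rat foraging in a 1 m × 1 m arena,
2. a generative population of MEC spatiotemporal grid cells (plus,
   optionally, weakly spatial EC cells), and
3. a bank of hippocampal model cells learning by non-negative sparse
   coding implemented with the locally competitive algorithm (LCA).

## Trajectory

Position follows dr/dt = v_t (cos θ_t, sin θ_t) with heading increments
θ drawn as a Wiener process scaled by the tortuosity σ_θ = 1 rad·s^-1/2
and speed v_t an Ornstein–Uhlenbeck process with long-term mean
v̄ = 0.30 m/s.  The step is 10 ms.  Within 2 cm of a wall, a heading
pointing into the wall is replaced by the parallel direction nearer the
current heading (ties break toward the arena centre); a step that would
still exit the arena redraws the heading increment (speed kept), capped
at 1000 attempts.

The OU speed process is not fully determined by the generative
equation; we use a relaxation time of 0.5 s and a stationary standard
deviation of 0.08 m/s, clipped at zero.  These give realistic speed
variability around 0.30 m/s without excursions that defeat the wall
logic; both are exposed on `TrajectoryParams`.

## MEC spatiotemporal grid cells

Each grid cell fires over a triangular lattice of circular fields.
Four modules with mean spacings 38.8, 48.4, 65 and 98.4 cm, mean
orientations 15°, 30°, 45° and 0°, and population shares 43.5%, 43.5%,
6.5% and 6.5% are used; per cell, spacing ~ N(mean, 8 cm) (negative
draws resampled), orientation ~ N(mean, 3°), offset ~ U[0, λ)², and
per-field amplitudes α_c ~ N(1, 0.1) (non-positive draws resampled).
The field radius is R = 0.32λ, so neighbouring fields of one cell can
never overlap (2R = 0.64λ < λ); the non-overlap is relied on when the
nearest lattice vertex is taken as "the" field at a query point.  Field
centres are enumerated over the arena expanded by R so edge fields
contribute partial in-arena responses.

Inside a field the rate is the product of a spatial envelope and a
theta-phase modulation,

    f(r, t) = f_s(r) · f_φ(r, t),
    f_s(r)  = α_c exp(−ln5 · ‖r − r_c‖² / R²)      (truncated at R),
    f_φ(r,t)= exp(k_φ (cos(2πFt − φ(r)) − 1)),

with theta frequency F = 10 Hz and modulation depth k_φ ~ U[0.8, 1.2].
The firing phase φ(r) decreases linearly with the projected distance in
the current running direction (pdcd): with û the heading, d = (r −
r_c)·û, c the perpendicular offset of the running line from the centre
and R′ = √(R² − c²) the half-chord,

    φ(r) = φ_0 − Δφ · (d + R′) / (2R′),

with φ_0, Δφ ~ U[300°, 340°].  Along any straight traversal φ is
exactly linear in pdcd (correlation −1), which is the temporal
structure the hippocampal cells can inherit.  The heading entering
φ(r) is the instantaneous trajectory heading; no smoothing is applied.

## EC weakly spatial cells

Each weakly spatial cell is a smoothed-noise rate map: i.i.d. U(0, 1)
values on a 100 × 100 lattice (1 cm resolution), Gaussian-smoothed with
σ = 6 cm (reflective boundary, so edges are not dimmed before
rescaling), affinely rescaled to [0, 0.1], and evaluated by bilinear
interpolation.  They carry spatial but no temporal information.

## Non-negative sparse coding (LCA)

Hippocampal model cells are leaky integrators,

    τ u̇ = −u + AᵀI − W s,    s = max(u − β, 0),   W = AᵀA − Id,

with τ = 10 ms, firing threshold β = 0.3, integrated by forward Euler
with dt = 0.2 ms (dt/τ = 0.02), 50 iterations per 10 ms trajectory
step.  After the 50 iterations of each step the dictionary is updated
once by ΔA = η (I − A s) sᵀ with η = 0.01, negative entries clipped and
the touched columns renormalised to unit norm (untouched columns
already have unit norm).  A is initialised U(0, 1) entrywise with
columns normalised.

Numerical choices:

- The membrane state carries over between trajectory steps within a
  session (reset only at session start): τ equals the trajectory step,
  so resetting each step would prevent settling.  This is the
  continuous-dynamics reading of the model; it is exposed as
  `carry_state` on `PlaceCellModel`.
- The lateral term W s is formed implicitly as Aᵀ(A s) − s, which is
  numerically identical to materialising W (tested to 1e−12) and avoids
  an O(n_inputs · n_cells²) product per step.
- s is recomputed from u inside every Euler step (synchronous update).
- The inner loops are numba-compiled; the per-step linear algebra goes
  through BLAS.

Grid inactivation (the MEC-lesion experiment) zeroes the grid-cell rows
of A, renormalises columns and disables learning.  A column left
entirely zero is reported as degenerate and kept at zero.

## Receptive-field recovery and fitting

Rate maps are the mean settled response per bin of a 40 × 40 lattice
(2.5 cm bins) along a held-out test trajectory, inference only.
Unvisited bins are flagged and excluded from fitting, never imputed.

Spatial fields are fitted with the same truncated-Gaussian bump as the
generator (free amplitude, centre, radius) and temporal traces with the
same phase-modulation form (free amplitude, k_φ, F, φ), both by
`scipy.optimize.least_squares`.  The fitting error is the ratio of the
summed squared residual to the summed squared data — the "squared norm
ratio" reading, which makes the two phrasings of the error (ratio of
summed squares vs square of the norm ratio) coincide.  Optimizer
starts: spatial — amplitude = map maximum, centre = argmax bin,
radius = 2 bins; temporal — amplitude = trace maximum, k_φ = 1,
F = 10 Hz, φ from the argmax sample time, with F bounded to [5, 20] Hz
and amplitudes/k_φ bounded below by 0.  A flat or all-zero trace is
flagged degenerate instead of fitted.

A cell is a **place cell** when (1) the fitted centre lies inside the
arena, (2) the fitted radius exceeds 5 cm, and (3) the fitting error is
below 40%.  The subset whose whole disc (centre ± R̂) lies inside the
arena is eligible for precession measurement.

## Measuring phase precession

The temporal response of a cell at a position r is probed by holding
the rat at r with a fixed heading while time advances at the 10 ms
cadence for 1 s, running LCA inference on the time-varying EC input.  A
0.1 s lead-in at negative times lets the network settle so that the
recorded trace starts at t = 0 and fitted phases are comparable across
positions.

For each eligible place cell a measurement trajectory starts at the
left edge of the fitted field at centre height heading east and evolves
by the same stochastic process (a straight variant suppresses the
noise).  At every 10 ms sample inside the fitted disc the 1 s trace is
fitted; the summary records fitted phase vs normalised pdcd (entry → 0,
exit → 1 along the current chord, computed against the *fitted* centre
and radius), the entry/exit phases (first/last valid fits, not
extrapolated to the boundary) and the Pearson correlation of
(pdcd, phase).  Correlation is computed on phases in degrees without
unwrapping; a series that crosses the 0°/360° boundary (a large
positive jump) is flagged `wrapped` and its correlation reported as
nan, since linear correlation is meaningless there.  Phase precession
spans less than a full cycle here, so wrapping is rare.

Because in-field membership uses the fitted disc while the measurement
trajectories are curved, entry/exit phases are compressed relative to
the idealised single-field values (entries near 270–310°, exits near
80–120°), exactly as in the model's own curved-traversal example;
straight passes through the field centre give entries near 300–340°
and exits near 0–60°.

## Scenarios and seeding

- Scenario 1: 900 grid cells → 100 hippocampal cells, 3600 s training.
- Scenario 2: 400 weakly spatial + 900 grid cells (input vector
  concatenates the weak block first), same training trajectory.
- Scenario 3: the trained scenario-2 dictionary with grid rows zeroed;
  no learning.  Place fields persist on the weak input alone, slightly
  enlarged and shifted.

Rate maps for all scenarios are recovered on a separate 1200 s test
trajectory.  A master seed spawns independent, stable streams
(`numpy.random.SeedSequence`) for the training trajectory, test
trajectory, grid population, weak population, dictionary and
measurement trajectories, so whole runs are bit-reproducible and any
stage can be re-seeded independently.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the model at desk scale,
chosen once as the largest sizes that keep a full three-scenario
recomputation interactive on one CPU:

- test suite: scenario 1 at 400 grid cells, 64 hippocampal cells,
  600 s training; scenarios 2/3 at 400 grid + 180 weak cells, 600 s
  training; both with the standard 1200 s test trajectory.
- acceptance script: all three scenarios with the full 100 hippocampal
  cells (so counts are out of 100) and 600 grid / 270 weak inputs
  (preserving the 400:900 weak:grid ratio), 2400 s training, 1200 s
  test.

At 600 s the dictionary is still converging and the place-cell fraction
is both lower and more seed-variable (roughly 58–78%) than after full
training; at 3600 s the scaled model reaches 97% (62/64), matching the
full-scale study.  Full-scale runs (900/400/100, 3600 s) are available
through `thetaplace run` or `ScenarioConfig` defaults and reproduce the
study's headline counts in distribution; exact printed counts are
seed-dependent.

## What the synthetic data does and does not emulate

All inputs are generated: the trajectory is a tortuous random walk with
no place preference, rest periods or behavioural structure; grid cells
have perfectly linear built-in precession, a common 10 Hz theta
frequency and no speed- or acceleration-dependent modulation; weakly
spatial maps are stationary smoothed noise.  Passing tests therefore
show that the learning model extracts spatiotemporal structure that is
present in its input with these idealisations — they do not show
robustness to biological variability (theta frequency drift, spiking
noise, non-stationary fields) that real recordings contain.

## Known limitations

- The model is rate-based; no spike generation or spike-phase
  statistics.
- No hippocampus→EC feedback, medial-septum input, or remapping
  experiments; the pathway is purely feedforward.
- Pearson correlation on phases in degrees is used throughout (no
  circular statistics); wrapped series are flagged rather than
  analysed.
- Headline counts (e.g., 94/100 place cells) are reproducible in
  distribution only; single runs vary by a few cells with the seed.
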