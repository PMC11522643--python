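# Methods

`swarmconvect` models the collective, buoyancy-driven motion of
enzyme-powered nanomotor swarms and re-implements the video-analysis
measurements used to characterise such swarms experimentally.  This note
records the governing models, the numerical choices, the shipped parameter
values and what they were chosen to achieve, and the limits of what the
synthetic pipeline can and cannot demonstrate.

## Side-view two-fluid model

A drop of enzymatically active particulate (volume density ρ) is released
at the bottom of a closed, fuel-filled 2D chamber (x horizontal and
periodic, z vertical with rigid walls).  The solvent obeys incompressible
Navier–Stokes dynamics with a vertical body force on particulate-laden
fluid,

    ρ₀ (∂t v + v·∇v) = η ∇²v − ∇p − ẑ ρ (gα − εc),

coupled to fuel transport with a second-order consumption reaction,

    ∂t c + ∇·(v c) = D_c ∇²c − γ ρ c,

and particulate transport with dispersion and gravitational settling,

    ∂t ρ + ∇·(v ρ) = (q ∇²ρ + αg ∂z ρ) / κ₁.

Here gα is the weight excess of the particulate-laden fluid (gravity ×
relative density contrast), εc the solutal lift from dissolved reaction
products (the reaction makes the suspending fluid lighter where fuel is
present), γ the reaction rate, D_c the fuel diffusivity, q the particulate
pressure factor (effective dispersion q/κ₁), and κ₁ the normalised drag
coefficient (settling speed gα/κ₁).  The physics is a competition: where
εc > gα the drop is lifted; the reaction consumes fuel where the
particulate sits, so dense drops starve themselves of lift and stall.

Incompressibility is not negotiable here — it is what determines the
pressure — so the momentum equation is integrated in
streamfunction–vorticity form (v = (∂z ψ, −∂x ψ), ∇²ψ = −ω), which
eliminates p exactly in 2D.  The particulate equation is integrated in
conservative flux form (advective flux vρ, Fickian flux −(q/κ₁)∇ρ,
settling flux −(gα/κ₁)ρ ẑ, zero total flux through the walls): this
conserves the discrete particulate mass to round-off and gives the αg term
its physical meaning of a settling drift, where the printed advective form
would leak mass at the walls.

### Discretisation

* Grid: Nx × Nz nodes, x periodic (spacing Lx/Nx), z including both walls
  (spacing Lz/(Nz−1)); finite-volume z-weights give wall nodes half cells
  so mass telescopes exactly.
* Poisson solve: FFT in x and a type-I discrete sine transform across the
  interior z nodes diagonalise the discrete 5-point Laplacian exactly, so
  ∇²ψ = −ω holds to round-off and the discrete divergence of the velocity
  (central differences of ψ) vanishes identically.
* Wall vorticity: Thom's first-order formula, ω_wall = −2ψ₁/Δz² (kept
  deliberately simple and isolated in `_wall_omega` so it can be swapped).
* Scalar advection: MUSCL reconstruction with the monotonized-central
  limiter, upwinded on the face velocity (settling drift folded into the
  face velocity), with central differencing for the diffusive fluxes.  On
  smooth fields the limiter reduces to second-order central slopes; at the
  drop edge and in sinking plumes, where the cell Péclet number is large,
  it keeps the scheme monotone.  Pure central fluxes were tried first and
  are unstable in the plume stage at the working resolutions.
* Vorticity transport: second-order central advection and diffusion (the
  viscosity is ample regularisation for ω).
* Time stepping: explicit Heun (RK2).  The step obeys a combined bound:
  diffusive (0.8/(2 D_max (Δx⁻² + Δz⁻²))), advective CFL 0.4, and an
  acceleration bound dt ≤ sqrt(0.4 Δz / a_max) with a_max the largest
  buoyant acceleration — the last matters in the first instants, when the
  flow accelerates from rest faster than a velocity-based CFL can see.
  By default dt is adaptive; a user-fixed dt is validated against the
  bound every step and the solver raises on violation or on any
  non-finite field, naming the field and time.
* Positivity: ρ and c are clipped at zero after each step and the removed
  mass is accumulated in `clipped_mass`; on the shipped scenarios it stays
  below 10⁻⁶ of the total.  Without clipping, negative densities would
  feed back into the buoyancy torque.

### Baseline parameter set

The equations are dimensionless; one length unit corresponds to 0.1 mm
(the 160 × 40 domain is the 16 × 4 mm field of view of the side-view
recordings) and a time unit to seconds-scale real time.  The published
description fixes the domain, grid and the swept ranges (ρ = 1…4,
c = 0.6…1.2, η = 0.6…1.2) but not the transport coefficients, so the
package ships a named baseline tuned to reproduce the qualitative regime
table at the working grid (256 × 64):

| parameter | value | role / why this value |
|---|---|---|
| η | 1.0 | solvent kinematic viscosity; centre of the swept range |
| ρ₀ | 1.0 | solvent density (sets the time scale) |
| ε (`buoy_eps`) | 1200 | product lift strength; sets ascent speed so the rich-fuel drop crosses the chamber within ~1.5 time units |
| gα (`g_alpha`) | 720 | particulate weight; the neutral fuel level gα/ε = 0.6 sits at the bottom of the swept fuel range, so c₀ = 0.6 settles, c₀ = 0.8 is marginal, c₀ ≥ 1.0 rises |
| γ | 1.2 | fuel consumption; fast enough that dense drops (ρ = 2–4) starve and stall, slow enough that the marginal c₀ = 0.8 drop still lifts measurably |
| D_c | 0.5 | fuel diffusivity; replenishes the drop's fuel on the σ = 4 blob scale over ~σ²/D_c ≈ 30 time units, i.e. slowly |
| κ₁ | 720 | drag normalisation; settling speed gα/κ₁ = 1 |
| q | 36 | particulate dispersion q/κ₁ = 0.05 |
| c₀ | 1.0 | default fuel level for parameter sweeps |
| drop | x = 80, z = 1, σ = 4, ρ_max = 1 | released *on the floor*: the wall shear slows the initial jolt, which is what lets fuel starvation outpace the (force ∝ ρ) early acceleration of dense drops |

### Observables

* `center_of_mass_height`: ∫zρ dA / ∫ρ dA with the finite-volume weights.
* `mean_upward_velocity`: (COM at its maximum − COM at release) divided by
  the time to that maximum.  The full upward excursion is averaged,
  including the late deceleration of stalling drops; a window that stops
  at 90% of the maximum was tried and rejected because it clips stalled
  runs down to their fast initial transient and destroys the monotone
  density response.  Returns 0 when the COM never rises one grid spacing.
* `classify_stages` labels each snapshot with a subset of {ascending,
  spreading, sinking, settled}: ascending = COM rising faster than 10⁻³
  domain heights per time; spreading = the circular x-spread of the top
  20% layer growing (computed from the resultant length of the mass
  distribution on the periodic circle, which is immune to wrap-around);
  sinking = net downward particulate flux through mid-height above 10⁻³
  of the total mass per unit time; settled = none of these with the COM
  in the bottom quartile.  All thresholds are keyword arguments.

## Height-averaged confined model

When the chamber height h is reduced, wall friction dominates and the
dynamics collapses onto the x–y plane.  The module integrates the
package's own height-averaged closure (isolated behind `confined_rhs` with
named coefficients so a different reduction can be transcribed in its
place; a run flags the closure in its log):

* Buoyant columns set a screened flow potential,
  (ℓ²∇² − 1) φ = −β ρ c, with β proportional to the reaction rate and
  ℓ the horizontal screening length of a recirculation cell (default 2).
* The in-plane particulate drift is friction-limited in both legs of the
  recirculation (vertical plume and horizontal return flow), giving a
  Darcy-type mobility ∝ ε² with ε ∝ h²:  u = M ε² ∇φ, M = 200.
* Particulate: ∂t ρ + ∇·(u ρ (1 − ρ/ρ_pack)) = D_ρ ∇²ρ − ν₄ ∇⁴ρ.  The
  packing factor (ρ_pack = 4) arrests aggregation at a finite spot
  density; the weak hyperdiffusion (ν₄ = 0.005) absorbs grid-scale
  spectral ringing without touching the pattern scale.
* Fuel: ∂t c = D_c ∇²c − γ_f β ρ c.  A column-filling scalar feels the
  depth-average of the recirculating flow, which cancels, so fuel is not
  advected; consumption is proportional to the same reaction rate β that
  drives the flow and is slow (γ_f = 0.001) on the simulated window.

This is a Keller–Segel-type aggregation dynamics: particulate converges on
buoyant columns, spots form and merge.  Confinement enters twice, exactly
as the experiments suggest — weaker drive and (quadratically) weaker
mobility — so the ε = 0.05 pattern keeps rearranging while the ε = 0.01
pattern is effectively pinned.

Numerics: Fourier pseudo-spectral on the periodic square (default 512²,
working resolution 256²), 2/3-rule dealiasing applied to every nonlinear
product and to the state, integrating-factor treatment of the (stiff)
diffusion and hyperdiffusion, Heun for the nonlinear terms, fixed dt
subdivided so snapshots land exactly on the requested schedule.  The mean
of ρ is conserved to round-off (the nonlinear term is a pure divergence
and the k = 0 mode of a divergence vanishes); the occasional negative
excursion from ringing is clipped in grid space with the mean restored
multiplicatively.

The initial state is seeded noise filtered to a ring of wavenumbers
(centre `noise_k0` = 1.8, width set by `noise_corr` = 3.0, amplitude 0.2):
spotty aggregates of a definite size, which is what the recordings show at
their first frame.  A narrow band matters for the strongly confined runs:
with a broadband start, differential diffusive decay across the spectrum
masquerades as pattern change even when nothing moves.

### Pattern metrics

* `pattern_change_metric`: both fields mean-subtracted and
  variance-normalised; the RMS difference equals sqrt(2 − 2 corr), so 0 is
  an identical pattern, √2 two uncorrelated fields, 2 a field and its
  negation.  The localized/dynamic boundary is 0.2 at lag 3 (configurable).
* `correlation_length`: 2π divided by the *peak* wavenumber of the
  radially binned, lightly smoothed power spectrum (parabolic
  interpolation around the peak).  The peak, unlike a spectral moment, is
  insensitive to the harmonics that sharp saturated spots place at high k.

## Video-analysis toolchain

* PIV (`piv_pair`): 32 × 32 interrogation windows with 16-pixel overlap
  (the recording-analysis protocol's settings are the defaults).  Windows
  are mean-subtracted and correlated by zero-padded FFT; the linear
  correlation is normalised by the per-offset overlap area — the plain
  circular estimator is biased low by ~d/window, which is larger than the
  0.2 px accuracy target at quarter-window displacements.  The integer
  peak is validated by a peak-to-second-peak ratio (1.2, with an exclusion
  zone scaling as window/8 so smooth textures are not spuriously
  rejected), refined by a three-point Gaussian fit per axis, and finally
  checked against the local 3 × 3 vector median.  Image row 0 is the top;
  `velocity_scale` converts px/frame to physical units via fps × pixel
  size and all physical-height outputs are flipped to z-up.
* Density maps: per-segment cumulative and average intensity (default
  1000-frame segments = 40 s at 25 fps), optional per-pixel temporal
  minimum as background.
* ROI statistics: 300 × 300 px region sampled every 12 s; histograms plus
  std and IQR to separate broad from monodispersed intensity profiles.
* Front tracking: topmost height whose row maximum exceeds a threshold
  fraction of the global maximum, with linear interpolation of the
  crossing (the raw row index quantises speeds); centred finite
  differences for the speed, an optional detectability floor below which
  speeds are reported as NaN, and optional speeds-at-heights reporting.
* MSD: time-averaged within tracks over all ordered pairs at each lag,
  pooled across tracks with lag-wise pair-count weighting (the
  lowest-variance conventional estimator).  The diffusion fit is weighted
  least squares through the origin on MSD = 4DΔt; a negative slope is
  reported as D = 0 with a flag.
* Specific activity: least-squares slope of absorbance vs time, converted
  to a concentration rate by Beer–Lambert (path length 0.5 cm by default)
  and to U/mg by an explicit `conversion_factor` (indicator response →
  substrate turnover) that defaults to 1 and is flagged loudly in the
  output: the calibration is assay-specific and not shipped.

## Synthetic data

The generators produce every input the toolchain needs: Brownian tracks
with per-axis increment variance 2DΔt, ballistic tracks, passive tracers
advected through solver output (bilinear in space, linear in time between
snapshots, midpoint RK2, periodic wrap in x, reflective z walls) and
rendered grayscale sequences (truncated-Gaussian spots, constant
background, additive Gaussian noise clipped at zero, deterministic per
seed).  `closed_loop_piv_correlation` chains the whole pipeline — freeze a
solver snapshot, advect a jittered tracer lattice for one frame interval,
render both instants at 3.2 px per length unit, run PIV — and correlates
the recovered displacements with the generating velocity at the window
centres.

What the synthetic pipeline does not emulate: optical point-spread
functions beyond an isotropic Gaussian, shot noise, bubble optics,
out-of-plane motion, or tracer inertia.  Passing tests therefore
demonstrate the *algorithms* are correct and internally consistent, not
that the tools are robust to every imaging artefact of real recordings.

## Problem sizes and reproducibility

Unit tests run the side-view model at 128 × 32 and the confined model at
64²–128²; the regime and sweep checks and the acceptance script use the
working resolutions 256 × 64 and 256² — large enough that every regime
result also holds at the publication-scale grids (1024 × 256, 512²),
small enough that the full suite runs on one CPU in minutes.  All
randomness (confined seeding, synthetic data, rendering noise) flows from
explicit seeds; the solvers themselves are deterministic.

## Known limitations

* The side-view COM trajectory at 256 × 64 agrees with 512 × 128 to about
  3.5% (rich fuel) and 5% (marginal fuel) in L∞ over a full
  ascend–spread–sink cycle: onset times of the plume instability remain
  the most grid-sensitive feature of the solution.  Regime labels,
  monotone responses, circulation signs and conservation properties are
  unchanged between these grids.
* The confined closure is a defensible reduction, not a transcription of
  a published derivation; `confined_rhs` isolates it for replacement.
* The dimensionless parameter set reproduces regimes and trends; no
  attempt is made to fit the absolute experimental velocities (mm/s) or
  to map ε quantitatively to the 1.6/0.5/0.25 mm chamber heights beyond
  ε ∝ h².
* The stage classifier's thresholds (10⁻³-type tolerances) are heuristic
  conventions for an inherently visual classification.
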