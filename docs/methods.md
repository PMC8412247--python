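# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic validation can show.

## Contour representation

Each frame's segmented polyline is smoothed coordinate-wise by kernel ridge
regression on the circle.  Support angles follow the normalized secant length
of the *closed* polygon (the closing edge is included in the normalization so
that all M angles lie strictly inside [0, 2π); normalizing by the open
polyline length would place the last support angle at 2π ≡ 0 and make the
system singular).  The kernel is the classical Poisson kernel

P_r(θ) = (1/2π)(1−r²)/(1−2r cos θ+r²),

the Gaussian-process covariance with harmonic spectrum r^|n|.  The two
hyperparameters — the scale r ∈ (0,1) and the noise level σ_n — are chosen
once per track by maximizing the summed x/y marginal likelihood on the first
frame (coarse grid plus Nelder–Mead polish) and reused for all frames; both
can be fixed in the configuration.  ML selection matters: a hand-picked r too
close to 1 aliases harmonics above the Nyquist index M/2 and can inflate the
apparent contour length by several percent, while the ML choice balances
residuals against that artifact.

**Arc-length reparametrization** inverts the cumulative speed integral on a
2048-point grid and refits the contour at equally spaced support angles,
iterating until ‖∂_θΦ‖ is uniform to 5·10⁻⁴ relative (half the documented
10⁻³ contract).  The refit grid starts at twice the input support count and
doubles (up to 8×) whenever the iteration plateaus: interpolating a curve
with harmonic content up to n at m support points reintroduces aliased speed
ripple of relative size r^(m−2n), so noisy fits — whose shrunken noise
harmonics extend to where the kernel spectrum meets σ_n² — need the larger
grids.

Curvature uses the standard signed formula with the convention: positive
orientation (interior left), outward normal = clockwise rotation of the unit
tangent, convex boundary ⇒ κ > 0.  The center of mass is the parametrization
average (equal to the arc-length average after reparametrization); the
enclosed area uses the surveyor's formula on a 4096-point evaluation.

## Regularized marker flows

A flow step minimizes H = F + λU over the N lifted target angles (the lift
keeps cyclic gaps well defined; mapping violations are nonpositive lifted
gaps, with the wrap term θ_0+2π−θ_{N−1} as the N-th gap).  The distances in U
are measured on the circle of parameters, not in the plane — the property
that prevents mapping violations under large deformations.

**Optimizer.**  First-order descent with Armijo backtracking.  The descent
direction is the raw gradient preconditioned by the fixed circulant matrix
λ·H_U + c·I (H_U is the exact Hessian of U, a cyclic Laplacian; c estimates
the F curvature scale 2(L/2π)²/(Nδt²)), applied in O(N log N) via FFT.  Plain
gradient descent needs O(condition number) ≈ 10⁷ iterations at λ = 1000; the
preconditioned iteration converges in fewer than twenty at every λ in
[0, 10³] and is also what keeps the 500-frame robustness suite cheap.  Plain
descent remains available (`method="gd"`).  Convergence is declared when the
max-norm of the gradient of H/(1+λ) falls below 10⁻⁸ — the scaling keeps the
criterion attainable in float64, since at λ = 1000 the objective is of order
λ·4π² ≈ 4·10⁴ and its gradient floor is ≈ 10⁻⁷ — or when the objective stops
decreasing at float64 resolution for five consecutive iterations, at which
point no preconditioned-gradient direction can make further progress.
Initialization is the identity map (target = source), exact for static frames.

**Phase alignment** minimizes the mean squared parametrization distance over
a 1024-point τ grid (via FFT cross-correlation) with bounded local
refinement; near-ties within 10⁻⁹ relative resolve to the smallest τ.  A
genuinely flat objective (possible only when the two contours' Fourier
cross-spectrum vanishes at every harmonic, e.g. pure harmonic-1 against pure
harmonic-2 curves; *not* for concentric circles, whose cross term
2πR₁R₂cos(α−τ) always selects a unique τ) raises a tie warning and returns
τ = 0.

The **global flow** (λ_glo = 1000, default N = 400) chains steps from the
uniform grid on frame 0 and defines the kymograph coordinate system; any
violation here raises, since it indicates an upstream problem.  The **local
flow** (λ_loc = 0.1) restarts every step from the uniform grid, making each
step independent of history.  The entropy-type uniformity measure
(1/N)Σ log gap is computed and stored as an alternative diagnostic but never
optimized.

## Kymographs

Flow-derived rows (LD, LM) are indexed by the earlier frame of each pair;
curvature rows by their own frame.  Local quantities live on the uniform ξ
grid of the local flow and are resampled onto the global marker angles of the
same frame by periodic linear interpolation (nearest-marker assignment behind
a flag).  Smoothing is a separable Gaussian, σ = (3 markers, 1 frame),
truncated at 4σ, periodic in the marker axis and reflective in time.

LD and the continuum dilation rate d = ∂v_t/∂s + κ·v_n differ by the
spatially constant length-change rate (1/δt)log(L_{k+1}/L_k), exposed
separately as `length_change_rate`; LD is defined by the gap-ratio formula
exactly.  Two discretization facts matter for the consistency check: the
tangential derivative in d is taken with respect to arc length (this is what
makes the units 1/s and reproduces d = ṙ/r on expanding circles), and the LD
of a finite gap estimates d at the *gap midpoint*, so the first-order-in-δt
convergence is asserted against midpoint-evaluated d.

## Expansion analysis

Thresholds come from the smoothed LD kymograph of the whole track: P90 = 90th
percentile (linear interpolation between order statistics) of the positive
values only; c_med = P90/3, c_high = 2P90/3, values above P90 stay "high";
contraction thresholds are the exact negatives.  Patterns are 8-connected
components (periodic in the marker axis, with a union-find merge across the
seam since `scipy.ndimage.label` has no periodic mode) of same-sign
medium-or-high cells; a component whose inclusive frame extent times δt is
below the minimal growth time (default 3 s) is discarded, and growth time is
(end − onset + 1)·δt.  Events are strict positive 8-neighborhood maxima of
the smoothed LD grid, flagged when they fall in medium/high expansion cells.

A pattern's per-frame *slice* is the closed polygon of its marker positions
on Γ_k traversed forward and their images under the (interpolated) local map
on Γ_{k+1} traversed backward.  A run of m markers spans m marker gaps: the
polygon boundary extends to the cyclically next marker, which closes
full-circumference slices into the exact inter-contour region and makes the
half-circle slice of a concentric-circle step half the annulus to within the
polygonal error (< 1% at N = 100).  Backmapping unions the slice polygons
with shapely; the invalid self-touching two-loop polygon of a
full-circumference slice is rebuilt as outer-minus-inner.  The circular
histogram of event positions uses 36 bins of 10° around the direction of the
center-of-mass displacement of the event's frame pair.

## Synthetic tracks

All recipes are polar curves r(ψ,t) around a (possibly moving) center with
closed-form partials, so curvature, the material-flow velocities (markers at
fixed ψ), the dilation rate d = (r′ṙ′ + rṙ)/(r²+r′²), lengths and
equal-arc-length samples are exact (the arc-length tables use a cubic-spline
antiderivative with Newton polish).  Because r > 0, every curve is simple;
recipes violating positivity are rejected.  Noise is isotropic Gaussian
jitter on the vertex coordinates, emulating segmentation error, from a single
`default_rng(seed)` stream.

The bump recipe plants a Gaussian protrusion a(t)·exp(−angdist²/2w²); the
planted mask is the band where the contribution exceeds 0.1·a during growth
(half width w√(2 ln 10)).  Amplitude profiles: linear, quadratic
(accelerating), and sine (a full grow-and-retract pulse).  Fixture geometry
for the recovery check uses a *narrow* pseudopod (w = 0.15 rad on a 10 μm
cell, ≈ 1.5 μm across, with 0.05 μm vertex noise): LD differs from the
physical dilation rate by the global length-change offset, so a protrusion
occupying a large angular fraction of the contour depresses the LD band
relative to the planted radial band and no threshold convention can align
them; narrow protrusions — the biologically typical case — keep the offset
small and the detected and planted supports agree (Jaccard ≈ 0.8 across
seeds).

What the synthetic tracks do **not** emulate: correlated segmentation errors,
multiple interacting protrusions, cell-scale rotation mixing into the phase
alignment, intensity information, and frame-to-frame topology changes.
Passing tests therefore demonstrate the correctness of the machinery and its
robustness to vertex noise and large smooth deformations, not performance on
every experimental pathology.

## Problem sizes and defaults

Library defaults are M = N = 400 markers, λ_glo = 1000, λ_loc = 0.1,
δt = 1 s, smoothing (3, 1), minimal growth time 3 s, percentile 90 — the
standard operating point for 1 Hz amoeboid recordings.  The test suite and
the acceptance script run at M = N = 60–150 and 5–500 frames, sizes at which
the full suite completes in about three minutes on one CPU while exercising
the same code paths; the 500-frame robustness fixture uses a 6 μm pulsed
protrusion on a 10 μm cell at M = N = 100.

## Known limitations

* The regression assumes a star-free smooth boundary sampling; extremely
  sparse or self-intersecting polylines are rejected rather than repaired.
* The flow optimizer finds local minima; for λ → 0 and non-convex target
  contours the nearest-point limit holds only where that projection is
  single-valued (the documented monotone-convex case).
* Mapping-violation detection on a bare cyclic marker set is ambiguous in
  mod-2π arithmetic (a small negative gap equals a near-full positive wrap);
  the package therefore detects on the optimizer's lifted angles, and the
  standalone detector treats drops larger than π as the single genuine wrap.
* Pattern slice areas attribute one marker gap per run boundary; two
  patterns sharing a boundary marker double-count that wedge.
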