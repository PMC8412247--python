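# contourflow

Quantitative analysis of amoeboid cell-shape dynamics from segmented cell
outlines.  Given a time-lapse sequence of closed boundary polylines (e.g. from
an active-contour segmentation of *Dictyostelium discoideum* recordings),
`contourflow` builds smooth periodic contour representations, tracks virtual
markers between successive contours with a one-parameter family of regularized
flows, assembles kymographs of local boundary quantities, and detects and
characterizes membrane expansions (pseudopods) and contractions fully
automatically.  No image data is touched: the input is columnar text
`frame,x,y` and everything downstream is deterministic.

## The model

Each segmented outline γ_k (M points, frame interval δt) is smoothed per
coordinate by kernel ridge regression on the circle with a Poisson kernel
P_r(θ) ∝ (1−r²)/(1−2r cos θ+r²), giving a C^∞ closed curve
Φ_k: [0,2π) → ℝ², which is then reparametrized to rescaled arc length
(‖∂_θΦ_k‖ ≡ L_k/2π) and phase-aligned with its predecessor by minimizing
∫‖Φ_{k+1}(θ−τ)−Φ_k(θ)‖²dθ.

A flow between consecutive contours maps N marker angles θ_k to θ_{k+1}
minimizing

&nbsp;&nbsp;&nbsp;&nbsp;H = F + λU,&nbsp;&nbsp;
F = (1/Nδt²) Σ_i ‖Φ_{k+1}(θ_{k+1,i}) − Φ_k(θ_{k,i})‖²,&nbsp;&nbsp;
U = N Σ_i (θ_{k+1,i+1} − θ_{k+1,i})²,

where U ≥ 4π² with equality exactly at uniform spacing.  Large λ (default
1000) yields the near-uniform *global* coordinate flow used as the kymograph
coordinate system; small λ (default 0.1), re-initialized from the uniform grid
at every frame, yields the *local* flow carrying shape information.  From the
local flow the package computes, per marker:

* **local dispersion** LD_i = (1/δt)·log(target gap / source gap) — the rate
  of logarithmic marker-spacing change (1/s), positive in expanding regions;
* **local motion** LM_i = ‖Φ_{k+1}(φ(ξ_i)) − Φ_k(ξ_i)‖/δt (μm/s);
* signed **curvature** κ (1/μm), positive where the boundary is convex.

Expansions and contractions are connected space-time regions of the smoothed
LD kymograph beyond thresholds ±P90/3 and ±2·P90/3 (P90 = 90th percentile of
the positive LD values), 8-connected and periodic in the marker axis, filtered
by a minimal growth time (default 3 s).  Each pattern carries slice areas,
area growth rates, events (strict positive LD maxima), and track-level
statistics (simultaneity counts, growth-time and activity distributions, a
circular histogram of expansion directions relative to cell motion).

## Worked example

Generate a 16-frame synthetic cell with a narrow protrusion growing over 15 s
(4 μm peak on a 10 μm-radius cell, 0.05 μm vertex noise) and run the full
pipeline:

```sh
contourflow synth --kind bump_protrusion --frames 16 --points 100 --radius 10 \
    --bump-amplitude 4 --bump-width 0.15 --noise 0.05 --seed 11 --out track.csv
contourflow run track.csv --out results --n-markers 100
```

which logs

```
contourflow INFO stage=fit contours=16 elapsed=3.16s
contourflow INFO stage=flow steps=15 violations=0 elapsed=0.83s
contourflow INFO stage=detect patterns=1 events=2 thresholds=(0.01291,0.02582) elapsed=0.51s
```

— the GPR hyperparameters were estimated from the first frame, all 15 flow
steps are violation-free, and thresholding the LD kymograph at
±0.0129/±0.0258 s⁻¹ finds exactly one expansion.  `results/patterns.csv`
contains

```
id,sign,onset_s,end_s,growth_time_s,total_area_um2,mean_area_growth_um2_per_s,n_events,peak_ld
0,expansion,0,14,15,15.72...,1.048...,2,0.0461...
```

i.e. the protrusion is tracked from onset to the final frame (growth time
15 s), sweeps ≈ 15.7 μm² of new area at ≈ 1.05 μm²/s, and its peak local
dispersion is 0.046 s⁻¹.  `results/` also holds the raw and smoothed
kymograph matrices, the per-marker flow export, the events table, the
statistics bundle and an HDF5 container with the fitted contours and flows.
The same results follow from composing the per-stage subcommands
(`fit`, `flow`, `kymo`, `detect`, `stats`) by hand.

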