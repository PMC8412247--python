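"""Kymographs: space-time maps of local contour quantities.

Rows are frames, columns are the N markers of the global (strongly
regularized) coordinate system.  Flow-derived quantities — local dispersion
(LD, 1/s) and local motion (LM, um/s) — are computed from the re-initialized
weakly regularized flow on each frame pair, then resampled onto the global
marker angles of the earlier frame; the curvature kymograph is evaluated
directly at the global marker angles of each frame.

Local dispersion of a flow step with equally spaced source markers xi_i is

    LD_i = (1/dt) * log( (phi(xi_{i+1}) - phi(xi_i)) / (xi_{i+1} - xi_i) ),

the discrete rate of logarithmic change of the angular gap; positive in
expanding regions, negative in contracting ones.  Its small-dt continuum limit
is the instantaneous dilation rate d = dv_t/ds + kappa * v_n up to the
spatially constant length-change rate (1/dt) log(L_{k+1}/L_k), which
:func:`length_change_rate` exposes as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import TWO_PI, SmoothContour, curvature as contour_curvature
from .flow import (
    FlowStep,
    MarkerSet,
    VelocityDecomposition,
    compute_global_flow,
    compute_local_flow,
)

__all__ = [
    "Kymograph",
    "local_dispersion",
    "local_motion",
    "continuous_dilation_rate",
    "length_change_rate",
    "map_to_global",
    "build_kymograph",
    "smooth_kymograph",
]

QUANTITIES = ("local_dispersion", "local_motion", "curvature")


@dataclass
class Kymograph:
    """(frame x marker) grid of one scalar quantity in the global coordinate system."""

    quantity_name: str
    values: np.ndarray             # (K-1, N) for flow quantities, (K, N) for curvature
    frame_times: np.ndarray        # (rows,) seconds; flow rows carry the earlier frame's time
    dt: float
    smoothing: tuple[float, float] | None = None  # (sigma_space markers, sigma_time frames)

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def local_dispersion(step: FlowStep, dt: float) -> np.ndarray:
    """Per-marker local dispersion (1/s) of one flow step.

    Requires a violation-free step; the source is normally the re-initialized
    equally spaced grid.
    """
    src_gaps = step.source.cyclic_gaps()
    tgt_gaps = step.target_gaps()
    if np.any(tgt_gaps <= 0.0):
        raise ValueError("nonpositive target gap: mapping violation upstream")
    return np.log(tgt_gaps / src_gaps) / dt


def local_motion(
    step: FlowStep, prev: SmoothContour, next_: SmoothContour, dt: float
) -> np.ndarray:
    """Per-marker displacement magnitude between contours divided by dt (um/s)."""
    d = next_.evaluate(step.target.angles) - prev.evaluate(step.source.angles)
    return np.hypot(d[:, 0], d[:, 1]) / dt


def length_change_rate(prev: SmoothContour, next_: SmoothContour, dt: float) -> float:
    """The spatially constant offset (1/dt) log(L_{k+1}/L_k) between LD and the
    instantaneous dilation rate."""
    return float(np.log(next_.length / prev.length) / dt)


def continuous_dilation_rate(
    v: VelocityDecomposition,
    kappa: np.ndarray,
    source_gaps: np.ndarray,
    length: float,
) -> np.ndarray:
    """Instantaneous dilation rate d = dv_t/ds + kappa * v_n (1/s).

    The tangential derivative is a periodic central finite difference with
    respect to arc length; ``source_gaps`` are the angular marker gaps on the
    arc-length parametrized contour of length ``length``.
    """
    vt = np.asarray(v.tangential_speed, dtype=float)
    ds = np.asarray(source_gaps, dtype=float) * (length / TWO_PI)
    # central difference over the two adjacent arc segments
    dvt = (np.roll(vt, -1) - np.roll(vt, 1)) / (ds + np.roll(ds, 1))
    return dvt + np.asarray(kappa, dtype=float) * np.asarray(v.normal_speed, dtype=float)


def map_to_global(
    local_values: np.ndarray,
    local_angles: np.ndarray,
    global_markers: MarkerSet,
    nearest: bool = False,
) -> np.ndarray:
    """Resample a profile given at ``local_angles`` onto the global marker angles.

    Periodic linear interpolation by default; nearest-marker assignment behind
    the ``nearest`` flag.  Both marker sets live on the same contour.
    """
    order = np.argsort(local_angles)
    xa = np.asarray(local_angles, dtype=float)[order]
    ya = np.asarray(local_values, dtype=float)[order]
    # extend one period on both sides for seamless wrap
    xx = np.concatenate([xa[-1:] - TWO_PI, xa, xa[:1] + TWO_PI])
    yy = np.concatenate([ya[-1:], ya, ya[:1]])
    q = np.mod(global_markers.angles, TWO_PI)
    if nearest:
        idx = np.searchsorted(xx, q)
        left = np.clip(idx - 1, 0, len(xx) - 1)
        right = np.clip(idx, 0, len(xx) - 1)
        pick = np.where(q - xx[left] <= xx[right] - q, left, right)
        return yy[pick]
    return np.interp(q, xx, yy)


def build_kymograph(
    contours: list[SmoothContour],
    quantity: str,
    lam_glo: float = 1000.0,
    lam_loc: float = 0.1,
    n_markers: int = 400,
    dt: float = 1.0,
    global_markers: list[MarkerSet] | None = None,
    local_steps: list[FlowStep] | None = None,
) -> Kymograph:
    """Assemble one kymograph from a fitted, phase-aligned track.

    Runs the global flow once and the re-initialized local flow per step
    (either may be passed in when several kymographs share them), evaluates
    the quantity, and maps it onto the global coordinates.
    """
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")
    k = len(contours)
    if global_markers is None:
        global_markers = compute_global_flow(contours, lam_glo, n_markers, dt)
    times = np.array([c.time for c in contours])
    if quantity == "curvature":
        rows = np.stack([
            contour_curvature(c, m.angles) for c, m in zip(contours, global_markers)
        ])
        return Kymograph("curvature", rows, times, dt)
    if local_steps is None:
        local_steps = compute_local_flow(contours, lam_loc, n_markers, dt)
    rows = np.empty((k - 1, n_markers))
    for i, step in enumerate(local_steps):
        if quantity == "local_dispersion":
            vals = local_dispersion(step, dt)
        else:
            vals = local_motion(step, contours[i], contours[i + 1], dt)
        rows[i] = map_to_global(vals, step.source.angles, global_markers[i])
    return Kymograph(quantity, rows, times[:-1], dt)


def smooth_kymograph(
    kymo: Kymograph, sigma_space: float = 3.0, sigma_time: float = 1.0
) -> Kymograph:
    """Separable Gaussian smoothing: periodic in the marker axis, reflective at
    the time boundaries, truncated at 4 sigma."""
    sm = ndimage.gaussian_filter(
        kymo.values,
        sigma=(sigma_time, sigma_space),
        mode=("reflect", "wrap"),
        truncate=4.0,
    )
    return replace(kymo, values=sm, smoothing=(sigma_space, sigma_time))
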