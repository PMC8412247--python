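"""Synthetic contour tracks with analytically known deformation fields.

Every recipe is a member of one polar family

    curve(psi, t) = c(t) + r(psi, t) * e_r(psi),

with closed-form partial derivatives of r and c, which yields exact curvature,
marker velocities (for the material flow that keeps the polar angle psi
fixed), the instantaneous dilation rate d = dv_t/ds + kappa * v_n, and contour
lengths on every frame.  Because r > 0, every generated curve is simple.

Frames are sampled with M points at equal arc length; optional isotropic
Gaussian noise emulates segmentation jitter on the vertex coordinates.  A
single pseudorandom stream per track, seeded from the recipe, makes the output
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import TWO_PI, ContourPolyline

__all__ = [
    "TrackRecipe",
    "GroundTruth",
    "RecipeError",
    "generate_track",
    "bump_protrusion_field",
    "angular_distance",
]

KINDS = ("static", "translating_circle", "expanding_circle", "ellipse_rotation",
         "bump_protrusion")

_DENSE = 4096


class RecipeError(ValueError):
    """Recipe parameters would produce an invalid (non-simple) curve."""


def angular_distance(psi: np.ndarray, psi0: float) -> np.ndarray:
    """Periodic angular distance in [0, pi]."""
    d = np.mod(psi - psi0 + np.pi, TWO_PI) - np.pi
    return np.abs(d)


def bump_protrusion_field(
    base_radius: float, bump_angle: float, width: float,
) -> Callable[[np.ndarray, float], np.ndarray]:
    """Radial field r(psi; a) = R + a * exp(-angdist(psi, psi0)^2 / (2 w^2)).

    Returns a callable of (psi, amplitude).  The planted-pattern mask used by
    the generator is {psi : bump contribution > 0.1 a}, i.e. an angular band of
    half width w * sqrt(2 ln 10) around the bump center.
    """
    if width <= 0:
        raise RecipeError("bump width must be positive")

    def r(psi: np.ndarray, a: float) -> np.ndarray:
        d = angular_distance(psi, bump_angle)
        return base_radius + a * np.exp(-d * d / (2.0 * width * width))

    return r


@dataclass(frozen=True)
class TrackRecipe:
    """Parameters of one synthetic track; the seed fully determines the output."""

    kind: str
    n_frames: int = 50
    n_points: int = 100
    dt: float = 1.0
    radius: float = 10.0                 # um; base radius / semi-major scale
    velocity: tuple[float, float] = (0.0, 0.0)   # um/s, translating kinds
    expansion_rate: float = 0.0          # um/s, dr/dt for expanding_circle
    axes: tuple[float, float] = (10.0, 5.0)      # um, ellipse_rotation
    omega: float = 0.0                   # rad/s, ellipse rotation rate
    bump_angle: float = 0.0              # rad, protrusion center
    bump_width: float = 0.4              # rad, Gaussian width w
    bump_amplitude: float = 5.0          # um, peak amplitude a_max
    bump_grow_frames: int | None = None  # frames of growth (default: all)
    bump_grow_time: float | None = None  # seconds; overrides bump_grow_frames
    bump_profile: str = "linear"         # amplitude trajectory: linear | quadratic | sine
    noise_sigma: float = 0.0             # um, vertex jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise RecipeError(f"unknown kind {self.kind!r}")
        if self.n_frames < 1 or self.n_points < 3:
            raise RecipeError("need n_frames >= 1 and n_points >= 3")
        if self.dt <= 0:
            raise RecipeError("dt must be positive")
        if self.kind == "bump_protrusion" and self.bump_amplitude >= self.radius:
            raise RecipeError("bump amplitude must stay below the base radius")
        if self.bump_profile not in ("linear", "quadratic", "sine"):
            raise RecipeError(f"unknown bump profile {self.bump_profile!r}")


@dataclass
class GroundTruth:
    """Closed-form reference quantities sampled on the generated vertices.

    All per-frame arrays are indexed like the polyline points; ``theta`` are
    the (uniform) rescaled arc-length coordinates of the samples.
    """

    theta: np.ndarray            # (M,) = 2 pi m / M
    psi: np.ndarray              # (K, M) polar angle of each sample
    curvature: np.ndarray        # (K, M) 1/um
    v_normal: np.ndarray         # (K, M) um/s, material flow, outward positive
    v_tangential: np.ndarray     # (K, M) um/s
    dilation: np.ndarray         # (K, M) 1/s, d = dv_t/ds + kappa v_n
    length: np.ndarray           # (K,) um
    center: np.ndarray           # (K, 2) um (center parameter c(t), not mass)
    planted_mask: np.ndarray     # (K, M) bool, growing-bump support
    material_theta: Callable[[int, np.ndarray], np.ndarray] = field(repr=False, default=None)
    """material_theta(k, psi) -> rescaled arc-length coordinate of the material
    point psi on frame k; propagating fixed psi between frames gives the exact
    marker flow of the generator."""


class _PolarCurve:
    """r(psi, t), c(t) and their exact partial derivatives for one recipe."""

    def __init__(self, recipe: TrackRecipe):
        self.rec = recipe

    # radial field ---------------------------------------------------------
    def _bump_amp(self, t: float) -> tuple[float, float]:
        """Amplitude a(t) and its rate; profiles emulate steady, accelerating
        and pulsed (grow-then-retract) protrusion growth."""
        rec = self.rec
        if rec.bump_grow_time is not None:
            t_grow = rec.bump_grow_time
        else:
            t_grow = (rec.bump_grow_frames if rec.bump_grow_frames is not None
                      else max(rec.n_frames - 1, 1)) * rec.dt
        a_max = rec.bump_amplitude
        if rec.bump_profile == "sine":
            # full pulse: grows on [0, t_grow], retracts on [t_grow, 2 t_grow]
            if t >= 2.0 * t_grow:
                return 0.0, 0.0
            x = np.pi * t / (2.0 * t_grow)
            return (a_max * np.sin(x) ** 2,
                    a_max * np.pi / (2.0 * t_grow) * np.sin(2.0 * x))
        if t > t_grow:
            return a_max, 0.0
        if rec.bump_profile == "quadratic":
            return a_max * (t / t_grow) ** 2, 2.0 * a_max * t / t_grow**2
        return a_max * t / t_grow, a_max / t_grow

    def r(self, psi: np.ndarray, t: float) -> np.ndarray:
        rec = self.rec
        if rec.kind in ("static", "translating_circle"):
            return np.full_like(psi, rec.radius, dtype=float)
        if rec.kind == "expanding_circle":
            return np.full_like(psi, rec.radius + rec.expansion_rate * t, dtype=float)
        if rec.kind == "ellipse_rotation":
            a, b = rec.axes
            u = psi - rec.omega * t
            return a * b / np.sqrt((b * np.cos(u)) ** 2 + (a * np.sin(u)) ** 2)
        amp, _ = self._bump_amp(t)
        d = angular_distance(psi, rec.bump_angle)
        return rec.radius + amp * np.exp(-d * d / (2.0 * rec.bump_width**2))

    def _derivs(self, psi: np.ndarray, t: float):
        """(r, r_psi, r_psipsi, r_t, r_tpsi) closed forms."""
        rec = self.rec
        z = np.zeros_like(psi, dtype=float)
        if rec.kind in ("static", "translating_circle"):
            return self.r(psi, t), z, z, z, z
        if rec.kind == "expanding_circle":
            return (self.r(psi, t), z, z,
                    np.full_like(psi, rec.expansion_rate, dtype=float), z)
        if rec.kind == "ellipse_rotation":
            a, b = rec.axes
            u = psi - rec.omega * t
            g = (b * np.cos(u)) ** 2 + (a * np.sin(u)) ** 2
            gp = (a * a - b * b) * np.sin(2.0 * u)
            gpp = 2.0 * (a * a - b * b) * np.cos(2.0 * u)
            r = a * b * g ** (-0.5)
            r_u = -0.5 * a * b * g ** (-1.5) * gp
            r_uu = a * b * (0.75 * g ** (-2.5) * gp * gp - 0.5 * g ** (-1.5) * gpp)
            return r, r_u, r_uu, -rec.omega * r_u, -rec.omega * r_uu
        amp, amp_dot = self._bump_amp(t)
        w2 = rec.bump_width**2
        d = np.mod(psi - rec.bump_angle + np.pi, TWO_PI) - np.pi  # signed, in (-pi, pi]
        e = np.exp(-d * d / (2.0 * w2))
        r = rec.radius + amp * e
        r_p = amp * e * (-d / w2)
        r_pp = amp * e * (d * d / w2 - 1.0) / w2
        r_t = amp_dot * e
        r_tp = amp_dot * e * (-d / w2)
        return r, r_p, r_pp, r_t, r_tp

    # center ---------------------------------------------------------------
    def center(self, t: float) -> np.ndarray:
        vx, vy = self.rec.velocity if self.rec.kind == "translating_circle" else (0.0, 0.0)
        return np.array([vx * t, vy * t])

    def center_dot(self) -> np.ndarray:
        vx, vy = self.rec.velocity if self.rec.kind == "translating_circle" else (0.0, 0.0)
        return np.array([vx, vy])

    # derived quantities ---------------------------------------------------
    def points(self, psi: np.ndarray, t: float) -> np.ndarray:
        r = self.r(psi, t)
        return self.center(t) + np.column_stack([r * np.cos(psi), r * np.sin(psi)])

    def quantities(self, psi: np.ndarray, t: float):
        """curvature, v_n, v_t, d for the fixed-psi material flow at time t."""
        r, r_p, r_pp, r_t, r_tp = self._derivs(psi, t)
        q2 = r * r + r_p * r_p
        q = np.sqrt(q2)
        kappa = (r * r + 2.0 * r_p * r_p - r * r_pp) / q**3
        e_r = np.column_stack([np.cos(psi), np.sin(psi)])
        e_p = np.column_stack([-np.sin(psi), np.cos(psi)])
        tangent = (r_p[:, None] * e_r + r[:, None] * e_p) / q[:, None]
        normal = (r[:, None] * e_r - r_p[:, None] * e_p) / q[:, None]
        v = self.center_dot()[None, :] + r_t[:, None] * e_r
        v_n = np.sum(v * normal, axis=1)
        v_t = np.sum(v * tangent, axis=1)
        # d = T . dV/ds ; dV/dpsi = r_tp e_r + r_t e_p (center_dot is constant)
        d = (r_p * r_tp + r * r_t) / q2
        return kappa, v_n, v_t, d

    def _speed(self, psi: np.ndarray, t: float) -> np.ndarray:
        r, r_p, _, _, _ = self._derivs(psi, t)
        return np.sqrt(r * r + r_p * r_p)

    def arclength_spline(self, t: float, n: int = _DENSE):
        """Cumulative arc length s(psi) as a spline antiderivative of the speed."""
        from scipy.interpolate import CubicSpline

        psi = np.linspace(0.0, TWO_PI, n + 1)
        s_fn = CubicSpline(psi, self._speed(psi, t), bc_type="periodic").antiderivative()
        return s_fn, float(s_fn(TWO_PI))

    def length(self, t: float) -> float:
        return self.arclength_spline(t)[1]

    def equal_arclength_psi(self, m: int, t: float) -> np.ndarray:
        s_fn, total = self.arclength_spline(t)
        targets = total * np.arange(m) / m
        dense = np.linspace(0.0, TWO_PI, _DENSE + 1)
        psi = np.interp(targets, s_fn(dense), dense)
        for _ in range(3):  # Newton polish with the exact speed
            psi -= (s_fn(psi) - targets) / self._speed(psi, t)
        return psi

    def theta_of_psi(self, psi_q: np.ndarray, t: float) -> np.ndarray:
        s_fn, total = self.arclength_spline(t)
        return TWO_PI * np.asarray(s_fn(np.mod(psi_q, TWO_PI))) / total


def generate_track(recipe: TrackRecipe) -> tuple[list[ContourPolyline], GroundTruth]:
    """Generate a synthetic contour track plus its closed-form ground truth."""
    curve = _PolarCurve(recipe)
    k, m = recipe.n_frames, recipe.n_points
    rng = np.random.default_rng(recipe.seed)

    # validate positivity of the radial field over all frames
    psi_dense = np.linspace(0.0, TWO_PI, 720, endpoint=False)
    for kk in range(k):
        if np.min(curve.r(psi_dense, kk * recipe.dt)) <= 0.0:
            raise RecipeError("radial field is nonpositive; curve would self-intersect")

    theta = TWO_PI * np.arange(m) / m
    psi_all = np.empty((k, m))
    kappa_all = np.empty((k, m))
    vn_all = np.empty((k, m))
    vt_all = np.empty((k, m))
    d_all = np.empty((k, m))
    length_all = np.empty(k)
    center_all = np.empty((k, 2))
    mask_all = np.zeros((k, m), dtype=bool)
    polylines = []

    for kk in range(k):
        t = kk * recipe.dt
        psi = curve.equal_arclength_psi(m, t)
        pts = curve.points(psi, t)
        if recipe.noise_sigma > 0:
            pts = pts + rng.normal(0.0, recipe.noise_sigma, size=pts.shape)
        polylines.append(ContourPolyline(kk, t, pts))
        kappa, v_n, v_t, d = curve.quantities(psi, t)
        psi_all[kk], kappa_all[kk] = psi, kappa
        vn_all[kk], vt_all[kk], d_all[kk] = v_n, v_t, d
        length_all[kk] = curve.length(t)
        center_all[kk] = curve.center(t)
        if recipe.kind == "bump_protrusion":
            amp, amp_dot = curve._bump_amp(t)
            if amp_dot > 0.0 and amp > 0.0:
                half_width = recipe.bump_width * np.sqrt(2.0 * np.log(10.0))
                mask_all[kk] = angular_distance(psi, recipe.bump_angle) < half_width

    def material_theta(frame: int, psi_q: np.ndarray) -> np.ndarray:
        return curve.theta_of_psi(psi_q, frame * recipe.dt)

    gt = GroundTruth(
        theta=theta, psi=psi_all, curvature=kappa_all,
        v_normal=vn_all, v_tangential=vt_all, dilation=d_all,
        length=length_all, center=center_all, planted_mask=mask_all,
        material_theta=material_theta,
    )
    return polylines, gt
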