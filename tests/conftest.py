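"""Shared fixtures: analytic contours and small synthetic tracks.

Expensive fitted objects are session-scoped; factory helpers build fresh
contours where mutation or parameter variation is needed.
"""

import numpy as np
import pytest

from contourflow.geometry import (
    ContourPolyline,
    SmoothContour,
    fit_smooth_contour,
    reparametrize_arclength,
)
from contourflow.flow import align_track
from contourflow.synthetic import TrackRecipe, generate_track

TWO_PI = 2.0 * np.pi


def circle_polyline(radius=1.0, n=400, center=(0.0, 0.0), frame=0, time=0.0,
                    noise=0.0, rng=None):
    t = np.linspace(0.0, TWO_PI, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(t),
                           center[1] + radius * np.sin(t)])
    if noise > 0:
        pts = pts + (rng or np.random.default_rng(0)).normal(0, noise, pts.shape)
    return ContourPolyline(frame, time, pts)


def ellipse_polyline(a=2.0, b=1.0, n=400, frame=0):
    t = np.linspace(0.0, TWO_PI, n, endpoint=False)
    return ContourPolyline(frame, 0.0, np.column_stack([a * np.cos(t), b * np.sin(t)]))


def make_circle(radius=1.0, n=200, center=(0.0, 0.0), frame=0, r=0.9, sigma=1e-6):
    c = fit_smooth_contour(circle_polyline(radius, n, center, frame), r, sigma)
    return reparametrize_arclength(c)


@pytest.fixture(scope="session")
def unit_circle():
    return make_circle(1.0, 400)


@pytest.fixture(scope="session")
def ellipse():
    """Arc-length parametrized ellipse a=2, b=1; theta=0 at the major vertex."""
    return reparametrize_arclength(fit_smooth_contour(ellipse_polyline(), 0.9, 1e-6))


@pytest.fixture(scope="session")
def bump_track():
    """Small noiseless bump-protrusion track with fitted, aligned contours."""
    recipe = TrackRecipe(kind="bump_protrusion", n_frames=16, n_points=100,
                         radius=10.0, bump_amplitude=4.0, bump_width=0.5,
                         bump_grow_frames=12, dt=1.0, seed=11)
    polylines, gt = generate_track(recipe)
    contours = [reparametrize_arclength(fit_smooth_contour(pl, 0.9, 0.01))
                for pl in polylines]
    aligned, _ = align_track(contours)
    return recipe, aligned, gt


@pytest.fixture(scope="session")
def bump_pair(bump_track):
    """One contour pair with a clearly growing protrusion."""
    _, contours, _ = bump_track
    return contours[5], contours[6]
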