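"""Detection and statistics of membrane expansions and contractions.

The smoothed local-dispersion kymograph is thresholded into five activity
classes.  The expansion thresholds divide the 90th percentile P90 of all
positive LD values into three equal intervals: c_med = P90/3 and
c_high = 2*P90/3 (values above P90 remain "high"); contraction thresholds are
the exact negatives.  Connected space-time regions of same-sign medium/high
activity — 8-connected, periodic in the marker axis — are the expansion and
contraction patterns; regions shorter than a minimal growth time are
discarded.  Each pattern carries its per-frame slice polygons (the region
between consecutive contours spanned by its markers), their areas and growth
rates, and the positive strict local maxima of the kymograph are the expansion
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import TWO_PI, SmoothContour
from .flow import FlowStep, MarkerSet
from .kymograph import Kymograph

__all__ = [
    "ActivityThresholds",
    "Pattern",
    "EventPoint",
    "PatternStatistics",
    "activity_thresholds",
    "classify_activity",
    "extract_patterns",
    "detect_events",
    "pattern_area_growth",
    "pattern_statistics",
    "backmap_patterns",
    "region_vertices",
]

# label codes
HIGH_EXPANSION = 2
MEDIUM_EXPANSION = 1
LOW = 0
MEDIUM_CONTRACTION = -1
HIGH_CONTRACTION = -2


@dataclass(frozen=True)
class ActivityThresholds:
    """Class boundaries (1/s); contraction thresholds are the negatives."""

    c_med: float
    c_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.c_med < self.c_high):
            raise ValueError("need 0 < c_med < c_high")


@dataclass
class EventPoint:
    """A positive strict local maximum of the smoothed LD kymograph."""

    frame_row: int
    marker_column: int
    ld_value: float
    inside_active_region: bool


@dataclass
class Pattern:
    """One connected space-time region of expanding or contracting activity."""

    cells: set[tuple[int, int]]          # (frame row, marker column)
    sign: int                            # +1 expansion, -1 contraction
    onset: int                           # first frame row
    end: int                             # last frame row
    dt: float
    has_high: bool = False               # contains at least one high-activity cell
    slice_areas: np.ndarray | None = None       # per active frame, um^2
    area_growth: np.ndarray | None = None       # per active frame, um^2/s
    slice_polygons: list | None = field(default=None, repr=False)
    events: list[EventPoint] = field(default_factory=list)

    @property
    def growth_time(self) -> float:
        """(end - onset + 1) * dt, the inclusive temporal extent in seconds."""
        return (self.end - self.onset + 1) * self.dt

    @property
    def frames(self) -> list[int]:
        return sorted({r for r, _ in self.cells})

    def columns_at(self, row: int) -> np.ndarray:
        return np.array(sorted(c for r, c in self.cells if r == row), dtype=int)


def activity_thresholds(kymo: Kymograph, percentile: float = 90.0) -> ActivityThresholds:
    """Thresholds from the positive LD values of a (smoothed) kymograph.

    The given percentile of the positive values only (linear interpolation
    between order statistics) is divided into three equal intervals.
    """
    pos = kymo.values[kymo.values > 0.0]
    if pos.size == 0:
        raise ValueError("kymograph has no positive values; thresholds undefined")
    p = float(np.percentile(pos, percentile))
    if p <= 0.0:
        raise ValueError("degenerate kymograph: percentile of positive values is 0")
    return ActivityThresholds(c_med=p / 3.0, c_high=2.0 * p / 3.0)


def classify_activity(kymo: Kymograph, thresholds: ActivityThresholds) -> np.ndarray:
    """Label grid with the five activity classes (every cell gets exactly one)."""
    v = kymo.values
    labels = np.zeros(v.shape, dtype=np.int8)
    labels[v >= thresholds.c_med] = MEDIUM_EXPANSION
    labels[v >= thresholds.c_high] = HIGH_EXPANSION
    labels[v <= -thresholds.c_med] = MEDIUM_CONTRACTION
    labels[v <= -thresholds.c_high] = HIGH_CONTRACTION
    return labels


def _periodic_components(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a boolean grid, periodic in axis 1.

    Returns a list of boolean masks, one per component.
    """
    structure = np.ones((3, 3), dtype=bool)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    # merge labels that touch across the marker wrap seam (8-adjacency)
    parent = list(range(n + 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    rows = mask.shape[0]
    left, right = lab[:, 0], lab[:, -1]
    for r in range(rows):
        if left[r]:
            for rr in (r - 1, r, r + 1):
                if 0 <= rr < rows and right[rr]:
                    union(int(left[r]), int(right[rr]))
    comps: list[np.ndarray] = []
    flat = lab.ravel()
    canon = np.array([0] + [find(i) for i in range(1, n + 1)])
    lab_c = canon[lab]
    for root in np.unique(lab_c):
        if root == 0:
            continue
        comps.append(lab_c == root)
    return comps


def extract_patterns(
    labels: np.ndarray,
    dt: float,
    min_growth_time: float = 3.0,
) -> list[Pattern]:
    """Connected same-sign medium/high regions surviving the growth-time filter.

    Medium and high cells of the same sign merge into one pattern; the level
    is retained per cell via ``has_high`` and the label grid itself.
    """
    patterns: list[Pattern] = []
    for sign in (+1, -1):
        mask = (labels * sign) >= MEDIUM_EXPANSION
        for comp in _periodic_components(mask):
            rows = np.flatnonzero(comp.any(axis=1))
            onset, end = int(rows.min()), int(rows.max())
            if (end - onset + 1) * dt < min_growth_time:
                continue
            cells = {(int(r), int(c)) for r, c in zip(*np.nonzero(comp))}
            has_high = bool(np.any(np.abs(labels[comp]) == HIGH_EXPANSION))
            patterns.append(Pattern(cells=cells, sign=sign, onset=onset, end=end,
                                    dt=dt, has_high=has_high))
    patterns.sort(key=lambda p: (p.onset, -p.sign, min(c for _, c in p.cells)))
    return patterns


def detect_events(kymo: Kymograph, labels: np.ndarray) -> list[EventPoint]:
    """Positive strict local maxima over the 8-neighborhood (periodic in space).

    An event is flagged as inside the active region when its cell is labeled
    medium- or high-expansion.
    """
    v = kymo.values
    rows, cols = v.shape
    padded = np.full((rows + 2, cols + 2), -np.inf)
    padded[1:-1, 1:-1] = v
    padded[1:-1, 0] = v[:, -1]
    padded[1:-1, -1] = v[:, 0]
    is_max = np.ones_like(v, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            is_max &= v > padded[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
    is_max &= v > 0.0
    events = []
    for r, c in zip(*np.nonzero(is_max)):
        events.append(EventPoint(int(r), int(c), float(v[r, c]),
                                 bool(labels[r, c] >= MEDIUM_EXPANSION)))
    return events


def _cyclic_runs(cols: np.ndarray, n_markers: int) -> list[np.ndarray]:
    """Split sorted column indices into cyclically contiguous runs."""
    if cols.size == 0:
        return []
    if cols.size == n_markers:
        return [cols]
    present = np.zeros(n_markers, dtype=bool)
    present[cols] = True
    # begin each run at a column whose cyclic predecessor is absent
    runs = []
    starts = [c for c in cols if not present[(c - 1) % n_markers]]
    for s in starts:
        run = [s]
        c = (s + 1) % n_markers
        while present[c]:
            run.append(c)
            c = (c + 1) % n_markers
        runs.append(np.array(run, dtype=int))
    return runs


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _local_map_interp(step: FlowStep, angles: np.ndarray) -> np.ndarray:
    """Interpolate the local flow phi at arbitrary source angles (periodic)."""
    xi = step.source.angles
    phi = step.lifted_target
    xx = np.concatenate([xi, [xi[0] + TWO_PI]])
    yy = np.concatenate([phi, [phi[0] + TWO_PI]])
    return np.interp(np.mod(angles, TWO_PI), xx, yy)


def pattern_area_growth(
    pattern: Pattern,
    contours: list[SmoothContour],
    global_markers: list[MarkerSet],
    local_steps: list[FlowStep],
    dt: float,
) -> Pattern:
    """Per-frame slice areas (um^2) and growth rates (um^2/s) of one pattern.

    For each active frame k the slice is the closed polygon formed by the
    pattern's marker positions on Gamma_k traversed forward and their images
    under the weakly regularized local map on Gamma_{k+1} traversed backward;
    its area comes from the surveyor's formula.  A run of m markers spans m
    marker gaps: the polygon boundary is extended to the cyclically next
    marker, which closes full-circumference slices into the exact area
    between the two contours.
    """
    n_markers = global_markers[0].n
    frames = pattern.frames
    areas, polys = [], []
    for k in frames:
        cols = pattern.columns_at(k)
        runs = _cyclic_runs(cols, n_markers)
        area_k = 0.0
        polys_k = []
        for run in runs:
            run = np.concatenate([run, [(run[-1] + 1) % n_markers]])
            src_ang = global_markers[k].angles[run]
            tgt_ang = _local_map_interp(local_steps[k], src_ang)
            a = contours[k].evaluate(src_ang)
            b = contours[k + 1].evaluate(np.mod(tgt_ang, TWO_PI))
            if run.size < 2:
                polys_k.append(np.vstack([a, b]))
                continue
            poly = np.vstack([a, b[::-1]])
            area_k += abs(_shoelace(poly))
            polys_k.append(poly)
        areas.append(area_k)
        polys.append(polys_k)
    pattern.slice_areas = np.array(areas)
    pattern.area_growth = pattern.slice_areas / dt
    pattern.slice_polygons = polys
    return pattern


@dataclass
class PatternStatistics:
    """Track-level statistics of the detected patterns and events."""

    frame_times: np.ndarray
    counts_expansion: np.ndarray         # per frame, active expansion patterns
    counts_contraction: np.ndarray
    counts_expansion_high: np.ndarray    # restricted to patterns containing high cells
    counts_contraction_high: np.ndarray
    fraction_time_expansion_gt2: float
    fraction_time_contraction_gt2: float
    ld_high_expansion: np.ndarray        # LD values in high-expansion cells
    ld_high_contraction: np.ndarray
    lm_high_expansion: np.ndarray
    lm_high_contraction: np.ndarray
    curv_high_expansion: np.ndarray
    curv_high_contraction: np.ndarray
    growth_times_expansion: np.ndarray   # s, per pattern
    growth_times_contraction: np.ndarray
    areas_expansion: np.ndarray          # total area per pattern, um^2
    areas_contraction: np.ndarray
    event_angle_hist: np.ndarray         # 36 bins of 10 degrees
    event_angle_bin_edges: np.ndarray    # radians, relative to CM motion
    expansions_per_minute: float


def pattern_statistics(
    patterns: list[Pattern],
    kymos: dict[str, Kymograph],
    labels: np.ndarray,
    events: list[EventPoint],
    contours: list[SmoothContour],
    global_markers: list[MarkerSet],
    centers: np.ndarray,
    dt: float,
    n_bins: int = 36,
) -> PatternStatistics:
    """Assemble the pattern statistics bundle.

    ``centers`` holds the per-frame center of mass; the circular histogram of
    event positions is measured relative to the instantaneous center-of-mass
    displacement direction of the event's frame pair.
    """
    ld = kymos["local_dispersion"]
    n_rows = ld.n_rows
    counts = {(+1, "any"): np.zeros(n_rows, dtype=int),
              (-1, "any"): np.zeros(n_rows, dtype=int),
              (+1, "high"): np.zeros(n_rows, dtype=int),
              (-1, "high"): np.zeros(n_rows, dtype=int)}
    for p in patterns:
        for r in p.frames:
            counts[(p.sign, "any")][r] += 1
            if p.has_high:
                counts[(p.sign, "high")][r] += 1

    def values_in(name: str, code_sign: int) -> np.ndarray:
        grid = kymos[name].values[: labels.shape[0]]
        return grid[labels == code_sign * HIGH_EXPANSION]

    bin_edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    rel_angles = []
    for ev in events:
        if not ev.inside_active_region:
            continue
        k = ev.frame_row
        if k + 1 >= len(centers):
            continue
        disp = centers[k + 1] - centers[k]
        if np.hypot(*disp) == 0.0:
            continue
        pos = contours[k].evaluate(global_markers[k].angles[[ev.marker_column]])[0]
        radial = pos - centers[k]
        ang = np.arctan2(radial[1], radial[0]) - np.arctan2(disp[1], disp[0])
        rel_angles.append(np.mod(ang + np.pi, TWO_PI) - np.pi)
    hist, _ = np.histogram(rel_angles, bins=bin_edges)

    gte = np.array([p.growth_time for p in patterns if p.sign > 0])
    gtc = np.array([p.growth_time for p in patterns if p.sign < 0])
    areas_e = np.array([
        float(np.sum(p.slice_areas)) if p.slice_areas is not None else np.nan
        for p in patterns if p.sign > 0])
    areas_c = np.array([
        float(np.sum(p.slice_areas)) if p.slice_areas is not None else np.nan
        for p in patterns if p.sign < 0])

    duration_min = n_rows * dt / 60.0
    n_exp = sum(1 for p in patterns if p.sign > 0)
    return PatternStatistics(
        frame_times=ld.frame_times,
        counts_expansion=counts[(+1, "any")],
        counts_contraction=counts[(-1, "any")],
        counts_expansion_high=counts[(+1, "high")],
        counts_contraction_high=counts[(-1, "high")],
        fraction_time_expansion_gt2=float(np.mean(counts[(+1, "high")] > 2)),
        fraction_time_contraction_gt2=float(np.mean(counts[(-1, "high")] > 2)),
        ld_high_expansion=values_in("local_dispersion", +1),
        ld_high_contraction=values_in("local_dispersion", -1),
        lm_high_expansion=values_in("local_motion", +1),
        lm_high_contraction=values_in("local_motion", -1),
        curv_high_expansion=values_in("curvature", +1),
        curv_high_contraction=values_in("curvature", -1),
        growth_times_expansion=gte,
        growth_times_contraction=gtc,
        areas_expansion=areas_e,
        areas_contraction=areas_c,
        event_angle_hist=hist,
        event_angle_bin_edges=bin_edges,
        expansions_per_minute=float(n_exp / duration_min) if duration_min > 0 else np.nan,
    )


def backmap_patterns(patterns: list[Pattern]) -> list:
    """Map each pattern back to the 2d plane as the union of its slice polygons.

    Returns one shapely geometry per pattern (empty for patterns without
    computed slices); :func:`region_vertices` turns a geometry into plain
    vertex lists for export.  Patterns must have been processed by
    :func:`pattern_area_growth` first.
    """
    import shapely
    from shapely.geometry import GeometryCollection, Polygon
    from shapely.ops import unary_union

    regions = []
    for p in patterns:
        polys = []
        for frame_polys in (p.slice_polygons or []):
            for poly in frame_polys:
                if poly.shape[0] < 3:
                    continue
                n_half = poly.shape[0] // 2
                shp = Polygon(poly)
                if not shp.is_valid:
                    # full-circumference slice: annulus between the two loops
                    outer = Polygon(poly[n_half:])
                    inner = Polygon(poly[:n_half])
                    if outer.is_valid and inner.is_valid:
                        big, small = (outer, inner) if outer.area >= inner.area else (inner, outer)
                        shp = big.difference(small)
                    else:
                        shp = shapely.make_valid(Polygon(poly))
                polys.append(shp)
        regions.append(unary_union(polys) if polys else GeometryCollection())
    return regions


def region_vertices(geometry) -> list[np.ndarray]:
    """Exterior (and hole) vertex arrays of a backmapped pattern region."""
    out = []
    for g in getattr(geometry, "geoms", [geometry]):
        if g.is_empty or not hasattr(g, "exterior"):
            continue
        out.append(np.asarray(g.exterior.coords))
        for ring in g.interiors:
            out.append(np.asarray(ring.coords))
    return out
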