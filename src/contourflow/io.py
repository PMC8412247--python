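"""Readers and writers for all pipeline artifacts.

Text formats (all comma-separated with ``#`` metadata preambles):

* contour track — columns ``frame,x,y``, frames contiguous from 0, points in
  order, positive orientation enforced on read (reversed with a warning);
  optional header ``# dt=<seconds> unit=<um|px>``;
* kymograph matrix — one row per frame, preamble carrying quantity, dt,
  marker count, smoothing and the first row time;
* long-format flow export — ``frame,marker,theta_source,theta_target``;
* pattern catalogue / events / statistics bundle CSVs.

Fitted tracks and flows are also stored in a single HDF5 container so the
pipeline stages can hand complete state to each other.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import h5py
import numpy as np

from .geometry import ContourPolyline, SmoothContour, _signed_polygon_area
from .flow import CostBreakdown, FlowStep, MarkerSet
from .kymograph import Kymograph

__all__ = [
    "read_track",
    "write_track",
    "write_kymograph",
    "read_kymograph",
    "save_contours",
    "load_contours",
    "save_global_flow",
    "load_global_flow",
    "save_local_flow",
    "load_local_flow",
    "save_kymograph_h5",
    "load_kymograph_h5",
    "write_flow_csv",
    "write_pattern_catalogue",
    "write_events",
    "write_statistics",
]

_FLOAT = "%.17g"  # round-trips float64 exactly


# ---------------------------------------------------------------------------
# contour-track text format
# ---------------------------------------------------------------------------

def read_track(path) -> tuple[list[ContourPolyline], float, str]:
    """Read a contour track; returns (polylines, dt, unit)."""
    dt, unit = 1.0, "um"
    frames: dict[int, list[tuple[float, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("dt="):
                        dt = float(token[3:])
                    elif token.startswith("unit="):
                        unit = token[5:]
                continue
            parts = line.replace(",", " ").split()
            k, x, y = int(parts[0]), float(parts[1]), float(parts[2])
            frames.setdefault(k, []).append((x, y))
    if not frames:
        raise ValueError(f"no contour data in {path}")
    keys = sorted(frames)
    if keys != list(range(len(keys))):
        raise ValueError("frames must be contiguous from 0")
    polylines = []
    for k in keys:
        pts = np.array(frames[k])
        if _signed_polygon_area(pts) < 0:
            warnings.warn(f"frame {k}: negative orientation, reversing", stacklevel=2)
            pts = pts[::-1]
        polylines.append(ContourPolyline(k, k * dt, pts))
    return polylines, dt, unit


def write_track(path, polylines: list[ContourPolyline], dt: float = 1.0,
                unit: str = "um") -> None:
    with open(path, "w") as fh:
        fh.write(f"# dt={dt:g} unit={unit}\n")
        fh.write("# frame,x,y\n")
        for pl in polylines:
            for x, y in pl.points:
                fh.write(f"{pl.frame_index},{_FLOAT % x},{_FLOAT % y}\n")


# ---------------------------------------------------------------------------
# kymograph text format
# ---------------------------------------------------------------------------

def write_kymograph(path, kymo: Kymograph) -> None:
    sm = "none" if kymo.smoothing is None else f"{kymo.smoothing[0]:g},{kymo.smoothing[1]:g}"
    t0 = float(kymo.frame_times[0]) if len(kymo.frame_times) else 0.0
    with open(path, "w") as fh:
        fh.write(f"# quantity={kymo.quantity_name}\n")
        fh.write(f"# dt={kymo.dt:g}\n")
        fh.write(f"# n_markers={kymo.n_markers}\n")
        fh.write(f"# smoothing={sm}\n")
        fh.write(f"# t0={_FLOAT % t0}\n")
        for row in kymo.values:
            fh.write(",".join(_FLOAT % v for v in row) + "\n")


def read_kymograph(path) -> Kymograph:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            rows.append([float(v) for v in line.split(",")])
    values = np.array(rows)
    dt = float(meta.get("dt", 1.0))
    t0 = float(meta.get("t0", 0.0))
    smoothing = None
    if meta.get("smoothing", "none") != "none":
        a, b = meta["smoothing"].split(",")
        smoothing = (float(a), float(b))
    times = t0 + dt * np.arange(values.shape[0])
    return Kymograph(meta.get("quantity", "unknown"), values, times, dt, smoothing)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_contours(path, contours: list[SmoothContour], mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "contours" in f:
            del f["contours"]
        grp = f.create_group("contours")
        grp.attrs["n_frames"] = len(contours)
        for c in contours:
            g = grp.create_group(str(c.frame_index))
            g.create_dataset("weights", data=c.weights)
            g.create_dataset("support_angles", data=c.support_angles)
            g.attrs.update({
                "kernel_scale": c.kernel_scale, "noise_level": c.noise_level,
                "frame_index": c.frame_index, "time": c.time, "length": c.length,
            })


def load_contours(path) -> list[SmoothContour]:
    out = []
    with h5py.File(path, "r") as f:
        grp = f["contours"]
        for k in range(int(grp.attrs["n_frames"])):
            g = grp[str(k)]
            out.append(SmoothContour(
                weights=g["weights"][()],
                support_angles=g["support_angles"][()],
                kernel_scale=float(g.attrs["kernel_scale"]),
                noise_level=float(g.attrs["noise_level"]),
                frame_index=int(g.attrs["frame_index"]),
                time=float(g.attrs["time"]),
                _length=float(g.attrs["length"]),
            ))
    return out


def save_global_flow(path, markers: list[MarkerSet]) -> None:
    with h5py.File(path, "a") as f:
        if "global_flow" in f:
            del f["global_flow"]
        g = f.create_group("global_flow")
        g.create_dataset("angles", data=np.stack([m.angles for m in markers]))
        g.create_dataset("frame_index", data=np.array([m.frame_index for m in markers]))


def load_global_flow(path) -> list[MarkerSet]:
    with h5py.File(path, "r") as f:
        angles = f["global_flow/angles"][()]
        idx = f["global_flow/frame_index"][()]
    return [MarkerSet(int(i), a) for i, a in zip(idx, angles)]


def save_local_flow(path, steps: list[FlowStep]) -> None:
    with h5py.File(path, "a") as f:
        if "local_flow" in f:
            del f["local_flow"]
        grp = f.create_group("local_flow")
        grp.attrs["n_steps"] = len(steps)
        for i, s in enumerate(steps):
            g = grp.create_group(str(i))
            g.create_dataset("source_angles", data=s.source.angles)
            g.create_dataset("lifted_target", data=s.lifted_target)
            g.create_dataset("violations", data=np.array(s.violations, dtype=int))
            g.attrs.update({
                "lam": s.lam, "F": s.costs.F, "U": s.costs.U,
                "converged": s.converged, "iterations": s.iterations,
                "source_frame": s.source.frame_index,
                "target_frame": s.target.frame_index,
            })


def load_local_flow(path) -> list[FlowStep]:
    from .geometry import TWO_PI

    out = []
    with h5py.File(path, "r") as f:
        grp = f["local_flow"]
        for i in range(int(grp.attrs["n_steps"])):
            g = grp[str(i)]
            lifted = g["lifted_target"][()]
            src = MarkerSet(int(g.attrs["source_frame"]), g["source_angles"][()])
            tgt = MarkerSet(int(g.attrs["target_frame"]), np.mod(lifted, TWO_PI))
            costs = CostBreakdown(F=float(g.attrs["F"]), U=float(g.attrs["U"]),
                                  lam=float(g.attrs["lam"]))
            out.append(FlowStep(
                source=src, target=tgt, lam=float(g.attrs["lam"]), costs=costs,
                violations=[int(v) for v in g["violations"][()]],
                converged=bool(g.attrs["converged"]),
                iterations=int(g.attrs["iterations"]),
                lifted_target=lifted,
            ))
    return out


def save_kymograph_h5(path, kymo: Kymograph, name: str) -> None:
    with h5py.File(path, "a") as f:
        key = f"kymographs/{name}"
        if key in f:
            del f[key]
        d = f.create_dataset(key, data=kymo.values)
        d.attrs["quantity"] = kymo.quantity_name
        d.attrs["dt"] = kymo.dt
        d.attrs["t0"] = float(kymo.frame_times[0])
        d.attrs["smoothing"] = "none" if kymo.smoothing is None else list(kymo.smoothing)


def load_kymograph_h5(path, name: str) -> Kymograph:
    with h5py.File(path, "r") as f:
        d = f[f"kymographs/{name}"]
        values = d[()]
        sm = d.attrs["smoothing"]
        smoothing = None if isinstance(sm, str) and sm == "none" else (float(sm[0]), float(sm[1]))
        dt = float(d.attrs["dt"])
        t0 = float(d.attrs["t0"])
        qn = d.attrs["quantity"]
    times = t0 + dt * np.arange(values.shape[0])
    return Kymograph(str(qn), values, times, dt, smoothing)


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------

def write_flow_csv(path, steps: list[FlowStep]) -> None:
    with open(path, "w") as fh:
        fh.write("frame,marker,theta_source,theta_target\n")
        for s in steps:
            k = s.source.frame_index
            for i, (a, b) in enumerate(zip(s.source.angles, s.target.angles)):
                fh.write(f"{k},{i},{_FLOAT % a},{_FLOAT % b}\n")


def write_pattern_catalogue(path, patterns) -> None:
    with open(path, "w") as fh:
        fh.write("id,sign,onset_s,end_s,growth_time_s,total_area_um2,"
                 "mean_area_growth_um2_per_s,n_events,peak_ld\n")
        for i, p in enumerate(patterns):
            total = float(np.sum(p.slice_areas)) if p.slice_areas is not None else float("nan")
            mean_g = float(np.mean(p.area_growth)) if p.area_growth is not None else float("nan")
            peak = max((e.ld_value for e in p.events), default=float("nan"))
            sign = "expansion" if p.sign > 0 else "contraction"
            fh.write(f"{i},{sign},{_FLOAT % (p.onset * p.dt)},{_FLOAT % (p.end * p.dt)},"
                     f"{_FLOAT % p.growth_time},{_FLOAT % total},{_FLOAT % mean_g},"
                     f"{len(p.events)},{_FLOAT % peak}\n")


def write_events(path, events, global_markers) -> None:
    with open(path, "w") as fh:
        fh.write("frame,marker,theta,ld,inside_active_region\n")
        for e in events:
            theta = global_markers[e.frame_row].angles[e.marker_column]
            fh.write(f"{e.frame_row},{e.marker_column},{_FLOAT % theta},"
                     f"{_FLOAT % e.ld_value},{int(e.inside_active_region)}\n")


def write_statistics(outdir, stats) -> list[Path]:
    """Write the statistics bundle as plain-text files; returns created paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created = []

    p = outdir / "simultaneous_counts.csv"
    with open(p, "w") as fh:
        fh.write("time_s,expansions,contractions,expansions_high,contractions_high\n")
        for i, t in enumerate(stats.frame_times):
            fh.write(f"{_FLOAT % t},{stats.counts_expansion[i]},{stats.counts_contraction[i]},"
                     f"{stats.counts_expansion_high[i]},{stats.counts_contraction_high[i]}\n")
    created.append(p)

    p = outdir / "summary.txt"
    with open(p, "w") as fh:
        fh.write(f"fraction_time_expansion_gt2={_FLOAT % stats.fraction_time_expansion_gt2}\n")
        fh.write(f"fraction_time_contraction_gt2={_FLOAT % stats.fraction_time_contraction_gt2}\n")
        fh.write(f"expansions_per_minute={_FLOAT % stats.expansions_per_minute}\n")
        fh.write(f"mean_growth_time_expansion_s={_FLOAT % (np.mean(stats.growth_times_expansion) if stats.growth_times_expansion.size else float('nan'))}\n")
        fh.write(f"mean_growth_time_contraction_s={_FLOAT % (np.mean(stats.growth_times_contraction) if stats.growth_times_contraction.size else float('nan'))}\n")
        fh.write(f"median_ld_high_expansion={_FLOAT % (np.median(stats.ld_high_expansion) if stats.ld_high_expansion.size else float('nan'))}\n")
        fh.write(f"median_ld_high_contraction={_FLOAT % (np.median(stats.ld_high_contraction) if stats.ld_high_contraction.size else float('nan'))}\n")
    created.append(p)

    p = outdir / "growth_times.csv"
    with open(p, "w") as fh:
        fh.write("sign,growth_time_s,total_area_um2\n")
        for gt, ar in zip(stats.growth_times_expansion, stats.areas_expansion):
            fh.write(f"expansion,{_FLOAT % gt},{_FLOAT % ar}\n")
        for gt, ar in zip(stats.growth_times_contraction, stats.areas_contraction):
            fh.write(f"contraction,{_FLOAT % gt},{_FLOAT % ar}\n")
    created.append(p)

    for name in ("ld", "lm", "curv"):
        p = outdir / f"distribution_{name}_high.csv"
        exp = getattr(stats, f"{name}_high_expansion")
        con = getattr(stats, f"{name}_high_contraction")
        with open(p, "w") as fh:
            fh.write("sign,value\n")
            for v in exp:
                fh.write(f"expansion,{_FLOAT % v}\n")
            for v in con:
                fh.write(f"contraction,{_FLOAT % v}\n")
        created.append(p)

    p = outdir / "event_angle_histogram.csv"
    with open(p, "w") as fh:
        fh.write("bin_left_rad,bin_right_rad,count\n")
        for left, right, c in zip(stats.event_angle_bin_edges[:-1],
                                  stats.event_angle_bin_edges[1:],
                                  stats.event_angle_hist):
            fh.write(f"{_FLOAT % left},{_FLOAT % right},{c}\n")
    created.append(p)
    return created
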