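"""End-to-end orchestration: fit -> geometry -> flows -> kymographs -> patterns.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
chains them and persists every artifact, and the CLI subcommands call the same
functions one at a time over the HDF5 container, so composing them manually
reproduces the monolithic run exactly.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import io as cfio
from .geometry import (
    ContourPolyline,
    SmoothContour,
    contour_summary,
    estimate_hyperparameters,
    fit_smooth_contour,
    reparametrize_arclength,
)
from .flow import align_track, compute_global_flow, compute_local_flow
from .kymograph import build_kymograph, smooth_kymograph
from .patterns import (
    activity_thresholds,
    classify_activity,
    detect_events,
    extract_patterns,
    pattern_area_growth,
    pattern_statistics,
)

logger = logging.getLogger("contourflow")

__all__ = ["PipelineConfig", "run_pipeline", "fit_track",
           "compute_kymographs", "detect_patterns"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the standard pipeline."""

    n_markers: int = 400
    lambda_glo: float = 1000.0
    lambda_loc: float = 0.1
    dt: float = 1.0
    gpr_r: float | None = None        # Poisson kernel scale; None = estimate
    gpr_sigma_n: float | None = None  # regression noise level; None = estimate
    sigma_space: float = 3.0          # kymograph smoothing, markers
    sigma_time: float = 1.0           # kymograph smoothing, frames
    min_growth_time: float = 3.0      # s
    percentile: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda_glo > self.lambda_loc > 0):
            raise ValueError("require lambda_glo > lambda_loc > 0")
        for name in ("n_markers", "dt", "sigma_space", "sigma_time",
                     "min_growth_time", "percentile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value text; '#' comments; keys match the field names."""
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in ("n_markers", "seed"):
                    kwargs[key] = int(val)
                elif key in ("gpr_r", "gpr_sigma_n"):
                    kwargs[key] = None if val.lower() == "none" else float(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(asdict(self).items()):
                fh.write(f"{key}={val}\n")


def fit_track(polylines: list[ContourPolyline], config: PipelineConfig
              ) -> list[SmoothContour]:
    """Fit, arc-length reparametrize and phase-align a whole track.

    Hyperparameters are estimated once on the first frame (unless fixed in
    the config) and reused for all frames.
    """
    r, sn = config.gpr_r, config.gpr_sigma_n
    if r is None or sn is None:
        est_r, est_sn = estimate_hyperparameters(polylines[0])
        r = est_r if r is None else r
        sn = est_sn if sn is None else sn
        logger.info("estimated GPR hyperparameters r=%.4f sigma_n=%.3g", r, sn)
    contours = [
        reparametrize_arclength(fit_smooth_contour(pl, r, sn))
        for pl in polylines
    ]
    aligned, _ = align_track(contours)
    return aligned


def compute_kymographs(contours, config: PipelineConfig):
    """Global flow, local flow, and raw + smoothed kymographs of all quantities."""
    gm = compute_global_flow(contours, config.lambda_glo, config.n_markers, config.dt)
    steps = compute_local_flow(contours, config.lambda_loc, config.n_markers, config.dt)
    kymos_raw = {
        q: build_kymograph(contours, q, n_markers=config.n_markers, dt=config.dt,
                           global_markers=gm, local_steps=steps)
        for q in ("local_dispersion", "local_motion", "curvature")
    }
    kymos_smooth = {
        q: smooth_kymograph(k, config.sigma_space, config.sigma_time)
        for q, k in kymos_raw.items()
    }
    return gm, steps, kymos_raw, kymos_smooth


def detect_patterns(contours, gm, steps, kymos_smooth, config: PipelineConfig):
    """Thresholds, labels, patterns with slice areas, events, statistics."""
    ld = kymos_smooth["local_dispersion"]
    thresholds = activity_thresholds(ld, config.percentile)
    labels = classify_activity(ld, thresholds)
    patterns = extract_patterns(labels, config.dt, config.min_growth_time)
    for p in patterns:
        pattern_area_growth(p, contours, gm, steps, config.dt)
    events = detect_events(ld, labels)
    for e in events:
        for p in patterns:
            if (e.frame_row, e.marker_column) in p.cells:
                p.events.append(e)
                break
    centers = np.stack([contour_summary(c).center_of_mass for c in contours])
    stats = pattern_statistics(patterns, kymos_smooth, labels, events,
                               contours, gm, centers, config.dt)
    return thresholds, labels, patterns, events, stats


def run_pipeline(track_path, config: PipelineConfig, outdir) -> Path:
    """Execute the full workflow on a contour-track file.

    Writes the HDF5 container, kymograph matrices (raw and smoothed), the
    pattern catalogue, events, the statistics bundle and the effective
    configuration into ``outdir``.  On a stage failure all partial outputs are
    removed and a stage-tagged error is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    stage = "read"
    try:
        t0 = _time.perf_counter()
        polylines, dt_file, _unit = cfio.read_track(track_path)
        if dt_file != config.dt:
            config = replace(config, dt=dt_file)
        logger.info("stage=read frames=%d dt=%gs elapsed=%.2fs",
                    len(polylines), config.dt, _time.perf_counter() - t0)

        stage = "fit"
        t0 = _time.perf_counter()
        contours = fit_track(polylines, config)
        container = outdir / "track.h5"
        cfio.save_contours(container, contours, mode="w")
        created.append(container)
        logger.info("stage=fit contours=%d elapsed=%.2fs",
                    len(contours), _time.perf_counter() - t0)

        stage = "flow"
        t0 = _time.perf_counter()
        gm, steps, kymos_raw, kymos_smooth = compute_kymographs(contours, config)
        cfio.save_global_flow(container, gm)
        cfio.save_local_flow(container, steps)
        flow_csv = outdir / "local_flow.csv"
        cfio.write_flow_csv(flow_csv, steps)
        created.append(flow_csv)
        n_viol = sum(len(s.violations) for s in steps)
        logger.info("stage=flow steps=%d violations=%d elapsed=%.2fs",
                    len(steps), n_viol, _time.perf_counter() - t0)

        stage = "kymo"
        t0 = _time.perf_counter()
        short = {"local_dispersion": "ld", "local_motion": "lm", "curvature": "curvature"}
        for q, k in kymos_raw.items():
            p = outdir / f"kymograph_{short[q]}.csv"
            cfio.write_kymograph(p, k)
            created.append(p)
            cfio.save_kymograph_h5(container, k, short[q])
        for q, k in kymos_smooth.items():
            p = outdir / f"kymograph_{short[q]}_smoothed.csv"
            cfio.write_kymograph(p, k)
            created.append(p)
            cfio.save_kymograph_h5(container, k, short[q] + "_smoothed")
        logger.info("stage=kymo elapsed=%.2fs", _time.perf_counter() - t0)

        stage = "detect"
        t0 = _time.perf_counter()
        thresholds, labels, patterns, events, stats = detect_patterns(
            contours, gm, steps, kymos_smooth, config)
        cat = outdir / "patterns.csv"
        cfio.write_pattern_catalogue(cat, patterns)
        created.append(cat)
        ev = outdir / "events.csv"
        cfio.write_events(ev, events, gm)
        created.append(ev)
        logger.info("stage=detect patterns=%d events=%d thresholds=(%.4g,%.4g) "
                    "elapsed=%.2fs", len(patterns), len(events),
                    thresholds.c_med, thresholds.c_high, _time.perf_counter() - t0)

        stage = "stats"
        t0 = _time.perf_counter()
        created += cfio.write_statistics(outdir / "statistics", stats)
        cfg_path = outdir / "config.txt"
        config.write(cfg_path)
        created.append(cfg_path)
        logger.info("stage=stats elapsed=%.2fs", _time.perf_counter() - t0)
    except Exception as exc:
        for p in created:
            try:
                Path(p).unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return outdir
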