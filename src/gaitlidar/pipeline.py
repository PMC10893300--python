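"""End-to-end orchestration: scans on disk -> gait parameters on disk.

``run_pipeline`` chains the five stages — scan I/O, sensor alignment,
motion segmentation, leg tracking, gait analysis — under a single validated
configuration, writes every intermediate artifact, and records a manifest
(config hash, seeds, per-stage counts) so a run can be audited and
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment import align_sensors
from .gait_analysis import PeakConfig, analyze_track
from .leg_tracking import track
from .scan_io import read_scans, resample_streams
from .segmentation import estimate_background

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class BackgroundConfig:
    n: int = 200
    seed: int = 0
    threshold: float = 0.5
    closing_radius: float = 0.10


@dataclass
class ClusteringConfig:
    n_clusters: int = 4
    linkage_threshold: float = 0.3
    min_size: int = 5
    max_size: int = 50
    merge_distance: float = 0.25


@dataclass
class GaitConfig:
    median_windows: tuple[int, int] = (5, 9)
    major_prominence: float = 100.0
    minor_prominence: float = 10.0
    valley_threshold: float = 25.0
    min_separation: float = 0.4


@dataclass
class StatsConfig:
    alpha: float = 0.01
    adjustment: str = "bonferroni"


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, validated at construction time."""

    rate: float = 40.0
    cell: float = 0.05
    reference_sensor: str | None = None  # default: first sensor in the file
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        bg = self.background
        if bg.n < 1 or not (0 < bg.threshold <= 1) or bg.closing_radius < 0:
            raise ValueError("invalid background configuration")
        cl = self.clustering
        if cl.n_clusters < 2 or cl.linkage_threshold <= 0:
            raise ValueError("invalid clustering configuration")
        if not (0 < cl.min_size <= cl.max_size):
            raise ValueError("cluster size band must satisfy 0 < min <= max")
        if cl.merge_distance <= 0:
            raise ValueError("merge distance must be positive")
        g = self.gait
        for w in g.median_windows:
            if w < 1 or w % 2 == 0:
                raise ValueError("median filter windows must be odd and >= 1")
        if not (0 < g.minor_prominence < g.major_prominence):
            raise ValueError("need 0 < minor_prominence < major_prominence")
        if g.valley_threshold <= 0 or g.min_separation < 0:
            raise ValueError("invalid peak detector configuration")
        if not (0 < self.stats.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict = {}
        for name, sub in (
            ("background", BackgroundConfig),
            ("clustering", ClusteringConfig),
            ("gait", GaitConfig),
            ("stats", StatsConfig),
        ):
            if name in data:
                payload = dict(data.pop(name))
                if name == "gait" and "median_windows" in payload:
                    payload["median_windows"] = tuple(payload["median_windows"])
                kwargs[name] = sub(**payload)
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(
    scans_path,
    config: PipelineConfig | dict | None = None,
    out_dir=None,
    dialect: str = "csv",
) -> dict:
    """Execute all pipeline stages on a scan file and write results.

    Writes (under ``out_dir``): the per-sensor transforms, the background
    mask, the leg track CSV, the gait events CSV, the parameters JSON and a
    run manifest.  Returns a dict with the in-memory results.  Stage errors
    propagate annotated with the stage name; artifacts of completed stages
    are retained for debugging.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "stages": {},
    }

    def _stage(name, fn):
        try:
            result = fn()
        except Exception as exc:
            if out is not None:
                manifest["stages"][name] = {"error": str(exc)}
                _write_json(out / "manifest.json", manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return result

    streams = _stage("scan_io", lambda: read_scans(scans_path, dialect=dialect))
    manifest["stages"]["scan_io"] = {
        "sensors": sorted(streams),
        "n_scans": {s: len(v) for s, v in streams.items()},
    }

    frames = _stage("resample", lambda: resample_streams(streams, config.rate))
    manifest["stages"]["resample"] = {"n_frames": len(frames)}

    reference = config.reference_sensor or sorted(streams)[0]
    frames, transforms = _stage(
        "alignment",
        lambda: align_sensors(frames, reference, cell=config.cell,
                              seed=config.background.seed),
    )
    manifest["stages"]["alignment"] = {
        "reference": reference,
        "transforms": {s: tf.to_dict() for s, tf in transforms.items()},
    }
    if out is not None:
        _write_json(out / "transforms.json", manifest["stages"]["alignment"])

    bg = config.background
    mask = _stage(
        "segmentation",
        lambda: estimate_background(
            frames, n=bg.n, closing_radius=bg.closing_radius,
            occupancy_threshold=bg.threshold, cell=config.cell, seed=bg.seed,
        ),
    )
    manifest["stages"]["segmentation"] = {
        "n_frames_used": mask.n_frames_used,
        "seed": mask.seed,
        "mask_cells": int(mask.grid.sum()),
    }
    if out is not None:
        np.savetxt(out / "background_mask.txt", mask.grid.astype(int), fmt="%d")
        _write_json(out / "background_mask_meta.json", {
            "origin": list(mask.origin), "cell": mask.cell,
            "n_frames_used": mask.n_frames_used, "seed": mask.seed,
            "threshold": bg.threshold, "closing_radius": bg.closing_radius,
        })

    cl = config.clustering
    leg_track = _stage(
        "leg_tracking",
        lambda: track(
            frames, mask, rate=config.rate,
            n_clusters=cl.n_clusters, linkage_threshold=cl.linkage_threshold,
            min_size=cl.min_size, max_size=cl.max_size,
            merge_distance=cl.merge_distance,
        ),
    )
    manifest["stages"]["leg_tracking"] = {
        "n_frames": len(leg_track.left),
        "n_gaps": len(leg_track.gaps),
        "n_predicted": sum(
            o.provenance == "predicted"
            for o in leg_track.left + leg_track.right
        ),
    }
    if out is not None:
        _write_track_csv(out / "leg_track.csv", leg_track)

    g = config.gait
    peak_cfg = PeakConfig(
        major_prominence=g.major_prominence,
        minor_prominence=g.minor_prominence,
        valley_threshold=g.valley_threshold,
        min_separation=g.min_separation,
    )
    params, events = _stage(
        "gait_analysis",
        lambda: analyze_track(
            leg_track, rate=config.rate,
            windows=g.median_windows, peak_config=peak_cfg,
        ),
    )
    manifest["stages"]["gait_analysis"] = {
        "n_events": len(events),
        "n_steps": params.n_steps,
    }
    if out is not None:
        _write_events_csv(out / "gait_events.csv", events)
        _write_json(out / "gait_parameters.json", {
            "means": params.summary(),
            "step_lengths_cm": params.step_lengths.tolist(),
            "step_times_s": params.step_times.tolist(),
            "stride_lengths_cm": params.stride_lengths.tolist(),
            "stride_times_s": params.stride_times.tolist(),
        })
        _write_json(out / "manifest.json", manifest)

    return {
        "frames": frames,
        "transforms": transforms,
        "mask": mask,
        "track": leg_track,
        "parameters": params,
        "events": events,
        "manifest": manifest,
    }


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_track_csv(path: Path, leg_track) -> None:
    with open(path, "w") as fh:
        fh.write("t,left_x,left_y,left_prov,right_x,right_y,right_prov\n")
        for lo, ro in zip(leg_track.left, leg_track.right):
            fh.write(
                f"{lo.t:.6f},{lo.centroid[0]:.6f},{lo.centroid[1]:.6f},{lo.provenance},"
                f"{ro.centroid[0]:.6f},{ro.centroid[1]:.6f},{ro.provenance}\n"
            )


def _write_events_csv(path: Path, events) -> None:
    with open(path, "w") as fh:
        fh.write("kind,leg,t,x,y\n")
        for e in events:
            if e.position is not None:
                fh.write(f"{e.kind},{e.leg},{e.t:.6f},{e.position[0]:.6f},{e.position[1]:.6f}\n")
            else:
                fh.write(f"{e.kind},{e.leg},{e.t:.6f},,\n")
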