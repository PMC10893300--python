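"""Synthetic lidar recordings of a two-leg walker in a polygonal room.

Every test in this repository runs against this simulator: it ray-casts a
scene of walls, props and two moving leg discs into per-sensor polar scans
(with seeded Gaussian range noise) and exports the exact ground truth —
per-frame leg positions, heel-strike events and the gait parameters they
imply — that the measurement pipeline is expected to recover.

The walker alternates stance and swing.  During stance a leg is pinned at
its foothold apart from a small mid-stance micro-motion bump (the shin
rocking as the ankle bends; this is what the minor-peak detector keys on).
During swing the shin advances to the next foothold with a raised-cosine
speed profile: zero at lift-off and strike, smooth peak mid-swing.
Footholds are laterally offset +/-0.12 m from the walking line.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .gait_analysis import GaitEvent, GaitParameters, compute_parameters
from .scan_io import PolarScan, write_scans

__all__ = [
    "SensorSpec",
    "Scene",
    "WalkerConfig",
    "GroundTruth",
    "WalkerMotion",
    "simulate_walker",
    "raycast",
    "simulate_recording",
    "make_fixture",
    "PRESETS",
    "sensor_to_world",
]

LEG_LATERAL_OFFSET = 0.12  # m, footholds either side of the walking line
LEAD_IN = 0.6              # s of quiet standing before the first swing
REST_HALF_STANCE = 0.175   # m, half the standing stance width before gait onset


@dataclass
class SensorSpec:
    """A planar scanner: pose in world coordinates, field of view, timing."""

    sensor_id: str
    pose: tuple[float, float, float]  # x, y, heading_deg
    fov: float = 270.0                # degrees
    angular_res: float = 0.125        # degrees
    rate: float = 40.0                # Hz
    max_range: float = 20.0           # m
    noise_sd: float = 0.0             # m, Gaussian range noise

    def beam_angles_rad(self) -> np.ndarray:
        """World-frame beam angles, strictly increasing (sensor frame is
        heading-centered: relative angles span +/- fov/2 inclusive)."""
        n = int(round(self.fov / self.angular_res)) + 1
        rel = -self.fov / 2 + self.angular_res * np.arange(n)
        return np.deg2rad(rel)


@dataclass
class Scene:
    walls: list[list[tuple[float, float]]]
    props: list[list[tuple[float, float]]] = field(default_factory=list)
    sensors: list[SensorSpec] = field(default_factory=list)

    def segments(self) -> np.ndarray:
        """All static obstacle segments, shape (n, 2, 2)."""
        segs = []
        for line in self.walls:
            segs.extend(zip(line, line[1:]))
        for poly in self.props:
            closed = list(poly) + [poly[0]]
            segs.extend(zip(closed, closed[1:]))
        return np.array(segs, dtype=float)

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.vstack([np.asarray(w, dtype=float) for w in self.walls])
        return (
            float(pts[:, 0].min()), float(pts[:, 1].min()),
            float(pts[:, 0].max()), float(pts[:, 1].max()),
        )


@dataclass
class WalkerConfig:
    start: tuple[float, float]
    end: tuple[float, float]
    step_length: float = 0.6       # m of forward progress per step
    cadence: float = 105.0         # steps/min
    leg_radius: float = 0.06       # m, shin cross-section at scan height
    stance_fraction: float = 0.6   # of the (two-step) gait cycle
    seed: int = 0
    stance_bump: bool = True       # mid-stance shin micro-motion
    stance_bump_peak: float = 0.45      # m/s, ankle-rollover shin advance
    stance_bump_duration: float = 0.4   # s

    def __post_init__(self) -> None:
        if self.step_length <= 0 or self.cadence <= 0:
            raise ValueError("step_length and cadence must be positive")


@dataclass
class GroundTruth:
    """What the pipeline should recover from a simulated walk."""

    times: np.ndarray
    leg_positions: dict[str, np.ndarray]   # world coordinates, (n, 2) per leg
    strikes: list[GaitEvent]
    parameters: GaitParameters
    config: WalkerConfig

    @property
    def n_steps(self) -> int:
        return len(self.strikes)


@dataclass
class _Segment:
    """One smooth motion piece: raised-cosine travel between two points."""

    t0: float
    t1: float
    p0: np.ndarray
    p1: np.ndarray

    def position(self, t: float) -> np.ndarray:
        phase = (t - self.t0) / (self.t1 - self.t0)
        s = phase - math.sin(2 * math.pi * phase) / (2 * math.pi)
        return self.p0 + s * (self.p1 - self.p0)


class WalkerMotion:
    """Continuous-time position of each leg, assembled from motion segments."""

    def __init__(self, segments: dict[str, list[_Segment]], rest: dict[str, np.ndarray]):
        self._segments = segments
        self._rest = rest  # initial standing position per leg
        self._starts = {
            leg: [s.t0 for s in segs] for leg, segs in segments.items()
        }

    def position(self, leg: str, t: float) -> np.ndarray:
        segs = self._segments[leg]
        i = bisect.bisect_right(self._starts[leg], t) - 1
        if i < 0:
            return self._rest[leg]
        seg = segs[i]
        if t >= seg.t1:
            return seg.p1
        return seg.position(t)

    def sample(self, leg: str, times: np.ndarray) -> np.ndarray:
        return np.array([self.position(leg, t) for t in times])


def _inside_bounds(scene: Scene, p: np.ndarray, margin: float = 0.2) -> bool:
    x0, y0, x1, y1 = scene.bounds()
    return (x0 + margin <= p[0] <= x1 - margin) and (y0 + margin <= p[1] <= y1 - margin)


def simulate_walker(
    scene: Scene, cfg: WalkerConfig
) -> tuple[WalkerMotion, GroundTruth]:
    """Build the walker's leg trajectories and their exact ground truth.

    Heel strike k occurs at ``LEAD_IN + swing + (k-1)*T`` (T = 60/cadence)
    at distance ``k * step_length`` along the line from start to end; legs
    alternate, the right leg swinging first.  The recording nominally ends
    one stance after the last strike; sample times are supplied by the
    sensors during ray casting.
    """
    start = np.asarray(cfg.start, dtype=float)
    end = np.asarray(cfg.end, dtype=float)
    D = float(np.linalg.norm(end - start))
    if D <= cfg.step_length:
        raise ValueError("path shorter than one step")
    u = (end - start) / D
    lateral = np.array([-u[1], u[0]])  # +90 deg: the left side of travel
    if not (_inside_bounds(scene, start) and _inside_bounds(scene, end)):
        raise ValueError("walker path exits the walkable region")

    T = 60.0 / cfg.cadence                      # step time
    cycle = 2 * T
    swing = (1 - cfg.stance_fraction) * cycle   # 0.8 T by default
    n_steps = int(math.floor(D / cfg.step_length + 1e-9))
    if n_steps < 3:
        raise ValueError("path too short for three steps")

    offsets = {"left": +LEG_LATERAL_OFFSET, "right": -LEG_LATERAL_OFFSET}
    def world(dist: float, leg: str) -> np.ndarray:
        return start + dist * u + offsets[leg] * lateral

    strike_times = [LEAD_IN + swing + k * T for k in range(n_steps)]
    strike_legs = ["right" if k % 2 == 0 else "left" for k in range(n_steps)]
    strike_dists = [(k + 1) * cfg.step_length for k in range(n_steps)]
    t_end = strike_times[-1] + cfg.stance_fraction * cycle

    bump_disp = (
        0.5 * cfg.stance_bump_peak * cfg.stance_bump_duration
        if cfg.stance_bump else 0.0
    )

    # before gait onset the walker stands with the feet in a relaxed wide
    # stance: two resting shins at walking width (0.24 m apart) would sit
    # closer than the clustering linkage threshold and merge into one blob
    rest = {
        "left": start + REST_HALF_STANCE * lateral,
        "right": start - REST_HALF_STANCE * lateral,
    }
    segments: dict[str, list[_Segment]] = {"left": [], "right": []}
    current = dict(rest)
    for t_k, leg, dist in zip(strike_times, strike_legs, strike_dists):
        target = world(dist, leg)
        segments[leg].append(_Segment(t_k - swing, t_k, current[leg], target))
        current[leg] = target
        if cfg.stance_bump:
            b0 = t_k + 0.6 * cfg.stance_fraction * cycle - cfg.stance_bump_duration / 2
            b1 = b0 + cfg.stance_bump_duration
            if b1 < t_end:
                bumped = target + bump_disp * u
                segments[leg].append(_Segment(b0, b1, target, bumped))
                current[leg] = bumped

    motion = WalkerMotion(segments, rest)

    strikes = [
        GaitEvent("heel_strike", leg, t_k, position=tuple(world(dist, leg)))
        for t_k, leg, dist in zip(strike_times, strike_legs, strike_dists)
    ]
    rate = scene.sensors[0].rate if scene.sensors else 40.0
    times = np.arange(0.0, t_end + 0.5 / rate, 1.0 / rate)
    truth = GroundTruth(
        times=times,
        leg_positions={leg: motion.sample(leg, times) for leg in ("left", "right")},
        strikes=strikes,
        parameters=compute_parameters(strikes),
        config=cfg,
    )
    return motion, truth


def _ray_segment_ranges(
    origin: np.ndarray, dirs: np.ndarray, segs: np.ndarray
) -> np.ndarray:
    """Per-beam nearest positive hit distance over all segments (inf if none)."""
    best = np.full(dirs.shape[0], np.inf)
    for p, q in segs:
        v = q - p
        w = p - origin
        denom = dirs[:, 0] * v[1] - dirs[:, 1] * v[0]  # d x v
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (w[0] * v[1] - w[1] * v[0]) / denom
            s = (dirs[:, 1] * w[0] - dirs[:, 0] * w[1]) / denom
        ok = (np.abs(denom) > 1e-12) & (t > 1e-9) & (s >= 0.0) & (s <= 1.0)
        best = np.where(ok & (t < best), t, best)
    return best


def _ray_circle_ranges(
    origin: np.ndarray, dirs: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    oc = center - origin
    b = dirs @ oc
    disc = b * b - (oc @ oc - radius * radius)
    with np.errstate(invalid="ignore"):
        t = b - np.sqrt(disc)
    return np.where((disc >= 0) & (t > 1e-9), t, np.inf)


def raycast(
    scene: Scene,
    motion: WalkerMotion | None,
    seed: int = 0,
    duration: float | None = None,
    return_leg_hits: bool = False,
):
    """Ray-cast the scene into per-sensor polar scan streams.

    Each beam returns the nearest intersection among walls, props and the
    two leg discs, plus seeded Gaussian range noise; beams with no hit
    within ``max_range`` are dropped.  With ``return_leg_hits`` a parallel
    per-scan boolean array marks beams whose *noiseless* nearest hit was a
    leg (ground-truth labels for segmentation tests).
    """
    rng = np.random.default_rng(seed)
    segs = scene.segments()
    if duration is None:
        raise ValueError("duration must be given")
    streams: dict[str, list[PolarScan]] = {}
    leg_hits: dict[str, list[np.ndarray]] = {}
    for sensor in scene.sensors:
        x, y, heading = sensor.pose
        origin = np.array([x, y])
        rel = sensor.beam_angles_rad()
        world_angles = rel + np.deg2rad(heading)
        dirs = np.column_stack([np.cos(world_angles), np.sin(world_angles)])
        n_scans = int(math.floor(duration * sensor.rate)) + 1
        scans: list[PolarScan] = []
        hits_list: list[np.ndarray] = []
        static_ranges = _ray_segment_ranges(origin, dirs, segs)
        for j in range(n_scans):
            t = j / sensor.rate
            ranges = static_ranges.copy()
            hit_leg = np.zeros(dirs.shape[0], dtype=bool)
            if motion is not None:
                for leg in ("left", "right"):
                    c = motion.position(leg, t)
                    r_leg = _ray_circle_ranges(
                        origin, dirs, c, _leg_radius(motion, leg)
                    )
                    hit_leg |= r_leg < ranges
                    ranges = np.minimum(ranges, r_leg)
            if sensor.noise_sd > 0:
                ranges = ranges + rng.normal(0.0, sensor.noise_sd, ranges.shape)
            valid = np.isfinite(ranges) & (ranges > 0) & (ranges <= sensor.max_range)
            scans.append(
                PolarScan(
                    sensor.sensor_id, t, rel[valid], ranges[valid],
                    max_range=sensor.max_range,
                )
            )
            hits_list.append(hit_leg[valid])
        streams[sensor.sensor_id] = scans
        leg_hits[sensor.sensor_id] = hits_list
    if return_leg_hits:
        return streams, leg_hits
    return streams


def _leg_radius(motion: WalkerMotion, leg: str) -> float:
    return getattr(motion, "leg_radius", 0.06)


def simulate_recording(
    scene: Scene, cfg: WalkerConfig | None, seed: int = 0, duration: float | None = None
):
    """Simulate a full recording: walker + ray cast.

    Returns ``(streams, truth)``; ``truth`` is ``None`` for a static scene
    (``cfg is None``), in which case ``duration`` must be given.
    """
    if cfg is None:
        if duration is None:
            raise ValueError("static scenes need an explicit duration")
        streams = raycast(scene, None, seed=seed, duration=duration)
        return streams, None
    motion, truth = simulate_walker(scene, cfg)
    motion.leg_radius = cfg.leg_radius
    streams = raycast(scene, motion, seed=seed, duration=float(truth.times[-1]))
    return streams, truth


def sensor_to_world(sensor: SensorSpec):
    """Rigid transform mapping the sensor's local frame to world coordinates."""
    from .alignment import RigidTransform2D

    x, y, heading = sensor.pose
    return RigidTransform2D(np.deg2rad(heading), x, y)


# ---------------------------------------------------------------------------
# Presets

def _rect_room(w: float = 7.0, h: float = 5.0) -> list[list[tuple[float, float]]]:
    return [[(0.0, 0.0), (w, 0.0), (w, h), (0.0, h), (0.0, 0.0)]]


def _square_prop(cx: float, cy: float, half: float):
    return [
        (cx - half, cy - half), (cx + half, cy - half),
        (cx + half, cy + half), (cx - half, cy + half),
    ]


def _straight_walk_scene(noise_sd: float = 0.01) -> Scene:
    """Two sensors on opposite walls (as in a multi-sensor room install):
    when a crossing leg occludes its partner from one side, the other
    sensor still sees it.  The asymmetric props break the 180-degree
    ambiguity of a rectangular room during feature-based alignment."""
    return Scene(
        walls=_rect_room(8.0, 6.0),
        props=[
            _square_prop(0.7, 5.0, 0.30),
            _square_prop(1.6, 0.9, 0.20),
            _square_prop(6.0, 5.0, 0.15),
        ],
        sensors=[
            SensorSpec("s0", (4.0, 0.5, 90.0), noise_sd=noise_sd),
            SensorSpec("s1", (4.0, 5.5, 270.0), noise_sd=noise_sd),
        ],
    )


def _preset_straight_walk(seed: int, **overrides):
    noise = overrides.pop("noise_sd", 0.01)
    scene = _straight_walk_scene(noise)
    cfg = WalkerConfig(
        start=(1.5, 3.0), end=(6.5, 3.0),
        step_length=overrides.pop("step_length", 0.6),
        cadence=overrides.pop("cadence", 105.0),
        seed=seed, **overrides,
    )
    return scene, cfg, None


def _preset_occluded_walk(seed: int, **overrides):
    # deliberately single-sensor so the pillar's shadow actually hides a leg
    noise = overrides.pop("noise_sd", 0.01)
    scene = Scene(
        walls=_rect_room(),
        sensors=[SensorSpec("s0", (3.5, 0.5, 90.0), noise_sd=noise)],
    )
    # A narrow pillar 60% of the way from the sensor to the walking line at
    # x = 1.9 m: its shadow on the line is ~15 cm wide and lies between two
    # footholds (…, 1.6, 2.2, …), so only swinging legs blink out behind it,
    # for roughly three frames each.
    scene.props.append(_square_prop(2.54, 1.70, 0.045))
    cfg = WalkerConfig(
        start=(1.0, 2.5), end=(6.0, 2.5),
        step_length=overrides.pop("step_length", 0.6),
        cadence=overrides.pop("cadence", 110.0),
        seed=seed, **overrides,
    )
    return scene, cfg, None


def _preset_static_room(seed: int, **overrides):
    scene = Scene(
        walls=_rect_room(),
        props=[_square_prop(5.2, 3.8, 0.25), _square_prop(1.5, 1.2, 0.18)],
        sensors=[SensorSpec("s0", (3.5, 0.5, 90.0), noise_sd=overrides.pop("noise_sd", 0.0))],
    )
    return scene, None, overrides.pop("duration", 6.0)


def _two_sensor_scene(noise_sd: float = 0.005) -> Scene:
    """Second sensor posed at 90 degrees and (3, 0) relative to the
    reference; three different-size boxes break the room's symmetry."""
    return Scene(
        walls=_rect_room(8.0, 6.0),
        props=[
            _square_prop(0.7, 5.0, 0.30),
            _square_prop(1.6, 0.9, 0.20),
            _square_prop(6.0, 5.0, 0.15),
        ],
        sensors=[
            SensorSpec("ref", (0.5, 2.5, 0.0), noise_sd=noise_sd),
            SensorSpec("mov", (3.5, 2.5, 90.0), noise_sd=noise_sd),
        ],
    )


def _preset_two_sensor_room(seed: int, **overrides):
    scene = _two_sensor_scene(overrides.pop("noise_sd", 0.005))
    return scene, None, overrides.pop("duration", 3.0)


PRESETS: dict[str, Callable] = {
    "straight_walk": _preset_straight_walk,
    "occluded_walk": _preset_occluded_walk,
    "static_room": _preset_static_room,
    "two_sensor_room": _preset_two_sensor_room,
}


def preset(name: str, seed: int = 0, **overrides):
    """Return ``(scene, walker_cfg_or_None, duration_or_None)`` for a preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](seed, **overrides)


def make_fixture(name: str, out_dir, seed: int = 0, **overrides) -> dict[str, str]:
    """Generate a preset recording and write scan CSV + ground-truth JSON.

    Deterministic under a fixed seed.  Returns the written file paths.
    """
    import os

    scene, cfg, duration = preset(name, seed=seed, **overrides)
    streams, truth = simulate_recording(scene, cfg, seed=seed, duration=duration)
    os.makedirs(out_dir, exist_ok=True)
    scan_path = os.path.join(out_dir, f"{name}_scans.csv")
    write_scans(scan_path, streams, dialect="csv")
    truth_path = os.path.join(out_dir, f"{name}_truth.json")
    payload: dict = {"preset": name, "seed": seed}
    if truth is not None:
        payload["strikes"] = [
            {"leg": s.leg, "t": s.t, "position": list(s.position)}
            for s in truth.strikes
        ]
        payload["parameters"] = truth.parameters.summary()
        payload["config"] = {
            "start": list(truth.config.start), "end": list(truth.config.end),
            "step_length": truth.config.step_length,
            "cadence": truth.config.cadence,
        }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"scans": scan_path, "truth": truth_path}
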