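"""Reading, writing and resampling of planar lidar scans.

A scanner reports, once per revolution, a fan of beams: an angle (in the
sensor's own frame) and a measured range for each beam.  This module parses
those records from plain-text files, converts them to Cartesian point sets
and resamples multi-sensor streams onto one uniform clock so that every
downstream stage can reason about synchronous *frames*.

Angles are radians internally; the file dialects store degrees for
readability.  Timestamps are seconds relative to the start of a recording.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PolarScan",
    "PointSet2D",
    "Frame",
    "read_scans",
    "write_scans",
    "polar_to_cartesian",
    "resample_streams",
]

#: Bracketing ranges that differ by more than this are treated as an
#: occlusion edge; the nearer return is kept instead of interpolating,
#: so that resampling never fabricates phantom mid-air points.
OCCLUSION_JUMP = 0.5


@dataclass
class PolarScan:
    """One revolution of one sensor: strictly increasing angles plus ranges."""

    sensor_id: str
    t: float
    angles: np.ndarray  # radians
    ranges: np.ndarray  # meters
    max_range: float = 20.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.ranges = np.asarray(self.ranges, dtype=float)
        if self.angles.shape != self.ranges.shape:
            raise ValueError("angles and ranges must have the same length")
        if self.angles.size > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("angles must be strictly increasing within a scan")
        if self.ranges.size and (
            np.any(self.ranges <= 0) or np.any(self.ranges > self.max_range)
        ):
            raise ValueError("ranges must lie in (0, max_range]")

    @property
    def n_beams(self) -> int:
        return int(self.angles.size)


@dataclass
class PointSet2D:
    """A timestamped 2D point cloud attributed to one sensor."""

    t: float
    points: np.ndarray  # (n, 2) meters
    sensor_id: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass
class Frame:
    """Time-aligned point sets from all sensors at a single instant."""

    t: float
    points_by_sensor: dict[str, PointSet2D] = field(default_factory=dict)

    def all_points(self) -> np.ndarray:
        """Concatenate every sensor's points into one (n, 2) array."""
        parts = [ps.points for ps in self.points_by_sensor.values() if len(ps)]
        if not parts:
            return np.empty((0, 2))
        return np.vstack(parts)


class ScanParseError(ValueError):
    """A scan file row that cannot be interpreted under the chosen dialect."""


def _build_scan(
    sensor: str,
    t: float,
    angles_deg: Sequence[float],
    ranges_m: Sequence[float],
    max_range: float,
    where: str,
) -> PolarScan:
    ang = np.asarray(angles_deg, dtype=float)
    rng = np.asarray(ranges_m, dtype=float)
    if ang.size != rng.size:
        raise ScanParseError(f"{where}: angle/range count mismatch")
    valid = (rng > 0) & (rng <= max_range) & np.isfinite(rng)
    n_dropped = int(np.sum(~valid))
    if n_dropped:
        logger.info("%s: dropped %d invalid range reading(s)", where, n_dropped)
    ang, rng = ang[valid], rng[valid]
    order = np.argsort(ang)
    ang, rng = ang[order], rng[order]
    if ang.size > 1 and np.any(np.diff(ang) <= 0):
        raise ScanParseError(f"{where}: duplicate beam angles within one scan")
    return PolarScan(sensor, float(t), np.deg2rad(ang), rng, max_range=max_range)


def read_scans(
    path, dialect: str = "csv", max_range: float = 20.0
) -> dict[str, list[PolarScan]]:
    """Read a scan file and return per-sensor scan lists sorted by time.

    Parameters
    ----------
    path : str or Path
        File to read.
    dialect : {"csv", "json"}
        ``csv``: one row per scan, ``sensor,t,angle_deg,range_m,angle_deg,...``.
        ``json``: array of ``{"sensor", "t", "angles_deg", "ranges_m"}``.
    max_range : float
        Readings above this (or non-positive) are dropped with a logged count.
    """
    scans: list[PolarScan] = []
    if dialect == "csv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split(",")
                if len(fields) < 2 or (len(fields) - 2) % 2 != 0:
                    raise ScanParseError(f"{path}:{lineno}: malformed scan row")
                sensor = fields[0].strip()
                try:
                    t = float(fields[1])
                    numbers = [float(x) for x in fields[2:]]
                except ValueError as exc:
                    raise ScanParseError(f"{path}:{lineno}: {exc}") from None
                scans.append(
                    _build_scan(
                        sensor, t, numbers[0::2], numbers[1::2],
                        max_range, f"{path}:{lineno}",
                    )
                )
    elif dialect == "json":
        with open(path) as fh:
            records = json.load(fh)
        for i, rec in enumerate(records):
            scans.append(
                _build_scan(
                    rec["sensor"], rec["t"], rec["angles_deg"], rec["ranges_m"],
                    max_range, f"{path}[{i}]",
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    streams: dict[str, list[PolarScan]] = {}
    for scan in scans:
        streams.setdefault(scan.sensor_id, []).append(scan)
    for sensor, seq in streams.items():
        ts = [s.t for s in seq]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ScanParseError(
                f"non-monotonic timestamps within sensor {sensor!r}"
            )
    return streams


def write_scans(path, streams: Mapping[str, Iterable[PolarScan]], dialect: str = "csv") -> None:
    """Write per-sensor scan streams in the named plain-text dialect."""
    ordered = [s for seq in streams.values() for s in seq]
    ordered.sort(key=lambda s: (s.t, s.sensor_id))
    if dialect == "csv":
        with open(path, "w") as fh:
            for s in ordered:
                pairs = ",".join(
                    f"{a:.6f},{r:.6f}"
                    for a, r in zip(np.rad2deg(s.angles), s.ranges)
                )
                row = f"{s.sensor_id},{s.t:.6f}"
                fh.write(row + ("," + pairs if pairs else "") + "\n")
    elif dialect == "json":
        records = [
            {
                "sensor": s.sensor_id,
                "t": round(s.t, 6),
                "angles_deg": [round(a, 6) for a in np.rad2deg(s.angles)],
                "ranges_m": [round(r, 6) for r in s.ranges],
            }
            for s in ordered
        ]
        with open(path, "w") as fh:
            json.dump(records, fh)
            fh.write("\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def polar_to_cartesian(scan: PolarScan) -> PointSet2D:
    """Convert one polar scan to Cartesian points in the sensor's own frame."""
    x = scan.ranges * np.cos(scan.angles)
    y = scan.ranges * np.sin(scan.angles)
    return PointSet2D(scan.t, np.column_stack([x, y]), scan.sensor_id)


def _angle_grid(scans: Sequence[PolarScan], tol: float = 1e-6) -> np.ndarray:
    """Union of beam angles across scans, merging angles closer than *tol*."""
    allang = np.sort(np.concatenate([s.angles for s in scans]))
    if allang.size == 0:
        return allang
    keep = np.ones(allang.size, dtype=bool)
    keep[1:] = np.diff(allang) > tol
    return allang[keep]


def resample_streams(
    streams: Mapping[str, Sequence[PolarScan]],
    rate: float = 40.0,
) -> list[Frame]:
    """Resample all sensors onto one uniform clock via linear interpolation.

    Interpolation acts per beam (matched by angle) in polar space between the
    two scans bracketing each output instant; the blended ranges are then
    converted to Cartesian points.  Beams missing from either bracketing scan
    are dropped for that frame, and beams whose bracketing ranges differ by
    more than :data:`OCCLUSION_JUMP` take the nearer return.

    The output grid spans the overlap of all sensors' time spans at ``1/rate``
    spacing; an empty overlap is an error.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not streams:
        raise ValueError("need at least one sensor stream")
    for sensor, seq in streams.items():
        if len(seq) < 2:
            raise ValueError(f"sensor {sensor!r}: need at least two scans")

    t0 = max(seq[0].t for seq in streams.values())
    t1 = min(seq[-1].t for seq in streams.values())
    if t1 < t0:
        raise ValueError("sensor streams have no overlapping time interval")
    dt = 1.0 / rate
    n_frames = int(math.floor((t1 - t0) / dt + 1e-9)) + 1
    grid_t = t0 + dt * np.arange(n_frames)

    # Per sensor: a (n_scans, n_beams) range matrix on the union angle grid,
    # NaN where a beam is missing from a scan.
    per_sensor: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for sensor, seq in streams.items():
        grid_a = _angle_grid(seq)
        ts = np.array([s.t for s in seq])
        mat = np.full((len(seq), grid_a.size), np.nan)
        for i, s in enumerate(seq):
            idx = np.searchsorted(grid_a, s.angles)
            idx = np.clip(idx, 0, grid_a.size - 1)
            left_ok = np.abs(grid_a[idx] - s.angles) < 1e-6
            idx_alt = np.clip(idx - 1, 0, grid_a.size - 1)
            use_alt = ~left_ok & (np.abs(grid_a[idx_alt] - s.angles) < 1e-6)
            idx = np.where(use_alt, idx_alt, idx)
            mat[i, idx] = s.ranges
        per_sensor[sensor] = (ts, grid_a, mat)

    frames: list[Frame] = []
    for t in grid_t:
        frame = Frame(float(t))
        for sensor, (ts, grid_a, mat) in per_sensor.items():
            j = int(np.searchsorted(ts, t, side="right") - 1)
            j = min(max(j, 0), len(ts) - 2)
            denom = ts[j + 1] - ts[j]
            w = 0.0 if denom == 0 else (t - ts[j]) / denom
            r0, r1 = mat[j], mat[j + 1]
            both = np.isfinite(r0) & np.isfinite(r1)
            blended = (1 - w) * r0 + w * r1
            # an occlusion edge (a moving object entering/leaving the beam):
            # blending would fabricate a phantom mid-air point, so take the
            # return of the temporally nearer scan instead
            jump = np.abs(r1 - r0) > OCCLUSION_JUMP
            blended = np.where(jump, r0 if w < 0.5 else r1, blended)
            rr = blended[both]
            aa = grid_a[both]
            pts = np.column_stack([rr * np.cos(aa), rr * np.sin(aa)])
            frame.points_by_sensor[sensor] = PointSet2D(float(t), pts, sensor)
        frames.append(frame)
    return frames
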