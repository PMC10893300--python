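"""Spatial alignment of multiple lidar sensors into one reference frame.

Each sensor measures in its own coordinate system.  Because all sensors see
the same static room structure (walls, furniture), a binary raster image of
each sensor's accumulated returns can be matched against the reference
sensor's raster with SIFT features; the matched keypoints, mapped back to
metric coordinates, constrain a 2D rigid transform (rotation + translation,
no scale, no reflection) that is solved in closed form by least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors

from .scan_io import Frame, PointSet2D

logger = logging.getLogger(__name__)

__all__ = [
    "RasterImage",
    "RigidTransform2D",
    "Correspondence",
    "rasterize",
    "find_correspondences",
    "estimate_rigid",
    "align_sensors",
]

DEFAULT_CELL = 0.05  # meters per raster pixel


@dataclass
class RasterImage:
    """Binary occupancy raster of a point cloud.

    ``grid[row, col]`` covers the cell whose center is
    ``origin + cell * (col + 0.5, row + 0.5)`` measured from the cell corner
    convention used throughout: ``origin`` is the (x, y) of the *corner* of
    pixel (0, 0); a point p lands in cell ``floor((p - origin) / cell)``.
    """

    grid: np.ndarray
    origin: tuple[float, float]
    cell: float

    def pixel_to_xy(self, rowcol: np.ndarray) -> np.ndarray:
        """Map (row, col) pixel indices to metric cell-center coordinates."""
        rc = np.asarray(rowcol, dtype=float).reshape(-1, 2)
        x = self.origin[0] + (rc[:, 1] + 0.5) * self.cell
        y = self.origin[1] + (rc[:, 0] + 0.5) * self.cell
        return np.column_stack([x, y])

    def xy_to_pixel(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        col = np.floor((pts[:, 0] - self.origin[0]) / self.cell).astype(int)
        row = np.floor((pts[:, 1] - self.origin[1]) / self.cell).astype(int)
        return np.column_stack([row, col])


@dataclass
class RigidTransform2D:
    """Rotation by ``theta`` about the origin followed by translation."""

    theta: float
    tx: float
    ty: float

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform2D":
        R = self.rotation
        t = -R.T @ self.translation
        return RigidTransform2D(-self.theta, t[0], t[1])

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform equivalent to applying *other* then *self*."""
        theta = self.theta + other.theta
        t = self.rotation @ other.translation + self.translation
        return RigidTransform2D(theta, t[0], t[1])

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)

    def to_dict(self) -> dict:
        return {"theta_rad": self.theta, "tx_m": self.tx, "ty_m": self.ty}


@dataclass
class Correspondence:
    """A matched point pair: ``p`` in the moving frame, ``q`` in the reference."""

    p: tuple[float, float]
    q: tuple[float, float]
    score: float = 0.0


def rasterize(points: np.ndarray, cell: float = DEFAULT_CELL) -> RasterImage:
    """Rasterize a point cloud: a pixel is set iff >= 1 point falls in it."""
    if cell <= 0:
        raise ValueError("cell size must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise ValueError("cannot rasterize an empty point set")
    origin = (float(np.min(pts[:, 0])), float(np.min(pts[:, 1])))
    col = np.floor((pts[:, 0] - origin[0]) / cell).astype(int)
    row = np.floor((pts[:, 1] - origin[1]) / cell).astype(int)
    grid = np.zeros((row.max() + 1, col.max() + 1), dtype=bool)
    grid[row, col] = True
    return RasterImage(grid, origin, cell)


def _sift_features(image: RasterImage, smooth_sigma: float):
    # SIFT needs smooth gradients; a binary raster of thin wall lines is
    # blurred into a float image first.
    img = ndimage.gaussian_filter(image.grid.astype(float), smooth_sigma)
    det = SIFT()
    det.detect_and_extract(img)
    return det.keypoints, det.descriptors


def find_correspondences(
    moving: RasterImage,
    reference: RasterImage,
    top_k: int = 20,
    smooth_sigma: float = 1.5,
    max_ratio: float = 0.85,
) -> list[Correspondence]:
    """Match SIFT keypoints between two rasters, in metric coordinates.

    Returns at most *top_k* correspondences sorted by descending match
    quality (negated descriptor distance).  Fewer than two matches cannot
    constrain a rigid transform and raise ``ValueError``.
    """
    if not moving.grid.any() or not reference.grid.any():
        raise ValueError("cannot match empty raster images")
    kp_m, desc_m = _sift_features(moving, smooth_sigma)
    kp_r, desc_r = _sift_features(reference, smooth_sigma)
    if len(kp_m) < 2 or len(kp_r) < 2:
        raise ValueError("too few keypoints to establish correspondences")
    matches = match_descriptors(
        desc_m, desc_r, cross_check=True, max_ratio=max_ratio
    )
    if matches.shape[0] < 2:
        raise ValueError("fewer than two feature matches between sensors")
    d = np.linalg.norm(
        desc_m[matches[:, 0]].astype(float) - desc_r[matches[:, 1]].astype(float),
        axis=1,
    )
    order = np.argsort(d)[:top_k]
    p_xy = moving.pixel_to_xy(kp_m[matches[order, 0]])
    q_xy = reference.pixel_to_xy(kp_r[matches[order, 1]])
    return [
        Correspondence(tuple(p), tuple(q), score=-float(dist))
        for p, q, dist in zip(p_xy, q_xy, d[order])
    ]


def estimate_rigid(pairs: Sequence[Correspondence]) -> RigidTransform2D:
    """Least-squares proper rigid transform mapping each ``p`` onto ``q``.

    Closed-form solution of the orthogonal Procrustes problem restricted to
    rotations: with centered coordinates, theta = atan2(sum(p x q), sum(p.q)).
    Exact (zero residual) for any noiseless rigid correspondence set.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two correspondence pairs")
    P = np.array([c.p for c in pairs], dtype=float)
    Q = np.array([c.q for c in pairs], dtype=float)
    if np.allclose(P, P[0], atol=1e-12):
        raise ValueError("degenerate configuration: all source points coincide")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # cross = sum p_i x q_i (z component), dot = sum p_i . q_i
    cross = float(np.sum(Pc[:, 0] * Qc[:, 1] - Pc[:, 1] * Qc[:, 0]))
    dot = float(np.sum(Pc[:, 0] * Qc[:, 0] + Pc[:, 1] * Qc[:, 1]))
    theta = np.arctan2(cross, dot)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return RigidTransform2D(float(theta), float(t[0]), float(t[1]))


def _fit_robust(
    pairs: list[Correspondence], tol: float
) -> tuple[RigidTransform2D, float]:
    """Refit after dropping worst-residual pairs until max residual < tol.

    Duplicate source/target keypoints are collapsed first (keeping the best
    score); the loop keeps at least three pairs so the fit stays
    overdetermined, and returns the best fit seen if trimming bottoms out.
    """
    seen: dict[tuple, Correspondence] = {}
    for c in sorted(pairs, key=lambda c: -c.score):
        seen.setdefault((c.p, c.q), c)
    unique: dict[tuple, Correspondence] = {}
    for c in seen.values():
        if c.p not in unique or unique[c.p].score < c.score:
            unique[c.p] = c
    pairs = list(unique.values())
    best: tuple[RigidTransform2D, float] | None = None
    while True:
        tf = estimate_rigid(pairs)
        P = np.array([c.p for c in pairs])
        Q = np.array([c.q for c in pairs])
        res = np.linalg.norm(tf.apply(P) - Q, axis=1)
        if best is None or res.max() < best[1]:
            best = (tf, float(res.max()))
        if res.max() < tol or len(pairs) <= 3:
            return best
        pairs.pop(int(np.argmax(res)))


def align_sensors(
    frames: Sequence[Frame],
    reference_sensor: str,
    cell: float = DEFAULT_CELL,
    n_background_frames: int = 50,
    top_k: int = 20,
    seed: int = 0,
) -> tuple[list[Frame], dict[str, RigidTransform2D]]:
    """Estimate per-sensor rigid transforms and map all frames into the
    reference sensor's coordinate system.

    Rasters are built from the union of ``n_background_frames`` randomly
    sampled frames so that alignment keys on static structure rather than on
    anything moving through the scene.  The reference sensor's transform is
    the identity; all transforms are returned for audit.
    """
    if not frames:
        raise ValueError("no frames to align")
    sensors = list(frames[0].points_by_sensor)
    if reference_sensor not in sensors:
        raise ValueError(f"reference sensor {reference_sensor!r} not present")

    rng = np.random.default_rng(seed)
    n = min(n_background_frames, len(frames))
    sample_idx = rng.choice(len(frames), size=n, replace=False)

    # Union raster of the sampled frames per sensor: static structure is
    # reinforced in every frame while the moving person leaves only a
    # faint smear that the ratio test and the robust refit reject.
    rasters: dict[str, RasterImage] = {}
    for sensor in sensors:
        clouds = [
            frames[i].points_by_sensor[sensor].points
            for i in sample_idx
            if sensor in frames[i].points_by_sensor
            and len(frames[i].points_by_sensor[sensor])
        ]
        if not clouds:
            raise ValueError(f"sensor {sensor!r} has no points to align on")
        rasters[sensor] = rasterize(np.vstack(clouds), cell)

    transforms: dict[str, RigidTransform2D] = {
        reference_sensor: RigidTransform2D.identity()
    }
    ref_raster = rasters[reference_sensor]
    for sensor in sensors:
        if sensor == reference_sensor:
            continue
        try:
            pairs = find_correspondences(rasters[sensor], ref_raster, top_k=top_k)
            tf, max_res = _fit_robust(pairs, tol=2 * cell)
        except ValueError as exc:
            raise ValueError(f"sensor {sensor!r}: {exc}") from exc
        logger.info(
            "sensor %s aligned: theta=%.4f rad t=(%.3f, %.3f) max residual %.3f m",
            sensor, tf.theta, tf.tx, tf.ty, max_res,
        )
        transforms[sensor] = tf

    aligned: list[Frame] = []
    for fr in frames:
        out = Frame(fr.t)
        for sensor, ps in fr.points_by_sensor.items():
            tf = transforms[sensor]
            out.points_by_sensor[sensor] = PointSet2D(
                fr.t, tf.apply(ps.points) if len(ps) else ps.points, sensor
            )
        aligned.append(out)
    return aligned, transforms
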