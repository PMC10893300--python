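"""Motion segmentation via a morphological background mask.

The static scene (walls, furniture) occupies the same raster cells in almost
every frame, while a walking person's legs only transit any given cell
briefly.  Averaging the occupancy of randomly sampled frames therefore
separates the two: cells occupied in at least ``occupancy_threshold`` of the
samples are background.  Morphological closing with a disk bridges the small
gaps between adjacent beam hits along walls.  No initial static (person-free)
recording is required — the mask is always built from the recording itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk

from .scan_io import Frame, PointSet2D

__all__ = ["BackgroundMask", "estimate_background", "classify_frame"]


@dataclass
class BackgroundMask:
    """Binary occupancy grid flagging static-scene cells.

    Geometry follows the raster convention of :mod:`gaitlidar.alignment`:
    a point p lies in cell ``floor((p - origin) / cell)``.
    """

    grid: np.ndarray
    origin: tuple[float, float]
    cell: float
    n_frames_used: int
    seed: int

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean per point: does it intersect the mask?  Points outside
        the raster extent are never background."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        col = np.floor((pts[:, 0] - self.origin[0]) / self.cell).astype(int)
        row = np.floor((pts[:, 1] - self.origin[1]) / self.cell).astype(int)
        inside = (
            (row >= 0)
            & (row < self.grid.shape[0])
            & (col >= 0)
            & (col < self.grid.shape[1])
        )
        out = np.zeros(pts.shape[0], dtype=bool)
        out[inside] = self.grid[row[inside], col[inside]]
        return out


def estimate_background(
    frames: list[Frame],
    n: int = 200,
    closing_radius: float = 0.10,
    occupancy_threshold: float = 0.5,
    cell: float = 0.05,
    seed: int = 0,
) -> BackgroundMask:
    """Build the static background mask from ``n`` randomly chosen frames.

    Per-cell occupancy is the fraction of sampled frames with at least one
    point in the cell; cells at or above ``occupancy_threshold`` are set, and
    the thresholded grid is closed (dilation then erosion) with a disk of
    radius ``closing_radius`` meters.  Sampling is without replacement and
    seeded, so the same seed yields the same mask.
    """
    if not frames:
        raise ValueError("cannot estimate a background from zero frames")
    rng = np.random.default_rng(seed)
    n_used = min(n, len(frames))
    idx = rng.choice(len(frames), size=n_used, replace=False)
    sampled = [frames[i] for i in idx]

    clouds = [f.all_points() for f in sampled]
    occupied = np.vstack([c for c in clouds if c.size])
    if occupied.size == 0:
        raise ValueError("sampled frames contain no points")
    origin = (float(occupied[:, 0].min()), float(occupied[:, 1].min()))
    n_rows = int(np.floor((occupied[:, 1].max() - origin[1]) / cell)) + 1
    n_cols = int(np.floor((occupied[:, 0].max() - origin[0]) / cell)) + 1

    counts = np.zeros((n_rows, n_cols), dtype=np.int32)
    for cloud in clouds:
        if not cloud.size:
            continue
        col = np.floor((cloud[:, 0] - origin[0]) / cell).astype(int)
        row = np.floor((cloud[:, 1] - origin[1]) / cell).astype(int)
        hit = np.zeros_like(counts, dtype=bool)
        hit[row, col] = True
        counts += hit

    grid = counts / n_used >= occupancy_threshold
    radius_px = int(round(closing_radius / cell))
    # union of closings up to the requested radius: digital disks are not
    # nested scalings, so a single closing is not monotone in the radius;
    # the cumulative union restores "larger radius never shrinks the mask"
    closed = grid
    for r in range(1, radius_px + 1):
        closed = closed | closing(grid, disk(r))
    return BackgroundMask(closed, origin, cell, n_used, seed)


def classify_frame(
    frame: Frame, mask: BackgroundMask
) -> tuple[PointSet2D, PointSet2D]:
    """Split a frame into (foreground, background) point sets.

    A point is background iff its containing cell is set in the mask; the
    partition is exhaustive and exclusive.  Sensor attribution is collapsed —
    downstream tracking works on the merged cloud.
    """
    pts = frame.all_points()
    is_bg = mask.contains(pts)
    fg = PointSet2D(frame.t, pts[~is_bg], "merged")
    bg = PointSet2D(frame.t, pts[is_bg], "merged")
    return fg, bg
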