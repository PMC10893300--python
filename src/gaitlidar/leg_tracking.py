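"""Two-leg tracking from foreground lidar returns.

Per frame, foreground points are grouped by agglomerative clustering
(average linkage, Euclidean distance).  Merging stops either when the next
merge would exceed the 0.3 m linkage threshold — roughly the distance
between two legs — or when four clusters remain (one per leg plus two to
absorb noise), whichever binds first.  Implausibly small or large clusters
are discarded.  Three scenarios then yield exactly two shin centroids:

* exactly two clusters: k-means (k=2, seeded at the cluster centroids)
  refines the centroids on the pooled member points;
* fewer than two: the missing leg is predicted from its last known position
  plus the finite-difference displacement of the two preceding frames;
* more than two: the closest centroid pairs are merged (pooled-point
  centroid) while they are within 25 cm — about the maximum diameter of a
  leg — and never below two clusters; if more than two survive, the two
  largest by point count are kept.

Left/right identity is seeded from the walking direction (the leg lying to
the left of the body-center velocity vector is "left") and propagated by
frame-to-frame proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .scan_io import Frame, PointSet2D
from .segmentation import BackgroundMask, classify_frame

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "LegObservation",
    "LegTrack",
    "cluster_frame",
    "resolve_legs",
    "label_legs",
    "track",
]

MAX_PLAUSIBLE_SPEED = 4.0  # m/s between consecutive frames
PREDICTION_CLAMP = 0.10    # max extrapolated displacement per frame, m
MAX_PREDICT_FRAMES = 20    # 0.5 s at 40 Hz: longer streaks end the bout
ACQUIRE_DISTANCE = 1.0     # m: max separation of one person's two shins


@dataclass
class Cluster:
    points: np.ndarray

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class LegObservation:
    t: float
    centroid: np.ndarray
    n_points: int
    provenance: str  # observed | predicted | merged

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class LegTrack:
    """Left/right shin centroid series on a shared timestamp grid."""

    left: list[LegObservation] = field(default_factory=list)
    right: list[LegObservation] = field(default_factory=list)
    gaps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return np.array([o.t for o in self.left])

    @property
    def body_center(self) -> np.ndarray:
        """Midpoint of the two leg centroids per frame, shape (n, 2)."""
        L = np.array([o.centroid for o in self.left])
        R = np.array([o.centroid for o in self.right])
        return 0.5 * (L + R)

    @property
    def direction(self) -> np.ndarray:
        """Per-frame unit vector of body-center motion (previous repeated
        where the center is momentarily still)."""
        bc = self.body_center
        d = np.diff(bc, axis=0)
        out = np.zeros_like(bc)
        last = np.array([1.0, 0.0])
        for i in range(len(bc)):
            if i > 0:
                norm = np.linalg.norm(d[i - 1])
                if norm > 1e-9:
                    last = d[i - 1] / norm
            out[i] = last
        return out

    def positions(self, leg: str) -> np.ndarray:
        obs = self.left if leg == "left" else self.right
        return np.array([o.centroid for o in obs])

    def count_faults(self, rate: float) -> int:
        """Frames whose centroid speed exceeds the plausibility bound."""
        n = 0
        for obs in (self.left, self.right):
            pos = np.array([o.centroid for o in obs])
            if len(pos) > 1:
                speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) * rate
                n += int(np.sum(speed > MAX_PLAUSIBLE_SPEED))
        return n


def cluster_labels(
    points: np.ndarray,
    n_clusters: int = 4,
    linkage_threshold: float = 0.3,
) -> np.ndarray:
    """Average-linkage agglomerative cluster labels for one frame.

    Merging stops at the linkage threshold or when ``n_clusters`` clusters
    remain, whichever binds first: the dendrogram is cut at the threshold
    but never below ``n_clusters`` clusters (when enough points exist).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([1])
    Z = linkage(pts, method="average", metric="euclidean")
    labels = fcluster(Z, t=linkage_threshold, criterion="distance")
    if labels.max() < n_clusters:
        labels = fcluster(Z, t=min(n_clusters, n), criterion="maxclust")
    return labels


def cluster_frame(
    foreground: np.ndarray | PointSet2D,
    n_clusters: int = 4,
    linkage_threshold: float = 0.3,
    min_size: int = 5,
    max_size: int = 50,
) -> list[Cluster]:
    """Agglomerative clustering of one frame's foreground points.

    Labels come from :func:`cluster_labels`; clusters outside the
    ``[min_size, max_size]`` point-count band are discarded as noise.
    """
    pts = foreground.points if isinstance(foreground, PointSet2D) else foreground
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        return []
    labels = cluster_labels(pts, n_clusters, linkage_threshold)
    clusters = [
        Cluster(pts[labels == lab]) for lab in np.unique(labels)
    ]
    return [c for c in clusters if min_size <= c.n_points <= max_size]


def _kmeans_refine(clusters: list[Cluster]) -> list[Cluster]:
    """Scenario A: k-means with k=2 on the pooled points, seeded at the
    agglomerative centroids; deterministic (fixed init, tight tolerance)."""
    pooled = np.vstack([c.points for c in clusters])
    init = np.array([c.centroid for c in clusters])
    km = KMeans(n_clusters=2, init=init, n_init=1, tol=1e-6).fit(pooled)
    return [Cluster(pooled[km.labels_ == k]) for k in range(2)]


def _merge_close(clusters: list[Cluster], merge_distance: float) -> list[Cluster]:
    """Iteratively merge the closest centroid pair while the pair is within
    the merge distance (25 cm, about the maximum diameter of a leg: two
    centroids that close belong to one leg, not two)."""
    clusters = list(clusters)
    while len(clusters) > 1:
        cents = np.array([c.centroid for c in clusters])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > merge_distance:
            break
        merged = Cluster(np.vstack([clusters[i].points, clusters[j].points]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return clusters


def _assign_slots(
    candidates: list[LegObservation], refs: Sequence[np.ndarray]
) -> list[LegObservation]:
    """Order two observations to match the slot reference positions,
    choosing the pairing that minimizes total displacement."""
    c0, c1 = candidates
    p0, p1 = refs
    keep = np.linalg.norm(c0.centroid - p0) + np.linalg.norm(c1.centroid - p1)
    swap = np.linalg.norm(c1.centroid - p0) + np.linalg.norm(c0.centroid - p1)
    return [c0, c1] if keep <= swap else [c1, c0]


def _predict(history: Sequence[Sequence[LegObservation]], slot: int, t: float) -> LegObservation:
    """Last known slot position plus a clamped backward difference.

    The per-frame velocity is averaged over up to three preceding frames:
    a single noisy fix (e.g. a half-occluded sliver of a leg) would
    otherwise be extrapolated verbatim."""
    last = history[-1][slot].centroid
    k = min(3, len(history) - 1)
    if k >= 1:
        step = (last - history[-1 - k][slot].centroid) / k
        norm = np.linalg.norm(step)
        if norm > PREDICTION_CLAMP:
            step = step * (PREDICTION_CLAMP / norm)
    else:
        step = np.zeros(2)
    return LegObservation(t, last + step, 0, "predicted")


def resolve_legs(
    clusters: list[Cluster],
    history: Sequence[Sequence[LegObservation]],
    t: float,
    merge_distance: float = 0.25,
    gate_distance: float = 0.5,
    fusion_distance: float = 0.4,
) -> list[LegObservation] | None:
    """Resolve one frame's clusters into exactly two slot-ordered leg
    observations, or ``None`` when the frame is untrackable (no history and
    fewer than two clusters).

    ``history`` is the list of previously resolved frames, each a pair of
    observations in consistent slot order.  Once a history exists, clusters
    farther than ``gate_distance`` from both previous leg positions are
    residual noise (flickering background leakage) and are ignored: legs
    move a few centimeters per frame, never half a meter.

    All proximity decisions compare against each slot's *predicted* position
    (last known plus the clamped backward difference): during a swing the
    leg moves 10-15 cm per frame, so the extrapolation, not the stale last
    fix, is the right reference when legs pass each other.
    """
    refs = None
    if history:
        refs = [_predict(history, slot, t).centroid for slot in (0, 1)]
    if refs is not None and clusters:
        clusters = [
            c for c in clusters
            if min(np.linalg.norm(c.centroid - refs[0]),
                   np.linalg.norm(c.centroid - refs[1])) <= gate_distance
        ]
    n_raw = len(clusters)
    if n_raw >= 2:
        clusters = _merge_close(clusters, merge_distance)
    if len(clusters) > 2:
        # Scenario C residue: nothing else merges, keep the two largest
        clusters = sorted(clusters, key=lambda c: c.n_points, reverse=True)[:2]
        obs = [LegObservation(t, c.centroid, c.n_points, "merged") for c in clusters]
    elif len(clusters) == 2:
        prov = "merged" if n_raw > 2 else "observed"
        refined = _kmeans_refine(clusters)
        obs = [
            LegObservation(t, c.centroid, c.n_points, prov) for c in refined
        ]
    else:  # 0 or 1 clusters
        if not history:
            return None
        if len(clusters) == 1:
            c = clusters[0]
            d0 = np.linalg.norm(c.centroid - refs[0])
            d1 = np.linalg.norm(c.centroid - refs[1])
            refs_close = np.linalg.norm(refs[0] - refs[1]) <= fusion_distance
            if refs_close and d0 <= fusion_distance and d1 <= fusion_distance:
                # both legs are near the single cluster: they have fused
                # into one blob while passing each other (possible whenever
                # they are within the clustering linkage threshold, plus
                # some prediction slack); the blob centroid is the midpoint
                # of the pair, not either shin, so both legs are carried by
                # prediction until they separate again
                return [_predict(history, 0, t), _predict(history, 1, t)]
            slot = 0 if d0 <= d1 else 1
            pair: list[LegObservation | None] = [None, None]
            pair[slot] = LegObservation(t, c.centroid, c.n_points, "observed")
            pair[1 - slot] = _predict(history, 1 - slot, t)
            return list(pair)  # already slot ordered
        return [_predict(history, 0, t), _predict(history, 1, t)]

    if refs is not None:
        obs = _assign_slots(obs, refs)
    elif (
        np.linalg.norm(obs[0].centroid - obs[1].centroid) > ACQUIRE_DISTANCE
    ):
        # first acquisition: two blobs farther apart than one person's legs
        # can be (e.g. a residual noise cluster at a wall) are not a pair
        return None
    return obs


def label_legs(
    resolved: list[list[LegObservation]],
    min_travel: float = 0.05,
    gaps: list[tuple[float, float]] | None = None,
) -> LegTrack:
    """Name the two tracked slots "left" and "right".

    The initial decision uses the walking direction: once the body center
    (midpoint of the two centroids) has travelled at least ``min_travel``,
    the slot whose offset from the body center has a positive z-component of
    cross(direction, offset) is the left leg.  Slot identity is already
    proximity-consistent across frames, so the naming then holds throughout.
    """
    if len(resolved) < 2:
        raise ValueError("need at least two resolved frames to label legs")
    centers = np.array(
        [0.5 * (pair[0].centroid + pair[1].centroid) for pair in resolved]
    )
    disp = centers - centers[0]
    dist = np.linalg.norm(disp, axis=1)
    idx = int(np.argmax(dist >= min_travel))
    if dist[idx] < min_travel:
        idx = int(np.argmax(dist))  # never moved far; use best available
    if dist[idx] < 1e-9:
        raise ValueError("body center never moved; cannot orient left/right")
    direction = disp[idx] / dist[idx]
    offset = resolved[idx][0].centroid - centers[idx]
    cross_z = direction[0] * offset[1] - direction[1] * offset[0]
    left_slot = 0 if cross_z > 0 else 1
    return LegTrack(
        left=[pair[left_slot] for pair in resolved],
        right=[pair[1 - left_slot] for pair in resolved],
        gaps=list(gaps or []),
    )


def track(
    frames: Sequence[Frame],
    mask: BackgroundMask,
    rate: float = 40.0,
    n_clusters: int = 4,
    linkage_threshold: float = 0.3,
    min_size: int = 5,
    max_size: int = 50,
    merge_distance: float = 0.25,
    max_predict_frames: int = MAX_PREDICT_FRAMES,
) -> LegTrack:
    """Run segmentation + clustering + resolution + labeling over a recording.

    Untrackable leading frames are excluded.  A streak of fully predicted
    frames longer than ``max_predict_frames`` ends the current walking bout:
    the streak is dropped, a gap is recorded, and tracking re-acquires when
    two clusters reappear.  Raises if no frame is trackable at all.
    """
    bouts: list[list[list[LegObservation]]] = []
    gaps: list[tuple[float, float]] = []
    bout: list[list[LegObservation]] = []
    streak = 0  # length of current fully-predicted run

    for frame in frames:
        fg, _ = classify_frame(frame, mask)
        clusters = cluster_frame(
            fg.points, n_clusters, linkage_threshold, min_size, max_size
        )
        pair = resolve_legs(clusters, bout, frame.t, merge_distance)
        if pair is None:
            continue
        if all(o.provenance == "predicted" for o in pair):
            streak += 1
            bout.append(pair)
            if streak > max_predict_frames:
                # the person is gone, not briefly occluded: cut the
                # extrapolated tail and close the walking bout
                gap_start = bout[len(bout) - streak][0].t
                del bout[len(bout) - streak:]
                if bout:
                    gaps.append((gap_start, frame.t))
                    bouts.append(bout)
                logger.warning(
                    "prediction streak > %d frames at t=%.2f s ended the bout",
                    max_predict_frames, frame.t,
                )
                bout, streak = [], 0
        else:
            streak = 0
            bout.append(pair)

    # a recording may end mid-occlusion; unconfirmed extrapolations are cut
    while bout and all(o.provenance == "predicted" for o in bout[-1]):
        bout.pop()
    if bout:
        bouts.append(bout)

    # stitch bouts, keeping slot identity consistent across gaps
    resolved: list[list[LegObservation]] = []
    for b in bouts:
        if resolved:
            prev = resolved[-1]
            keep = (
                np.linalg.norm(b[0][0].centroid - prev[0].centroid)
                + np.linalg.norm(b[0][1].centroid - prev[1].centroid)
            )
            swap = (
                np.linalg.norm(b[0][1].centroid - prev[0].centroid)
                + np.linalg.norm(b[0][0].centroid - prev[1].centroid)
            )
            if swap < keep:
                b = [[p[1], p[0]] for p in b]
        resolved.extend(b)

    if len(resolved) < 2:
        raise ValueError("no trackable frames in recording")
    tr = label_legs(resolved, gaps=gaps)
    n_faults = tr.count_faults(rate)
    if n_faults:
        logger.info("%d frame(s) exceed the %.1f m/s plausibility bound",
                    n_faults, MAX_PLAUSIBLE_SPEED)
    return tr
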