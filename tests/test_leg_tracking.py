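"""Clustering, scenario resolution and left/right labeling."""

import numpy as np
import pytest

import gaitlidar as gl
from gaitlidar.leg_tracking import (
    Cluster,
    LegObservation,
    cluster_frame,
    cluster_labels,
    label_legs,
    resolve_legs,
)
from tests.conftest import run_walk


def blob(center, n=20, sd=0.02, seed=0):
    rng = np.random.default_rng(seed)
    return np.asarray(center) + rng.normal(0, sd, size=(n, 2))


def naive_average_linkage(points, n_clusters=4, threshold=0.3):
    """O(n^3) agglomeration oracle: merge the closest pair (mean pairwise
    distance) while the distance is within the threshold and more than
    ``n_clusters`` clusters remain."""
    clusters = [[i] for i in range(len(points))]
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    while len(clusters) > max(n_clusters, 1):
        best, bi, bj = np.inf, -1, -1
        for i in range(len(clusters)):
            for j in range(i):
                dist = d[np.ix_(clusters[i], clusters[j])].mean()
                if dist < best:
                    best, bi, bj = dist, i, j
        if best > threshold:
            break
        clusters[bj] = clusters[bj] + clusters[bi]
        del clusters[bi]
    return {frozenset(c) for c in clusters}


class TestClusterFrame:
    def test_two_blobs_match_oracle_and_centroids(self):
        pts = np.vstack([blob((0.0, 0.0), seed=1), blob((0.4, 0.0), seed=2)])
        clusters = cluster_frame(pts)
        assert len(clusters) == 2
        cents = sorted(c.centroid[0] for c in clusters)
        assert cents[0] == pytest.approx(0.0, abs=0.01)
        assert cents[1] == pytest.approx(0.4, abs=0.01)

    def test_small_blob_discarded(self):
        assert cluster_frame(blob((0, 0), n=3)) == []

    def test_large_blob_discarded(self):
        # with a single expected cluster the 60-point blob stays whole and
        # is rejected by the size band
        assert cluster_frame(blob((0, 0), n=60), n_clusters=1) == []

    def test_empty_input(self):
        assert cluster_frame(np.empty((0, 2))) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_labels_match_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 41)
        pts = rng.uniform(0, 2, size=(n, 2))
        labels = cluster_labels(pts)
        ours = {
            frozenset(np.flatnonzero(labels == lab)) for lab in np.unique(labels)
        }
        assert ours == naive_average_linkage(pts)


def hist_pair(t, c0, c1):
    return [
        LegObservation(t, np.asarray(c0, dtype=float), 20, "observed"),
        LegObservation(t, np.asarray(c1, dtype=float), 20, "observed"),
    ]


class TestResolveLegs:
    def test_scenario_a_kmeans_fixed_point(self):
        clusters = [Cluster(blob((0, 0), seed=3)), Cluster(blob((0.5, 0), seed=4))]
        obs = resolve_legs(clusters, [], t=0.0)
        assert obs is not None
        cents = sorted(o.centroid[0] for o in obs)
        assert cents[0] == pytest.approx(0.0, abs=0.01)
        assert cents[1] == pytest.approx(0.5, abs=0.01)
        assert all(o.provenance == "observed" for o in obs)

    def test_scenario_b_finite_difference_prediction(self):
        # constant velocity 0.02 m/frame in x for one slot
        history = [
            hist_pair(i * 0.025, (0.02 * i, 0.0), (0.0, 0.5)) for i in range(4)
        ]
        obs = resolve_legs([], history, t=0.1)
        assert obs[0].provenance == "predicted"
        assert obs[0].centroid[0] == pytest.approx(0.08, abs=1e-9)
        assert obs[1].centroid[1] == pytest.approx(0.5, abs=1e-9)

    def test_scenario_c_merges_close_centroids(self):
        clusters = [
            Cluster(blob((0.0, 0.0), seed=5)),
            Cluster(blob((0.08, 0.0), seed=6)),  # 8 cm from the first: same leg
            Cluster(blob((0.5, 0.0), seed=7)),
        ]
        obs = resolve_legs(clusters, [], t=0.0)
        assert len(obs) == 2
        cents = sorted(o.centroid[0] for o in obs)
        assert cents[0] == pytest.approx(0.04, abs=0.02)  # pooled-point centroid
        assert cents[1] == pytest.approx(0.5, abs=0.02)

    def test_untrackable_without_history(self):
        assert resolve_legs([], [], t=0.0) is None
        assert resolve_legs([Cluster(blob((0, 0)))], [], t=0.0) is None

    def test_implausible_pair_rejected_at_acquisition(self):
        clusters = [Cluster(blob((0, 0), seed=8)), Cluster(blob((3, 3), seed=9))]
        assert resolve_legs(clusters, [], t=0.0) is None

    def test_noise_cluster_gated_out_with_history(self):
        history = [hist_pair(0.0, (0.0, 0.0), (0.5, 0.0))]
        clusters = [
            Cluster(blob((0.01, 0.0), seed=10)),
            Cluster(blob((5.0, 5.0), seed=11)),  # background leakage far away
        ]
        obs = resolve_legs(clusters, history, t=0.025)
        assert obs[0].provenance == "observed"
        assert obs[1].provenance == "predicted"  # far blob was not adopted


class TestLabelLegs:
    def test_cross_product_convention(self):
        # walker moving +x with legs at y = +/-0.15: +0.15 is the left leg
        resolved = [
            [
                LegObservation(i * 0.025, (0.05 * i, 0.15), 20, "observed"),
                LegObservation(i * 0.025, (0.05 * i, -0.15), 20, "observed"),
            ]
            for i in range(5)
        ]
        track = label_legs(resolved)
        assert track.left[0].centroid[1] == pytest.approx(0.15)
        assert track.right[0].centroid[1] == pytest.approx(-0.15)

    def test_labels_constant_when_stationary_after_motion(self):
        resolved = [
            hist_pair(i * 0.025, (min(i, 5) * 0.02, 0.15), (min(i, 5) * 0.02, -0.15))
            for i in range(10)
        ]
        track = label_legs(resolved)
        ys = [o.centroid[1] for o in track.left]
        assert all(y == pytest.approx(0.15) for y in ys)

    def test_simulated_walk_zero_label_swaps(self):
        from tests.conftest import swap_frame_count

        scene, cfg, _ = gl.preset("straight_walk", seed=5)
        params, events, track, truth, _ = run_walk(scene, cfg, seed=5)
        assert swap_frame_count(track, truth, scene) == 0


class TestTrack:
    def test_straight_walk_mostly_observed(self, default_walk_run):
        params, events, track, truth, tfs, scene, cfg = default_walk_run
        n = len(track.left) + len(track.right)
        n_pred = sum(
            o.provenance == "predicted" for o in track.left + track.right
        )
        assert n_pred / n <= 0.12  # occlusions during crossings only
        assert len(track.left) == len(track.right)
        assert all(
            lo.t == ro.t for lo, ro in zip(track.left, track.right)
        )

    def test_tracked_centroids_near_truth(self, default_walk_run):
        params, events, track, truth, tfs, scene, cfg = default_walk_run
        s2w = gl.sensor_to_world(scene.sensors[0])
        idx = np.round(np.array(track.t) * 40).astype(int)
        err = []
        for leg in ("left", "right"):
            rec = s2w.apply(track.positions(leg))
            err.append(np.linalg.norm(rec - truth.leg_positions[leg][idx], axis=1))
        assert float(np.mean(err)) <= 0.05

    def test_empty_room_untrackable(self):
        scene, cfg, dur = gl.preset("static_room", seed=0)
        streams, _ = gl.simulate_recording(scene, cfg, seed=0, duration=dur)
        frames = gl.resample_streams(streams, rate=40.0)
        frames, _ = gl.align_sensors(frames, "s0")
        mask = gl.estimate_background(frames, n=200, seed=0)
        with pytest.raises(ValueError, match="no trackable"):
            gl.track(frames, mask)
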