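"""Rasterization, feature matching and rigid-transform estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitlidar as gl
from gaitlidar.alignment import (
    Correspondence,
    RasterImage,
    RigidTransform2D,
    estimate_rigid,
    find_correspondences,
    rasterize,
)

def random_blob_raster(seed=0, n=300, size=6.0, cell=0.05):
    """An asymmetric binary raster with blob structure for SIFT to chew on."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0.5, size - 0.5, size=(8, 2))
    pts = np.vstack([
        c + rng.normal(0, 0.15, size=(n // 8, 2)) for c in centers
    ])
    return rasterize(pts, cell)


class TestRasterize:
    def test_single_point_round_trip(self):
        img = rasterize(np.array([[0.0, 0.0]]), cell=0.05)
        assert img.grid.sum() == 1
        rc = np.argwhere(img.grid)
        back = img.pixel_to_xy(rc)[0]
        assert abs(back[0]) <= 0.025 and abs(back[1]) <= 0.025

    def test_two_points_column_distance(self):
        img = rasterize(np.array([[0.0, 0.0], [1.0, 0.0]]), cell=0.05)
        cols = np.argwhere(img.grid)[:, 1]
        assert abs(cols.max() - cols.min()) == 20

    def test_empty_error(self):
        with pytest.raises(ValueError):
            rasterize(np.empty((0, 2)), cell=0.05)

    def test_bad_cell_error(self):
        with pytest.raises(ValueError):
            rasterize(np.array([[0.0, 0.0]]), cell=0.0)


class TestRigidTransform:
    @settings(max_examples=30, derandomize=True)
    @given(
        theta=st.floats(-np.pi, np.pi),
        tx=st.floats(-10, 10),
        ty=st.floats(-10, 10),
    )
    def test_inverse_and_distance_preservation(self, theta, tx, ty):
        tf = RigidTransform2D(theta, tx, ty)
        pts = np.array([[0.0, 0.0], [1.0, 2.0], [-3.0, 0.5]])
        out = tf.apply(pts)
        # pairwise distances preserved
        for i in range(3):
            for j in range(i):
                assert np.linalg.norm(out[i] - out[j]) == pytest.approx(
                    np.linalg.norm(pts[i] - pts[j]), abs=1e-9
                )
        back = tf.inverse().apply(out)
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestEstimateRigid:
    def test_identity_from_fixed_points(self):
        pairs = [Correspondence((0, 0), (0, 0)), Correspondence((1, 2), (1, 2))]
        tf = estimate_rigid(pairs)
        assert tf.theta == pytest.approx(0.0, abs=1e-12)
        assert tf.tx == pytest.approx(0.0, abs=1e-12)
        assert tf.ty == pytest.approx(0.0, abs=1e-12)

    def test_recovers_forward_generated_transform(self):
        truth = RigidTransform2D(np.deg2rad(30.0), 1.0, 2.0)
        rng = np.random.default_rng(0)
        P = rng.uniform(-3, 3, size=(6, 2))
        Q = truth.apply(P)
        tf = estimate_rigid(
            [Correspondence(tuple(p), tuple(q)) for p, q in zip(P, Q)]
        )
        assert tf.theta == pytest.approx(truth.theta, abs=1e-9)
        assert tf.tx == pytest.approx(truth.tx, abs=1e-9)
        assert tf.ty == pytest.approx(truth.ty, abs=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        truth = RigidTransform2D(0.7, -1.0, 0.5)
        P = rng.uniform(-2, 2, size=(10, 2))
        Q = truth.apply(P) + rng.normal(0, 0.01, size=(10, 2))
        pairs = [Correspondence(tuple(p), tuple(q)) for p, q in zip(P, Q)]
        tf = estimate_rigid(pairs)
        ls_res = np.mean(np.sum((tf.apply(P) - Q) ** 2, axis=1))

        # brute-force oracle: theta grid at 0.001 rad with optimal t per
        # theta.  Compared in mean-squared terms: the grid quantization
        # bound is mean|p|^2 * (step/2)^2 < 1e-6 m^2 at this point scale.
        thetas = np.arange(0.0, 2 * np.pi, 0.001)
        Pc = P - P.mean(axis=0)
        Qc = Q - Q.mean(axis=0)
        c, s = np.cos(thetas), np.sin(thetas)
        px, py = Pc[:, 0][:, None], Pc[:, 1][:, None]
        qx, qy = Qc[:, 0][:, None], Qc[:, 1][:, None]
        rx = c * px - s * py - qx
        ry = s * px + c * py - qy
        res = np.mean(rx**2 + ry**2, axis=0)
        grid_best = res.min()
        assert grid_best >= ls_res - 1e-12
        assert grid_best - ls_res <= 1e-6

    def test_degenerate_error(self):
        pairs = [Correspondence((1, 1), (0, 0)), Correspondence((1, 1), (2, 2))]
        with pytest.raises(ValueError, match="degenerate"):
            estimate_rigid(pairs)


class TestFindCorrespondences:
    def test_self_match_is_identity(self):
        img = random_blob_raster(seed=3)
        pairs = find_correspondences(img, img, top_k=10)
        assert len(pairs) >= 2
        for c in pairs:
            assert np.linalg.norm(np.array(c.p) - np.array(c.q)) < 1e-9

    def test_translated_copy_median_displacement(self):
        img = random_blob_raster(seed=4)
        shifted_grid = np.zeros_like(img.grid)
        shifted_grid[:, 10:] = img.grid[:, :-10]  # shift 10 pixels in +x
        shifted = RasterImage(shifted_grid, img.origin, img.cell)
        pairs = find_correspondences(shifted, img, top_k=20)
        dx = np.median([c.q[0] - c.p[0] for c in pairs])
        assert dx == pytest.approx(-10 * img.cell, abs=img.cell)

    def test_blank_images_error(self):
        blank = RasterImage(np.zeros((50, 50), dtype=bool), (0.0, 0.0), 0.05)
        other = random_blob_raster(seed=5)
        with pytest.raises(ValueError):
            find_correspondences(blank, other)


class TestAlignSensors:
    def test_single_sensor_identity(self):
        scene, cfg, dur = gl.preset("static_room", seed=0)
        streams, _ = gl.simulate_recording(scene, cfg, seed=0, duration=dur)
        frames = gl.resample_streams(streams, rate=40.0)
        aligned, tfs = gl.align_sensors(frames, "s0")
        assert tfs["s0"].theta == 0.0 and tfs["s0"].tx == 0.0
        np.testing.assert_allclose(
            aligned[0].points_by_sensor["s0"].points,
            frames[0].points_by_sensor["s0"].points,
        )

    def test_two_sensor_recovery_and_idempotence(self):
        # second sensor posed at theta=90 deg, t=(3, 0) relative to the
        # reference (poses (0.5,2.5,0) and (3.5,2.5,90) in the preset scene)
        scene, cfg, dur = gl.preset("two_sensor_room", seed=1)
        streams, _ = gl.simulate_recording(scene, cfg, seed=1, duration=dur)
        frames = gl.resample_streams(streams, rate=40.0)
        cell = 0.05
        aligned, tfs = gl.align_sensors(frames, "ref", cell=cell)
        tf = tfs["mov"]
        dtheta = (tf.theta - np.pi / 2 + np.pi) % (2 * np.pi) - np.pi
        assert abs(dtheta) * 3.0 < 2 * cell  # rotation error over a 3 m lever
        assert abs(tf.tx - 3.0) < 2 * cell
        assert abs(tf.ty - 0.0) < 2 * cell
        # idempotence: re-aligning aligned frames yields ~identity
        again, tfs2 = gl.align_sensors(aligned, "ref", cell=cell)
        tf2 = tfs2["mov"]
        assert abs((tf2.theta + np.pi) % (2 * np.pi) - np.pi) * 3.0 < 2 * cell
        assert abs(tf2.tx) < 2 * cell and abs(tf2.ty) < 2 * cell

    def test_alignment_preserves_within_sensor_distances(self):
        scene, cfg, dur = gl.preset("two_sensor_room", seed=2)
        streams, _ = gl.simulate_recording(scene, cfg, seed=2, duration=dur)
        frames = gl.resample_streams(streams, rate=40.0)
        aligned, _ = gl.align_sensors(frames, "ref")
        before = frames[0].points_by_sensor["mov"].points[:50]
        after = aligned[0].points_by_sensor["mov"].points[:50]
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=2)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=2)
        np.testing.assert_allclose(d0, d1, atol=1e-9)
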