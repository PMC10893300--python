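"""Shared fixtures: simulated recordings and full-pipeline runs.

The heavy 20-walk recovery sweep is computed once per session and shared by
the acceptance tests that assert on it.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitlidar as gl


def run_walk(scene, cfg, seed, rate=40.0, duration=None):
    """Run the full measurement pipeline on one simulated recording.

    Returns ``(parameters, events, track, truth, transforms)``.
    """
    streams, truth = gl.simulate_recording(scene, cfg, seed=seed, duration=duration)
    frames = gl.resample_streams(streams, rate=rate)
    frames, transforms = gl.align_sensors(frames, scene.sensors[0].sensor_id)
    mask = gl.estimate_background(frames, n=200, seed=0)
    track = gl.track(frames, mask, rate=rate)
    params, events = gl.analyze_track(track, rate=rate)
    return params, events, track, truth, transforms


def swap_frame_count(track, truth, scene):
    """Frames where pairing tracked-left with true-right fits better than
    the direct pairing: >0 indicates a left/right identity swap."""
    s2w = gl.sensor_to_world(scene.sensors[0])
    Lw = s2w.apply(np.array([o.centroid for o in track.left]))
    Rw = s2w.apply(np.array([o.centroid for o in track.right]))
    rate = scene.sensors[0].rate
    idx = np.round(np.array(track.t) * rate).astype(int)
    tL = truth.leg_positions["left"][idx]
    tR = truth.leg_positions["right"][idx]
    direct = np.linalg.norm(Lw - tL, axis=1) + np.linalg.norm(Rw - tR, axis=1)
    crossed = np.linalg.norm(Lw - tR, axis=1) + np.linalg.norm(Rw - tL, axis=1)
    return int(np.sum(crossed < direct))


@pytest.fixture(scope="session")
def default_walk_run():
    """One straight walk at the default gait, run through the pipeline."""
    scene, cfg, _ = gl.preset("straight_walk", seed=3)
    return run_walk(scene, cfg, seed=3) + (scene, cfg)


@pytest.fixture(scope="session")
def recovery_sweep():
    """Twenty simulated straight walks with step lengths 0.45-0.75 m and
    cadences 90-130 steps/min (seeds 1-20), each run end to end.

    Returns a list of dicts with recovered and true parameter summaries.
    """
    results = []
    for seed in range(1, 21):
        rng = np.random.default_rng(seed)
        step_length = float(rng.uniform(0.45, 0.75))
        cadence = float(rng.uniform(90.0, 130.0))
        scene, cfg, _ = gl.preset(
            "straight_walk", seed=seed, step_length=step_length, cadence=cadence
        )
        params, events, track, truth, _ = run_walk(scene, cfg, seed=seed)
        results.append(
            {
                "seed": seed,
                "step_length": step_length,
                "cadence": cadence,
                "recovered": params.summary(),
                "truth": truth.parameters.summary(),
            }
        )
    return results
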