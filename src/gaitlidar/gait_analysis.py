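"""Velocity profiles, gait events and spatiotemporal gait parameters.

The shin centroid of a walking leg alternates between a near-zero-velocity
stance phase and a high-velocity swing.  The scalar speed series of each leg
is median-filtered twice, then three detectors run over it:

* **major peaks** — the swing of a step (high prominence);
* **minor peaks** — small mid-stance bumps from ankle bending (low
  prominence, between major peaks);
* **valleys** — maximal runs of near-zero speed (stance).

The heel strike of a step is the median timestamp of the valley that follows
a major peak, truncated at the next minor peak when one occurs inside it.
Heel-strike times and positions then give the six classical parameters:
step/stride length, step/stride time, cadence and walking velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .leg_tracking import LegTrack

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityProfile",
    "GaitEvent",
    "GaitParameters",
    "PeakConfig",
    "velocity_profile",
    "filter_profile",
    "detect_events",
    "heel_strikes",
    "compute_parameters",
    "analyze_track",
]


@dataclass
class VelocityProfile:
    """Scalar speed of one leg's centroid, cm/s, on a uniform time grid."""

    leg: str
    t: np.ndarray          # interval midpoints, seconds
    speed: np.ndarray      # cm/s
    filtered: np.ndarray | None = None
    positions: np.ndarray | None = None  # raw centroids at the track grid
    t_track: np.ndarray | None = None


@dataclass
class GaitEvent:
    kind: str  # major_peak | minor_peak | valley | heel_strike
    leg: str
    t: float
    position: tuple[float, float] | None = None
    t_start: float | None = None  # valleys only
    t_end: float | None = None


@dataclass
class PeakConfig:
    """Thresholds of the three hard-coded detectors (cm/s and seconds)."""

    major_prominence: float = 100.0
    minor_prominence: float = 10.0
    valley_threshold: float = 25.0
    min_separation: float = 0.4


@dataclass
class GaitParameters:
    """Per-event series and per-walk means of the six gait parameters."""

    step_lengths: np.ndarray   # cm
    step_times: np.ndarray     # s
    stride_lengths: np.ndarray # cm
    stride_times: np.ndarray   # s
    cadence: float             # steps/min
    velocity: float            # cm/s
    n_steps: int

    @property
    def step_length(self) -> float:
        return float(np.mean(self.step_lengths))

    @property
    def step_time(self) -> float:
        return float(np.mean(self.step_times))

    @property
    def stride_length(self) -> float:
        return float(np.mean(self.stride_lengths))

    @property
    def stride_time(self) -> float:
        return float(np.mean(self.stride_times))

    def summary(self) -> dict[str, float]:
        return {
            "step_length_cm": self.step_length,
            "step_time_s": self.step_time,
            "stride_length_cm": self.stride_length,
            "stride_time_s": self.stride_time,
            "cadence_spm": self.cadence,
            "velocity_cms": self.velocity,
            "n_steps": self.n_steps,
        }


def velocity_profile(track: LegTrack, rate: float = 40.0) -> tuple[VelocityProfile, VelocityProfile]:
    """Finite-difference speed (cm/s) of each leg's centroid series."""
    profiles = []
    for leg in ("left", "right"):
        pos = track.positions(leg)
        t = track.t
        if len(pos) < 2:
            raise ValueError("need at least two frames for a velocity profile")
        speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) * rate * 100.0
        mid_t = 0.5 * (t[:-1] + t[1:])
        profiles.append(
            VelocityProfile(leg, mid_t, speed, positions=pos, t_track=t)
        )
    return profiles[0], profiles[1]


def filter_profile(
    profile: VelocityProfile, windows: tuple[int, int] = (5, 9)
) -> VelocityProfile:
    """Apply the two outlier-removing median filters (reflected edges)."""
    for w in windows:
        if w < 1 or w % 2 == 0:
            raise ValueError("median filter windows must be odd and >= 1")
    filtered = profile.speed
    for w in windows:
        filtered = median_filter(filtered, size=w, mode="reflect")
    profile.filtered = filtered
    return profile


def detect_events(
    profile: VelocityProfile, params: PeakConfig | None = None, rate: float = 40.0
) -> list[GaitEvent]:
    """Find major peaks, minor peaks and valleys in a filtered profile."""
    params = params or PeakConfig()
    if profile.filtered is None:
        raise ValueError("profile must be filtered before event detection")
    v = profile.filtered
    t = profile.t
    events: list[GaitEvent] = []

    distance = max(1, int(round(params.min_separation * rate)))
    majors, _ = find_peaks(v, prominence=params.major_prominence, distance=distance)
    for i in majors:
        events.append(GaitEvent("major_peak", profile.leg, float(t[i])))

    if len(majors):
        first_major = majors[0]
        minor_idx, props = find_peaks(v, prominence=params.minor_prominence)
        for i, prom in zip(minor_idx, props["prominences"]):
            if prom >= params.major_prominence or i in majors:
                continue
            if i > first_major:
                events.append(GaitEvent("minor_peak", profile.leg, float(t[i])))

    below = v <= params.valley_threshold
    if below.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
        for start, stop in zip(edges[0::2], edges[1::2]):
            mid = _median_time(t[start:stop])
            events.append(
                GaitEvent(
                    "valley", profile.leg, mid,
                    t_start=float(t[start]), t_end=float(t[stop - 1]),
                )
            )

    events.sort(key=lambda e: e.t)
    return events


def _median_time(times: np.ndarray) -> float:
    return float(np.median(times))


def heel_strikes(
    events: list[GaitEvent], profile: VelocityProfile
) -> list[GaitEvent]:
    """Locate heel strikes: the median point of the valley that follows each
    major peak, truncated at the first minor peak inside the valley.

    Every swing (major peak) contributes at most one heel strike — the
    first valley opening after it and before the next swing of the same
    leg — so a stance valley fragmented by mid-stance micro-motion never
    yields duplicate strikes, and a valley with no preceding major peak
    (initial standing) yields none.
    """
    majors = [e for e in events if e.kind == "major_peak"]
    minors = [e for e in events if e.kind == "minor_peak"]
    valleys = sorted(
        (e for e in events if e.kind == "valley"), key=lambda e: e.t_start
    )
    strikes: list[GaitEvent] = []
    for i, major in enumerate(majors):
        t_next_major = majors[i + 1].t if i + 1 < len(majors) else np.inf
        valley = next(
            (
                v for v in valleys
                if v.t_start > major.t and v.t_start < t_next_major
            ),
            None,
        )
        if valley is None:
            continue
        t_end = valley.t_end
        inside = [m.t for m in minors if valley.t_start <= m.t <= valley.t_end]
        if inside:
            t_end = min(inside)
        mask = (profile.t >= valley.t_start) & (profile.t < t_end)
        if not mask.any():
            mask = (profile.t >= valley.t_start) & (profile.t <= t_end)
        if not mask.any():
            continue
        t_strike = _median_time(profile.t[mask])
        pos = _position_at(profile, t_strike)
        strikes.append(
            GaitEvent("heel_strike", profile.leg, t_strike, position=tuple(pos))
        )
    return strikes


def _position_at(profile: VelocityProfile, t: float) -> np.ndarray:
    """Raw (unfiltered) centroid at time t, linearly interpolated."""
    tt = profile.t_track
    pos = profile.positions
    x = np.interp(t, tt, pos[:, 0])
    y = np.interp(t, tt, pos[:, 1])
    return np.array([x, y])


def compute_parameters(strikes: list[GaitEvent]) -> GaitParameters:
    """Compute the six spatiotemporal gait parameters from heel strikes.

    step  = consecutive heel strikes of contralateral legs;
    stride = consecutive heel strikes of the same leg;
    cadence = (n_steps - 1) / elapsed * 60;
    velocity = path length between first and last strike / elapsed * 100.
    Non-alternating consecutive strike pairs are skipped for the step
    metrics (and logged).
    """
    strikes = sorted(strikes, key=lambda e: e.t)
    if len(strikes) < 3:
        raise ValueError("walk too short: need at least three heel strikes")
    pos = np.array([s.position for s in strikes])
    t = np.array([s.t for s in strikes])

    step_lengths, step_times = [], []
    n_skipped = 0
    for a, b in zip(strikes, strikes[1:]):
        if a.leg == b.leg:
            n_skipped += 1
            continue
        step_lengths.append(
            float(np.linalg.norm(np.array(b.position) - np.array(a.position))) * 100
        )
        step_times.append(b.t - a.t)
    if n_skipped:
        logger.warning("%d non-alternating strike pair(s) skipped", n_skipped)

    stride_lengths, stride_times = [], []
    for leg in ("left", "right"):
        own = [s for s in strikes if s.leg == leg]
        for a, b in zip(own, own[1:]):
            stride_lengths.append(
                float(np.linalg.norm(np.array(b.position) - np.array(a.position))) * 100
            )
            stride_times.append(b.t - a.t)

    elapsed = t[-1] - t[0]
    cadence = (len(strikes) - 1) / elapsed * 60.0
    path = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    velocity = path / elapsed * 100.0
    return GaitParameters(
        step_lengths=np.array(step_lengths),
        step_times=np.array(step_times),
        stride_lengths=np.array(stride_lengths),
        stride_times=np.array(stride_times),
        cadence=float(cadence),
        velocity=float(velocity),
        n_steps=len(strikes),
    )


def analyze_track(
    track: LegTrack,
    rate: float = 40.0,
    windows: tuple[int, int] = (5, 9),
    peak_config: PeakConfig | None = None,
) -> tuple[GaitParameters, list[GaitEvent]]:
    """Full gait analysis of a leg track: profiles -> events -> parameters."""
    left, right = velocity_profile(track, rate)
    all_events: list[GaitEvent] = []
    all_strikes: list[GaitEvent] = []
    for profile in (left, right):
        filter_profile(profile, windows)
        events = detect_events(profile, peak_config, rate)
        strikes = heel_strikes(events, profile)
        all_events.extend(events)
        all_strikes.extend(strikes)
    all_events.extend(all_strikes)
    all_events.sort(key=lambda e: e.t)
    params = compute_parameters(all_strikes)
    return params, all_events
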