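"""Core data containers shared across the pipeline.

Coordinate convention (fixed throughout the package): image origin top-left,
x rightward, y downward; angles in degrees, clockwise-positive in image
coordinates; heading 0 deg along +x.  With y pointing down, a clockwise
rotation is a *positive* mathematical angle, so ``atan2(dy, dx)`` already
returns clockwise-positive angles and no sign flip is needed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def wrap_angle(a):
    """Wrap angle(s) in degrees to [-180, 180)."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


@dataclass
class BehaviorSession:
    """Synchronized kinematic time series of one free-swimming fish.

    ``body_centroid`` is in mm (arena coordinates), angles in degrees,
    ``tail_segment_angles`` has shape (n_samples, 8).
    """

    time: np.ndarray
    body_centroid: np.ndarray            # (n, 2) mm
    heading: np.ndarray                  # (n,) deg
    left_eye_angle: np.ndarray           # (n,) deg, clockwise-positive
    right_eye_angle: np.ndarray
    tail_segment_angles: np.ndarray      # (n, 8) deg
    sampling_rate: float
    px_per_mm: float = 24.8

    @property
    def vergence(self) -> np.ndarray:
        """Ocular vergence, left minus right eye angle (deg)."""
        return self.left_eye_angle - self.right_eye_angle

    @property
    def cumulative_tail_angle(self) -> np.ndarray:
        """Sum of the 8 inter-segment angles; rightward bending positive."""
        return self.tail_segment_angles.sum(axis=1)

    def eyes_center(self, eye_offset_mm: float = 0.1) -> np.ndarray:
        """Mid-point between the eye centroids, offset forward of the body centroid."""
        h = np.deg2rad(self.heading)
        u = np.stack([np.cos(h), np.sin(h)], axis=1)
        return self.body_centroid + eye_offset_mm * u

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class PreyTruth:
    """Ground-truth prey paths at the low (full-frame) rate; positions in mm."""

    time: np.ndarray                     # (m,)
    positions: np.ndarray                # (m, n_prey, 2) mm
    rate: float

    @property
    def n_prey(self) -> int:
        return self.positions.shape[1]

    def position_at(self, prey_id: int, t) -> np.ndarray:
        """Linear interpolation of one prey path to arbitrary time(s)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x = np.interp(t, self.time, self.positions[:, prey_id, 0])
        y = np.interp(t, self.time, self.positions[:, prey_id, 1])
        out = np.stack([x, y], axis=-1)
        return out[0] if out.shape[0] == 1 else out


@dataclass
class GroundTruthLog:
    """Generator-side record of routines, bouts, escapes and capture events."""

    routines: pd.DataFrame   # onset, offset, target_id, outcome, n_bouts
    bouts: pd.DataFrame      # onset, offset, routine_id, displacement, turn, distance_gain, orientation_gain
    events: pd.DataFrame     # epoch_id, event ('ram'|'suction'|'ingestion'), time
    escapes: pd.DataFrame    # onset, peak_speed


@dataclass
class PreyTracks:
    """Linked prey detections: one row per (frame, detection)."""

    table: pd.DataFrame      # frame, time, x, y, track_id

    def __post_init__(self) -> None:
        self._cache: dict = {}

    @property
    def track_ids(self) -> np.ndarray:
        return np.unique(self.table["track_id"].to_numpy())

    def track(self, track_id: int) -> pd.DataFrame:
        return self.table[self.table["track_id"] == track_id]

    def _arrays(self, track_id: int):
        hit = self._cache.get(track_id)
        if hit is None:
            tr = self.track(track_id)
            hit = (tr["time"].to_numpy(), tr["x"].to_numpy(), tr["y"].to_numpy())
            self._cache[track_id] = hit
        return hit

    def position_at(self, track_id: int, t: float) -> np.ndarray | None:
        """Linearly interpolated position of one track at time ``t``.

        Returns None if the track is not alive at ``t``.
        """
        times, x, y = self._arrays(track_id)
        if len(times) == 0 or t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            return None
        return np.array([np.interp(t, times, x), np.interp(t, times, y)])


@dataclass
class FrameStack:
    """Grayscale video frames with uniform shape and increasing timestamps."""

    frames: np.ndarray       # (n_frames, h, w) uint8
    timestamps: np.ndarray   # (n_frames,) s
    px_per_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps):
            raise ValueError("frames and timestamps length mismatch")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(xy_mm) - self.origin_mm) * self.px_per_mm

    def to_mm(self, xy_px: np.ndarray) -> np.ndarray:
        return np.asarray(xy_px) / self.px_per_mm + self.origin_mm


@dataclass
class ActivityMatrix:
    """Z-scored fluorescence per ROI per imaging frame."""

    F: np.ndarray            # (n_rois, n_frames) z-scored
    frame_times: np.ndarray  # (n_frames,) s
    rois: pd.DataFrame       # roi_id, region, side; optional flat flag

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))


@dataclass
class TrialTable:
    """Stimulus epochs, GO/NO-GO labels and convergence events."""

    stimuli: pd.DataFrame      # stim_id, type, onset, offset, go (bool, NaN where n/a)
    convergences: pd.DataFrame # time, side ('left'|'right'), spontaneous (bool), stim_id (-1 spont)
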