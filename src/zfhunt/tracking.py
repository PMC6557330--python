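"""Fish pose, tail and prey extraction from video frames; prey track linking.

Frames are background-subtracted against a continuously updated (exponential
moving average) background model; the body is the largest in-range blob
above a threshold, eyes come from a second, stricter threshold constrained
to lie near the body centroid, and orientations come from intensity-weighted
second central moments, with the 180-degree heading ambiguity resolved by
the third-moment skew along the body axis (a larva's thin tail makes the
mass distribution skew-negative along the heading direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .config import TrackingConfig
from .containers import PreyTracks, wrap_angle


# --------------------------------------------------------------------------
# background model

@dataclass
class BackgroundModel:
    background: np.ndarray
    update_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.update_rate <= 1.0:
            raise ValueError("update_rate must be in (0, 1]")
        self.background = np.asarray(self.background, dtype=float)


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """Exponential moving average update; returns the updated model."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.background.shape:
        raise ValueError(f"frame shape {frame.shape} != model {model.background.shape}")
    a = model.update_rate
    return BackgroundModel(background=(1 - a) * model.background + a * frame,
                           update_rate=a)


# --------------------------------------------------------------------------
# fish pose

@dataclass
class FishPose:
    body_centroid: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    heading: float = np.nan
    left_eye_angle: float = np.nan
    right_eye_angle: float = np.nan
    tail_points: np.ndarray | None = None     # (9, 2) px
    tail_segment_angles: np.ndarray | None = None  # (8,) deg
    valid: bool = False


def _weighted_moments(weights: np.ndarray, ys: np.ndarray, xs: np.ndarray):
    """Centroid, orientation (deg, cw-positive) and axis skew of a weighted blob."""
    w = weights.astype(float)
    total = w.sum()
    cx = (w * xs).sum() / total
    cy = (w * ys).sum() / total
    dx, dy = xs - cx, ys - cy
    mu20 = (w * dx * dx).sum() / total
    mu02 = (w * dy * dy).sum() / total
    mu11 = (w * dx * dy).sum() / total
    # principal axis; atan2 form handles mu20 == mu02
    angle = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    return (cx, cy), angle, (dx, dy, w, total)


def _axis_skew(moment_ctx, angle_deg: float) -> float:
    dx, dy, w, total = moment_ctx
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    u = c * dx + s * dy
    return float((w * u**3).sum() / total)


def detect_fish(frame: np.ndarray, model: BackgroundModel,
                config: TrackingConfig | None = None) -> FishPose:
    """Locate the fish and measure heading and eye angles in one frame.

    Returns an invalid pose (``valid=False``) rather than raising when no
    in-range body blob is found or fewer than two eye candidates survive.
    """
    config = config or TrackingConfig()
    diff = model.background - np.asarray(frame, dtype=float)
    body_mask = diff > config.body_threshold
    labels = measure.label(body_mask)
    best = None
    lo, hi = config.body_area_limits
    for region in measure.regionprops(labels):
        if lo <= region.area <= hi and (best is None or region.area > best.area):
            best = region
    if best is None:
        return FishPose()
    ys, xs = best.coords[:, 0], best.coords[:, 1]
    # weights above threshold: down-weights anti-aliased edges for sub-pixel
    # centroids and stable orientations
    (cx, cy), axis, ctx = _weighted_moments(
        diff[ys, xs] - config.body_threshold, ys, xs)
    # heading: the thin tail side has the long (negative) tail of the mass
    # distribution, so the skew along the heading direction is negative
    heading = axis if _axis_skew(ctx, axis) < 0 else wrap_angle(axis + 180.0)

    # eyes: stricter threshold, near the body centroid
    eye_mask = diff > config.eye_threshold
    eye_labels = measure.label(eye_mask)
    cands = []
    elo, ehi = config.eye_area_limits
    for region in measure.regionprops(eye_labels):
        if not elo <= region.area <= ehi:
            continue
        ey, ex = region.centroid
        if np.hypot(ex - cx, ey - cy) <= config.eye_search_radius_px:
            cands.append(region)
    if len(cands) < 2:
        return FishPose(body_centroid=np.array([cx, cy]), heading=float(heading))
    cands.sort(key=lambda r: r.area, reverse=True)
    eyes = cands[:2]

    hrad = np.deg2rad(heading)
    hvec = np.array([np.cos(hrad), np.sin(hrad)])
    results = {}
    for region in eyes:
        ys_e, xs_e = region.coords[:, 0], region.coords[:, 1]
        (ex, ey), eaxis, _ = _weighted_moments(
            diff[ys_e, xs_e] - config.eye_threshold, ys_e, xs_e)
        # eye orientation is defined mod 180; take the representative
        # within +-90 deg of the heading
        rel = wrap_angle(eaxis - heading)
        if rel > 90:
            rel -= 180.0
        elif rel < -90:
            rel += 180.0
        off = np.array([ex - cx, ey - cy])
        # cross product sign: positive => clockwise of heading => fish's right
        cross = hvec[0] * off[1] - hvec[1] * off[0]
        results["right" if cross > 0 else "left"] = rel
    if set(results) != {"left", "right"}:
        return FishPose(body_centroid=np.array([cx, cy]), heading=float(heading))
    return FishPose(body_centroid=np.array([cx, cy]), heading=float(heading),
                    left_eye_angle=float(results["left"]),
                    right_eye_angle=float(results["right"]), valid=True)


# --------------------------------------------------------------------------
# tail tracing

def trace_tail(frame: np.ndarray, pose: FishPose, model: BackgroundModel,
               config: TrackingConfig | None = None,
               step_px: float | None = None):
    """Annular line-scan tail tracer.

    Starting at the body centroid and progressing tailward, finds at each of
    9 radii the darkest point along an arc centered on the previous point
    and restricted to a forward sector around the previous segment
    direction.  Returns (9 tail points, 8 inter-segment angles); rightward
    bending is positive.  Invalid poses propagate; points whose arc leaves
    the frame are marked NaN.
    """
    config = config or TrackingConfig()
    if not np.isfinite(pose.heading):
        return None, None
    if step_px is None:
        step_px = 3.0 * 24.8 / 9.0  # default tail length 3 mm at 24.8 px/mm
    diff = model.background - np.asarray(frame, dtype=float)
    h, w = diff.shape
    pts = np.full((config.tail_n_points, 2), np.nan)
    n_seg = config.tail_n_points - 1
    angles = np.full(n_seg, np.nan)
    prev = np.asarray(pose.body_centroid, dtype=float)
    direction = pose.heading + 180.0
    arc = np.arange(-config.tail_sector_deg, config.tail_sector_deg + 0.25, 0.25)
    directions = []
    for i in range(config.tail_n_points):
        thetas = np.deg2rad(direction + arc)
        px = prev[0] + step_px * np.cos(thetas)
        py = prev[1] + step_px * np.sin(thetas)
        ok = (px >= 0) & (px <= w - 1) & (py >= 0) & (py <= h - 1)
        if ok.sum() < 5:
            break
        vals = ndimage.map_coordinates(diff, [py[ok], px[ok]], order=1)
        sub_arc = arc[ok]
        vmax = vals.max()
        if vmax < 5.0:
            best_off = 0.0  # nothing dark ahead: continue straight
        else:
            # sub-degree localization: intensity-weighted mean angle of the
            # dark profile (handles both a narrow tail stroke and the wide
            # plateau where the arc crosses the body)
            wgt = np.clip(vals - 0.5 * vmax, 0.0, None)
            best_off = float((wgt * sub_arc).sum() / wgt.sum())
        direction = direction + best_off
        th = np.deg2rad(direction)
        prev = prev + step_px * np.array([np.cos(th), np.sin(th)])
        pts[i] = prev
        directions.append(direction)
    # inter-segment angles: bending toward the fish's right is positive,
    # i.e. a clockwise-negative rotation of successive segment directions
    for i in range(1, len(directions)):
        angles[i - 1] = wrap_angle(directions[i - 1] - directions[i])
    return pts, angles


# --------------------------------------------------------------------------
# prey detection and linking

def detect_prey(frame: np.ndarray, model: BackgroundModel,
                config: TrackingConfig | None = None) -> np.ndarray:
    """Detect prey as local maxima of the inverted, Gaussian-smoothed frame.

    Dark prey become peaks on the background-subtracted image; smoothing
    uses the configured sigma (7 px at 24.8 px/mm).  Returns (n, 2) sub-pixel
    centers as (x, y); an empty frame yields an empty array.
    """
    config = config or TrackingConfig()
    diff = model.background - np.asarray(frame, dtype=float)
    sm = ndimage.gaussian_filter(diff, config.prey_sigma_px)
    mx = ndimage.maximum_filter(sm, size=5, mode="nearest")
    # band-pass on peak value: the fish blob smooths to peaks far above any
    # prey-sized particle and is rejected by the upper bound
    peaks = (sm == mx) & (sm > config.prey_min_prominence) \
        & (sm < config.prey_max_value)
    ys, xs = np.nonzero(peaks)
    out = []
    h, w = sm.shape
    for y, x in zip(ys, xs):
        sx, sy = float(x), float(y)
        if 0 < x < w - 1:
            d = sm[y, x - 1] - 2 * sm[y, x] + sm[y, x + 1]
            if d != 0:
                sx += np.clip(0.5 * (sm[y, x - 1] - sm[y, x + 1]) / d, -1, 1)
        if 0 < y < h - 1:
            d = sm[y - 1, x] - 2 * sm[y, x] + sm[y + 1, x]
            if d != 0:
                sy += np.clip(0.5 * (sm[y - 1, x] - sm[y + 1, x]) / d, -1, 1)
        out.append((sx, sy))
    return np.array(out).reshape(-1, 2)


def link_tracks(detections: list[np.ndarray],
                max_link_distance: float | None = None,
                gap_frames: int | None = None,
                timestamps: np.ndarray | None = None) -> PreyTracks:
    """Frame-by-frame minimum-cost (Hungarian) linking of detections.

    Per frame pair, the assignment minimizes total Euclidean cost among
    links no longer than ``max_link_distance``; unmatched detections start
    new tracks and tracks unmatched for more than ``gap_frames`` frames are
    closed.
    """
    cfg = TrackingConfig()
    if max_link_distance is None:
        max_link_distance = cfg.max_link_distance_px
    if gap_frames is None:
        gap_frames = cfg.gap_frames
    if timestamps is None:
        timestamps = np.arange(len(detections), dtype=float)

    rows = []
    next_id = 0
    # active tracks: id -> (last_position, last_frame)
    active: dict[int, tuple[np.ndarray, int]] = {}
    for f, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        ids = list(active)
        assigned = {}
        if len(ids) and len(dets):
            prev = np.array([active[i][0] for i in ids])
            cost = np.linalg.norm(prev[:, None, :] - dets[None, :, :], axis=2)
            # forbid over-distance links but keep the matrix feasible
            big = 1e9
            cost = np.where(cost <= max_link_distance, cost, big)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] < big:
                    assigned[c] = ids[r]
        for c, (x, y) in enumerate(dets):
            tid = assigned.get(c)
            if tid is None:
                tid = next_id
                next_id += 1
            active[tid] = (np.array([x, y]), f)
            rows.append(dict(frame=f, time=float(timestamps[f]), x=x, y=y,
                             track_id=tid))
        # close stale tracks
        for tid in [t for t, (_, lf) in active.items() if f - lf > gap_frames]:
            del active[tid]
    table = pd.DataFrame(rows, columns=["frame", "time", "x", "y", "track_id"])
    return PreyTracks(table=table)
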