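"""Render grayscale video frames from simulated fish and prey state.

Contrast polarity matches IR darkfield-style acquisition as used by the
tracker: fish and prey are dark on a light background.  Shapes are drawn
with ~1 px anti-aliased edges so that intensity-weighted centroids and
moment-based orientations recover the ground-truth pose to sub-pixel /
sub-degree accuracy.

The rendered fish is a compound of an elongated body ellipse, a broad head
ellipse carrying two dark eye ellipses, and a faint tail stroke.  The body
ellipse is shifted backward by a numerically solved offset so that the
threshold-weighted centroid of the compound blob (body + head + eyes)
coincides with the nominal body centroid, and the compact head/eye mass in
front of the spread-out body gives the blob the negative along-axis skew a
real larva has (thin tail trailing the heading direction), which is what
the pose detector uses to resolve the 180-degree heading ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..containers import BehaviorSession, FrameStack, PreyTruth


_SHIFT_CACHE: dict = {}


@dataclass
class RenderParams:
    mode: str = "full"              # 'full' (arena) or 'crop' (fish-centered)
    px_per_mm: float = 24.8
    crop_size_mm: float = 7.25      # side of the fish-centered window
    background: float = 200.0
    body_depth: float = 70.0           # translucent body, light gray
    eye_depth: float = 180.0           # heavily pigmented eyes, near black
    tail_depth: float = 35.0
    prey_depth: float = 50.0   # translucent paramecia, much lighter than the fish
    body_ab_mm: tuple[float, float] = (0.65, 0.20)   # semi-axes
    head_ab_mm: tuple[float, float] = (0.28, 0.24)   # broad head under the eyes
    body_back_mm: float = 0.55         # body center behind the eyes-center
    head_back_mm: float = 0.13         # head center behind the eyes-center
    eye_ab_mm: tuple[float, float] = (0.30, 0.11)
    eye_lateral_mm: float = 0.18       # eye centers sit at the eyes-center line
    eye_edge_px: float = 2.0           # soft eye edge for sub-pixel moments
    tail_length_mm: float = 3.0
    tail_width_px: float = 1.5
    prey_sigma_mm: float = 0.1
    body_threshold_ref: float = 40.0   # tracker body threshold the offset assumes

    def blob_offset_mm(self) -> float:
        """Distance from the eyes-center back to the compound blob's
        threshold-weighted centroid (the tracker's "body centroid").

        Measured once on a fine raster and cached; the renderer then anchors
        the whole fish so the blob centroid lands exactly on the session's
        nominal body centroid.
        """
        key = (self.body_ab_mm, self.head_ab_mm, self.body_back_mm,
               self.head_back_mm, self.eye_ab_mm, self.eye_lateral_mm,
               self.body_depth, self.eye_depth, self.body_threshold_ref,
               self.px_per_mm)
        if key in _SHIFT_CACHE:
            return _SHIFT_CACHE[key]
        scale = self.px_per_mm * 4.0
        half = self.body_back_mm + 2 * self.body_ab_mm[0]
        n = int(np.ceil(2 * half * scale)) | 1
        c0 = np.array([n / 2.0, n / 2.0])   # the eyes-center
        depth = np.zeros((n, n))
        _draw_fish_shapes(depth, c0, np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                          0.0, 0.0, 0.0, self, scale)
        w = depth - self.body_threshold_ref
        mask = w > 0
        xs = np.nonzero(mask)[1].astype(float)
        off = (c0[0] - (w[mask] * xs).sum() / w[mask].sum()) / scale
        _SHIFT_CACHE[key] = off
        return off


def _draw_fish_shapes(depth_map, eyes_c, u, v, hd, left_eye, right_eye,
                      params, s):
    """Body, head and eyes anchored at the eyes-center ``eyes_c`` (px)."""
    _draw_ellipse(depth_map, eyes_c - params.body_back_mm * s * u,
                  (params.body_ab_mm[0] * s, params.body_ab_mm[1] * s),
                  hd, params.body_depth, profile="dome")
    _draw_ellipse(depth_map, eyes_c - params.head_back_mm * s * u,
                  (params.head_ab_mm[0] * s, params.head_ab_mm[1] * s),
                  hd, params.body_depth, profile="dome")
    for sign, ang in ((-1.0, left_eye), (+1.0, right_eye)):
        ec = eyes_c + sign * params.eye_lateral_mm * s * v
        _draw_ellipse(depth_map, ec,
                      (params.eye_ab_mm[0] * s, params.eye_ab_mm[1] * s),
                      hd + ang, params.eye_depth, params.eye_edge_px,
                      profile="gauss")


def _rot(deg: float) -> np.ndarray:
    """Rotation matrix; positive angle is clockwise in image (y-down) coords."""
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s], [s, c]])


def _draw_ellipse(depth_map, center_px, ab_px, angle_deg, depth, edge_px=1.0,
                  profile="flat"):
    a, b = ab_px
    pad = int(np.ceil(max(a, b))) + 3 + int(np.ceil(edge_px))
    cx, cy = center_px
    h, w = depth_map.shape
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    r = _rot(-angle_deg)
    u = r[0, 0] * dx + r[0, 1] * dy
    v = r[1, 0] * dx + r[1, 1] * dy
    dn2 = (u / a) ** 2 + (v / b) ** 2
    if profile == "dome":
        # graded profile, darkest along the midline ridge
        cov = np.clip(1.0 - dn2, 0.0, 1.0)
    elif profile == "gauss":
        # anisotropic Gaussian: smooth everywhere, so intensity-weighted
        # moments localize center and orientation with sub-pixel precision
        cov = np.exp(-2.0 * dn2)
    else:
        cov = np.clip(0.5 - (np.sqrt(dn2) - 1.0) * b / edge_px, 0.0, 1.0)
    patch = depth_map[y0:y1, x0:x1]
    np.maximum(patch, depth * cov, out=patch)


def _draw_gaussian(depth_map, center_px, sigma_px, depth):
    pad = int(np.ceil(4 * sigma_px)) + 1
    cx, cy = center_px
    h, w = depth_map.shape
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    r2 = (xs - cx) ** 2 + (ys - cy) ** 2
    patch = depth_map[y0:y1, x0:x1]
    np.maximum(patch, depth * np.exp(-r2 / (2 * sigma_px**2)), out=patch)


def tail_points_from_angles(centroid_mm, heading_deg, segment_angles_deg,
                            tail_length_mm: float = 3.0) -> np.ndarray:
    """Ground-truth tail polyline (centroid + 9 points, mm) from 8 angles.

    The first segment leaves the centroid along the tailward axis
    (heading + 180); each of the 8 inter-segment angles then bends the next
    segment, rightward-positive (a positive angle rotates the segment
    direction by minus that angle in clockwise-positive image coordinates,
    which displaces the tail toward the fish's right).
    """
    seg = tail_length_mm / 9.0
    pts = [np.asarray(centroid_mm, dtype=float)]
    direction = heading_deg + 180.0
    d = np.deg2rad(direction)
    pts.append(pts[-1] + seg * np.array([np.cos(d), np.sin(d)]))
    cum = 0.0
    for i in range(8):
        cum += segment_angles_deg[i]
        d = np.deg2rad(direction - cum)
        pts.append(pts[-1] + seg * np.array([np.cos(d), np.sin(d)]))
    return np.array(pts)


def _draw_tail(depth_map, pts_px, width_px, depth):
    # stroke the polyline with a Gaussian profile, compositing by max
    for i in range(len(pts_px) - 1):
        p0, p1 = pts_px[i], pts_px[i + 1]
        npts = max(2, int(np.ceil(np.hypot(*(p1 - p0)) / 0.5)))
        for f in np.linspace(0, 1, npts, endpoint=(i == len(pts_px) - 2)):
            _draw_gaussian(depth_map, p0 + f * (p1 - p0), width_px, depth)


def render_tail_scene(shape, origin_mm, params: RenderParams, centroid_mm,
                      heading_deg, segment_angles_deg) -> np.ndarray:
    """Render only a tail polyline (no body): isolates the annular tracer
    from body-blob occlusion for quantitative curvature checks."""
    depth_map = np.zeros(shape)
    pts = tail_points_from_angles(np.asarray(centroid_mm), heading_deg,
                                  segment_angles_deg, params.tail_length_mm)
    _draw_tail(depth_map, (pts - np.asarray(origin_mm)) * params.px_per_mm,
               params.tail_width_px, params.tail_depth)
    return np.clip(np.rint(params.background - depth_map), 0, 255).astype(np.uint8)


def draw_scene(shape, origin_mm, params: RenderParams,
               fish: dict | None = None,
               prey_mm: np.ndarray | None = None) -> np.ndarray:
    """Render one frame.  ``fish`` holds centroid (mm), heading, left/right
    eye angles (deg) and optionally tail_segment_angles (8,)."""
    depth_map = np.zeros(shape)
    s = params.px_per_mm
    if fish is not None:
        c = (np.asarray(fish["centroid"]) - origin_mm) * s
        hd = fish["heading"]
        u = np.array([np.cos(np.deg2rad(hd)), np.sin(np.deg2rad(hd))])
        v = _rot(90.0) @ u   # fish's right
        tail = fish.get("tail_segment_angles")
        if tail is not None:
            pts = tail_points_from_angles(np.asarray(fish["centroid"]), hd, tail,
                                          params.tail_length_mm)
            _draw_tail(depth_map, (pts - origin_mm) * s, params.tail_width_px,
                       params.tail_depth)
        eyes_c = c + params.blob_offset_mm() * s * u
        _draw_fish_shapes(depth_map, eyes_c, u, v, hd,
                          fish["left_eye"], fish["right_eye"], params, s)
    if prey_mm is not None and len(prey_mm):
        for p in np.atleast_2d(prey_mm):
            _draw_gaussian(depth_map, (np.asarray(p) - origin_mm) * s,
                           params.prey_sigma_mm * s, params.prey_depth)
    frame = np.clip(np.rint(params.background - depth_map), 0, 255).astype(np.uint8)
    return frame


def render_frames(session: BehaviorSession, prey: PreyTruth | None,
                  params: RenderParams | None = None,
                  frame_indices: np.ndarray | None = None,
                  arena_diameter_mm: float = 35.0) -> FrameStack:
    """Render a frame stack from simulated state.

    ``mode='full'``: whole-arena frames at the prey (low) frame rate.
    ``mode='crop'``: fish-centered windows at the kinematic (high) rate,
    with a per-frame origin recorded in the stack.
    """
    params = params or RenderParams(px_per_mm=session.px_per_mm)
    s = params.px_per_mm
    if params.mode == "full":
        side = int(np.ceil(arena_diameter_mm * s))
        times = prey.time if prey is not None else session.time
        if frame_indices is None:
            frame_indices = np.arange(len(times))
        origin = np.zeros(2)
        frames = np.empty((len(frame_indices), side, side), dtype=np.uint8)
        for j, i in enumerate(frame_indices):
            t = times[i]
            k = int(np.clip(round(t * session.sampling_rate), 0, len(session) - 1))
            fish = dict(centroid=session.body_centroid[k], heading=session.heading[k],
                        left_eye=session.left_eye_angle[k],
                        right_eye=session.right_eye_angle[k],
                        tail_segment_angles=session.tail_segment_angles[k])
            pm = prey.positions[i] if prey is not None else None
            frames[j] = draw_scene((side, side), origin, params, fish, pm)
        return FrameStack(frames=frames, timestamps=np.asarray(times)[frame_indices],
                          px_per_mm=s, origin_mm=origin)
    if params.mode == "crop":
        side = int(np.ceil(params.crop_size_mm * s))
        if side < int(2 * params.body_ab_mm[0] * s) + 4:
            raise ValueError("crop view smaller than the fish")
        if frame_indices is None:
            frame_indices = np.arange(len(session))
        frames = np.empty((len(frame_indices), side, side), dtype=np.uint8)
        origins = np.empty((len(frame_indices), 2))
        half = params.crop_size_mm / 2.0
        for j, i in enumerate(frame_indices):
            origins[j] = session.body_centroid[i] - half
            fish = dict(centroid=session.body_centroid[i], heading=session.heading[i],
                        left_eye=session.left_eye_angle[i],
                        right_eye=session.right_eye_angle[i],
                        tail_segment_angles=session.tail_segment_angles[i])
            pm = None
            if prey is not None and prey.n_prey:
                t = session.time[i]
                pm = np.array([prey.position_at(k, t) for k in range(prey.n_prey)])
                inside = np.all(np.abs(pm - session.body_centroid[i]) < half + 0.5, axis=1)
                pm = pm[inside]
            frames[j] = draw_scene((side, side), origins[j], params, fish, pm)
        return FrameStack(frames=frames,
                          timestamps=session.time[frame_indices],
                          px_per_mm=s, origin_mm=origins)
    raise ValueError(f"unknown render mode: {params.mode}")
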