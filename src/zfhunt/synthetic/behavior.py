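"""Synthetic free-swimming hunting sessions with complete ground truth.

The generator emulates the statistical structure the downstream analyses
assume: bout-structured locomotion in a circular dish, a bimodal eye-vergence
distribution with convergence episodes marking hunting routines, Brownian
(Ornstein-Uhlenbeck velocity) prey motion, and per-bout pursuit gains that
are exact by construction.  Hunting routines satisfy the target criterion
(initial range <= 6 mm, |azimuth| <= 120 deg, first two bouts positive-gain)
by construction; aborted routines optionally end in a bout with negative
distance- and orientation-gain followed by vergence relaxation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import BehaviorSimConfig
from ..containers import BehaviorSession, GroundTruthLog, PreyTruth, wrap_angle

OUTCOMES = (
    "abort",
    "attempt-ram-success",
    "attempt-ram-fail",
    "attempt-suction-success",
    "attempt-suction-fail",
)


def sample_routine_outcomes(
    n: int, config: BehaviorSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw routine outcome labels and negative-gain-bout flags.

    This is the single outcome model used both by :func:`simulate_session`
    and by fast cohort-level sampling (ethogram power analyses).
    """
    abort = rng.random(n) < config.p_abort
    ram = rng.random(n) < config.p_ram_given_attempt
    success = rng.random(n) < config.p_success_given_attempt
    labels = []
    for a, r, s in zip(abort, ram, success):
        if a:
            labels.append("abort")
        else:
            kind = "ram" if r else "suction"
            labels.append(f"attempt-{kind}-{'success' if s else 'fail'}")
    p_neg = np.where(abort, config.p_negative_gain_abort, config.p_negative_gain_attempt)
    neg = rng.random(n) < p_neg
    return pd.DataFrame({"outcome": labels, "negative_gain_bout": neg})


def _simulate_prey(config: BehaviorSimConfig, rng: np.random.Generator) -> PreyTruth:
    """OU-velocity prey paths in a circular arena, sampled at the low rate."""
    n_frames = int(round(config.duration * config.rate_lo)) + 1
    t = np.arange(n_frames) / config.rate_lo
    n = config.n_prey
    radius = config.arena_diameter / 2.0 - 0.5
    if n == 0:
        return PreyTruth(time=t, positions=np.zeros((n_frames, 0, 2)), rate=config.rate_lo)
    # stationary per-axis SD such that mean speed ~= prey_speed
    sd = config.prey_speed / np.sqrt(np.pi / 2.0)
    dt = 1.0 / config.rate_lo
    rho = np.exp(-dt / config.prey_tau)
    kick = sd * np.sqrt(1.0 - rho**2)
    # uniform initial positions in the disc
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    vel = rng.normal(0.0, sd, (n, 2))
    out = np.empty((n_frames, n, 2))
    out[0] = pos
    center_offset = config.arena_diameter / 2.0
    for k in range(1, n_frames):
        vel = rho * vel + kick * rng.normal(0.0, 1.0, (n, 2))
        pos = pos + vel * dt
        # reflect at the dish wall
        dist = np.hypot(pos[:, 0], pos[:, 1])
        outside = dist > radius
        if np.any(outside):
            unit = pos[outside] / dist[outside, None]
            pos[outside] = unit * (2 * radius - dist[outside, None])
            v_rad = (vel[outside] * unit).sum(axis=1, keepdims=True)
            vel[outside] -= 2 * v_rad * unit
        out[k] = pos
    out += center_offset  # arena coordinates with dish center at (R, R)
    return PreyTruth(time=t, positions=out, rate=config.rate_lo)


def _raised_cosine(phase: np.ndarray) -> np.ndarray:
    """Cumulative raised-cosine displacement profile on phase in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(phase, 0.0, 1.0)))


def _smooth_noise(n: int, sd: float, rng: np.random.Generator, alpha: float = 0.05) -> np.ndarray:
    """AR(1)-filtered Gaussian noise with stationary SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter
    w = rng.normal(0.0, 1.0, n)
    out = lfilter([alpha], [1.0, -(1.0 - alpha)], w)
    out *= sd / np.sqrt(alpha / (2 - alpha))
    return out


class _FishState:
    """Eyes-center position (mm) and heading (deg); body centroid derived."""

    def __init__(self, pos, heading, eye_offset):
        self.pos = np.asarray(pos, dtype=float)
        self.heading = float(heading)
        self.eye_offset = eye_offset

    def body(self, pos=None, heading=None):
        pos = self.pos if pos is None else pos
        heading = self.heading if heading is None else heading
        h = np.deg2rad(heading)
        return pos - self.eye_offset * np.array([np.cos(h), np.sin(h)])


def simulate_session(
    config: BehaviorSimConfig,
) -> tuple[BehaviorSession, PreyTruth, GroundTruthLog]:
    """Simulate one free-swimming session.

    Returns the kinematic series at ``rate_hi``, prey paths at ``rate_lo``,
    and a complete ground-truth log of routines, bouts, capture events and
    escapes.  A single seed fans out to independent per-subsystem generators
    (prey, fish trajectory, eyes/tail noise) so each can be re-simulated.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_prey, rng_fish, rng_noise = [np.random.default_rng(s) for s in ss.spawn(3)]

    prey = _simulate_prey(config, rng_prey)

    n = int(round(config.duration * config.rate_hi)) + 1
    t = np.arange(n) / config.rate_hi
    dt = 1.0 / config.rate_hi
    radius = config.arena_diameter / 2.0 - 1.5
    center = np.array([config.arena_diameter / 2.0] * 2)

    pos = np.empty((n, 2))
    heading = np.empty(n)
    cumtail = np.zeros(n)
    verg_delta = np.zeros(n)      # vergence elevation above baseline, 0..1
    verg_side = np.zeros(n)       # +1 left-dominant, -1 right-dominant

    r0 = 0.5 * radius * np.sqrt(rng_fish.random())
    th0 = rng_fish.uniform(0, 2 * np.pi)
    fish = _FishState(center + [r0 * np.cos(th0), r0 * np.sin(th0)],
                      rng_fish.uniform(-180, 180), config.eye_offset_mm)
    pos[:] = fish.pos
    heading[:] = fish.heading

    routines: list[dict] = []
    bouts: list[dict] = []
    events: list[dict] = []
    escapes: list[dict] = []

    def idx(time_s: float) -> int:
        return int(np.clip(round(time_s * config.rate_hi), 0, n - 1))

    def fill_state(i0: int) -> None:
        """Hold current fish state from sample i0 onward (overwritten later)."""
        pos[i0:] = fish.pos
        heading[i0:] = fish.heading

    def write_bout_motion(t0: float, t1: float, p0, h0, p1, h1, peak_vel_deg_s: float):
        """Raised-cosine translation + turn, plus a tail-beat burst."""
        i0, i1 = idx(t0), idx(t1)
        if i1 <= i0:
            i1 = min(i0 + 1, n - 1)
        phase = (t[i0:i1 + 1] - t0) / (t1 - t0)
        prof = _raised_cosine(phase)
        pos[i0:i1 + 1] = np.asarray(p0) + prof[:, None] * (np.asarray(p1) - np.asarray(p0))
        dh = wrap_angle(h1 - h0)
        heading[i0:i1 + 1] = h0 + prof * dh
        # tail burst: sinusoidal beats under a Hann envelope
        amp = peak_vel_deg_s / (2 * np.pi * config.tail_beat_hz)
        tt = t[i0:i1 + 1] - t0
        env = np.sin(np.pi * np.clip(tt / (t1 - t0), 0, 1)) ** 2
        cumtail[i0:i1 + 1] += amp * np.sin(2 * np.pi * config.tail_beat_hz * tt) * env

    def spontaneous_bout(t0: float) -> float:
        """One exploratory bout; returns its end time."""
        t1 = t0 + config.bout_duration
        disp = rng_fish.uniform(0.5, 1.5)
        turn = rng_fish.normal(0.0, 30.0)
        h1 = fish.heading + turn
        # steer back toward the center when close to the wall
        to_center = center - fish.pos
        if np.hypot(*to_center) > radius - 3.0:
            h1 = np.degrees(np.arctan2(to_center[1], to_center[0])) + rng_fish.normal(0, 15)
            turn = wrap_angle(h1 - fish.heading)
        hr = np.deg2rad(h1)
        p1 = fish.pos + disp * np.array([np.cos(hr), np.sin(hr)])
        if np.hypot(*(p1 - center)) > radius:
            p1 = fish.pos  # stay put rather than leave the dish
        write_bout_motion(t0, t1, fish.pos, fish.heading, p1, h1,
                          rng_fish.uniform(1500, 3000))
        bouts.append(dict(onset=t0, offset=t1, routine_id=-1,
                          displacement=float(np.hypot(*(p1 - fish.pos))),
                          turn=float(wrap_angle(h1 - fish.heading)),
                          distance_gain=np.nan, orientation_gain=np.nan))
        fish.pos, fish.heading = p1, wrap_angle(h1)
        fill_state(idx(t1))
        return t1

    def escape_event(t0: float) -> float:
        peak = rng_fish.uniform(120, 160)
        dur = 0.1
        t1 = t0 + dur
        h1 = fish.heading + rng_fish.uniform(-120, 120)
        to_center = center - fish.pos
        if np.hypot(*to_center) > radius - 8.0:
            h1 = np.degrees(np.arctan2(to_center[1], to_center[0]))
        disp = peak * dur / 2.0  # mean of raised-cosine speed profile
        hr = np.deg2rad(h1)
        p1 = fish.pos + disp * np.array([np.cos(hr), np.sin(hr)])
        if np.hypot(*(p1 - center)) > radius:
            p1 = center + (p1 - center) / np.hypot(*(p1 - center)) * radius
        write_bout_motion(t0, t1, fish.pos, fish.heading, p1, h1, 5000.0)
        escapes.append(dict(onset=t0, peak_speed=float(peak)))
        fish.pos, fish.heading = p1, wrap_angle(h1)
        fill_state(idx(t1))
        return t1

    def hunting_routine(t0: float, outcome: str, neg_gain: bool) -> float | None:
        """Build one routine starting at t0; returns end time, or None if no
        prey satisfies the reactive-perceptive-field criterion."""
        cand = []
        for k in range(prey.n_prey):
            p = prey.position_at(k, t0)
            d = np.hypot(*(p - fish.pos))
            az = wrap_angle(np.degrees(np.arctan2(p[1] - fish.pos[1],
                                                  p[0] - fish.pos[0])) - fish.heading)
            if d <= 5.5 and abs(az) <= 110.0 and d >= 1.0:
                cand.append((d, k, az))
        if not cand:
            return None
        cand.sort()
        _, target, az0 = cand[0]
        side = "left" if az0 > 0 else "right"  # eye contralateral to target dominates

        rid = len(routines)
        is_abort = outcome == "abort"
        n_track = int(2 + rng_fish.poisson(2.0))
        bt = t0 + 0.08  # first bout shortly after the convergent saccade
        gains = []
        for b in range(n_track):
            g_d = rng_fish.uniform(0.2, 0.5)
            g_o = rng_fish.uniform(0.3, 0.7)
            gains.append((g_d, g_o, False))
        if is_abort and neg_gain:
            gains.append((rng_fish.uniform(-0.8, -0.3), rng_fish.uniform(-1.5, -0.5), True))
        elif not is_abort and neg_gain:
            # a mid-routine lapse the fish recovers from
            gains.insert(max(2, n_track - 1),
                         (rng_fish.uniform(-0.8, -0.3), rng_fish.uniform(-1.5, -0.5), True))

        last_end = bt
        for g_d, g_o, _neg in gains:
            t1 = bt + config.bout_duration
            if t1 > config.duration - 0.5:
                break
            p_end = prey.position_at(target, t1)
            p_start = prey.position_at(target, bt)
            d_pre = np.hypot(*(p_start - fish.pos))
            az_pre = wrap_angle(np.degrees(np.arctan2(p_start[1] - fish.pos[1],
                                                      p_start[0] - fish.pos[0])) - fish.heading)
            d_post = (1.0 - g_d) * d_pre
            az_post = (1.0 - g_o) * az_pre
            bearing = np.degrees(np.arctan2(p_end[1] - fish.pos[1], p_end[0] - fish.pos[0]))
            br = np.deg2rad(bearing)
            p1 = p_end - d_post * np.array([np.cos(br), np.sin(br)])
            h1 = wrap_angle(bearing - az_post)
            write_bout_motion(bt, t1, fish.pos, fish.heading, p1, h1,
                              rng_fish.uniform(1500, 3000))
            bouts.append(dict(onset=bt, offset=t1, routine_id=rid,
                              displacement=float(np.hypot(*(p1 - fish.pos))),
                              turn=float(wrap_angle(h1 - fish.heading)),
                              distance_gain=float(g_d), orientation_gain=float(g_o)))
            fish.pos, fish.heading = p1, h1
            fill_state(idx(t1))
            last_end = t1
            bt = t1 + rng_fish.uniform(0.25, 0.45)

        if is_abort:
            t_end = last_end + 0.05
        else:
            # capture maneuver at the end of tracking
            kind = "ram" if "ram" in outcome else "suction"
            events.append(dict(epoch_id=rid, event=kind, time=last_end))
            if outcome.endswith("success"):
                events.append(dict(epoch_id=rid, event="ingestion", time=last_end + 0.05))
            t_end = last_end + 0.1

        # vergence envelope: 50 ms saccadic rise, hold, 350 ms relaxation
        i_on, i_off = idx(t0), idx(t_end)
        i_rise = idx(t0 + 0.05)
        i_relax = idx(t_end + 0.35)
        verg_delta[i_on:i_rise + 1] = _raised_cosine(
            (t[i_on:i_rise + 1] - t0) / 0.05)
        verg_delta[i_rise:i_off + 1] = 1.0
        verg_delta[i_off:i_relax + 1] = 1.0 - _raised_cosine(
            (t[i_off:i_relax + 1] - t_end) / 0.35)
        verg_side[i_on:i_relax + 1] = 1.0 if side == "left" else -1.0

        routines.append(dict(onset=t0, offset=t_end, target_id=target, outcome=outcome,
                             n_bouts=sum(1 for b in bouts if b["routine_id"] == rid),
                             side=side,
                             negative_gain_bout=bool(neg_gain)))
        return t_end + 0.35

    # --- event timeline -----------------------------------------------------
    outcome_draws = sample_routine_outcomes(
        max(64, int(config.hunt_rate * config.duration / 60 * 3) + 8), config, rng_fish)
    draw_i = 0
    cursor = 0.2
    next_hunt = (cursor + rng_fish.exponential(60.0 / config.hunt_rate)
                 if config.hunt_rate > 0 else np.inf)
    next_escape = (cursor + rng_fish.exponential(60.0 / config.escape_rate)
                   if config.escape_rate > 0 else np.inf)
    while cursor < config.duration - 1.0:
        if next_hunt <= cursor:
            row = outcome_draws.iloc[draw_i % len(outcome_draws)]
            draw_i += 1
            end = hunting_routine(cursor, row["outcome"], bool(row["negative_gain_bout"]))
            if end is not None:
                cursor = end + 0.1
            next_hunt = cursor + rng_fish.exponential(60.0 / config.hunt_rate)
            continue
        if next_escape <= cursor:
            cursor = escape_event(cursor) + 0.2
            next_escape = cursor + rng_fish.exponential(60.0 / config.escape_rate)
            continue
        gap = rng_fish.exponential(1.0 / config.bout_rate) if config.bout_rate > 0 else np.inf
        nxt = min(next_hunt, next_escape, cursor + gap)
        if nxt >= config.duration - 1.0:
            break
        if nxt == cursor + gap:
            cursor = spontaneous_bout(nxt)
        else:
            cursor = nxt

    # --- assemble channels --------------------------------------------------
    vergence = (config.vergence_baseline_deg
                + verg_delta * (config.vergence_hunting_deg - config.vergence_baseline_deg))
    v_noise_sd = (config.vergence_baseline_sd
                  + verg_delta * (config.vergence_hunting_sd - config.vergence_baseline_sd))
    # eye-angle noise is tracking jitter: near-white at 700 Hz (~3 ms tau)
    vergence = vergence + _smooth_noise(n, 1.0, rng_noise, alpha=0.5) * v_noise_sd
    # asymmetric split: dominant eye takes a larger share of the elevation
    asym = 0.15 * verg_side * verg_delta
    left = vergence * (0.5 + asym) + _smooth_noise(n, 0.5, rng_noise, alpha=0.5)
    right = -vergence * (0.5 - asym) + _smooth_noise(n, 0.5, rng_noise)
    # enforce exact vergence = left - right by assigning the residual to right
    right = left - vergence

    cumtail = cumtail + rng_noise.normal(0.0, config.tail_noise_sd, n)
    tail_segments = np.repeat((cumtail / 8.0)[:, None], 8, axis=1)

    hr = np.deg2rad(heading)
    body = pos - config.eye_offset_mm * np.stack([np.cos(hr), np.sin(hr)], axis=1)
    session = BehaviorSession(
        time=t, body_centroid=body,
        heading=heading, left_eye_angle=left, right_eye_angle=right,
        tail_segment_angles=tail_segments,
        sampling_rate=config.rate_hi, px_per_mm=config.px_per_mm)

    log = GroundTruthLog(
        routines=pd.DataFrame(routines, columns=[
            "onset", "offset", "target_id", "outcome", "n_bouts", "side",
            "negative_gain_bout"]),
        bouts=pd.DataFrame(bouts, columns=[
            "onset", "offset", "routine_id", "displacement", "turn",
            "distance_gain", "orientation_gain"]),
        events=pd.DataFrame(events, columns=["epoch_id", "event", "time"]),
        escapes=pd.DataFrame(escapes, columns=["onset", "peak_speed"]))
    return session, prey, log
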