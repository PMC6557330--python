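"""Pursuit gains, target assignment, outcome classification and ethograms."""

import numpy as np
import pandas as pd
import pytest

from zfhunt.config import BehaviorSimConfig, HuntingConfig
from zfhunt.containers import BehaviorSession, PreyTracks
from zfhunt.hunting import (AnnotationError, Ethogram, HuntingRoutine,
                            assign_target, build_ethogram, classify_outcome,
                            compare_groups, compute_gains, summarize_routines)
from zfhunt.kinematics import Bout, HuntingEpoch
from zfhunt.synthetic import sample_routine_outcomes

HCFG = HuntingConfig()


def _session_two_poses(pos0, hd0, pos1, hd1, rate=700.0):
    return BehaviorSession(
        time=np.array([0.0, 1.0 / rate]),
        body_centroid=np.array([pos0, pos1], dtype=float),
        heading=np.array([hd0, hd1], dtype=float),
        left_eye_angle=np.zeros(2), right_eye_angle=np.zeros(2),
        tail_segment_angles=np.zeros((2, 8)), sampling_rate=rate)


def _target_at(session, index, dist, azimuth):
    """Place a target at (dist, azimuth) relative to the eyes-center."""
    h = np.deg2rad(session.heading[index])
    eyes = session.body_centroid[index] + HCFG.eye_offset_mm * np.array(
        [np.cos(h), np.sin(h)])
    ang = np.deg2rad(session.heading[index] + azimuth)
    return eyes + dist * np.array([np.cos(ang), np.sin(ang)])


BOUT = Bout(onset=0.0, offset=1 / 700.0, peak_velocity=1000.0,
            onset_index=0, offset_index=1)


@pytest.mark.parametrize("pre,post,expect", [
    ((4.0, 30.0), (4.0, 30.0), (0.0, 0.0)),        # nothing changes
    ((4.0, 30.0), (2.0, 15.0), (0.5, 0.5)),        # half eliminated
    ((3.0, 20.0), (4.5, 40.0), (-0.5, -1.0)),      # negative-gain bout
])
def test_gain_arithmetic(pre, post, expect):
    session = _session_two_poses([5.0, 5.0], 0.0, [5.0, 5.0], 0.0)
    p0 = _target_at(session, 0, *pre)
    p1 = _target_at(session, 1, *post)
    g = compute_gains(session, p0, p1, BOUT)
    assert g.distance_gain == pytest.approx(expect[0], abs=1e-9)
    assert g.orientation_gain == pytest.approx(expect[1], abs=1e-9)
    assert g.negative == (expect[0] < 0 and expect[1] < 0)


def test_gains_invariant_under_rigid_scene_transform():
    """Translating and rotating fish + prey together leaves gains unchanged."""
    rng = np.random.default_rng(3)
    for _ in range(200):
        pre = (rng.uniform(1, 6), rng.uniform(-120, 120))
        post = (rng.uniform(0.5, 7), rng.uniform(-150, 150))
        base = _session_two_poses([5, 5], 10.0, [5.5, 5.2], 25.0)
        p0, p1 = _target_at(base, 0, *pre), _target_at(base, 1, *post)
        g0 = compute_gains(base, p0, p1, BOUT)

        shift = rng.uniform(-5, 5, 2)
        rot = rng.uniform(-180, 180)
        c, s = np.cos(np.deg2rad(rot)), np.sin(np.deg2rad(rot))
        R = np.array([[c, -s], [s, c]])
        moved = _session_two_poses(R @ base.body_centroid[0] + shift, 10.0 + rot,
                                   R @ base.body_centroid[1] + shift, 25.0 + rot)
        g1 = compute_gains(moved, R @ p0 + shift, R @ p1 + shift, BOUT)
        assert g1.distance_gain == pytest.approx(g0.distance_gain, abs=1e-9)
        assert g1.orientation_gain == pytest.approx(g0.orientation_gain, abs=1e-9)


def test_lost_target_flags_invalid_gain():
    session = _session_two_poses([5, 5], 0.0, [5, 5], 0.0)
    g = compute_gains(session, None, None, BOUT)
    assert not g.valid and np.isnan(g.distance_gain)


# --------------------------------------------------------------------------
# target assignment

def _tracks_from_paths(paths, times):
    rows = []
    for tid, path in paths.items():
        for f, (t, (x, y)) in enumerate(zip(times, path)):
            rows.append(dict(frame=f, time=t, x=x, y=y, track_id=tid))
    return PreyTracks(table=pd.DataFrame(rows))


def _epoch(onset=0.0, offset=1.0):
    return HuntingEpoch(onset=onset, offset=offset, dominant_eye="left",
                        onset_index=0, offset_index=int(offset * 700))


def test_no_prey_in_field_gives_no_target():
    n = 1400
    session = BehaviorSession(
        time=np.arange(n) / 700.0, body_centroid=np.zeros((n, 2)),
        heading=np.zeros(n), left_eye_angle=np.zeros(n),
        right_eye_angle=np.zeros(n), tail_segment_angles=np.zeros((n, 8)),
        sampling_rate=700.0)
    times = np.arange(0, 2.0, 1 / 17.5)
    far = [(10.0, 10.0)] * len(times)      # ~14 mm away: outside the field
    tracks = _tracks_from_paths({0: far}, times)
    bouts = [Bout(0.1, 0.25, 1000, onset_index=70, offset_index=175),
             Bout(0.5, 0.65, 1000, onset_index=350, offset_index=455)]
    tid, ambig, _ = assign_target(_epoch(), bouts, tracks, session)
    assert tid is None


def _pursuit_session(target=(5.0, 1.0), states=((4.5, 20.0), (3.5, 12.0),
                                                (2.5, 6.0))):
    """Piecewise-constant fish poses realizing a (distance, azimuth)
    schedule toward a fixed target; states switch at the bout offsets
    (sample 175 and 455)."""
    n = 1400
    target = np.asarray(target, dtype=float)
    boundaries = [0, 175, 455]
    pos = np.zeros((n, 2))
    hdg = np.zeros(n)
    for start, (d, az) in zip(boundaries, states):
        eyes = target - np.array([d, 0.0])     # bearing fixed at 0 deg
        heading = -az                          # azimuth = bearing - heading
        h = np.deg2rad(heading)
        body = eyes - HCFG.eye_offset_mm * np.array([np.cos(h), np.sin(h)])
        pos[start:, :] = body
        hdg[start:] = heading
    return BehaviorSession(
        time=np.arange(n) / 700.0, body_centroid=pos, heading=hdg,
        left_eye_angle=np.zeros(n), right_eye_angle=np.zeros(n),
        tail_segment_angles=np.zeros((n, 8)), sampling_rate=700.0)


def test_unique_positive_gain_candidate_wins():
    """Fish closes distance and azimuth on prey A; prey B sits behind it."""
    session = _pursuit_session()
    times = np.arange(0, 2.0, 1 / 17.5)
    ahead = [(5.0, 1.0)] * len(times)          # the pursued target
    behind = [(-3.0, -0.5)] * len(times)       # azimuth ~180 deg: excluded
    tracks = _tracks_from_paths({7: ahead, 9: behind}, times)
    bouts = [Bout(0.1, 0.25, 1000, onset_index=70, offset_index=175),
             Bout(0.5, 0.65, 1000, onset_index=350, offset_index=455)]
    tid, ambig, gains = assign_target(_epoch(), bouts, tracks, session)
    assert tid == 7 and not ambig


def test_fewer_than_two_bouts_gives_no_target(behavior_bundle):
    _, session, prey, _ = behavior_bundle
    from zfhunt.pipeline import truth_tracks
    tid, _, _ = assign_target(_epoch(), [], truth_tracks(prey), session)
    assert tid is None


def test_assignment_invariant_to_track_id_permutation():
    session = _pursuit_session()
    times = np.arange(0, 2.0, 1 / 17.5)
    ahead = [(5.0, 1.0)] * len(times)
    side = [(2.0, 4.0)] * len(times)
    bouts = [Bout(0.1, 0.25, 1000, onset_index=70, offset_index=175),
             Bout(0.5, 0.65, 1000, onset_index=350, offset_index=455)]
    t1, _, _ = assign_target(_epoch(), bouts,
                             _tracks_from_paths({0: ahead, 1: side}, times), session)
    t2, _, _ = assign_target(_epoch(), bouts,
                             _tracks_from_paths({1: ahead, 0: side}, times), session)
    assert t1 == 0 and t2 == 1   # same physical prey wins under either labeling


# --------------------------------------------------------------------------
# outcome classification and ethograms

def _routine(onset=0.0, offset=1.0):
    return HuntingRoutine(epoch=_epoch(onset, offset), bouts=[])


def test_no_capture_event_is_abort():
    r = classify_outcome(_routine(), pd.DataFrame(columns=["event", "time"]))
    assert r.outcome == "abort" and r.attempt_type == "n/a" and r.success is None


def test_ram_plus_ingestion_is_successful_attempt():
    ev = pd.DataFrame({"event": ["ram", "ingestion"], "time": [0.8, 0.85]})
    r = classify_outcome(_routine(), ev)
    assert (r.outcome, r.attempt_type, r.success) == ("attempt", "ram", True)


def test_ingestion_without_capture_raises():
    ev = pd.DataFrame({"event": ["ingestion"], "time": [0.5]})
    with pytest.raises(AnnotationError):
        classify_outcome(_routine(), ev)


def test_ethogram_ratio_arithmetic():
    labels = (["abort"] * 60 + ["attempt-ram-success"] * 5
              + ["attempt-ram-fail"] * 5 + ["attempt-suction-success"] * 15
              + ["attempt-suction-fail"] * 15)
    df = pd.DataFrame({"outcome": labels, "fish_id": 0})
    eth = build_ethogram(df)
    assert eth.probabilities["P(abort)"] == pytest.approx(0.6)
    assert eth.probabilities["P(suction|attempt)"] == pytest.approx(0.75)
    assert eth.probabilities["P(success|ram)"] == pytest.approx(0.5)
    assert eth.probabilities["P(abort)"] + eth.probabilities["P(attempt)"] == 1.0


def test_all_abort_ethogram():
    df = pd.DataFrame({"outcome": ["abort"] * 10, "fish_id": 0})
    eth = build_ethogram(df)
    assert eth.probabilities["P(abort)"] == 1.0
    assert np.isnan(eth.probabilities["P(ram|attempt)"])
    assert eth.counts["routines"] == 10


def test_ethogram_counts_conserve_routines():
    cfg = BehaviorSimConfig(seed=0)
    draws = sample_routine_outcomes(300, cfg, np.random.default_rng(0))
    df = draws.assign(fish_id=np.arange(300) % 5)
    eth = build_ethogram(df)
    assert eth.counts["abort"] + eth.counts["attempt"] == 300
    assert eth.counts["ram"] + eth.counts["suction"] == eth.counts["attempt"]


def test_group_comparison_detects_large_difference():
    rng = np.random.default_rng(1)
    cfg_a = BehaviorSimConfig(seed=0, p_abort=0.60)
    cfg_b = BehaviorSimConfig(seed=0, p_abort=0.80)

    def cohort(cfg, n_fish):
        frames = []
        for f in range(n_fish):
            d = sample_routine_outcomes(112, cfg, rng)
            frames.append(d.assign(fish_id=f))
        return build_ethogram(pd.concat(frames, ignore_index=True))

    res = compare_groups(cohort(cfg_a, 7), cohort(cfg_b, 8))
    assert res["p_value"] < 0.05
    assert res["median_b"] > res["median_a"]


# --------------------------------------------------------------------------
# summaries

def test_negative_gain_fractions_by_construction():
    from zfhunt.hunting import BoutGain

    def routine(outcome, neg):
        r = _routine()
        r.outcome = outcome
        g = BoutGain(-0.5 if neg else 0.5, -0.5 if neg else 0.5, 3, 4, 20, 30)
        r.gains = [g]
        return r

    routines = [routine("abort", True) for _ in range(4)] \
        + [routine("attempt", False) for _ in range(6)]
    s = summarize_routines(routines)
    assert s["frac_negative_gain_abort"] == 1.0
    assert s["frac_negative_gain_attempt"] == 0.0


def test_no_negative_gain_bouts_yields_zero_fractions():
    s = summarize_routines([])
    assert s["frac_negative_gain_abort"] == 0.0
    assert s["frac_negative_gain_attempt"] == 0.0


def test_target_switch_detected_on_reorientation():
    """A later bout pair with positive gains toward another prey while the
    current target shows negative gains re-assigns the target."""
    from zfhunt.hunting import detect_target_switch

    # 4 bouts: first two pursue prey A; last two pursue prey B while A is
    # left behind.  Poses are piecewise-constant; bouts at fixed indices.
    n = 2800
    A = np.array([5.0, 1.0])     # initially pursued, ahead of the fish
    B = np.array([-4.0, 1.0])    # behind: pursuing it moves away from A
    idx = [0, 350, 700, 1050, 1400]
    pos = np.zeros((n, 2))
    hdg = np.zeros(n)
    for start, (target, bearing, d, az) in zip(idx, [
            (A, 0.0, 4.5, 20.0), (A, 0.0, 3.5, 12.0), (A, 0.0, 3.0, 10.0),
            (B, 180.0, 3.0, 15.0), (B, 180.0, 2.0, 8.0)]):
        br = np.deg2rad(bearing)
        eyes = target - d * np.array([np.cos(br), np.sin(br)])
        heading = bearing - az
        h = np.deg2rad(heading)
        body = eyes - HCFG.eye_offset_mm * np.array([np.cos(h), np.sin(h)])
        pos[start:] = body
        hdg[start:] = heading
    session = BehaviorSession(
        time=np.arange(n) / 700.0, body_centroid=pos, heading=hdg,
        left_eye_angle=np.zeros(n), right_eye_angle=np.zeros(n),
        tail_segment_angles=np.zeros((n, 8)), sampling_rate=700.0)
    times = np.arange(0, 4.0, 1 / 17.5)
    tracks = _tracks_from_paths({0: [tuple(A)] * len(times),
                                 1: [tuple(B)] * len(times)}, times)
    bouts = [Bout((i + 1) / 700.0, (i + 350) / 700.0, 1000,
                  onset_index=i + 1, offset_index=i + 350)
             for i in (0, 350, 700, 1050)]
    out = detect_target_switch(bouts, tracks, session, current_target=0)
    assert out is not None
    k, new_target = out
    assert new_target == 1
    assert k >= 2
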