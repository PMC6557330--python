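"""Per-bout pursuit gains, target assignment, outcome classification,
ethograms and cohort summaries.

Distance-gain and orientation-gain of a bout are the fractions of the
fish-target distance and azimuth eliminated by that bout; both negative
flags a pursuit-abandoning ("negative-gain") bout.  A prey item is the
routine's target if, at routine onset, it lies within the reactive
perceptive field (<= 6 mm from the eyes-center and |azimuth| <= 120 deg)
and both gains of the first two bouts are positive with respect to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .config import HuntingConfig
from .containers import BehaviorSession, PreyTracks, wrap_angle
from .kinematics import Bout, HuntingEpoch


@dataclass
class BoutGain:
    distance_gain: float
    orientation_gain: float
    pre_distance: float        # mm
    post_distance: float
    pre_azimuth: float         # deg, signed, positive to the fish's right
    post_azimuth: float
    valid: bool = True

    @property
    def negative(self) -> bool:
        """Negative-gain bout: both distance- and orientation-gain negative."""
        return self.valid and self.distance_gain < 0 and self.orientation_gain < 0


def _fish_target_geometry(session: BehaviorSession, target_pos: np.ndarray,
                          index: int, eye_offset_mm: float):
    h = np.deg2rad(session.heading[index])
    eyes = session.body_centroid[index] + eye_offset_mm * np.array(
        [np.cos(h), np.sin(h)])
    vec = np.asarray(target_pos) - eyes
    dist = float(np.hypot(*vec))
    bearing = np.degrees(np.arctan2(vec[1], vec[0]))
    azimuth = float(wrap_angle(bearing - session.heading[index]))
    return dist, azimuth


def compute_gains(session: BehaviorSession, target_pos_pre: np.ndarray,
                  target_pos_post: np.ndarray, bout: Bout,
                  config: HuntingConfig | None = None) -> BoutGain:
    """Gains of one bout against a target's interpolated positions.

    Distance is measured from the center of the eye centroids to the target;
    azimuth is the angle between the eyes-center-to-target vector and the
    heading.  Gains are the fraction eliminated: positive values indicate
    orienting toward and approaching the prey.
    """
    config = config or HuntingConfig()
    if target_pos_pre is None or target_pos_post is None:
        return BoutGain(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)
    d0, a0 = _fish_target_geometry(session, target_pos_pre, bout.onset_index,
                                   config.eye_offset_mm)
    d1, a1 = _fish_target_geometry(session, target_pos_post, bout.offset_index,
                                   config.eye_offset_mm)
    dg = (d0 - d1) / d0 if d0 > 0 else np.nan
    og = (abs(a0) - abs(a1)) / abs(a0) if abs(a0) > 0 else np.nan
    return BoutGain(distance_gain=float(dg), orientation_gain=float(og),
                    pre_distance=d0, post_distance=d1,
                    pre_azimuth=a0, post_azimuth=a1)


@dataclass
class HuntingRoutine:
    epoch: HuntingEpoch
    bouts: list[Bout]
    gains: list[BoutGain] = field(default_factory=list)
    target_id: int | None = None
    ambiguous_target: bool = False
    outcome: str = "unclassified"          # 'abort' | 'attempt'
    attempt_type: str = "n/a"              # 'ram' | 'suction' | 'n/a'
    success: bool | None = None
    fish_id: int = 0

    @property
    def negative_gain_bout_present(self) -> bool:
        return any(g.negative for g in self.gains)

    @property
    def outcome_label(self) -> str:
        if self.outcome == "abort":
            return "abort"
        if self.outcome == "attempt":
            return (f"attempt-{self.attempt_type}-"
                    f"{'success' if self.success else 'fail'}")
        return self.outcome


def _track_position(tracks: PreyTracks, tid: int, t: float):
    return tracks.position_at(tid, t)


def assign_target(epoch: HuntingEpoch, bouts: list[Bout], tracks: PreyTracks,
                  session: BehaviorSession,
                  config: HuntingConfig | None = None):
    """Find the prey track the routine is directed at.

    Among tracks inside the reactive perceptive field at routine onset,
    returns the one with positive distance- and orientation-gain on both of
    the routine's first two bouts.  When several candidates qualify (dense
    prey make incidental positive gains common), the winner is the one the
    fish keeps pursuing: candidates are ranked by the number of consecutive
    leading bouts with both gains positive across the whole routine, then
    by summed first-two-bout gains; multiple qualifiers set the ambiguous
    flag.  Routines with fewer than two bouts get no target.  Returns
    (target_id or None, ambiguous flag, gains dict).
    """
    config = config or HuntingConfig()
    if len(bouts) < 2:
        return None, False, {}
    if config.field_at == "first_bout":
        ref_index = bouts[0].onset_index
        ref_time = bouts[0].onset
    else:
        ref_index = epoch.onset_index
        ref_time = epoch.onset
    candidates = []
    for tid in tracks.track_ids:
        p = _track_position(tracks, tid, ref_time)
        if p is None:
            continue
        d, az = _fish_target_geometry(session, p, ref_index, config.eye_offset_mm)
        if d <= config.max_target_distance_mm and abs(az) <= config.max_target_azimuth_deg:
            candidates.append(tid)
    gains_by_tid = {}
    qualified = []
    for tid in candidates:
        gg = []
        for b in bouts:
            p0 = _track_position(tracks, tid, b.onset)
            p1 = _track_position(tracks, tid, b.offset)
            if p0 is None or p1 is None:
                break
            gg.append(compute_gains(session, p0, p1, b, config))
        if len(gg) < 2 or not all(
                g.distance_gain > 0 and g.orientation_gain > 0 for g in gg[:2]):
            continue
        streak = 0
        for g in gg:
            if g.distance_gain > 0 and g.orientation_gain > 0:
                streak += 1
            else:
                break
        sum2 = sum(g.distance_gain + g.orientation_gain for g in gg[:2])
        qualified.append(((streak, sum2), tid))
        gains_by_tid[tid] = gg[:2]
    if not qualified:
        return None, False, {}
    qualified.sort(reverse=True)
    return qualified[0][1], len(qualified) > 1, gains_by_tid


def detect_target_switch(routine_bouts, tracks, session, current_target,
                         config: HuntingConfig | None = None):
    """Scan bout pairs for a re-orientation toward a different prey item.

    A switch is a later consecutive bout pair with positive gains for some
    other candidate while the current target has negative gains on the same
    pair.  Returns (bout_index, new_target) for the first switch, or None.
    """
    config = config or HuntingConfig()
    for k in range(2, len(routine_bouts) - 1):
        pair = routine_bouts[k:k + 2]

        def pair_gains(tid):
            gg = []
            for b in pair:
                p0 = _track_position(tracks, tid, b.onset)
                p1 = _track_position(tracks, tid, b.offset)
                if p0 is None or p1 is None:
                    return None
                gg.append(compute_gains(session, p0, p1, b, config))
            return gg

        cur = pair_gains(current_target)
        if cur is None or not all(
                g.distance_gain < 0 and g.orientation_gain < 0 for g in cur):
            continue
        for tid in tracks.track_ids:
            if tid == current_target:
                continue
            gg = pair_gains(tid)
            if gg and all(g.distance_gain > 0 and g.orientation_gain > 0 for g in gg):
                return k, tid
    return None


class AnnotationError(ValueError):
    """Inconsistent capture/ingestion annotations."""


def classify_outcome(routine: HuntingRoutine, events: pd.DataFrame) -> HuntingRoutine:
    """Label a routine from capture/suction/ingestion event annotations.

    ``events`` columns: event in {'ram','suction','ingestion'} and time
    (capture scoring was manual in the source assay; the pipeline consumes
    annotation flags, from the generator's ground truth or a CSV).  A
    routine with no capture event within its epoch is an abort.
    """
    t0, t1 = routine.epoch.onset, routine.epoch.offset + 0.2
    within = events[(events["time"] >= t0) & (events["time"] <= t1)]
    captures = within[within["event"].isin(["ram", "suction"])]
    ingests = within[within["event"] == "ingestion"]
    if len(captures) == 0:
        if len(ingests):
            raise AnnotationError(
                f"ingestion at t={ingests['time'].iloc[0]:.3f} without a capture event")
        routine.outcome = "abort"
        routine.attempt_type = "n/a"
        routine.success = None
        return routine
    routine.outcome = "attempt"
    routine.attempt_type = str(captures["event"].iloc[0])
    routine.success = bool(len(ingests))
    return routine


@dataclass
class Ethogram:
    counts: dict
    probabilities: dict
    per_fish: pd.DataFrame

    @staticmethod
    def branch_probs(counts: dict) -> dict:
        n = counts["routines"]
        n_att = counts["attempt"]
        probs = {
            "P(abort)": counts["abort"] / n if n else np.nan,
            "P(attempt)": n_att / n if n else np.nan,
            "P(ram|attempt)": counts["ram"] / n_att if n_att else np.nan,
            "P(suction|attempt)": counts["suction"] / n_att if n_att else np.nan,
            "P(success|ram)": counts["ram-success"] / counts["ram"]
            if counts["ram"] else np.nan,
            "P(success|suction)": counts["suction-success"] / counts["suction"]
            if counts["suction"] else np.nan,
        }
        return probs


def _count_outcomes(labels) -> dict:
    c = dict(routines=len(labels), abort=0, attempt=0, ram=0, suction=0,
             **{"ram-success": 0, "suction-success": 0})
    for lab in labels:
        if lab == "abort":
            c["abort"] += 1
            continue
        c["attempt"] += 1
        _, kind, result = lab.split("-")
        c[kind] += 1
        if result == "success":
            c[f"{kind}-success"] += 1
    return c


def build_ethogram(routines: list[HuntingRoutine] | pd.DataFrame) -> Ethogram:
    """Branch counts and probabilities, pooled and per fish.

    Accepts classified HuntingRoutine objects or a DataFrame with columns
    ``outcome`` (full labels) and ``fish_id``.  Fish with zero routines are
    omitted.  Per-fish medians support group comparisons.
    """
    if isinstance(routines, pd.DataFrame):
        df = routines
    else:
        df = pd.DataFrame({
            "outcome": [r.outcome_label for r in routines],
            "fish_id": [r.fish_id for r in routines]})
    counts = _count_outcomes(df["outcome"].tolist())
    per_fish_rows = []
    for fid, grp in df.groupby("fish_id"):
        c = _count_outcomes(grp["outcome"].tolist())
        row = dict(fish_id=fid, n_routines=c["routines"])
        row.update(Ethogram.branch_probs(c))
        per_fish_rows.append(row)
    return Ethogram(counts=counts, probabilities=Ethogram.branch_probs(counts),
                    per_fish=pd.DataFrame(per_fish_rows))


def compare_groups(eth_a: Ethogram, eth_b: Ethogram,
                   branch: str = "P(abort)"):
    """Wilcoxon rank-sum test on per-fish branch probabilities."""
    a = eth_a.per_fish[branch].dropna().to_numpy()
    b = eth_b.per_fish[branch].dropna().to_numpy()
    stat, p = ranksums(a, b)
    return {"statistic": float(stat), "p_value": float(p),
            "median_a": float(np.median(a)) if len(a) else np.nan,
            "median_b": float(np.median(b)) if len(b) else np.nan}


def summarize_routines(routines: list[HuntingRoutine],
                       config: HuntingConfig | None = None) -> dict:
    """Cohort summary tables.

    Includes the fraction of routines containing a negative-gain bout split
    by outcome, target distance/azimuth at onset and at capture initiation,
    routine durations and bout counts.
    """
    config = config or HuntingConfig()
    rows = []
    for r in routines:
        neg = r.negative_gain_bout_present
        dur = r.epoch.offset - r.epoch.onset
        d_on = az_on = d_cap = az_cap = np.nan
        if r.gains:
            first = r.gains[0]
            d_on, az_on = first.pre_distance, first.pre_azimuth
            if r.outcome == "attempt":
                last = r.gains[-1]
                d_cap, az_cap = last.pre_distance, last.pre_azimuth
        rows.append(dict(outcome=r.outcome, label=r.outcome_label,
                         negative_gain=neg, duration=dur, n_bouts=len(r.bouts),
                         dist_onset=d_on, az_onset=az_on,
                         dist_capture=d_cap, az_capture=az_cap))
    df = pd.DataFrame(rows, columns=["outcome", "label", "negative_gain",
                                     "duration", "n_bouts", "dist_onset",
                                     "az_onset", "dist_capture", "az_capture"])
    out = {"table": df}
    for outcome in ("abort", "attempt"):
        sel = df[df["outcome"] == outcome]
        out[f"frac_negative_gain_{outcome}"] = (
            float(sel["negative_gain"].mean()) if len(sel) else 0.0)
    out["median_duration"] = float(df["duration"].median()) if len(df) else np.nan
    out["median_bouts"] = float(df["n_bouts"].median()) if len(df) else np.nan
    return out


def analyze_session(session: BehaviorSession, tracks: PreyTracks,
                    epochs: list[HuntingEpoch], bouts: list[Bout],
                    events: pd.DataFrame,
                    config: HuntingConfig | None = None,
                    fish_id: int = 0) -> list[HuntingRoutine]:
    """Assemble classified routines for one session.

    Groups detected bouts into epochs, assigns targets, computes per-bout
    gains against the assigned target and classifies outcomes from the
    event annotations.
    """
    config = config or HuntingConfig()
    routines = []
    for ep in epochs:
        rb = [b for b in bouts if ep.onset - 0.02 <= b.onset <= ep.offset + 0.02]
        routine = HuntingRoutine(epoch=ep, bouts=rb, fish_id=fish_id)
        tid, ambig, _ = assign_target(ep, rb, tracks, session, config)
        routine.target_id = tid
        routine.ambiguous_target = ambig
        if tid is not None:
            for b in rb:
                p0 = _track_position(tracks, tid, b.onset)
                p1 = _track_position(tracks, tid, b.offset)
                routine.gains.append(compute_gains(session, p0, p1, b, config))
        routines.append(classify_outcome(routine, events))
    return routines
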