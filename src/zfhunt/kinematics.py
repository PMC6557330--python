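"""Vergence state, hunting epochs, swim bouts and escape events.

The hunting-state threshold is estimated per fish by fitting a
two-component Gaussian mixture to the (invariably bimodal) vergence-angle
distribution; the threshold is one standard deviation below the mean of the
higher-angle component.  Bouts are supra-threshold runs (500 deg/s) of the
smoothed cumulative tail-angle velocity; escapes are centroid-speed
excursions above 75 mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.mixture import GaussianMixture

from .config import KinematicsConfig
from .containers import BehaviorSession


class DegenerateMixtureError(ValueError):
    """Raised when the vergence distribution does not support two modes."""


@dataclass
class VergenceThreshold:
    """Result of the two-Gaussian vergence fit (statsmodels-style results)."""

    threshold: float
    means: np.ndarray          # sorted ascending
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n_samples: int

    def summary(self) -> str:
        lines = ["Two-Gaussian vergence mixture",
                 f"  n samples        {self.n_samples}",
                 f"  low mode         {self.means[0]:8.2f} +- {self.sds[0]:.2f} deg"
                 f"  (w={self.weights[0]:.3f})",
                 f"  high mode        {self.means[1]:8.2f} +- {self.sds[1]:.2f} deg"
                 f"  (w={self.weights[1]:.3f})",
                 f"  threshold        {self.threshold:8.2f} deg"
                 "  (high mean - high SD)"]
        return "\n".join(lines)


def fit_vergence_threshold(vergence: np.ndarray,
                           config: KinematicsConfig | None = None) -> VergenceThreshold:
    """Fit the bimodal vergence distribution and derive the hunting threshold.

    A two-component Gaussian mixture is fit by EM (k-means initialization,
    restarts), then refined by least squares against the binned vergence
    distribution.  The refinement matters because real vergence series
    carry a thin ribbon of between-mode samples from saccadic transitions;
    maximum likelihood absorbs that mass into the upper component and
    inflates its SD, while the histogram fit is dominated by the two peaks.
    Raises DegenerateMixtureError when a component collapses (weight below
    floor) or the modes are closer than the separation floor, signaling a
    unimodal distribution.
    """
    from scipy.optimize import curve_fit

    config = config or KinematicsConfig()
    x = np.asarray(vergence, dtype=float).reshape(-1, 1)
    x = x[np.isfinite(x[:, 0])].reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=config.mixture_n_init,
                         tol=config.mixture_tol, covariance_type="full",
                         random_state=0)
    gm.fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    def two_gauss(c, w1, m1, s1, w2, m2, s2):
        return (w1 / (np.sqrt(2 * np.pi) * s1) * np.exp(-0.5 * ((c - m1) / s1) ** 2)
                + w2 / (np.sqrt(2 * np.pi) * s2) * np.exp(-0.5 * ((c - m2) / s2) ** 2))

    edges = np.arange(x.min(), x.max() + 0.5, 0.5)
    if len(edges) > 8:
        dens, edges = np.histogram(x.ravel(), bins=edges, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p0 = [weights[0], means[0], sds[0], weights[1], means[1], sds[1]]
        try:
            popt, _ = curve_fit(
                two_gauss, centers, dens, p0=p0, maxfev=20_000,
                bounds=([0, x.min(), 1e-3, 0, x.min(), 1e-3],
                        [1.5, x.max(), np.ptp(x), 1.5, x.max(), np.ptp(x)]))
            w1, m1, s1, w2, m2, s2 = popt
            refined = np.argsort([m1, m2])
            means = np.array([m1, m2])[refined]
            sds = np.abs(np.array([s1, s2]))[refined]
            w = np.array([w1, w2])[refined]
            weights = w / w.sum()
        except RuntimeError:
            pass  # keep the EM estimates
    if weights.min() < config.mixture_min_weight:
        raise DegenerateMixtureError(
            f"component weight {weights.min():.4f} below floor; unimodal input?")
    pooled = float(np.sqrt(weights @ sds**2))
    if means[1] - means[0] < config.mixture_min_separation_sd * pooled:
        raise DegenerateMixtureError(
            f"mode separation {means[1] - means[0]:.2f} deg below "
            f"{config.mixture_min_separation_sd} pooled SDs; unimodal input?")
    return VergenceThreshold(threshold=float(means[1] - sds[1]), means=means,
                             sds=sds, weights=weights,
                             log_likelihood=float(gm.score(x) * len(x)),
                             n_samples=len(x))


@dataclass
class HuntingEpoch:
    onset: float
    offset: float
    dominant_eye: str          # 'left' or 'right'
    onset_index: int = 0
    offset_index: int = 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop index pairs (half-open) of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _merge_runs(runs, max_gap: int):
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def segment_hunting_epochs(session: BehaviorSession, threshold: float,
                           config: KinematicsConfig | None = None) -> list[HuntingEpoch]:
    """Segment maximal above-threshold vergence runs into hunting epochs.

    Sub-gap dips are merged and short runs pruned.  The reported onset
    marks the convergent saccade: anchored at the steepest vergence rise
    near the run start and walked back along the ramp until the slope is
    low and the level has returned to the local pre-saccade baseline; the
    offset is the threshold down-crossing.  The dominant eye is the one
    with the larger nasal rotation from pre-saccade baseline to the epoch.
    """
    config = config or KinematicsConfig()
    rate = session.sampling_rate
    v = session.vergence
    win = min(config.savgol_window, len(v) - (1 - len(v) % 2))
    vs = savgol_filter(v, win, config.savgol_order) if len(v) > win > config.savgol_order else v
    mask = vs > threshold
    runs = _merge_runs(_runs(mask), int(round(config.epoch_merge_gap * rate)))
    runs = [(s, e) for s, e in runs if (e - s) / rate >= config.epoch_min_duration]
    dv = (savgol_filter(v, win, config.savgol_order, deriv=1, delta=1.0 / rate)
          if len(v) > win > config.savgol_order else np.gradient(v) * rate)
    slope_floor = 140.0  # deg/s: below this the saccadic rise has not yet begun
    epochs = []
    for s, e in runs:
        # the threshold crossing lags (or, with noise, can lead) the
        # convergent saccade: anchor on the steepest rise near the run start
        # and walk back along it to the saccade onset
        j0, j1 = max(0, s - int(0.25 * rate)), min(len(v), s + int(0.1 * rate))
        pk = j0 + int(np.argmax(dv[j0:j1]))
        # local pre-saccade baseline level: brief noise dips of the slope
        # mid-ramp must not stop the walk-back while vergence is elevated
        b0 = max(0, pk - int(0.35 * rate))
        b1 = max(b0 + 1, pk - int(0.12 * rate))
        base = float(np.median(vs[b0:b1]))
        i = pk
        while i > 0 and (dv[i - 1] > slope_floor
                         or vs[max(0, i - 5):i].mean() > base + 2.0):
            i -= 1
        pre = slice(max(0, i - int(0.05 * rate)), max(1, i))
        dl = np.mean(session.left_eye_angle[s:min(e, s + int(0.1 * rate))]) \
            - np.mean(session.left_eye_angle[pre])
        dr = np.mean(session.right_eye_angle[s:min(e, s + int(0.1 * rate))]) \
            - np.mean(session.right_eye_angle[pre])
        # nasal rotation: clockwise (+) for the left eye, ccw (-) for the right
        dominant = "left" if dl > -dr else "right"
        epochs.append(HuntingEpoch(onset=float(session.time[i]),
                                   offset=float(session.time[min(e, len(v) - 1)]),
                                   dominant_eye=dominant,
                                   onset_index=int(i), offset_index=int(e)))
    return epochs


@dataclass
class Bout:
    onset: float
    offset: float
    peak_velocity: float       # deg/s
    displacement: float = np.nan   # mm
    turn: float = np.nan           # deg
    onset_index: int = 0
    offset_index: int = 0


def detect_bouts(tail_segment_angles: np.ndarray, rate: float,
                 config: KinematicsConfig | None = None,
                 session: BehaviorSession | None = None) -> list[Bout]:
    """Detect swim bouts from the cumulative tail angle.

    The cumulative angle (sum of the 8 inter-segment angles) is smoothed
    with a Savitzky-Golay filter; bouts are runs where the absolute time
    derivative exceeds 500 deg/s, merged across sub-gap pauses and pruned
    to a minimum duration.  Onsets/offsets are refined outward to where the
    velocity falls below a low floor so they mark movement start/end.
    """
    config = config or KinematicsConfig()
    tail = np.asarray(tail_segment_angles)
    cum = tail.sum(axis=1) if tail.ndim == 2 else tail
    n = len(cum)
    win = config.savgol_window if n > config.savgol_window else max(
        config.savgol_order + 2 + (config.savgol_order % 2), 5)
    if n <= win:
        return []
    vel = savgol_filter(cum, win, config.savgol_order, deriv=1, delta=1.0 / rate)
    speed = np.abs(vel)
    mask = speed > config.bout_velocity_threshold
    runs = _merge_runs(_runs(mask), int(round(config.bout_merge_gap * rate)))
    bouts = []
    floor = config.bout_onset_floor
    # bridge the brief near-zero dips between tail half-beats when walking
    # out to the movement envelope start/end
    look = max(1, int(round(0.015 * rate)))
    last_end = -1
    for s, e in runs:
        if (e - s) / rate < config.bout_min_duration:
            continue
        i = s
        while i > last_end + 1 and i > 0 and speed[max(0, i - look):i].max() > floor:
            i -= 1
        j = e
        while j < n - 1 and speed[j:j + look].max() > floor:
            j += 1
        last_end = j
        bout = Bout(onset=float(i / rate), offset=float(j / rate),
                    peak_velocity=float(speed[s:e].max()),
                    onset_index=i, offset_index=j)
        if session is not None:
            p0, p1 = session.body_centroid[i], session.body_centroid[min(j, n - 1)]
            bout.displacement = float(np.hypot(*(p1 - p0)))
            bout.turn = float((session.heading[min(j, n - 1)] - session.heading[i]
                               + 180) % 360 - 180)
        bouts.append(bout)
    return bouts


@dataclass
class EscapeEvent:
    onset: float
    peak_speed: float          # mm/s
    latency: float = np.nan    # s from stimulus onset, if a stimulus log given


def detect_escapes(body_centroid: np.ndarray, time: np.ndarray,
                   config: KinematicsConfig | None = None,
                   sample_rate: float = 17.5,
                   stimulus_onsets: np.ndarray | None = None) -> list[EscapeEvent]:
    """Detect escapes as supra-75 mm/s excursions of the centroid speed.

    Speed is the finite difference of the centroid resampled at the
    low (full-frame) rate, unsmoothed: a single frame-to-frame step above
    threshold at 17.5 Hz is unambiguous.  One event per supra-threshold run.
    """
    config = config or KinematicsConfig()
    time = np.asarray(time, dtype=float)
    pos = np.asarray(body_centroid, dtype=float)
    t_lo = np.arange(time[0], time[-1], 1.0 / sample_rate)
    x = np.interp(t_lo, time, pos[:, 0])
    y = np.interp(t_lo, time, pos[:, 1])
    if len(t_lo) < 2:
        return []
    speed = np.hypot(np.diff(x), np.diff(y)) * sample_rate
    events = []
    for s, e in _runs(speed > config.escape_speed_threshold):
        onset = float(t_lo[s])
        ev = EscapeEvent(onset=onset, peak_speed=float(speed[s:e].max()))
        if stimulus_onsets is not None and len(stimulus_onsets):
            prior = np.asarray(stimulus_onsets)[np.asarray(stimulus_onsets) <= onset]
            if len(prior):
                ev.latency = onset - float(prior[-1])
        events.append(ev)
    return events


def epochs_to_frame(epochs: list[HuntingEpoch]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in epochs],
                        columns=["onset", "offset", "dominant_eye",
                                 "onset_index", "offset_index"])


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bouts],
                        columns=["onset", "offset", "peak_velocity", "displacement",
                                 "turn", "onset_index", "offset_index"])
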