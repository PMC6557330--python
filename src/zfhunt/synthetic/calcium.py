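"""Synthetic trial-structured calcium recordings.

Builds a pseudo-random stimulus schedule (whole-field flashes, prey-like
spots moving clockwise/counterclockwise, looms and luminance-matched
dimming), assigns each cell a response class, places class-specific event
trains (stimulus-locked for visual classes; convergence-locked, GO-only,
for convergence-modulated cells), convolves with a single-exponential
kernel and samples at the imaging frame rate with additive Gaussian noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import CalciumSimConfig
from ..containers import ActivityMatrix, TrialTable

STIM_TYPES = ("flash-light", "flash-dark", "spot-CW", "spot-CCW", "loom", "dimming")
STIM_DURATION = {"flash-light": 3.0, "flash-dark": 3.0, "spot-CW": 5.0,
                 "spot-CCW": 5.0, "loom": 3.0, "dimming": 3.0}

# stimulus types that drive each visual cell class (amplitude scale factors)
CLASS_DRIVE = {
    "whole-field": {"flash-light": 1.0, "flash-dark": 1.0},
    "spot-CW": {"spot-CW": 1.0},
    "spot-CCW": {"spot-CCW": 1.0},
    "loom-phasic": {"loom": 1.0},
    "loom-sustained": {"loom": 0.8},
    "dimming-nonselective": {"loom": 1.0, "dimming": 1.0},
}


def _schedule(config: CalciumSimConfig, rng: np.random.Generator):
    """Pseudo-random interleaved stimulus order with fixed ISI."""
    order = [s for s in STIM_TYPES for _ in range(config.n_repeats)]
    rng.shuffle(order)
    rows = []
    t = config.isi
    for i, stim in enumerate(order):
        dur = STIM_DURATION[stim]
        rows.append(dict(stim_id=i, type=stim, onset=t, offset=t + dur))
        t += dur + config.isi
    return pd.DataFrame(rows), t


def simulate_calcium(
    config: CalciumSimConfig,
) -> tuple[ActivityMatrix, TrialTable, pd.DataFrame]:
    """Simulate one imaging session.

    Returns the raw (not yet z-scored) fluorescence wrapped in an
    ActivityMatrix, the trial table, and a per-cell ground-truth table with
    the true class and (for convergence cells) the preferred side.
    """
    rng = np.random.default_rng(config.seed)
    stimuli, total = _schedule(config, rng)

    # GO/NO-GO labels for prey-spot trials and convergence events
    go_col = np.full(len(stimuli), np.nan)
    conv_rows = []
    for i, row in stimuli.iterrows():
        if row["type"] in ("spot-CW", "spot-CCW"):
            go = rng.random() < config.go_fraction
            go_col[i] = float(go)
            if go:
                t_conv = row["onset"] + rng.uniform(0.5, row["offset"] - row["onset"] - 0.5)
                # eye contralateral to spot motion direction dominates
                side = "right" if row["type"] == "spot-CW" else "left"
                conv_rows.append(dict(time=t_conv, side=side, spontaneous=False,
                                      stim_id=int(row["stim_id"])))
    stimuli = stimuli.assign(go=go_col)

    # spontaneous convergences in stimulus-free periods, away from epochs
    n_spont = rng.poisson(config.spont_conv_rate * total / 60.0)
    onsets = stimuli["onset"].to_numpy()
    offsets = stimuli["offset"].to_numpy()
    placed = 0
    guard = 0
    while placed < n_spont and guard < 10000:
        guard += 1
        t_c = rng.uniform(5.0, total - 5.0)
        # keep the 4 s analysis window clear of stimulus epochs
        if np.any((t_c > onsets - 2.5) & (t_c < offsets + 2.5)):
            continue
        if any(abs(t_c - r["time"]) < 8.0 for r in conv_rows):
            continue
        conv_rows.append(dict(time=t_c, side=rng.choice(["left", "right"]),
                              spontaneous=True, stim_id=-1))
        placed += 1
    convergences = pd.DataFrame(conv_rows, columns=["time", "side", "spontaneous",
                                                    "stim_id"]).sort_values(
        "time").reset_index(drop=True)

    # cell roster: classes drawn from the mixture within each region
    classes = list(config.mixture)
    probs = np.array([config.mixture[c] for c in classes])
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))  # silent remainder
    classes.append("silent")
    cells = []
    for region, count in config.n_cells.items():
        for _ in range(count):
            cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
            side = rng.choice(["left", "right"])
            pref = rng.choice(["left", "right"]) if cls == "convergence-modulated" else ""
            cells.append(dict(region=region, side=side, cell_class=cls,
                              preferred_side=pref))
    truth = pd.DataFrame(cells)
    truth.insert(0, "roi_id", np.arange(len(truth)))

    n_frames = int(np.ceil(total * config.frame_rate)) + 1
    frame_times = np.arange(n_frames) / config.frame_rate
    F = np.zeros((len(truth), n_frames))

    def kernel_at(event_t: float, amp: float) -> np.ndarray:
        dt = frame_times - event_t
        out = np.zeros(n_frames)
        m = dt >= 0
        out[m] = amp * np.exp(-dt[m] / config.kernel_tau)
        return out

    amp = config.response_amplitude
    for i, row in truth.iterrows():
        cls = row["cell_class"]
        if cls == "silent":
            continue
        if cls == "convergence-modulated":
            sel = convergences[convergences["side"] == row["preferred_side"]]
            for t_c in sel["time"]:
                F[i] += kernel_at(t_c, amp)
            continue
        drive = CLASS_DRIVE[cls]
        for _, st in stimuli.iterrows():
            scale = drive.get(st["type"], 0.0)
            if scale == 0.0:
                continue
            jitter = rng.uniform(0.0, 0.2)
            if cls == "loom-phasic":
                F[i] += kernel_at(st["offset"] - 0.2 + jitter, amp * scale)
            elif cls == "loom-sustained":
                # sustained: events spread through the epoch
                for frac in (0.2, 0.5, 0.8):
                    F[i] += kernel_at(st["onset"] + frac * (st["offset"] - st["onset"]),
                                      amp * scale * 0.5)
            else:
                F[i] += kernel_at(st["onset"] + jitter, amp * scale)

    if config.noise_sd > 0:
        F += rng.normal(0.0, config.noise_sd, F.shape)

    rois = truth[["roi_id", "region", "side"]].copy()
    activity = ActivityMatrix(F=F, frame_times=frame_times, rois=rois)
    return activity, TrialTable(stimuli=stimuli, convergences=convergences), truth
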