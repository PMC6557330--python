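"""Trial-based calcium statistics: z-scoring, visual response vectors,
two-stage correlation clustering, and the convergence modulation index.

The convergence modulation index (CMI) quantifies hunting-related (motor)
activity: for each GO event, mean activity in a 4 s window centered on the
convergent saccade is compared against activity in the same epoch-relative
window of NO-GO presentations of the same stimulus, in units of the NO-GO
standard deviation; the CMI is the mean of these distances over GO events.
Cells with CMI > 3 are "CMI+".  Sp-CMI is the analog for spontaneous
convergences, referenced against stimulus-free baseline windows.  Chance
levels come from circularly permuting each cell's time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .config import NeuralConfig
from .containers import ActivityMatrix, TrialTable


# --------------------------------------------------------------------------
# z-scoring

def zscore(raw_F: np.ndarray, frame_times: np.ndarray,
           rois: pd.DataFrame, eps: float = 1e-6) -> ActivityMatrix:
    """Standardize each ROI trace over the full recording.

    Flat traces (SD < eps) map to all-zero and are flagged in the ROI table.
    """
    F = np.asarray(raw_F, dtype=float)
    mu = F.mean(axis=1, keepdims=True)
    sd = F.std(axis=1, keepdims=True)
    flat = sd[:, 0] < eps
    sd[flat] = 1.0
    out = (F - mu) / sd
    out[flat] = 0.0
    rois = rois.copy()
    rois["flat"] = flat
    return ActivityMatrix(F=out, frame_times=np.asarray(frame_times), rois=rois)


# --------------------------------------------------------------------------
# visual response vectors

@dataclass
class VRVMatrix:
    vrvs: np.ndarray            # (n_rois, total_len)
    segments: dict              # stimulus type -> (start, stop) column range
    stim_order: list


def build_vrvs(activity: ActivityMatrix, trials: TrialTable,
               config: NeuralConfig | None = None,
               stim_order: list | None = None) -> VRVMatrix:
    """Concatenate per-stimulus trial-averaged responses into VRVs.

    For each stimulus type, every repetition's trace is linearly
    interpolated onto a fixed epoch-relative frame grid (epoch onsets are
    asynchronous to the frame clock), averaged across repetitions, and the
    averages are concatenated in a fixed stimulus order.  Types with zero
    repetitions are excluded from the segment map with a warning.
    """
    import warnings

    config = config or NeuralConfig()
    stimuli = trials.stimuli
    if stim_order is None:
        stim_order = sorted(stimuli["type"].unique())
    rate = activity.frame_rate
    pieces = []
    segments = {}
    kept_order = []
    col = 0
    for stim in stim_order:
        eps = stimuli[stimuli["type"] == stim]
        if len(eps) == 0:
            warnings.warn(f"stimulus type {stim!r} has zero repetitions; excluded")
            continue
        dur = float((eps["offset"] - eps["onset"]).max()) + config.vrv_tail
        grid = np.arange(0.0, dur, 1.0 / rate)
        acc = np.zeros((activity.n_rois, len(grid)))
        for _, row in eps.iterrows():
            tt = row["onset"] + grid
            for r in range(activity.n_rois):
                acc[r] += np.interp(tt, activity.frame_times, activity.F[r])
        acc /= len(eps)
        pieces.append(acc)
        segments[stim] = (col, col + len(grid))
        col += len(grid)
        kept_order.append(stim)
    vrvs = np.concatenate(pieces, axis=1) if pieces else np.zeros((activity.n_rois, 0))
    return VRVMatrix(vrvs=vrvs, segments=segments, stim_order=kept_order)


# --------------------------------------------------------------------------
# two-stage clustering

@dataclass
class ClusterResult:
    assignments: np.ndarray     # archetype index per ROI, -1 unassigned
    centroids: np.ndarray       # (n_archetypes, vrv_len)
    stage1_labels: np.ndarray
    member_distances: np.ndarray  # distance to assigned centroid, NaN if none


def _corr_dist(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 1.0
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def cluster_vrvs(vrvs: np.ndarray, config: NeuralConfig | None = None) -> ClusterResult:
    """Two-stage agglomerative clustering with a correlation distance metric.

    Stage 1: average-linkage dendrogram cut at distance 1 - 0.9; clusters
    define candidate centroids (member means).  Stage 2: members farther
    than 0.5 from their centroid are pruned (single pass); surviving
    clusters of at least ``archetype_min_size`` members become archetypes.
    Stage 3: the dendrogram is re-cut at 1 - 0.7 and every member of those
    lenient clusters is assigned de novo to the nearest archetypal centroid
    within distance 0.5; everything else is unassigned.  If no archetype
    survives, all ROIs are unassigned (a valid result).
    """
    config = config or NeuralConfig()
    X = np.asarray(vrvs, dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need >= 2 VRVs")
    variable = X.std(axis=1) > 1e-12
    assignments = np.full(n, -1, dtype=int)
    member_dist = np.full(n, np.nan)
    idx = np.nonzero(variable)[0]
    if len(idx) < 2:
        return ClusterResult(assignments, np.zeros((0, X.shape[1])),
                             np.full(n, -1, dtype=int), member_dist)
    Xv = X[idx]
    d = pdist(Xv, metric="correlation")
    d = np.clip(d, 0.0, 2.0)
    Z = linkage(d, method="average")
    strict = fcluster(Z, t=1.0 - config.strict_corr, criterion="distance")
    stage1 = np.full(n, -1, dtype=int)
    stage1[idx] = strict

    centroids = []
    for lab in np.unique(strict):
        members = Xv[strict == lab]
        if len(members) < 2:
            continue
        centroid = members.mean(axis=0)
        dists = np.array([_corr_dist(m, centroid) for m in members])
        if (dists <= config.centroid_dist_limit).sum() >= config.archetype_min_size:
            centroids.append(centroid)
    centroids = np.array(centroids) if centroids else np.zeros((0, X.shape[1]))
    if len(centroids) == 0:
        return ClusterResult(assignments, centroids, stage1, member_dist)

    lenient = fcluster(Z, t=1.0 - config.lenient_corr, criterion="distance")
    counts = pd.Series(lenient).value_counts()
    for j, gi in enumerate(idx):
        if counts[lenient[j]] < 2:
            continue  # singleton at the lenient cut: never entered a cluster
        dists = np.array([_corr_dist(Xv[j], c) for c in centroids])
        k = int(np.argmin(dists))
        if dists[k] <= config.centroid_dist_limit:
            assignments[gi] = k
            member_dist[gi] = dists[k]
    return ClusterResult(assignments, centroids, stage1, member_dist)


# --------------------------------------------------------------------------
# convergence modulation index

@dataclass
class CmiResult:
    side: str
    spontaneous: bool
    cmi: np.ndarray             # (n_rois,), NaN if undefined
    n_events: np.ndarray        # usable GO events per ROI
    distances: list             # per ROI: array of d_i values

    def positive(self, cutoff: float = 3.0) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.cmi > cutoff


def _window_mean(F: np.ndarray, frame_times: np.ndarray, center: float,
                 half: float, min_cover: float = 0.5):
    """Mean of F over [center-half, center+half] per ROI, or None if the
    window is truncated below min_cover of its nominal sample count."""
    i0 = int(np.searchsorted(frame_times, center - half, side="left"))
    i1 = int(np.searchsorted(frame_times, center + half, side="right"))
    rate = 1.0 / np.median(np.diff(frame_times))
    expected = max(1, int(np.floor(2 * half * rate)))
    if i1 - i0 < min_cover * expected or i1 <= i0:
        return None
    return F[:, i0:i1].mean(axis=1)


def _collect_windows(activity: ActivityMatrix, trials: TrialTable, side: str,
                     config: NeuralConfig):
    """Per GO event of the given side: (GO center, list of NO-GO centers)."""
    stimuli = trials.stimuli
    conv = trials.convergences
    go_events = conv[(~conv["spontaneous"]) & (conv["side"] == side)]
    out = []
    for _, ev in go_events.iterrows():
        srow = stimuli[stimuli["stim_id"] == ev["stim_id"]]
        if len(srow) != 1:
            continue
        srow = srow.iloc[0]
        delta = float(ev["time"] - srow["onset"])
        nogo = stimuli[(stimuli["type"] == srow["type"]) & (stimuli["go"] == 0.0)]
        centers = [float(o + delta) for o in nogo["onset"]]
        out.append((float(ev["time"]), centers))
    return out


def _spont_windows(activity: ActivityMatrix, trials: TrialTable, side: str,
                   config: NeuralConfig):
    """Spontaneous events vs stimulus-free, convergence-free baseline centers."""
    conv = trials.convergences
    events = conv[conv["spontaneous"] & (conv["side"] == side)]
    half = config.cmi_window / 2.0
    t0 = activity.frame_times[0] + half
    t1 = activity.frame_times[-1] - half
    grid = np.arange(t0, t1, 2.0)
    on = trials.stimuli["onset"].to_numpy()
    off = trials.stimuli["offset"].to_numpy()
    all_conv = conv["time"].to_numpy()
    ok = np.ones(len(grid), dtype=bool)
    for i, g in enumerate(grid):
        if np.any((g + half > on) & (g - half < off)):
            ok[i] = False
        elif len(all_conv) and np.min(np.abs(all_conv - g)) < config.cmi_window:
            ok[i] = False
    baseline = [float(g) for g in grid[ok]]
    return [(float(ev["time"]), baseline) for _, ev in events.iterrows()]


def compute_cmi(activity: ActivityMatrix, trials: TrialTable, side: str,
                config: NeuralConfig | None = None,
                spontaneous: bool = False,
                F: np.ndarray | None = None) -> CmiResult:
    """Convergence (or spontaneous-convergence) modulation index per ROI.

    For each GO event: X_GO is the mean z-scored activity in the
    ``cmi_window`` (4 s) centered on the convergent saccade; the NO-GO
    reference samples are the means over the identical epoch-relative
    window in NO-GO epochs of the same stimulus type (>= ``min_nogo``
    required, sample SD with n-1); d_i = (X_GO - mean)/SD and the CMI is
    the mean of the d_i.  Computed separately per convergence side.
    """
    config = config or NeuralConfig()
    if F is None:
        F = activity.F
    half = config.cmi_window / 2.0
    pairs = (_spont_windows if spontaneous else _collect_windows)(
        activity, trials, side, config)
    n_rois = F.shape[0]
    dlists: list[list] = [[] for _ in range(n_rois)]
    for center, ref_centers in pairs:
        x = _window_mean(F, activity.frame_times, center, half)
        if x is None:
            continue
        refs = []
        for rc in ref_centers:
            m = _window_mean(F, activity.frame_times, rc, half)
            if m is not None:
                refs.append(m)
        if len(refs) < config.min_nogo:
            continue
        R = np.stack(refs)                       # (n_ref, n_rois)
        mu = R.mean(axis=0)
        sd = R.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (x - mu) / sd
        for r in range(n_rois):
            if sd[r] >= config.flat_eps and np.isfinite(d[r]):
                dlists[r].append(float(d[r]))
    cmi = np.array([np.mean(dl) if dl else np.nan for dl in dlists])
    n_events = np.array([len(dl) for dl in dlists])
    return CmiResult(side=side, spontaneous=spontaneous, cmi=cmi,
                     n_events=n_events, distances=[np.array(dl) for dl in dlists])


def shuffle_null(activity: ActivityMatrix, trials: TrialTable, side: str,
                 n_perm: int | None = None,
                 config: NeuralConfig | None = None,
                 spontaneous: bool = False,
                 seed: int | np.random.Generator = 0) -> dict:
    """Null CMI distribution by circular permutation of each cell's trace.

    Each permutation circularly shifts F(t) by a random amount (shared
    event structure, per-ROI independent shifts) and recomputes the CMI.
    Returns the (n_perm, n_rois) null matrix plus chance-level summaries
    (mean null CMI and null CMI+ fraction per ROI).
    """
    config = config or NeuralConfig()
    if n_perm is None:
        n_perm = config.n_perm
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = activity.F.shape[1]
    null = np.empty((n_perm, activity.n_rois))
    for p in range(n_perm):
        shifts = rng.integers(0, n_frames, size=activity.n_rois)
        Fs = np.empty_like(activity.F)
        for r in range(activity.n_rois):
            Fs[r] = np.roll(activity.F[r], shifts[r])
        null[p] = compute_cmi(activity, trials, side, config,
                              spontaneous=spontaneous, F=Fs).cmi
    with np.errstate(invalid="ignore"):
        return {
            "null": null,
            "null_mean": np.nanmean(null, axis=0),
            "null_positive_fraction": np.nanmean(null > config.cmi_positive_cutoff,
                                                 axis=0),
        }


# --------------------------------------------------------------------------
# responsiveness and region summaries

def visually_responsive(activity: ActivityMatrix, trials: TrialTable,
                        k_sd: float = 2.0) -> np.ndarray:
    """Repository convention for 'visually responsive' ROIs.

    An ROI is responsive if the maximum |mean F| over any stimulus epoch
    exceeds ``k_sd`` times the SD of its activity outside stimulus epochs.
    """
    t = activity.frame_times
    in_stim = np.zeros(len(t), dtype=bool)
    for _, row in trials.stimuli.iterrows():
        in_stim |= (t >= row["onset"]) & (t <= row["offset"])
    base_sd = activity.F[:, ~in_stim].std(axis=1)
    base_sd[base_sd < 1e-12] = np.inf
    best = np.zeros(activity.n_rois)
    for _, row in trials.stimuli.iterrows():
        sel = (t >= row["onset"]) & (t <= row["offset"])
        if sel.sum() == 0:
            continue
        best = np.maximum(best, np.abs(activity.F[:, sel].mean(axis=1)))
    return best > k_sd * base_sd


def region_summaries(cmi_by_side: dict[str, CmiResult], rois: pd.DataFrame,
                     assignments: np.ndarray | None = None,
                     null_by_side: dict[str, dict] | None = None,
                     config: NeuralConfig | None = None) -> dict:
    """Per region x convergence side: mean CMI, CMI+ fraction, chance level.

    Also a cross-tabulation of cluster identity vs CMI+ and the
    ipsi/contra lateralization contrast: 'ipsi' means the ROI hemisphere
    ipsilateral to the more-converging (dominant) eye.
    """
    import warnings

    config = config or NeuralConfig()
    cut = config.cmi_positive_cutoff
    rows = []
    for side, res in cmi_by_side.items():
        for region, grp in rois.groupby("region"):
            i = grp.index.to_numpy()
            vals = res.cmi[i]
            valid = np.isfinite(vals)
            if valid.sum() == 0:
                warnings.warn(f"region {region!r} has no usable CMI for side {side}")
                continue
            row = dict(region=region, conv_side=side,
                       mean_cmi=float(np.mean(vals[valid])),
                       frac_positive=float(np.mean(vals[valid] > cut)),
                       n=int(valid.sum()))
            if null_by_side and side in null_by_side:
                nm = null_by_side[side]["null_mean"][i]
                nf = null_by_side[side]["null_positive_fraction"][i]
                row["chance_mean_cmi"] = float(np.nanmean(nm[valid]))
                row["chance_frac_positive"] = float(np.nanmean(nf[valid]))
            rows.append(row)
    by_region = pd.DataFrame(rows)

    # lateralization: per ROI, CMI for convergences ipsi vs contra to its side
    lat = None
    if set(cmi_by_side) == {"left", "right"}:
        side_arr = rois["side"].to_numpy()
        ipsi = np.where(side_arr == "left", cmi_by_side["left"].cmi,
                        cmi_by_side["right"].cmi)
        contra = np.where(side_arr == "left", cmi_by_side["right"].cmi,
                          cmi_by_side["left"].cmi)
        lat = pd.DataFrame({"roi_id": rois["roi_id"], "region": rois["region"],
                            "ipsi_cmi": ipsi, "contra_cmi": contra})

    crosstab = None
    if assignments is not None:
        pooled = np.nanmax(np.stack([r.cmi for r in cmi_by_side.values()]), axis=0)
        with np.errstate(invalid="ignore"):
            pos = pooled > cut
        crosstab = pd.crosstab(pd.Series(assignments, name="cluster"),
                               pd.Series(pos, name="cmi_positive"))
    return {"by_region": by_region, "lateralization": lat, "crosstab": crosstab}
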