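"""Calcium statistics: z-scoring, VRVs, clustering, CMI and shuffle null."""

import numpy as np
import pandas as pd
import pytest

from zfhunt.config import CalciumSimConfig, NeuralConfig
from zfhunt.containers import ActivityMatrix, TrialTable
from zfhunt.neural import (CmiResult, build_vrvs, cluster_vrvs, compute_cmi,
                           region_summaries, shuffle_null, visually_responsive,
                           zscore)
from zfhunt.synthetic import simulate_calcium

NCFG = NeuralConfig()


def _rois(n, region="OT", side="left"):
    return pd.DataFrame({"roi_id": np.arange(n), "region": region, "side": side})


# --------------------------------------------------------------------------
# z-scoring

def test_zscore_standardizes():
    act = zscore(np.arange(10, dtype=float)[None], np.arange(10.0), _rois(1))
    assert act.F.mean() == pytest.approx(0.0, abs=1e-12)
    assert act.F.std() == pytest.approx(1.0)


def test_flat_trace_zeroed_and_flagged():
    act = zscore(np.full((1, 20), 7.0), np.arange(20.0), _rois(1))
    assert (act.F == 0).all()
    assert act.rois["flat"].iloc[0]


def test_zscore_affine_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (3, 50))
    a = zscore(x, np.arange(50.0), _rois(3)).F
    b = zscore(2.5 * x + 7.0, np.arange(50.0), _rois(3)).F
    np.testing.assert_allclose(a, b, atol=1e-12)


# --------------------------------------------------------------------------
# VRVs

def _single_stim_trials(onsets, stim="spot-CW", dur=5.0, go=None):
    rows = [dict(stim_id=i, type=stim, onset=o, offset=o + dur,
                 go=(go[i] if go is not None else np.nan))
            for i, o in enumerate(onsets)]
    return TrialTable(stimuli=pd.DataFrame(rows),
                      convergences=pd.DataFrame(
                          columns=["time", "side", "spontaneous", "stim_id"]))


def test_vrv_single_repetition_equals_trace():
    rate = 2.0
    t = np.arange(100) / rate
    F = np.sin(t)[None]
    act = ActivityMatrix(F=F, frame_times=t, rois=_rois(1))
    trials = _single_stim_trials([10.0])
    vrv = build_vrvs(act, trials)
    s0, s1 = vrv.segments["spot-CW"]
    grid = np.arange(0.0, 10.0, 1 / rate)
    np.testing.assert_allclose(vrv.vrvs[0, s0:s1], np.sin(10.0 + grid), atol=1e-9)


def test_vrv_mean_of_identical_repetitions_is_idempotent():
    rate = 2.0
    t = np.arange(200) / rate
    F = np.zeros((1, 200))
    for onset in (10.0, 50.0):
        sel = (t >= onset) & (t < onset + 5.0)
        F[0, sel] = 1.0
    act = ActivityMatrix(F=F, frame_times=t, rois=_rois(1))
    one = build_vrvs(act, _single_stim_trials([10.0]))
    two = build_vrvs(act, _single_stim_trials([10.0, 50.0]))
    np.testing.assert_allclose(one.vrvs, two.vrvs, atol=1e-9)


def test_vrv_segment_lengths_sum_to_total(calcium_bundle):
    _, raw, trials, _ = calcium_bundle
    act = zscore(raw.F, raw.frame_times, raw.rois)
    vrv = build_vrvs(act, trials)
    assert sum(b - a for a, b in vrv.segments.values()) == vrv.vrvs.shape[1]


def test_noiseless_spot_cell_vrv_peaks_in_its_segment():
    cfg = CalciumSimConfig(seed=1, noise_sd=0.0, n_cells={"OT": 6},
                           mixture={"spot-CW": 1.0}, n_repeats=4)
    raw, trials, truth = simulate_calcium(cfg)
    act = zscore(raw.F, raw.frame_times, raw.rois)
    vrv = build_vrvs(act, trials)
    cw0, cw1 = vrv.segments["spot-CW"]
    ccw0, ccw1 = vrv.segments["spot-CCW"]
    for row in vrv.vrvs:
        assert row[cw0:cw1].max() > 5 * max(1e-9, abs(row[ccw0:ccw1]).max())


def test_noiseless_convergence_cell_is_go_locked():
    cfg = CalciumSimConfig(seed=2, noise_sd=0.0, n_cells={"aCh-A": 8},
                           mixture={"convergence-modulated": 1.0},
                           n_repeats=6, go_fraction=0.5, spont_conv_rate=0.0)
    raw, trials, truth = simulate_calcium(cfg)
    conv = trials.convergences
    for i, row in truth.iterrows():
        pref = conv[conv["side"] == row["preferred_side"]]
        f = raw.F[i]
        if len(pref) == 0:
            assert np.allclose(f, 0)
            continue
        assert f.max() > 1.0
        first = pref["time"].min()
        before = raw.frame_times < first - 1e-9
        assert np.allclose(f[before], 0.0)


def test_silent_noiseless_recording_is_zero_after_guard():
    cfg = CalciumSimConfig(seed=3, noise_sd=0.0, n_cells={"OT": 4}, mixture={})
    raw, trials, _ = simulate_calcium(cfg)
    act = zscore(raw.F, raw.frame_times, raw.rois)
    assert (act.F == 0).all()
    assert act.rois["flat"].all()


def test_calcium_determinism():
    cfg = CalciumSimConfig(seed=11, n_cells={"OT": 5}, n_repeats=3)
    a, ta, _ = simulate_calcium(cfg)
    b, tb, _ = simulate_calcium(cfg)
    np.testing.assert_array_equal(a.F, b.F)
    pd.testing.assert_frame_equal(ta.stimuli, tb.stimuli)


def test_rejects_nonpositive_kernel_tau():
    with pytest.raises(ValueError, match="kernel_tau"):
        CalciumSimConfig(kernel_tau=0.0)


def test_event_rate_conservation(calcium_bundle):
    """Total convergences = GO-trial count + spontaneous count."""
    _, _, trials, _ = calcium_bundle
    n_go_trials = int((trials.stimuli["go"] == 1.0).sum())
    conv = trials.convergences
    assert (~conv["spontaneous"]).sum() == n_go_trials
    assert len(conv) == n_go_trials + conv["spontaneous"].sum()


# --------------------------------------------------------------------------
# clustering

def test_identical_vrvs_form_one_archetype():
    base = np.sin(np.linspace(0, 6, 80))
    X = np.tile(base, (20, 1))
    res = cluster_vrvs(X)
    assert len(res.centroids) == 1
    assert (res.assignments == 0).all()


def test_two_orthogonal_templates_recovered():
    rng = np.random.default_rng(4)
    t = np.linspace(0, 6, 120)
    tmpl = [np.sin(t), np.cos(3 * t)]
    X, labels = [], []
    for k, tp in enumerate(tmpl):
        for _ in range(50):
            X.append(tp + rng.normal(0, 0.15, len(t)))
            labels.append(k)
    X, labels = np.array(X), np.array(labels)
    res = cluster_vrvs(X)
    assert len(res.centroids) == 2
    ok = 0
    for k in (0, 1):
        got = res.assignments[labels == k]
        vals, counts = np.unique(got[got >= 0], return_counts=True)
        ok += counts.max()
    assert ok >= 0.95 * len(X)


def test_pure_noise_yields_zero_archetypes():
    rng = np.random.default_rng(6)
    res = cluster_vrvs(rng.normal(0, 1, (40, 60)))
    assert len(res.centroids) == 0
    assert (res.assignments == -1).all()


def test_members_within_distance_limit_of_centroid():
    rng = np.random.default_rng(7)
    t = np.linspace(0, 6, 120)
    X = np.array([np.sin(t) + rng.normal(0, 0.3, len(t)) for _ in range(30)])
    res = cluster_vrvs(X)
    d = res.member_distances[res.assignments >= 0]
    assert (d <= NCFG.centroid_dist_limit + 1e-12).all()


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(8)
    t = np.linspace(0, 6, 120)
    X = np.concatenate([
        [np.sin(t) + rng.normal(0, 0.1, len(t)) for _ in range(12)],
        [np.cos(2 * t) + rng.normal(0, 0.1, len(t)) for _ in range(12)]])
    perm = rng.permutation(len(X))
    a = cluster_vrvs(X).assignments
    b = cluster_vrvs(X[perm]).assignments
    # same partition up to label renaming
    for i in range(len(X)):
        for j in range(len(X)):
            same_a = a[perm[i]] == a[perm[j]] and a[perm[i]] >= 0
            same_b = b[i] == b[j] and b[i] >= 0
            assert same_a == same_b


# --------------------------------------------------------------------------
# CMI

def _hand_cmi_setup(go_mean=3.0, nogo_means=(0.0, 1.0, 2.0)):
    """One GO + three NO-GO epochs of one stimulus; window means are exact."""
    t = np.arange(100, dtype=float)     # 1 Hz frames
    F = np.zeros((1, 100))
    onsets = [8.0, 28.0, 48.0, 68.0]
    go = [1.0, 0.0, 0.0, 0.0]
    conv_t = 10.0                        # delta = 2 s after onset
    F[0, 8:13] = go_mean                 # frames in [8, 12]
    for onset, m in zip(onsets[1:], nogo_means):
        c = int(onset + 2)
        F[0, c - 2:c + 3] = m
    stimuli = pd.DataFrame([dict(stim_id=i, type="spot-CW", onset=o,
                                 offset=o + 5.0, go=g)
                            for i, (o, g) in enumerate(zip(onsets, go))])
    conv = pd.DataFrame([dict(time=conv_t, side="left", spontaneous=False,
                              stim_id=0)])
    act = ActivityMatrix(F=F, frame_times=t, rois=_rois(1))
    return act, TrialTable(stimuli=stimuli, convergences=conv)


def test_cmi_hand_worked_example():
    """GO window mean 3 vs NO-GO {0,1,2} (mean 1, sample SD 1): d1 = 2."""
    act, trials = _hand_cmi_setup()
    res = compute_cmi(act, trials, "left")
    assert res.cmi[0] == pytest.approx(2.0, abs=1e-9)
    assert res.n_events[0] == 1


def test_cmi_zero_when_go_equals_nogo_mean():
    act, trials = _hand_cmi_setup(go_mean=1.0)
    res = compute_cmi(act, trials, "left")
    assert res.cmi[0] == pytest.approx(0.0, abs=1e-9)


def test_cmi_event_dropped_when_nogo_sd_zero():
    act, trials = _hand_cmi_setup(nogo_means=(1.0, 1.0, 1.0))
    res = compute_cmi(act, trials, "left")
    assert np.isnan(res.cmi[0])
    assert res.n_events[0] == 0


def test_cmi_affine_invariant_to_raw_trace_scaling():
    cfg = CalciumSimConfig(seed=5, n_cells={"aCh-A": 10}, n_repeats=10)
    raw, trials, _ = simulate_calcium(cfg)
    a = compute_cmi(zscore(raw.F, raw.frame_times, raw.rois), trials, "left")
    b = compute_cmi(zscore(3.0 * raw.F - 11.0, raw.frame_times, raw.rois),
                    trials, "left")
    np.testing.assert_allclose(a.cmi, b.cmi, atol=1e-9)


def test_modulated_cells_separate_from_silent(calcium_bundle):
    _, raw, trials, truth = calcium_bundle
    act = zscore(raw.F, raw.frame_times, raw.rois)
    res = {s: compute_cmi(act, trials, s) for s in ("left", "right")}
    mod = truth["cell_class"] == "convergence-modulated"
    for i in truth.index[mod]:
        assert res[truth.loc[i, "preferred_side"]].cmi[i] > 3.0


def test_zero_shift_reproduces_observed_cmi(calcium_bundle):
    _, raw, trials, _ = calcium_bundle
    act = zscore(raw.F, raw.frame_times, raw.rois)
    obs = compute_cmi(act, trials, "left")
    rolled = compute_cmi(act, trials, "left", F=np.roll(act.F, 0, axis=1))
    np.testing.assert_allclose(obs.cmi, rolled.cmi, atol=1e-12)


def test_shuffle_null_deterministic_and_centered(calcium_bundle):
    _, raw, trials, _ = calcium_bundle
    act = zscore(raw.F, raw.frame_times, raw.rois)
    a = shuffle_null(act, trials, "left", n_perm=25, seed=3)
    b = shuffle_null(act, trials, "left", n_perm=25, seed=3)
    np.testing.assert_array_equal(a["null"], b["null"])
    assert abs(np.nanmean(a["null_mean"])) < 0.3


def test_spontaneous_cmi_runs(calcium_bundle):
    _, raw, trials, truth = calcium_bundle
    act = zscore(raw.F, raw.frame_times, raw.rois)
    for side in ("left", "right"):
        res = compute_cmi(act, trials, side, spontaneous=True)
        assert res.spontaneous
        mod = (truth["cell_class"] == "convergence-modulated") \
            & (truth["preferred_side"] == side)
        if mod.any() and np.isfinite(res.cmi[mod.to_numpy()]).any():
            assert np.nanmean(res.cmi[mod.to_numpy()]) > 1.0


# --------------------------------------------------------------------------
# summaries

def test_region_summary_ranks_modulated_region_highest():
    n = 30
    rois = pd.DataFrame({"roi_id": np.arange(n),
                         "region": ["aCh-A"] * 10 + ["OT"] * 10 + ["Ch-B"] * 10,
                         "side": ["left"] * n})
    cmi = np.zeros(n)
    cmi[:10] = 6.0
    res = CmiResult(side="left", spontaneous=False, cmi=cmi,
                    n_events=np.full(n, 5), distances=[np.array([])] * n)
    out = region_summaries({"left": res}, rois)
    by = out["by_region"].set_index("region")["mean_cmi"]
    assert by.idxmax() == "aCh-A"
    assert out["by_region"].set_index("region")["frac_positive"]["aCh-A"] == 1.0


def test_crosstab_conserves_cell_counts():
    n = 20
    rois = pd.DataFrame({"roi_id": np.arange(n), "region": "OT",
                         "side": ["left"] * n})
    cmi = np.concatenate([np.full(5, 6.0), np.zeros(15)])
    res = CmiResult(side="left", spontaneous=False, cmi=cmi,
                    n_events=np.full(n, 5), distances=[np.array([])] * n)
    assignments = np.array([0] * 8 + [1] * 6 + [-1] * 6)
    out = region_summaries({"left": res}, rois, assignments=assignments)
    ct = out["crosstab"]
    assert ct.to_numpy().sum() == n
    for lab in (-1, 0, 1):
        assert ct.loc[lab].sum() == (assignments == lab).sum()


def test_visually_responsive_flags_driven_cells():
    cfg = CalciumSimConfig(seed=6, n_cells={"OT": 20}, n_repeats=8,
                           mixture={"whole-field": 0.5})
    raw, trials, truth = simulate_calcium(cfg)
    act = zscore(raw.F, raw.frame_times, raw.rois)
    resp = visually_responsive(act, trials)
    wf = (truth["cell_class"] == "whole-field").to_numpy()
    assert resp[wf].mean() > 0.9
    assert resp[~wf].mean() < 0.3
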