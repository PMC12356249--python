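import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sstclassify import features as feat
from sstclassify import preprocess as pp
from sstclassify.session import (CellRegistry, Experiment, Session,
                                 seconds_to_frames)
from conftest import make_trial, trial_with_peak


def test_feature_grid_is_large_unique_and_roundtrips(tmp_path):
    grid = feat.default_feature_grid()
    names = [s.name for s in grid]
    assert len(grid) >= 100  # full combinatorial instantiation
    assert len(set(names)) == len(names)
    for name in names:
        assert feat.spec_from_name(name) in grid
    path = tmp_path / "grid.json"
    feat.grid_to_json(grid, path)
    assert feat.grid_from_json(path) == grid


def test_sigma1_is_population_sd_of_concatenated_baselines():
    # two trials with baselines [0,0] and [1,1] -> sigma1 = 0.5
    rate = 2.0
    n = seconds_to_frames(3, rate) + seconds_to_frames(5, rate)
    base = seconds_to_frames(3, rate)
    dffs = []
    for v in (0.0, 1.0):
        d = np.zeros(n)
        d[base - 2:base] = v
        dffs.append(d)
    trials = [make_trial(d, rate=rate) for d in dffs]
    sig = feat.compute_sigmas(trials, np.zeros(100))
    assert sig.sigma1 == pytest.approx(0.5)
    assert sig.sigma2 == 0.0


def test_sigma1_ignores_post_onset_transients_sigma2_does_not():
    rate = 5.0
    trials = [trial_with_peak(0.0, rate), trial_with_peak(0.0, rate)]
    quiet = feat.compute_sigmas(trials, np.zeros(200))
    spont = np.zeros(200)
    spont[100:105] = 5.0  # large transient in the session trace
    loud = feat.compute_sigmas(trials, spont)
    assert loud.sigma1 == quiet.sigma1
    assert loud.sigma2 > quiet.sigma2
    with pytest.raises(ValueError, match="no valid trials"):
        feat.compute_sigmas([], np.zeros(10))


def test_response_probability_fraction_and_monotonicity():
    sigma1 = 1.0
    trials = [trial_with_peak(p) for p in (0.5, 2.0, 4.0)]
    assert feat.response_probability(trials, 1, sigma1) == pytest.approx(2 / 3)
    assert feat.response_probability(trials, 100, sigma1) == 0.0
    rng = np.random.default_rng(3)
    random_trials = [trial_with_peak(p) for p in rng.lognormal(0, 1, 20)]
    probs = [feat.response_probability(random_trials, k, sigma1)
             for k in (1, 2, 3, 5, 10)]
    assert all(a >= b for a, b in zip(probs, probs[1:]))


def test_in_trial_metrics_on_constructed_transients():
    rate = 5.0
    n = seconds_to_frames(3, rate) + seconds_to_frames(5, rate)
    base = seconds_to_frames(3, rate)
    # triangle peaking exactly 1 s after onset
    d = np.zeros(n)
    apex = base + seconds_to_frames(1, rate)
    d[apex - 3:apex + 4] = [0.2, 0.5, 0.8, 1.1, 0.8, 0.5, 0.2]
    m = feat.in_trial_metrics(make_trial(d, rate=rate), "response")
    assert m["peak"] == pytest.approx(1.1)
    assert m["peak_latency"] == pytest.approx(1.0)
    # symmetric transient -> center of mass at the symmetry point
    assert m["center_of_mass"] == pytest.approx(1.0)
    # interior rectangle of height h over m frames: trapezoidal AUC is
    # h*(m-1)*dt for the flat top plus two h*dt/2 edge triangles = h*m*dt
    d = np.zeros(n)
    d[base + 2:base + 8] = 2.0
    m = feat.in_trial_metrics(make_trial(d, rate=rate), "response")
    assert m["auc"] == pytest.approx(2.0 * 6 / rate)
    # all-nonpositive segment: midpoint substituted and flagged
    m = feat.in_trial_metrics(make_trial(np.full(n, -0.1), rate=rate),
                              "response")
    assert not m["com_defined"]
    seg_len = seconds_to_frames(2, rate)
    assert m["center_of_mass"] == pytest.approx((seg_len - 1) / rate / 2)


def test_event_detection_by_prominence():
    sigma2 = 1.0
    flat = np.zeros(100)
    assert len(feat.detect_spontaneous_events(flat, 1, sigma2)["frame"]) == 0
    # one isolated bump of height 5 sigma: prominence equals its height
    bump = np.zeros(100)
    bump[48:53] = [1.0, 3.0, 5.0, 3.0, 1.0]
    ev = feat.detect_spontaneous_events(bump, 3, sigma2)
    assert list(ev["frame"]) == [50]
    assert ev["amplitude"][0] == pytest.approx(5.0)
    assert ev["prominence"][0] == pytest.approx(5.0)
    # counts non-increasing in k; NaN gaps split segments without error
    rng = np.random.default_rng(0)
    noisy = rng.normal(0, 1, 500)
    noisy[100:110] = np.nan
    counts = [len(feat.detect_spontaneous_events(noisy, k, 1.0)["frame"])
              for k in range(1, 11)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def _deterministic_experiment(n_cells=2, peak=0.5):
    """Two identical cells with one rectangular evoked transient per trial."""
    rate = 5.0
    flank = seconds_to_frames(100, rate)
    onsets = [(flank + i * seconds_to_frames(20, rate),
               "stimulus" if i % 2 == 0 else "blank") for i in range(6)]
    n = onsets[-1][0] + seconds_to_frames(110, rate)
    f0 = 100.0
    trace = np.full(n, f0)
    for ofr, ttype in onsets:
        if ttype == "stimulus":
            trace[ofr + 2:ofr + 5] = f0 * (1 + peak)
    roi = np.tile(trace, (n_cells, 1))
    sessions = [
        Session(animal_id="m", fov_id="f", day_label=d,
                roi_traces=roi, neuropil_traces=np.zeros_like(roi),
                frame_shifts=np.zeros((n, 2), int), trial_onsets=onsets,
                frame_rate_hz=rate)
        for d in ("ACC4", "ACC5", "ACC6")
    ]
    reg = pd.DataFrame(
        {"cell_id": [f"c{i}" for i in range(n_cells)], "animal_id": "m",
         "fov_id": "f", "true_label": "unknown",
         **{f"idx_{d}": range(n_cells) for d in ("ACC4", "ACC5", "ACC6")}}
    )
    return Experiment(sessions=sessions, registry=CellRegistry(reg)), peak


def test_feature_matrix_matches_hand_computation_and_duplicates_rows():
    exp, peak = _deterministic_experiment()
    X, grid = feat.build_feature_matrix(exp)
    assert X.shape == (2, len(grid))
    # identical cells -> identical rows
    np.testing.assert_array_equal(X.iloc[0].values, X.iloc[1].values)
    # deterministic transient: evoked peak equals the constructed amplitude
    assert X.loc["c0", "trial|stimulus|response|peak"] == pytest.approx(peak)
    # every stimulus trial responds, baselines are exactly flat -> sigma1=0
    # and all peaks exceed any multiple of it
    assert X.loc["c0", "rp|stimulus|response|probability|k10"] == 1.0
    # blank trials carry no transient
    assert X.loc["c0", "trial|blank|response|peak"] == pytest.approx(0.0)
    # pretrial window is flat
    assert X.loc["c0", "trial|stimulus|pretrial|auc"] == pytest.approx(0.0)


def test_feature_ranking_matches_closed_form_t_test():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(
        rng.normal(0, 1, (10, 4)),
        columns=["a", "b", "separated", "constant"],
        index=[f"c{i}" for i in range(10)],
    )
    labels = pd.Series(["SST-Calb2"] * 5 + ["SST-O"] * 5, index=X.index)
    X["separated"] = np.r_[10 + rng.normal(0, 0.1, 5), rng.normal(0, 0.1, 5)]
    X["constant"] = 1.0
    ranked = feat.rank_features(X, labels)
    assert ranked.iloc[0]["feature"] == "separated"
    assert ranked.iloc[-1]["feature"] == "constant"
    assert bool(ranked.iloc[-1]["degenerate"])
    # closed-form check of the reported t statistic for one column
    a, b = X["a"][:5].values, X["a"][5:].values
    t_oracle = stats.ttest_ind(a, b).statistic
    row = ranked[ranked.feature == "a"].iloc[0]
    assert row["t"] == pytest.approx(t_oracle)
    assert feat.top_features(ranked, 3) == list(ranked["feature"][:3])


def test_top_features_dominated_by_response_probability_and_peak(
    two_class_features,
):
    X, y = two_class_features
    ranked = feat.rank_features(X, y)
    top = feat.top_features(ranked, 30)
    # stimulus-evoked specs (response probability + in-trial response
    # measurements) form the majority of the top 30, and response
    # probability dominates the very top of the ranking
    evoked = [f for f in top
              if f.startswith(("rp|", "trial|stimulus", "trial|all"))]
    assert len(evoked) >= 15
    assert sum(f.startswith("rp|") for f in top[:10]) >= 5
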