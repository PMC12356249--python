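import numpy as np
import pytest

from sstclassify import preprocess as pp
from sstclassify.session import Session, seconds_to_frames


def test_neuropil_correction_formula_and_linearity():
    np.testing.assert_allclose(pp.neuropil_correct([2.0], [1.0], r=0.7), [1.3])
    np.testing.assert_array_equal(pp.neuropil_correct([1, 1], [0, 0]), [1, 1])
    roi = np.array([5.0, 7.0])
    np.testing.assert_array_equal(pp.neuropil_correct(roi, [1.0, 2.0], r=0),
                                  roi)
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=50), rng.normal(size=50)
    np.testing.assert_allclose(
        pp.neuropil_correct(3.5 * x, 3.5 * y), 3.5 * pp.neuropil_correct(x, y)
    )
    with pytest.raises(ValueError, match="mismatch"):
        pp.neuropil_correct([1, 2], [1])


def test_shift_flagging_is_strict_beyond_20px():
    shifts = np.array([[21, 0], [0, -21], [20, 20], [0, 0]])
    np.testing.assert_array_equal(
        pp.flag_shifted_frames(shifts), [True, True, False, False]
    )
    assert not pp.flag_shifted_frames(np.zeros((10, 2))).any()


def test_short_shift_runs_interpolated_from_neighbors():
    trace = np.array([1.0, 99.0, 3.0])
    mask = np.array([False, True, False])
    filled, interp, long_run = pp.interpolate_runs(trace, mask)
    np.testing.assert_allclose(filled, [1.0, 2.0, 3.0])
    assert interp.tolist() == [False, True, False]
    assert not long_run.any()
    # run of two shifted frames shares the same neighbor mean
    trace = np.array([1.0, 0.0, 0.0, 5.0])
    filled, _, _ = pp.interpolate_runs(trace, [False, True, True, False])
    np.testing.assert_allclose(filled, [1.0, 3.0, 3.0, 5.0])
    # boundary run uses the single available neighbor
    filled, _, _ = pp.interpolate_runs([0.0, 7.0], [True, False])
    np.testing.assert_allclose(filled, [7.0, 7.0])


def test_long_runs_invalidate_overlapping_trials_only():
    rate = 5.0
    n = 200
    trace = np.ones(n)
    mask = np.zeros(n, dtype=bool)
    mask[100:105] = True  # 5-frame run inside the first trial's window
    onsets = [(102, "stimulus"), (160, "blank")]
    ct, valid = pp.interpolate_or_reject(trace, mask, onsets, rate)
    assert valid.tolist() == [False, True]
    assert ct.long_run_mask[100:105].all()
    assert not ct.interpolated_mask.any()


def test_exactly_three_consecutive_shifted_frames_reject_the_trial():
    # runs of >=3 are grouped with removal, not interpolated
    rate = 5.0
    mask = np.zeros(100, dtype=bool)
    mask[50:53] = True
    ct, valid = pp.interpolate_or_reject(np.ones(100), mask,
                                         [(52, "stimulus")], rate)
    assert not valid[0]
    assert not ct.interpolated_mask.any()


def test_no_shifts_is_identity_and_interpolation_is_idempotent():
    rng = np.random.default_rng(1)
    trace = rng.uniform(1, 2, 300)
    mask = rng.random(300) < 0.05
    ct, valid = pp.interpolate_or_reject(trace, np.zeros(300, bool),
                                         [(150, "stimulus")], 5.0)
    np.testing.assert_array_equal(ct.values, trace)
    assert valid.all()
    once, _, _ = pp.interpolate_runs(trace, mask)
    twice, _, _ = pp.interpolate_runs(once, mask)
    np.testing.assert_array_equal(once, twice)


def test_trial_dff_zero_on_constant_trace_and_local_baseline():
    rate = 5.0
    trace = np.full(300, 4.2)
    tw = pp.dff_trial(trace, 150, rate)
    assert tw.valid
    np.testing.assert_allclose(tw.dff, 0.0)
    # baseline mean 2.0, frame at 3.0 -> dff 0.5 there
    trace = np.full(300, 2.0)
    trace[160] = 3.0
    tw = pp.dff_trial(trace, 150, rate)
    idx = 160 - (150 - tw.onset_index)
    assert tw.dff[idx] == pytest.approx(0.5)
    # F0 depends only on pre-onset frames
    trace2 = trace.copy()
    trace2[151:] = 99.0
    assert pp.dff_trial(trace2, 150, rate).baseline_f0 == tw.baseline_f0


def test_trial_dff_invalid_on_bad_baseline_or_edges():
    rate = 5.0
    trace = np.full(100, -1.0)
    assert pp.dff_trial(trace, 50, rate).reason == "nonpositive_f0"
    assert pp.dff_trial(np.ones(100), 5, rate).reason == "edge"
    assert pp.dff_trial(np.ones(100), 95, rate).reason == "edge"


def test_sliding_percentile_matches_bruteforce_on_step_trace():
    # 200-frame toy trace with a step; oracle loops over explicit windows
    rate, window_s, q = 1.0, 5.0, 20.0
    x = np.concatenate([np.full(100, 1.0), np.full(100, 3.0)])
    x[50], x[150] = 10.0, 0.5
    f0 = pp.sliding_percentile_baseline(x, rate, window_s, q)
    w = seconds_to_frames(window_s, rate)
    assert w % 2 == 1
    half = w // 2
    oracle = np.array([
        np.percentile(x[max(0, i - half):min(len(x), i + half + 1)], q)
        for i in range(len(x))
    ])
    np.testing.assert_allclose(f0, oracle)
    # baseline tracks the lower level away from the step
    assert f0[20] == pytest.approx(1.0)
    assert f0[180] == pytest.approx(3.0)


def test_spontaneous_dff_conventions():
    rate = 1.0
    assert np.allclose(pp.dff_spontaneous(np.full(50, 2.0), rate, 5.0), 0.0)
    # percentile=0 on a monotone increasing trace -> F0 = window minimum
    x = np.arange(1.0, 21.0)
    f0 = pp.sliding_percentile_baseline(x, rate, 5.0, 0.0)
    np.testing.assert_allclose(f0[2:], x[2:] - 2.0)
    # nonpositive baseline -> NaN frames
    x = np.full(30, -1.0)
    assert np.isnan(pp.dff_spontaneous(x, rate, 5.0)).all()


def _schedule_session(interval_s=20.0, n_trials=5, rate=5.11, extra=()):
    flank = seconds_to_frames(100, rate)
    onsets = [
        (flank + int(np.floor(i * interval_s * rate)), "stimulus")
        for i in range(n_trials)
    ]
    onsets = sorted(onsets + list(extra))
    n = onsets[-1][0] + seconds_to_frames(110, rate)
    rng = np.random.default_rng(0)
    return Session(
        animal_id="m", fov_id="f", day_label="ACC4",
        roi_traces=rng.uniform(90, 110, (1, n)),
        neuropil_traces=np.zeros((1, n)),
        frame_shifts=np.zeros((n, 2), int),
        trial_onsets=onsets, frame_rate_hz=rate,
    )


def test_segmentation_blocks_at_the_papers_trial_spacing():
    sess = _schedule_session()
    spans, blocks = pp.segment_session(sess)
    inter = [b for b in blocks if b.kind == "intertrial"]
    assert len(inter) == 4
    for b in inter:  # 20-s spacing minus the 8-s trial window ~ 12 s
        dur = (b.end_frame - b.start_frame) / sess.frame_rate_hz
        assert dur == pytest.approx(12.0, abs=0.5)
    initial = [b for b in blocks if b.kind == "initial"]
    final = [b for b in blocks if b.kind == "final"]
    assert len(initial) == 1 and len(final) == 1
    # the initial block is the 100-s pre-task window, truncated where the
    # first trial window begins 3 s before onset
    assert 95 <= (initial[0].end_frame - initial[0].start_frame
                  ) / sess.frame_rate_hz <= 100
    # every frame in at most one trial window; blocks don't overlap trials
    cover = np.zeros(sess.n_frames, dtype=int)
    for _, _, s, e in spans:
        cover[s:e] += 1
    assert cover.max() == 1
    for b in blocks:
        assert (cover[b.span] == 0).all()


def test_segmentation_drops_negative_span_blocks_and_degenerate_sessions():
    rate = 5.11
    # two onsets closer than 8 s leave no intertrial room
    sess = _schedule_session(
        n_trials=1, extra=[(seconds_to_frames(100, rate) + 30, "blank")]
    )
    _, blocks = pp.segment_session(sess)
    assert all(b.kind != "intertrial" for b in blocks)
    # no trials -> the whole trace is one initial block
    no_trials = Session(
        animal_id="m", fov_id="f", day_label="ACC4",
        roi_traces=np.ones((1, 50)), neuropil_traces=np.zeros((1, 50)),
        frame_shifts=np.zeros((50, 2), int), trial_onsets=[],
        frame_rate_hz=rate,
    )
    _, blocks = pp.segment_session(no_trials)
    assert len(blocks) == 1 and blocks[0].kind == "initial"
    assert (blocks[0].start_frame, blocks[0].end_frame) == (0, 50)


def test_invalid_trial_fraction_grows_with_injected_shifts():
    from dataclasses import replace

    from sstclassify import synthetic

    cfg = synthetic.fixture_config("two-cell-smoke")
    fractions = []
    for rate_ in (0.0, 3.0, 12.0):
        exp, _ = synthetic.generate_experiment(
            replace(cfg, shift_rate_per_session=rate_,
                    shift_run_lengths=((5, 1.0),)),
            seed=7,
        )
        p = pp.preprocess_session(exp.sessions[0], compute_spontaneous=False)
        qc = p.qc_table()
        fractions.append(1.0 - qc["valid"].mean())
    assert fractions[0] <= fractions[1] <= fractions[2]
    assert fractions[0] == 0.0 and fractions[2] > 0.0
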