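"""Raw trace -> corrected fluorescence -> ΔF/F under two baseline conventions.

The pipeline applies, in order: neuropil correction
(``F_corrected = F_ROI - r * F_neuropil`` with ``r = 0.7``), motion-shift
handling (frames displaced by more than 20 px are interpolated when the run
is short, otherwise the overlapping trial is rejected), and ΔF/F computation.

Two ΔF/F baseline conventions coexist:

* trial convention — per-trial ``F0`` is the mean corrected fluorescence in
  the 1 s preceding stimulus onset; the trial window spans −3 s … +5 s;
* spontaneous convention — a per-frame ``F0`` from a centered 1-min sliding
  20th-percentile filter, applied to the whole session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .session import Session, seconds_to_frames

logger = logging.getLogger(__name__)

DEFAULT_NEUROPIL_R = 0.7
SHIFT_THRESHOLD_PX = 20
MAX_INTERP_RUN = 2  # 1-2 shifted frames interpolated; >=3 invalidates trials
TRIAL_PRE_S = 3.0
TRIAL_POST_S = 5.0
BASELINE_S = 1.0
SPONT_FLANK_S = 100.0
INTERTRIAL_GAP_PRE_S = 3.0  # block ends this long before the next onset


def neuropil_correct(roi, neuropil, r: float = DEFAULT_NEUROPIL_R):
    """Subtract scaled neuropil signal: ``roi - r * neuropil`` elementwise."""
    roi = np.asarray(roi, dtype=float)
    neuropil = np.asarray(neuropil, dtype=float)
    if roi.shape != neuropil.shape:
        raise ValueError(
            f"roi {roi.shape} and neuropil {neuropil.shape} length mismatch"
        )
    return roi - r * neuropil


def flag_shifted_frames(frame_shifts, threshold_px: int = SHIFT_THRESHOLD_PX):
    """Boolean mask of frames displaced by more than ``threshold_px`` pixels
    in either x or y (strict inequality)."""
    shifts = np.asarray(frame_shifts)
    if shifts.ndim != 2 or shifts.shape[1] != 2:
        raise ValueError("frame_shifts must have shape (n_frames, 2)")
    return (np.abs(shifts[:, 0]) > threshold_px) | (
        np.abs(shifts[:, 1]) > threshold_px
    )


def _runs(mask: np.ndarray):
    """Yield (start, stop) for maximal runs of True in a boolean vector."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def interpolate_runs(x, mask, max_run: int = MAX_INTERP_RUN):
    """Replace short runs of masked samples with the mean of the nearest
    unmasked neighbors.

    Works on 1-D vectors or 2-D (n_frames, k) arrays (each column treated
    alike, e.g. fluorescence and shift records). Runs longer than
    ``max_run`` are left untouched. A run at the trace boundary uses the
    single available neighbor (logged).

    Returns ``(filled, interpolated_mask, long_run_mask)``.
    """
    x = np.array(x, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n = x.shape[0]
    if mask.shape != (n,):
        raise ValueError("mask must align with the trace's frame axis")
    filled = x.copy()
    interp = np.zeros(n, dtype=bool)
    long_run = np.zeros(n, dtype=bool)
    for start, stop in _runs(mask):
        if stop - start > max_run:
            long_run[start:stop] = True
            continue
        neighbors = []
        if start - 1 >= 0 and not mask[start - 1]:
            neighbors.append(filled[start - 1])
        if stop < n and not mask[stop]:
            neighbors.append(filled[stop])
        if not neighbors:
            long_run[start:stop] = True
            logger.warning(
                "shifted run %d:%d has no unshifted neighbor; left masked",
                start, stop,
            )
            continue
        if len(neighbors) == 1:
            logger.info(
                "shifted run %d:%d at trace boundary; using single neighbor",
                start, stop,
            )
        filled[start:stop] = np.mean(neighbors, axis=0)
        interp[start:stop] = True
    return filled, interp, long_run


@dataclass
class CorrectedTrace:
    """Neuropil-corrected, shift-interpolated fluorescence for one cell."""

    values: np.ndarray
    interpolated_mask: np.ndarray
    long_run_mask: np.ndarray
    r_neuropil: float = DEFAULT_NEUROPIL_R


def trial_window_span(onset: int, frame_rate_hz: float) -> tuple[int, int]:
    """[start, stop) frame span of the −3 s … +5 s trial window."""
    return (
        onset - seconds_to_frames(TRIAL_PRE_S, frame_rate_hz),
        onset + seconds_to_frames(TRIAL_POST_S, frame_rate_hz),
    )


def interpolate_or_reject(trace, shifted_mask, trial_onsets, frame_rate_hz,
                          r_neuropil: float = DEFAULT_NEUROPIL_R):
    """Apply the shift-handling rules to one corrected trace.

    Runs of 1–2 shifted frames are replaced by the mean of the nearest
    preceding and following unshifted values; runs of >=3 frames are not
    interpolated, and any trial window overlapping such a run is invalid.

    Returns ``(CorrectedTrace, trial_valid)`` where ``trial_valid`` is a
    boolean array over ``trial_onsets``.
    """
    filled, interp, long_run = interpolate_runs(trace, shifted_mask)
    n = filled.shape[0]
    valid = np.ones(len(trial_onsets), dtype=bool)
    for i, (onset, _ttype) in enumerate(trial_onsets):
        start, stop = trial_window_span(onset, frame_rate_hz)
        start, stop = max(start, 0), min(stop, n)
        if long_run[start:stop].any():
            valid[i] = False
    ct = CorrectedTrace(
        values=filled,
        interpolated_mask=interp,
        long_run_mask=long_run,
        r_neuropil=r_neuropil,
    )
    return ct, valid


@dataclass
class TrialWindow:
    """ΔF/F segment spanning −3 s … +5 s around one trial onset.

    ``dff`` is None when the trial is invalid for a reason that prevents
    computing it (edge clipping or nonpositive baseline).
    """

    trial_type: str
    onset_frame: int
    dff: np.ndarray | None
    baseline_f0: float
    frame_rate_hz: float
    valid: bool = True
    reason: str = ""

    @property
    def onset_index(self) -> int:
        """Index of the onset frame within ``dff``."""
        return seconds_to_frames(TRIAL_PRE_S, self.frame_rate_hz)

    def period_slice(self, start_s: float, stop_s: float) -> slice:
        """Frame slice of ``dff`` for a period given in s relative to onset."""
        base = self.onset_index
        i0 = base + seconds_to_frames(start_s + 0, self.frame_rate_hz) if start_s >= 0 \
            else base - seconds_to_frames(-start_s, self.frame_rate_hz)
        i1 = base + seconds_to_frames(stop_s, self.frame_rate_hz) if stop_s >= 0 \
            else base - seconds_to_frames(-stop_s, self.frame_rate_hz)
        return slice(i0, i1)


def dff_trial(corrected, onset_frame: int, frame_rate_hz: float,
              trial_type: str = "stimulus") -> TrialWindow:
    """Trial-convention ΔF/F for one trial.

    ``F0`` is the mean corrected fluorescence over the 1 s preceding onset;
    ``dff = (F - F0) / F0`` over −3 s … +5 s. Trials whose window clips the
    trace edge, or with ``F0 <= 0`` (possible after neuropil subtraction),
    are invalid — ΔF/F is undefined there and clipping would fabricate
    signal.
    """
    x = np.asarray(corrected, dtype=float)
    n = x.shape[0]
    start, stop = trial_window_span(onset_frame, frame_rate_hz)
    nb = seconds_to_frames(BASELINE_S, frame_rate_hz)
    if start < 0 or stop > n:
        return TrialWindow(trial_type, onset_frame, None, np.nan,
                           frame_rate_hz, valid=False, reason="edge")
    f0 = float(np.mean(x[onset_frame - nb:onset_frame]))
    if f0 <= 0:
        logger.info("trial at frame %d invalid: F0=%g <= 0", onset_frame, f0)
        return TrialWindow(trial_type, onset_frame, None, f0,
                           frame_rate_hz, valid=False, reason="nonpositive_f0")
    dff = (x[start:stop] - f0) / f0
    return TrialWindow(trial_type, onset_frame, dff, f0, frame_rate_hz)


def sliding_percentile_baseline(x, frame_rate_hz: float,
                                window_s: float = 60.0,
                                percentile: float = 20.0) -> np.ndarray:
    """Per-frame baseline: percentile of a centered window, truncated at edges."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n <= 1:
        raise ValueError("trace must be longer than one frame")
    w = max(seconds_to_frames(window_s, frame_rate_hz), 1)
    if w % 2 == 0:
        w += 1  # symmetric centered window
    half = w // 2
    f0 = np.empty(n)
    has_nan = bool(np.isnan(x).any())
    pctl = np.nanpercentile if has_nan else np.percentile
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        interior = sliding_window_view(x, w)
        f0[half:n - half] = pctl(interior, percentile, axis=1)
        edge_idx = list(range(half)) + list(range(n - half, n))
    else:
        edge_idx = range(n)
    for i in edge_idx:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        f0[i] = pctl(x[lo:hi], percentile)
    return f0


def dff_spontaneous(corrected, frame_rate_hz: float, window_s: float = 60.0,
                    percentile: float = 20.0) -> np.ndarray:
    """Spontaneous-convention ΔF/F over a whole trace.

    Frames where the sliding baseline is nonpositive (or the input is
    non-finite, e.g. masked long shift runs) come out NaN and are excluded
    downstream.
    """
    x = np.asarray(corrected, dtype=float)
    f0 = sliding_percentile_baseline(x, frame_rate_hz, window_s, percentile)
    with np.errstate(invalid="ignore", divide="ignore"):
        dff = (x - f0) / f0
    bad = ~(f0 > 0)
    if bad.any():
        logger.info("%d frame(s) with nonpositive sliding baseline", bad.sum())
        dff[bad] = np.nan
    return dff


@dataclass
class SpontaneousBlock:
    """A task-free segment of the session: initial / intertrial / final."""

    kind: str  # initial | intertrial | final
    start_frame: int
    end_frame: int  # exclusive

    @property
    def span(self) -> slice:
        return slice(self.start_frame, self.end_frame)


def segment_session(session: Session):
    """Split a session into trial windows and spontaneous blocks.

    Trial windows span −3 s … +5 s around each onset. Intertrial blocks
    fill the gap between consecutive trial windows (≈12 s at the 20-s trial
    spacing); negative-span blocks are dropped. The initial and final
    blocks are the 100-s windows before the first and after the last trial
    window (truncated to the recording).

    Returns ``(trial_spans, blocks)`` where ``trial_spans`` is a list of
    ``(onset, trial_type, start, stop)``.
    """
    rate = session.frame_rate_hz
    n = session.n_frames
    flank = seconds_to_frames(SPONT_FLANK_S, rate)
    if not session.trial_onsets:
        logger.info("session %s has no trials; whole trace is one block",
                    session.key)
        return [], [SpontaneousBlock("initial", 0, n)]
    spans = []
    for onset, ttype in session.trial_onsets:
        start, stop = trial_window_span(onset, rate)
        spans.append((onset, ttype, max(start, 0), min(stop, n)))
    blocks = []
    first_start = spans[0][2]
    if first_start > 0:
        blocks.append(
            SpontaneousBlock("initial", max(0, first_start - flank), first_start)
        )
    for (_, _, _, prev_stop), (_, _, next_start, _) in zip(spans, spans[1:]):
        if next_start > prev_stop:
            blocks.append(SpontaneousBlock("intertrial", prev_stop, next_start))
    last_stop = spans[-1][3]
    if last_stop < n:
        blocks.append(
            SpontaneousBlock("final", last_stop, min(n, last_stop + flank))
        )
    return spans, blocks


@dataclass
class PreprocessedSession:
    """All per-cell preprocessing products for one session."""

    session: Session
    corrected: list[CorrectedTrace]
    trials: list[list[TrialWindow]]  # per cell, per onset
    spont_dff: np.ndarray  # (n_cells, n_frames), NaN where undefined
    blocks: list[SpontaneousBlock]

    def qc_table(self):
        """Per-trial validity table: cell, trial, type, valid, reason."""
        import pandas as pd

        rows = []
        for ci, tws in enumerate(self.trials):
            for ti, tw in enumerate(tws):
                rows.append(
                    {
                        "cell": ci,
                        "day": self.session.day_label,
                        "trial": ti,
                        "trial_type": tw.trial_type,
                        "valid": tw.valid,
                        "reason": tw.reason,
                    }
                )
        return pd.DataFrame(rows)


def preprocess_session(session: Session,
                       r_neuropil: float = DEFAULT_NEUROPIL_R,
                       shift_threshold_px: int = SHIFT_THRESHOLD_PX,
                       compute_spontaneous: bool = True) -> PreprocessedSession:
    """Run the full per-session preprocessing chain for every cell."""
    shifted = flag_shifted_frames(session.frame_shifts, shift_threshold_px)
    _, blocks = segment_session(session)
    corrected_list, trials_list = [], []
    spont = np.full((session.n_cells, session.n_frames), np.nan)
    for ci in range(session.n_cells):
        fc = neuropil_correct(
            session.roi_traces[ci], session.neuropil_traces[ci], r_neuropil
        )
        ct, shift_valid = interpolate_or_reject(
            fc, shifted, session.trial_onsets, session.frame_rate_hz,
            r_neuropil=r_neuropil,
        )
        tws = []
        for (onset, ttype), ok in zip(session.trial_onsets, shift_valid):
            tw = dff_trial(ct.values, onset, session.frame_rate_hz, ttype)
            if not ok:
                tw.valid = False
                tw.reason = (tw.reason + "+shifted_run").lstrip("+")
            tws.append(tw)
        if compute_spontaneous:
            v = ct.values.copy()
            v[ct.long_run_mask] = np.nan
            spont[ci] = dff_spontaneous(v, session.frame_rate_hz)
        corrected_list.append(ct)
        trials_list.append(tws)
    return PreprocessedSession(
        session=session,
        corrected=corrected_list,
        trials=trials_list,
        spont_dff=spont,
        blocks=blocks,
    )
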