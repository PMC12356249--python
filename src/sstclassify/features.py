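"""First-order activity features for cell-type separation.

Each cell-day yields a vector of features over a combinatorial grid of

* response-probability features — fraction of trials whose response-window
  ΔF/F peak exceeds k·σ₁, k ∈ {1, 2, 3, 5, 10};
* in-trial features — peak, peak latency, center of mass and AUC over named
  in-trial periods (pretrial −2…0 s, response 0…2 s, posttrial 2…4 s,
  full −3…+5 s), per trial type;
* spontaneous features — per-event peak amplitude and event counts at
  prominence thresholds k·σ₂, k ∈ 1…10, plus per-block AUC, over the
  initial / intertrial / final spontaneous blocks.

σ₁ is the SD of the concatenated 1-s pre-onset baselines (trial-convention
ΔF/F); σ₂ is the SD of the whole session's spontaneous-convention ΔF/F.
Both use the population SD (divide by n) — a pinned convention; the
difference is negligible at these sample sizes. Per-unit values (per trial,
per block, per event) are averaged within day, then across ACC4–6.

Only first-order features are computed; higher-order combinations (ratios,
summations) are out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import preprocess
from .session import Experiment, seconds_to_frames

logger = logging.getLogger(__name__)

DEFAULT_SOURCE_DAYS = ("ACC4", "ACC5", "ACC6")
RESPONSE_WINDOW_S = (0.0, 2.0)  # evoked-response window (0.5-s stimulus +
# GCaMP6f decay); used for responsive-trial detection and evoked peaks

#: In-trial periods in seconds relative to onset.
PERIODS = {
    "pretrial": (-2.0, 0.0),
    "response": (0.0, 2.0),
    "posttrial": (2.0, 4.0),
    "full": (-3.0, 5.0),
}
TRIAL_TYPES = ("stimulus", "blank", "all")
IN_TRIAL_METRICS = ("peak", "peak_latency", "center_of_mass", "auc")
RP_THRESHOLDS = (1, 2, 3, 5, 10)
EVENT_THRESHOLDS = tuple(range(1, 11))
BLOCK_KINDS = ("initial", "intertrial", "final")


@dataclass(frozen=True)
class FeatureSpec:
    """One named first-order feature.

    category: response_probability | in_trial | spontaneous
    trial_type: stimulus | blank | all (trial categories only)
    period: in-trial period name, or block kind for spontaneous features
    metric: probability | peak | peak_latency | center_of_mass | auc |
            event_peak | event_count | block_auc
    threshold_multiple: multiple of σ₁ (response probability) or σ₂
            (event detection); None otherwise
    """

    category: str
    trial_type: str | None
    period: str
    metric: str
    threshold_multiple: int | None = None

    @property
    def name(self) -> str:
        parts = [
            {"response_probability": "rp", "in_trial": "trial",
             "spontaneous": "spont"}[self.category]
        ]
        if self.trial_type is not None:
            parts.append(self.trial_type)
        parts.append(self.period)
        parts.append(self.metric)
        if self.threshold_multiple is not None:
            parts.append(f"k{self.threshold_multiple}")
        return "|".join(parts)


def default_feature_grid() -> list[FeatureSpec]:
    """Instantiate the full feature grid (126 specs).

    The grid is the cartesian structure of the main-text parameter lists;
    it is shipped as data (see :func:`grid_to_json`) so it can be edited.
    """
    grid: list[FeatureSpec] = []
    for tt in TRIAL_TYPES:
        for k in RP_THRESHOLDS:
            grid.append(FeatureSpec("response_probability", tt, "response",
                                    "probability", k))
    for tt in TRIAL_TYPES:
        for period in PERIODS:
            for metric in IN_TRIAL_METRICS:
                grid.append(FeatureSpec("in_trial", tt, period, metric))
    for kind in BLOCK_KINDS:
        for metric in ("event_peak", "event_count"):
            for k in EVENT_THRESHOLDS:
                grid.append(FeatureSpec("spontaneous", None, kind, metric, k))
    for kind in BLOCK_KINDS:
        grid.append(FeatureSpec("spontaneous", None, kind, "block_auc"))
    names = [s.name for s in grid]
    assert len(set(names)) == len(names)
    return grid


def grid_to_json(grid, path=None) -> str:
    payload = json.dumps([asdict(s) for s in grid], indent=1)
    if path is not None:
        from pathlib import Path

        Path(path).write_text(payload)
    return payload


def grid_from_json(source) -> list[FeatureSpec]:
    from pathlib import Path

    text = Path(source).read_text() if not str(source).lstrip().startswith("[") \
        else str(source)
    return [FeatureSpec(**d) for d in json.loads(text)]


def spec_from_name(name: str) -> FeatureSpec:
    """Inverse of :attr:`FeatureSpec.name`."""
    parts = name.split("|")
    cat = {"rp": "response_probability", "trial": "in_trial",
           "spont": "spontaneous"}[parts[0]]
    k = None
    if parts[-1].startswith("k") and parts[-1][1:].isdigit():
        k = int(parts[-1][1:])
        parts = parts[:-1]
    if cat == "spontaneous":
        return FeatureSpec(cat, None, parts[1], parts[2], k)
    return FeatureSpec(cat, parts[1], parts[2], parts[3], k)


@dataclass
class SigmaPair:
    """Noise scales for one cell-session.

    sigma1 — SD of concatenated 1-s pre-onset baseline ΔF/F across valid
    trials (used to detect responsive trials). sigma2 — SD of the entire
    session's spontaneous-convention ΔF/F (used for event prominence).
    """

    sigma1: float
    sigma2: float


def compute_sigmas(trials, session_spont_dff) -> SigmaPair:
    """Compute σ₁/σ₂ for one cell-session.

    Raises if no valid trials exist (σ₁ undefined; the cell-day is flagged
    upstream).
    """
    baselines = []
    for tw in trials:
        if not tw.valid or tw.dff is None:
            continue
        nb = seconds_to_frames(preprocess.BASELINE_S, tw.frame_rate_hz)
        base = tw.onset_index
        baselines.append(tw.dff[base - nb:base])
    if not baselines:
        raise ValueError("sigma1 undefined: no valid trials")
    sigma1 = float(np.std(np.concatenate(baselines)))  # population SD
    x = np.asarray(session_spont_dff, dtype=float)
    sigma2 = float(np.nanstd(x)) if np.isfinite(x).any() else np.nan
    return SigmaPair(sigma1=sigma1, sigma2=sigma2)


def _select_trials(trials, trial_type):
    return [
        tw for tw in trials
        if tw.valid and tw.dff is not None
        and (trial_type == "all" or tw.trial_type == trial_type)
    ]


def response_window_peak(tw) -> float:
    """Peak ΔF/F in the evoked-response window (0…2 s post-onset)."""
    return float(np.max(tw.dff[tw.period_slice(*RESPONSE_WINDOW_S)]))


def response_probability(trials, k: float, sigma1: float,
                         trial_type: str = "stimulus") -> float:
    """Fraction of valid trials whose response-window peak exceeds k·σ₁."""
    sel = _select_trials(trials, trial_type)
    if not sel:
        return np.nan
    peaks = np.array([response_window_peak(tw) for tw in sel])
    return float(np.mean(peaks > k * sigma1))


def in_trial_metrics(tw, period) -> dict:
    """Peak, peak latency, center of mass and AUC over one in-trial period.

    Latency and center of mass are in seconds relative to the period start;
    center of mass weights by positive-rectified ΔF/F (negative weights make
    the quantity ill-defined). If the segment is all-nonpositive, the period
    midpoint is substituted (flagged via the ``com_defined`` key). AUC is
    the trapezoidal integral in ΔF/F·s.
    """
    start_s, stop_s = PERIODS[period] if isinstance(period, str) else period
    seg = tw.dff[tw.period_slice(start_s, stop_s)]
    if seg.size == 0:
        raise ValueError(f"empty period {period!r}")
    dt = 1.0 / tw.frame_rate_hz
    t = np.arange(seg.size) * dt
    imax = int(np.argmax(seg))
    weights = np.clip(seg, 0.0, None)
    wsum = weights.sum()
    if wsum > 0:
        com = float(np.sum(t * weights) / wsum)
        com_defined = True
    else:
        com = float(t[-1] / 2)
        com_defined = False
    return {
        "peak": float(seg[imax]),
        "peak_latency": float(t[imax]),
        "center_of_mass": com,
        "auc": float(np.trapezoid(seg, dx=dt)),
        "com_defined": com_defined,
    }


def _finite_segments(x):
    finite = np.isfinite(x)
    for start, stop in _runs_of(finite):
        yield start, x[start:stop]


def _runs_of(mask):
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        yield int(start), int(stop)


def block_peak_candidates(block_dff):
    """All local maxima of a block with their topographic prominences.

    Returns ``(indices, amplitudes, prominences)``; NaN stretches split the
    block into independent finite segments.
    """
    idx_all, amp_all, prom_all = [], [], []
    for offset, seg in _finite_segments(np.asarray(block_dff, dtype=float)):
        if seg.size < 3:
            continue
        peaks, props = signal.find_peaks(seg, prominence=(0, None))
        idx_all.append(peaks + offset)
        amp_all.append(seg[peaks])
        prom_all.append(props["prominences"])
    if not idx_all:
        empty = np.array([])
        return empty.astype(int), empty, empty
    return (np.concatenate(idx_all).astype(int), np.concatenate(amp_all),
            np.concatenate(prom_all))


def detect_spontaneous_events(block_dff, k: float, sigma2: float):
    """Spontaneous events: local maxima with prominence > k·σ₂ (strict).

    Returns a structured record of (frame, amplitude, prominence) arrays.
    """
    idx, amp, prom = block_peak_candidates(block_dff)
    keep = prom > k * sigma2
    return {"frame": idx[keep], "amplitude": amp[keep],
            "prominence": prom[keep]}


def _block_auc(block_dff, frame_rate_hz):
    dt = 1.0 / frame_rate_hz
    total = 0.0
    any_seg = False
    for _, seg in _finite_segments(np.asarray(block_dff, dtype=float)):
        if seg.size >= 2:
            total += float(np.trapezoid(seg, dx=dt))
            any_seg = True
    return total if any_seg else np.nan


def compute_cell_day_features(trials, spont_dff, blocks, frame_rate_hz,
                              grid=None) -> np.ndarray:
    """Feature vector for one cell on one day (NaN where undefined)."""
    if grid is None:
        grid = default_feature_grid()
    sigmas = compute_sigmas(trials, spont_dff)
    out = np.full(len(grid), np.nan)

    trial_cache: dict[str, list] = {
        tt: _select_trials(trials, tt) for tt in TRIAL_TYPES
    }
    peak_cache = {
        tt: np.array([response_window_peak(tw) for tw in sel])
        for tt, sel in trial_cache.items()
    }
    metrics_cache: dict[tuple, np.ndarray] = {}
    block_cache: dict[int, tuple] = {}
    blocks_by_kind: dict[str, list[int]] = {k: [] for k in BLOCK_KINDS}
    for bi, b in enumerate(blocks):
        blocks_by_kind[b.kind].append(bi)

    for si, spec in enumerate(grid):
        if spec.category == "response_probability":
            peaks = peak_cache[spec.trial_type]
            if peaks.size:
                out[si] = np.mean(peaks > spec.threshold_multiple * sigmas.sigma1)
        elif spec.category == "in_trial":
            key = (spec.trial_type, spec.period, spec.metric)
            if key not in metrics_cache:
                sel = trial_cache[spec.trial_type]
                vals = [in_trial_metrics(tw, spec.period)[spec.metric]
                        for tw in sel]
                metrics_cache[key] = np.asarray(vals, dtype=float)
            vals = metrics_cache[key]
            if vals.size:
                out[si] = np.mean(vals)
        else:  # spontaneous
            bis = blocks_by_kind[spec.period]
            if not bis:
                continue
            if spec.metric == "block_auc":
                aucs = []
                for bi in bis:
                    aucs.append(_block_auc(spont_dff[blocks[bi].span],
                                           frame_rate_hz))
                aucs = np.asarray(aucs, dtype=float)
                if np.isfinite(aucs).any():
                    out[si] = np.nanmean(aucs)
                continue
            if not np.isfinite(sigmas.sigma2):
                continue
            counts, amps = [], []
            for bi in bis:
                if bi not in block_cache:
                    block_cache[bi] = block_peak_candidates(
                        spont_dff[blocks[bi].span]
                    )
                _, amp, prom = block_cache[bi]
                keep = prom > spec.threshold_multiple * sigmas.sigma2
                counts.append(int(keep.sum()))
                amps.append(amp[keep])
            if spec.metric == "event_count":
                out[si] = float(np.mean(counts))
            else:  # event_peak: mean amplitude per event; 0 when no events
                allamps = np.concatenate(amps) if amps else np.array([])
                out[si] = float(np.mean(allamps)) if allamps.size else 0.0
    return out


def build_feature_matrix(experiment: Experiment,
                         days=DEFAULT_SOURCE_DAYS,
                         grid=None,
                         preprocessed: dict | None = None):
    """Cells × features matrix averaged within day, then across ``days``.

    Cells missing any source day are excluded (logged). Returns
    ``(DataFrame indexed by cell_id, grid)``. ``preprocessed`` may supply
    already-computed :class:`~sstclassify.preprocess.PreprocessedSession`
    objects keyed by session key, to avoid recomputation.
    """
    if grid is None:
        grid = default_feature_grid()
    days = list(days)
    names = [s.name for s in grid]
    rows, index = [], []
    for animal, fov in experiment.fovs():
        try:
            sessions = {d: experiment.session(animal, fov, d) for d in days}
        except KeyError:
            logger.warning("FOV (%s, %s) lacks day coverage %s; skipped",
                           animal, fov, days)
            continue
        pre = {}
        for d, sess in sessions.items():
            key = sess.key
            if preprocessed and key in preprocessed:
                pre[d] = preprocessed[key]
            else:
                pre[d] = preprocess.preprocess_session(sess)
        reg = experiment.registry
        fov_cells = [
            c for c in reg.complete_cells(days)
            if (reg.table.loc[reg.table.cell_id == c, "animal_id"].iloc[0],
                reg.table.loc[reg.table.cell_id == c, "fov_id"].iloc[0])
            == (animal, fov)
        ]
        for cell in fov_cells:
            day_vecs = []
            for d in days:
                ri = reg.row_index(cell, d)
                p = pre[d]
                day_vecs.append(
                    compute_cell_day_features(
                        p.trials[ri], p.spont_dff[ri], p.blocks,
                        p.session.frame_rate_hz, grid,
                    )
                )
            vec = np.mean(np.vstack(day_vecs), axis=0)
            if np.isnan(vec).any():
                logger.warning("cell %s has undefined features; excluded", cell)
                continue
            rows.append(vec)
            index.append(cell)
    df = pd.DataFrame(np.vstack(rows) if rows else
                      np.empty((0, len(grid))), index=index, columns=names)
    df.index.name = "cell_id"
    return df, grid


def rank_features(matrix: pd.DataFrame, labels: pd.Series,
                  positive: str = "SST-Calb2") -> pd.DataFrame:
    """Rank features by class separability (unpaired two-sample t-test).

    ``labels`` maps cell_id -> class; exactly two classes are required,
    with >= 2 cells each. Features are sorted by p-value ascending;
    zero-variance-in-both-classes features get NaN p and sort last
    (flagged in the ``degenerate`` column).
    """
    labels = pd.Series(labels).reindex(matrix.index)
    classes = sorted(labels.dropna().unique(), key=lambda c: c != positive)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {list(classes)}")
    a_mask = (labels == classes[0]).values
    b_mask = (labels == classes[1]).values
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("need >= 2 cells per class")
    a = matrix.values[a_mask]
    b = matrix.values[b_mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0)
    degenerate = np.std(matrix.values, axis=0) == 0
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, np.nan, p)
    out = pd.DataFrame(
        {"feature": matrix.columns, "t": t, "p": p, "degenerate": degenerate}
    )
    out = out.sort_values("p", na_position="last", kind="mergesort")
    out["rank"] = np.arange(len(out))
    return out.reset_index(drop=True)


def top_features(ranking: pd.DataFrame, n: int = 30) -> list[str]:
    """The n best-separating feature names (paper uses the top 30)."""
    return list(ranking.loc[~ranking["degenerate"], "feature"].head(n))
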