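"""Daily evoked responses, training-epoch fold changes and group statistics.

The per-cell plasticity readout is the daily mean evoked peak: the mean,
over all valid stimulus trials of a day, of the trial ΔF/F peak in the
response window. All stimulus trials enter the mean, irrespective of
response amplitude. Peaks from ACC4–6 form each cell's pretraining
baseline; training-epoch responses (SAT1/2, SAT5/6, SAT9/10) are expressed
as fold changes relative to that baseline, so the readout is invariant to
uniform rescaling of a cell's fluorescence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from . import preprocess
from .session import Experiment, sort_days

logger = logging.getLogger(__name__)

BASELINE_DAYS = ("ACC4", "ACC5", "ACC6")
#: Training epochs averaged for reporting, as day-label pairs.
EPOCHS = {
    "SAT1/2": ("SAT1", "SAT2"),
    "SAT5/6": ("SAT5", "SAT6"),
    "SAT9/10": ("SAT9", "SAT10"),
}
PSE_EPOCHS = {
    "PSE1/2": ("PSE1", "PSE2"),
    "PSE5/6": ("PSE5", "PSE6"),
    "PSE9/10": ("PSE9", "PSE10"),
}
CALB2_INTENSITY_THRESHOLD = 200.0


def daily_mean_peak(trials) -> float:
    """Mean response-window ΔF/F peak over valid stimulus trials of a day.

    Non-responsive trials are included (their peaks may be ~0 or negative).
    Returns NaN (flagged) if the day has no valid stimulus trials.
    """
    peaks = [
        feat.response_window_peak(tw)
        for tw in trials
        if tw.valid and tw.dff is not None and tw.trial_type == "stimulus"
    ]
    if not peaks:
        logger.warning("no valid stimulus trials; daily mean peak undefined")
        return float("nan")
    return float(np.mean(peaks))


def plasticity_table(experiment: Experiment, days=None,
                     baseline_days=BASELINE_DAYS, epochs=None,
                     preprocessed: dict | None = None) -> pd.DataFrame:
    """Per-cell daily mean peaks, ACC baseline and epoch fold changes.

    Columns: ``peak_<day>`` per requested day, ``acc_baseline`` (mean of
    the baseline days' peaks), ``fold_<epoch>`` per epoch, ``true_label``.
    Cells with nonpositive baseline are excluded (flagged); an epoch with a
    missing day uses the available day(s) (logged).
    """
    if days is None:
        days = experiment.days
    if epochs is None:
        prefix = "PSE" if any(d.startswith("PSE") for d in days) else "SAT"
        epochs = PSE_EPOCHS if prefix == "PSE" else EPOCHS
    days = sort_days(set(days) | set(baseline_days))
    reg = experiment.registry
    rows = []
    for animal, fov in experiment.fovs():
        fov_days = [d for d in days
                    if any(s.key == (animal, fov, d) for s in experiment.sessions)]
        pre = {}
        for d in fov_days:
            sess = experiment.session(animal, fov, d)
            if preprocessed and sess.key in preprocessed:
                pre[d] = preprocessed[sess.key]
            else:
                pre[d] = preprocess.preprocess_session(
                    sess, compute_spontaneous=False
                )
        sub = reg.table[(reg.table.animal_id == animal)
                        & (reg.table.fov_id == fov)]
        for cell in sub["cell_id"]:
            row = {"cell_id": cell, "true_label": reg.true_label(cell)}
            for d in fov_days:
                ri = reg.row_index(cell, d)
                row[f"peak_{d}"] = (
                    daily_mean_peak(pre[d].trials[ri]) if ri is not None
                    else np.nan
                )
            rows.append(row)
    table = pd.DataFrame(rows).set_index("cell_id")
    base_cols = [f"peak_{d}" for d in baseline_days]
    missing = [c for c in base_cols if c not in table.columns]
    if missing:
        raise ValueError(f"baseline day columns missing: {missing}")
    table["acc_baseline"] = table[base_cols].mean(axis=1)
    bad = ~(table["acc_baseline"] > 0)
    if bad.any():
        logger.warning("excluding %d cell(s) with nonpositive ACC baseline",
                       int(bad.sum()))
        table = table[~bad]
    for name, epoch_days in epochs.items():
        cols = [f"peak_{d}" for d in epoch_days if f"peak_{d}" in table.columns]
        if not cols:
            continue
        if len(cols) < len(epoch_days):
            logger.info("epoch %s missing day(s); using %s", name, cols)
        table[f"fold_{name}"] = table[cols].mean(axis=1) / table["acc_baseline"]
    return table


def epoch_fold_changes(table: pd.DataFrame, grouping: str | pd.Series | None = None):
    """Group mean ± SEM fold change per epoch.

    ``grouping`` may be a column name of ``table`` (e.g. ``true_label``),
    an external per-cell Series (e.g. predicted subtype), or None to pool
    all cells. Returns a tidy DataFrame (group, epoch, n, mean, sem).
    """
    fold_cols = [c for c in table.columns if c.startswith("fold_")]
    if grouping is None:
        groups = pd.Series("all", index=table.index)
    elif isinstance(grouping, str):
        groups = table[grouping]
    else:
        groups = pd.Series(grouping).reindex(table.index)
    rows = []
    for g, sub in table.groupby(groups):
        for c in fold_cols:
            vals = sub[c].dropna()
            rows.append(
                {
                    "group": g,
                    "epoch": c[len("fold_"):],
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sem": vals.sem(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _paired_t(a, b):
    """Paired t-test that returns (t=0, p=1) for identical samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d = a - b
    if np.allclose(d, 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def group_stats(table: pd.DataFrame, epochs=None, grouping=None) -> dict:
    """Paired t-tests (epoch vs ACC baseline, Bonferroni-corrected) and
    one-way repeated-measures ANOVA across days.

    Bonferroni: corrected p = min(1, raw p * m), m = number of epoch
    comparisons. The RM-ANOVA uses cells as subjects (the grouping level —
    cells vs animals — varies across the study's summaries and is left to
    the caller via prior pooling). Groups with n < 2 are skipped (flagged).
    """
    fold_cols = [c for c in table.columns if c.startswith("fold_")]
    if epochs is not None:
        fold_cols = [f"fold_{e}" for e in epochs if f"fold_{e}" in table.columns]
    m = len(fold_cols)
    if grouping is None:
        groups = pd.Series("all", index=table.index)
    elif isinstance(grouping, str):
        groups = table[grouping]
    else:
        groups = pd.Series(grouping).reindex(table.index)
    t_rows = []
    for g, sub in table.groupby(groups):
        for c in fold_cols:
            epoch = c[len("fold_"):]
            pair = sub[[c, "acc_baseline"]].dropna()
            if len(pair) < 2:
                logger.warning("group %s epoch %s has n<2; test skipped",
                               g, epoch)
                t_rows.append({"group": g, "epoch": epoch, "n": len(pair),
                               "t": np.nan, "p_raw": np.nan,
                               "p_bonferroni": np.nan})
                continue
            # epoch mean peak vs ACC baseline, paired within cells
            epoch_peak = pair[c] * pair["acc_baseline"]
            t, p = _paired_t(epoch_peak, pair["acc_baseline"])
            t_rows.append(
                {"group": g, "epoch": epoch, "n": len(pair), "t": t,
                 "p_raw": p, "p_bonferroni": min(1.0, p * m)}
            )
    report = {"paired_t": pd.DataFrame(t_rows), "n_comparisons": m}
    report["rm_anova"] = _rm_anova(table, groups)
    return report


def _rm_anova(table, groups):
    """One-way repeated-measures ANOVA of daily mean peak across days."""
    from statsmodels.stats.anova import AnovaRM

    day_cols = [c for c in table.columns if c.startswith("peak_")]
    out = []
    for g, sub in table.groupby(groups):
        complete = sub[day_cols].dropna()
        if len(complete) < 2 or len(day_cols) < 2:
            continue
        long = complete.reset_index().melt(
            id_vars="cell_id", var_name="day", value_name="peak"
        )
        try:
            res = AnovaRM(long, depvar="peak", subject="cell_id",
                          within=["day"]).fit()
        except Exception as e:  # unbalanced / degenerate designs
            logger.warning("RM-ANOVA failed for group %s: %s", g, e)
            continue
        row = res.anova_table.iloc[0]
        out.append({"group": g, "n": len(complete),
                    "F": float(row["F Value"]),
                    "p": float(row["Pr > F"])})
    return pd.DataFrame(out)


def label_calb2_by_intensity(red_intensity,
                             threshold: float = CALB2_INTENSITY_THRESHOLD):
    """Calb2-positive iff mean mCherry pixel intensity strictly exceeds the
    threshold (200 a.u.) on the initial imaging day; missing -> unknown.

    Returns an object array of {"SST-Calb2", "SST-O", "unknown"}.
    """
    red = np.asarray(red_intensity, dtype=float)
    out = np.where(red > threshold, "SST-Calb2", "SST-O").astype(object)
    out[~np.isfinite(red)] = "unknown"
    return out
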