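"""Home-cage training behavior: anticipatory licking and performance.

Learning in the stimulus-reward association task is read out from
anticipatory licking — licks in the 300-ms window immediately before water
delivery. Blank trials have no water; their anticipatory window is placed
at the time water *would* have been delivered given the trial's schedule,
so that a blank-trial lick frequency exists for comparison. Performance is
``licking_stimulus − licking_blank`` (Hz), computed per 4-hour bin; bins
with fewer than 10 trials are removed (blank-trial frequency cannot be
assessed from one or two trials).

Logs are delimited text with (timestamp, event, value) rows:
``trial`` events carry the trial type, ``water`` events mark deliveries,
``lick`` events mark individual licks. Timestamps are in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ANTICIPATORY_WINDOW_S = 0.3
BIN_HOURS = 4.0
MIN_TRIALS_PER_BIN = 10
#: Scheduled stimulus-to-water delay: 0.2-0.8 s random delay + 0.5-s air
#: puff + 0.5-s post-puff delay; the midpoint (1.5 s) stands in when no
#: water event is logged (blank trials).
DEFAULT_SCHEDULED_DELAY_S = 1.5


@dataclass
class BehaviorLog:
    """Parsed event log: per-trial table plus lick timestamps."""

    trials: pd.DataFrame  # columns: t, trial_type, water_time
    licks: np.ndarray


def parse_log(rows, scheduled_delay_s: float = DEFAULT_SCHEDULED_DELAY_S) -> BehaviorLog:
    """Build a :class:`BehaviorLog` from (timestamp, event, value) rows.

    ``rows`` is a DataFrame or a path to a delimited file with columns
    ``timestamp``, ``event`` (trial | water | lick) and ``value`` (trial
    type for trial events). Each trial's water time is the first logged
    delivery within 5 s of onset; otherwise the scheduled equivalent
    ``onset + scheduled_delay_s``.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.read_csv(rows)
    rows = rows.sort_values("timestamp")
    licks = rows.loc[rows.event == "lick", "timestamp"].to_numpy(float)
    waters = rows.loc[rows.event == "water", "timestamp"].to_numpy(float)
    trials = []
    for r in rows[rows.event == "trial"].itertuples():
        t = float(r.timestamp)
        after = waters[(waters > t) & (waters <= t + 5.0)]
        water_time = float(after[0]) if after.size else t + scheduled_delay_s
        trials.append({"t": t, "trial_type": str(r.value),
                       "water_time": water_time})
    return BehaviorLog(trials=pd.DataFrame(trials,
                                           columns=["t", "trial_type",
                                                    "water_time"]),
                       licks=licks)


def anticipatory_frequency(licks, water_time: float,
                           window_s: float = ANTICIPATORY_WINDOW_S) -> float:
    """Lick frequency (Hz) in the window immediately before delivery."""
    licks = np.asarray(licks, dtype=float)
    n = int(np.sum((licks >= water_time - window_s) & (licks < water_time)))
    return n / window_s


def _per_trial_frequencies(log: BehaviorLog) -> pd.DataFrame:
    trials = log.trials.copy()
    trials["freq"] = [
        anticipatory_frequency(log.licks, wt) for wt in trials["water_time"]
    ]
    return trials


def bin_performance(log: BehaviorLog, bin_hours: float = BIN_HOURS,
                    min_trials: int = MIN_TRIALS_PER_BIN) -> pd.DataFrame:
    """Per-4-hour-bin anticipatory frequencies and performance.

    Bins are aligned to t=0 of the log; bins with fewer than ``min_trials``
    trials are removed. Performance = f_stimulus − f_blank.
    """
    trials = _per_trial_frequencies(log)
    if trials.empty:
        return pd.DataFrame(columns=["bin", "n_trials", "f_stimulus",
                                     "f_blank", "performance"])
    bin_s = bin_hours * 3600.0
    trials["bin"] = (trials["t"] // bin_s).astype(int)
    rows = []
    for b, sub in trials.groupby("bin"):
        if len(sub) < min_trials:
            logger.info("bin %d removed (%d < %d trials)", b, len(sub),
                        min_trials)
            continue
        f_stim = sub.loc[sub.trial_type == "stimulus", "freq"].mean()
        f_blank = sub.loc[sub.trial_type == "blank", "freq"].mean()
        rows.append(
            {"bin": b, "n_trials": len(sub), "f_stimulus": f_stim,
             "f_blank": f_blank, "performance": f_stim - f_blank}
        )
    return pd.DataFrame(rows)


def behavior_performance(log: BehaviorLog, bin_hours: float = BIN_HOURS,
                         min_trials: int = MIN_TRIALS_PER_BIN,
                         last_fraction: float = 0.2) -> dict:
    """Per-bin and per-day performance plus the end-of-day learning test.

    Days are 24-h segments of the log. Per day, bins passing the trial
    filter are averaged; days with zero qualifying bins are excluded. The
    learning test compares stimulus-vs-blank anticipatory frequencies over
    the last ``last_fraction`` of the day's trials: qualifying bins within
    that segment give paired (f_stimulus, f_blank) samples for a Wilcoxon
    signed-rank test.
    """
    bins = bin_performance(log, bin_hours, min_trials)
    bins_per_day = max(int(round(24.0 / bin_hours)), 1)
    if not bins.empty:
        bins = bins.assign(day=(bins["bin"] // bins_per_day).astype(int))
    daily_rows = []
    trials = _per_trial_frequencies(log)
    if not trials.empty:
        trials["day"] = (trials["t"] // 86400.0).astype(int)
    for day in sorted(trials["day"].unique()) if not trials.empty else []:
        day_bins = bins[bins["day"] == day] if not bins.empty else bins
        if day_bins.empty:
            logger.info("day %d excluded: no qualifying bins", day)
            continue
        day_trials = trials[trials["day"] == day].sort_values("t")
        n_last = max(int(np.ceil(last_fraction * len(day_trials))), 1)
        last = day_trials.tail(n_last)
        bin_s = bin_hours * 3600.0
        last_bins = set((last["t"] // bin_s).astype(int))
        seg = day_bins[day_bins["bin"].isin(last_bins)].dropna(
            subset=["f_stimulus", "f_blank"]
        )
        if len(seg) >= 1 and not np.allclose(seg["f_stimulus"],
                                             seg["f_blank"]):
            try:
                stat, p = stats.wilcoxon(seg["f_stimulus"], seg["f_blank"])
            except ValueError:
                stat, p = np.nan, np.nan
        else:
            stat, p = np.nan, np.nan
        daily_rows.append(
            {
                "day": day,
                "n_bins": len(day_bins),
                "performance": day_bins["performance"].mean(),
                "f_stimulus": day_bins["f_stimulus"].mean(),
                "f_blank": day_bins["f_blank"].mean(),
                "wilcoxon_stat": stat,
                "wilcoxon_p": p,
            }
        )
    return {"bins": bins, "daily": pd.DataFrame(daily_rows)}
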