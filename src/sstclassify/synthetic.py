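"""Synthetic labeled imaging experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a 10-min-scale daily session — a 100-s spontaneous block, stimulus/blank
  trials interleaved at equal probability every 20 s, and a closing 100-s
  spontaneous block, imaged at 5.11 Hz;
* two SST subpopulations: a Calb2-like class with higher response
  probability and evoked peak, and an "other" class, with lognormal evoked
  amplitudes spanning ~100-fold across cells;
* multiplicative suppression of evoked (not spontaneous) responses in the
  Calb2-like class across training days, with per-cell mean-one lognormal
  plasticity diversity that persists across days;
* GCaMP-like transient kernels, neuropil contamination mixed so that the
  r = 0.7 correction recovers the clean trace in expectation, Gaussian
  noise and occasional frame-shift artifacts;
* per-subtype mCherry intensity distributions straddling the 200 a.u.
  labeling threshold.

Every generated event, trial response and parameter is recorded in a
ground-truth ledger so downstream estimates can be checked against the
generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .session import (ACC_DAYS, SAT_DAYS, CellRegistry, Experiment, Session,
                      seconds_to_frames)

DEFAULT_DAYS = ACC_DAYS + SAT_DAYS

#: Training-day suppression anchors for the Calb2-like class (fold change
#: of the evoked peak relative to the pretraining baseline).
CALB2_SAT_ANCHORS = {1: 0.62, 5: 0.56, 10: 0.46}


def calb2_suppression_schedule(anchors=None) -> dict[str, float]:
    """Per-day multiplicative suppression factors for the Calb2-like class.

    ACC days are 1.0; SAT days interpolate linearly between the anchor
    days (SAT1, SAT5, SAT10 by default).
    """
    anchors = dict(CALB2_SAT_ANCHORS if anchors is None else anchors)
    xs = sorted(anchors)
    ys = [anchors[x] for x in xs]
    sched = {d: 1.0 for d in ACC_DAYS}
    for i, d in enumerate(SAT_DAYS, start=1):
        sched[d] = float(np.interp(i, xs, ys))
    return sched


@dataclass(frozen=True)
class SubtypeSpec:
    """Generating parameters for one subpopulation."""

    name: str
    true_label: str
    n_cells: int
    response_prob: float
    amp_median: float  # evoked ΔF/F at the kernel peak, median across cells
    amp_sigma: float = 0.8  # per-class lognormal sigma; combined with the
    # between-class median gap this spans ~100-fold across the population
    spont_rate_hz: float = 0.01
    spont_amp_factor: float = 0.5  # spontaneous amplitude vs evoked, per cell
    red_median: float = 80.0
    red_sigma: float = 0.7
    suppression: dict | None = None  # day -> factor; None = 1.0 throughout
    plasticity_sigma: float = 0.3  # per-cell lognormal diversity on training days

    def __post_init__(self):
        if not (0 <= self.response_prob <= 1):
            raise ValueError("response_prob must be in [0, 1]")
        if self.suppression is not None and any(
            v <= 0 for v in self.suppression.values()
        ):
            raise ValueError("suppression factors must be > 0")


def default_subtypes():
    return (
        SubtypeSpec(
            name="calb2", true_label="SST-Calb2", n_cells=28,
            response_prob=0.8, amp_median=0.8,
            red_median=400.0, red_sigma=0.5,
            suppression=calb2_suppression_schedule(),
        ),
        SubtypeSpec(
            name="other", true_label="SST-O", n_cells=56,
            response_prob=0.35, amp_median=0.3,
            red_median=80.0, red_sigma=0.7,
            suppression=None,
        ),
    )


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic experiment."""

    subtypes: tuple = field(default_factory=default_subtypes)
    days: tuple = DEFAULT_DAYS
    frame_rate_hz: float = 5.11
    n_trials: int = 30  # ~15 stimulus trials/day after 50/50 interleaving
    trial_interval_s: float = 20.0
    spont_flank_s: float = 100.0
    stim_latency_s: float = 0.2
    tau_rise_s: float = 0.05  # GCaMP6f-scale indicator kinetics
    tau_decay_s: float = 0.7
    amp_trial_sigma: float = 0.1  # mean-one lognormal trial-to-trial jitter
    baseline_median_au: float = 100.0
    baseline_sigma: float = 0.3
    noise_sd_au: float = 1.0
    neuropil_level_au: float = 40.0
    neuropil_fluct_au: float = 2.0
    neuropil_r: float = 0.7
    shift_rate_per_session: float = 0.0  # expected shift runs per session
    shift_run_lengths: tuple = ((1, 0.4), (2, 0.3), (5, 0.3))
    shift_px: int = 30
    inject_negative_artifacts: bool = False  # exercise F0 <= 0 error paths
    suppress_spontaneous: bool = False  # sensitivity-analysis flag
    record_trials: bool = True
    animal_id: str = "m1"
    fov_id: str = "f1"

    def __post_init__(self):
        if self.tau_rise_s >= self.tau_decay_s:
            raise ValueError("tau_rise must be < tau_decay")
        trial_span_pre = 3.0
        if self.spont_flank_s < trial_span_pre:
            raise ValueError("spontaneous flank shorter than trial window")
        if self.trial_interval_s < 8.0:
            raise ValueError("trials would overlap (interval < 8 s)")

    @property
    def duration_s(self) -> float:
        return (self.spont_flank_s + (self.n_trials - 1) * self.trial_interval_s
                + 5.0 + self.spont_flank_s + 5.0)


@dataclass
class GroundTruth:
    """Generating parameters and per-event records."""

    cells: pd.DataFrame  # cell_id, subtype, true_label, p, amp, f0, red, ...
    day_factors: pd.DataFrame  # cell_id x day effective suppression factor
    trials: pd.DataFrame | None  # per cell/day/trial: responded, amplitude


def _kernel(config: GeneratorConfig) -> np.ndarray:
    rate = config.frame_rate_hz
    n = max(int(np.ceil((config.tau_rise_s + 6 * config.tau_decay_s) * rate)), 2)
    t = np.arange(n) / rate
    k = (1 - np.exp(-t / config.tau_rise_s)) * np.exp(-t / config.tau_decay_s)
    return k / k.max()


def _lognormal_mean_one(rng, sigma, size=None):
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _sample_run_length(rng, dist):
    lengths = np.array([l for l, _ in dist])
    probs = np.array([p for _, p in dist], dtype=float)
    return int(rng.choice(lengths, p=probs / probs.sum()))


def generate_experiment(config: GeneratorConfig | None = None,
                        seed: int = 0):
    """Generate a labeled experiment under ``config``.

    Deterministic given ``seed``. Returns ``(Experiment, GroundTruth)``.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    rate = config.frame_rate_hz
    n_frames = seconds_to_frames(config.duration_s, rate)
    kernel = _kernel(config)
    latency_f = seconds_to_frames(config.stim_latency_s, rate)

    onset_times = config.spont_flank_s + config.trial_interval_s * np.arange(
        config.n_trials
    )
    onset_frames = np.floor(onset_times * rate).astype(int)
    if onset_frames.size and onset_frames[-1] + seconds_to_frames(5.0, rate) > n_frames:
        raise ValueError("trial schedule overflows the session")

    # static per-cell parameters (cells persist across days)
    cell_rows = []
    for spec in config.subtypes:
        for j in range(spec.n_cells):
            cell_rows.append(
                {
                    "cell_id": f"{spec.name}_{j:03d}",
                    "subtype": spec.name,
                    "true_label": spec.true_label,
                    "response_prob": spec.response_prob,
                    "amp": spec.amp_median
                    * rng.lognormal(mean=0.0, sigma=spec.amp_sigma),
                    "f0": config.baseline_median_au
                    * rng.lognormal(mean=0.0, sigma=config.baseline_sigma),
                    "red": spec.red_median
                    * rng.lognormal(mean=0.0, sigma=spec.red_sigma),
                    "spont_rate_hz": spec.spont_rate_hz,
                    "spont_amp_factor": spec.spont_amp_factor,
                    "plasticity_mod": _lognormal_mean_one(
                        rng, spec.plasticity_sigma
                    ) if spec.plasticity_sigma > 0 else 1.0,
                }
            )
    cells = pd.DataFrame(cell_rows)
    n_cells = len(cells)
    spec_by_name = {s.name: s for s in config.subtypes}

    factor_rows, trial_rows, sessions = [], [], []
    for day in config.days:
        trial_types = np.where(rng.random(config.n_trials) < 0.5,
                               "stimulus", "blank")
        roi = np.empty((n_cells, n_frames))
        neuropil = np.empty((n_cells, n_frames))
        t_axis = np.arange(n_frames) / rate
        for ci, cell in enumerate(cells.itertuples()):
            spec = spec_by_name[cell.subtype]
            base_factor = (spec.suppression or {}).get(day, 1.0)
            # plasticity diversity applies on training days only
            if day.startswith("ACC"):
                factor = base_factor
            else:
                factor = base_factor * cell.plasticity_mod
            factor_rows.append({"cell_id": cell.cell_id, "day": day,
                                "factor": factor})
            impulses = np.zeros(n_frames)
            for ti, (ofr, ttype) in enumerate(zip(onset_frames, trial_types)):
                responded = False
                amp = 0.0
                if ttype == "stimulus":
                    responded = bool(rng.random() < cell.response_prob)
                    if responded:
                        amp = (cell.amp * factor
                               * _lognormal_mean_one(rng,
                                                     config.amp_trial_sigma))
                        impulses[ofr + latency_f] += amp
                if config.record_trials:
                    trial_rows.append(
                        {"cell_id": cell.cell_id, "day": day, "trial": ti,
                         "trial_type": ttype, "responded": responded,
                         "amplitude": amp}
                    )
            spont_amp = cell.amp * cell.spont_amp_factor
            if config.suppress_spontaneous and not day.startswith("ACC"):
                spont_amp *= base_factor
            n_ev = rng.poisson(cell.spont_rate_hz * config.duration_s)
            if n_ev:
                ev_frames = rng.integers(0, n_frames, size=n_ev)
                ev_amps = spont_amp * _lognormal_mean_one(rng, 0.3, n_ev)
                np.add.at(impulses, ev_frames, ev_amps)
            dff = np.convolve(impulses, kernel)[:n_frames]
            clean = cell.f0 * (1.0 + dff)
            phase = rng.uniform(0, 2 * np.pi)
            npil = (config.neuropil_level_au
                    + config.neuropil_fluct_au
                    * np.sin(2 * np.pi * t_axis / 60.0 + phase))
            roi[ci] = (clean + config.neuropil_r * npil
                       + rng.normal(0.0, config.noise_sd_au, n_frames))
            neuropil[ci] = npil

        shifts = np.zeros((n_frames, 2), dtype=int)
        n_runs = rng.poisson(config.shift_rate_per_session)
        for _ in range(n_runs):
            length = _sample_run_length(rng, config.shift_run_lengths)
            start = int(rng.integers(0, max(n_frames - length, 1)))
            axis = int(rng.integers(0, 2))
            shifts[start:start + length, axis] = (
                config.shift_px * (1 if rng.random() < 0.5 else -1)
            )
            scale = -1.5 if config.inject_negative_artifacts else -0.5
            roi[:, start:start + length] *= (1.0 + scale * 0.5)

        sessions.append(
            Session(
                animal_id=config.animal_id,
                fov_id=config.fov_id,
                day_label=day,
                roi_traces=roi,
                neuropil_traces=neuropil,
                frame_shifts=shifts,
                trial_onsets=list(zip(onset_frames.tolist(),
                                      trial_types.tolist())),
                frame_rate_hz=rate,
                red_intensity=cells["red"].to_numpy(),
            )
        )

    reg = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "animal_id": config.animal_id,
            "fov_id": config.fov_id,
            "true_label": cells["true_label"],
        }
    )
    for day in config.days:
        reg[f"idx_{day}"] = np.arange(n_cells)
    experiment = Experiment(sessions=sessions, registry=CellRegistry(reg))
    truth = GroundTruth(
        cells=cells,
        day_factors=pd.DataFrame(factor_rows),
        trials=pd.DataFrame(trial_rows) if config.record_trials else None,
    )
    return experiment, truth


# --- canned fixtures ------------------------------------------------------

def _fixture_two_cell_smoke():
    subtypes = (
        replace(default_subtypes()[0], n_cells=1, amp_sigma=0.2,
                plasticity_sigma=0.0),
        replace(default_subtypes()[1], n_cells=1, amp_sigma=0.2,
                plasticity_sigma=0.0),
    )
    return GeneratorConfig(subtypes=subtypes, days=("ACC4", "ACC5"),
                           n_trials=10)


def _fixture_null_no_effect():
    spec = replace(default_subtypes()[0], n_cells=12, suppression=None,
                   plasticity_sigma=0.3)
    return GeneratorConfig(
        subtypes=(spec,),
        days=("ACC4", "ACC5", "ACC6", "SAT1", "SAT2", "SAT5", "SAT6",
              "SAT9", "SAT10"),
    )


def _fixture_three_subtype_clusters():
    subtypes = (
        SubtypeSpec(name="classA", true_label="SST-Calb2", n_cells=10,
                    response_prob=0.9, amp_median=1.0, amp_sigma=0.2,
                    spont_rate_hz=0.02, red_median=400, plasticity_sigma=0.0),
        SubtypeSpec(name="classB", true_label="SST-O", n_cells=10,
                    response_prob=0.5, amp_median=0.3, amp_sigma=0.2,
                    spont_rate_hz=0.005, red_median=80, plasticity_sigma=0.0),
        SubtypeSpec(name="classC", true_label="SST-O", n_cells=10,
                    response_prob=0.05, amp_median=0.1, amp_sigma=0.2,
                    spont_rate_hz=0.05, spont_amp_factor=2.0, red_median=80,
                    plasticity_sigma=0.0),
    )
    return GeneratorConfig(subtypes=subtypes, days=("ACC4", "ACC5", "ACC6"))


def _fixture_two_class():
    """Labeled two-class population at the default effect sizes, ACC only."""
    subtypes = tuple(
        replace(s, n_cells=14, suppression=None) for s in default_subtypes()
    )
    return GeneratorConfig(subtypes=subtypes, days=("ACC4", "ACC5", "ACC6"))


FIXTURES = {
    "two-cell-smoke": _fixture_two_cell_smoke,
    "null-no-effect": _fixture_null_no_effect,
    "three-subtype-clusters": _fixture_three_subtype_clusters,
    "two-class-labeled": _fixture_two_class,
}


def fixture_config(name: str) -> GeneratorConfig:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(FIXTURES)}"
        ) from None


def make_fixture(name: str, seed: int = 0):
    """Deterministic small experiments used by the test suite and docs."""
    return generate_experiment(fixture_config(name), seed=seed)
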