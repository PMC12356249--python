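"""Data model and I/O for longitudinal two-photon imaging experiments.

A :class:`Session` is one imaging day for one field of view: raw ROI and
neuropil fluorescence traces, per-frame motion shifts, and the trial onset
schedule. A :class:`CellRegistry` aligns cell identities across days so that
the same neuron can be followed through acclimation (ACC) and training
(SAT or PSE). Experiments are serialized as plain CSV tables plus a JSON
manifest, which keeps the on-disk format language-portable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ACC_DAYS = tuple(f"ACC{i}" for i in range(1, 7))
SAT_DAYS = tuple(f"SAT{i}" for i in range(1, 11))
PSE_DAYS = tuple(f"PSE{i}" for i in range(1, 11))
#: Total ordering of day labels: ACC1 < ... < ACC6 < SAT1 < ... < SAT10.
#: PSE days occupy the same slots as SAT days (the two paradigms never mix).
DAY_ORDER = ACC_DAYS + SAT_DAYS + PSE_DAYS

TRIAL_TYPES = ("stimulus", "blank")
SUBTYPE_LABELS = ("SST-Calb2", "SST-O", "unknown")

DEFAULT_FRAME_RATE_HZ = 5.11


def day_key(label: str) -> int:
    """Sort key implementing the day-label total order."""
    try:
        return DAY_ORDER.index(label)
    except ValueError:
        raise ValueError(f"unknown day label {label!r}") from None


def sort_days(labels) -> list[str]:
    return sorted(labels, key=day_key)


def seconds_to_frames(t_seconds: float, frame_rate_hz: float) -> int:
    """Convert a duration in seconds to a frame count, flooring.

    The acquisition rate (5.11 Hz) makes second-valued windows non-integer
    in frames; flooring gives an unambiguous, conservative convention.
    """
    return int(np.floor(t_seconds * frame_rate_hz))


@dataclass
class Session:
    """One imaging day for one field of view.

    Traces are raw fluorescence in arbitrary units, shape
    ``(n_cells, n_frames)``. ``frame_shifts`` holds per-frame ``(dx, dy)``
    integer pixel displacements from motion registration. ``trial_onsets``
    is a list of ``(frame_index, trial_type)`` with trial_type in
    ``{"stimulus", "blank"}``.
    """

    animal_id: str
    fov_id: str
    day_label: str
    roi_traces: np.ndarray
    neuropil_traces: np.ndarray
    frame_shifts: np.ndarray
    trial_onsets: list[tuple[int, str]]
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    red_intensity: np.ndarray | None = None

    def __post_init__(self):
        self.roi_traces = np.asarray(self.roi_traces, dtype=float)
        self.neuropil_traces = np.asarray(self.neuropil_traces, dtype=float)
        self.frame_shifts = np.asarray(self.frame_shifts, dtype=int)
        if self.roi_traces.ndim != 2:
            raise ValueError("roi_traces must be 2-D (cells x frames)")
        if self.roi_traces.shape != self.neuropil_traces.shape:
            raise ValueError(
                f"roi_traces {self.roi_traces.shape} and neuropil_traces "
                f"{self.neuropil_traces.shape} must share shape"
            )
        if self.frame_shifts.shape != (self.n_frames, 2):
            raise ValueError("frame_shifts must have shape (n_frames, 2)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        day_key(self.day_label)  # validates label
        self.trial_onsets = [(int(f), str(t)) for f, t in self.trial_onsets]
        frames = [f for f, _ in self.trial_onsets]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        if frames and (frames[0] < 0 or frames[-1] >= self.n_frames):
            raise ValueError("trial onset frame out of range")
        for _, t in self.trial_onsets:
            if t not in TRIAL_TYPES:
                raise ValueError(f"unknown trial type {t!r}")
        if self.red_intensity is not None:
            self.red_intensity = np.asarray(self.red_intensity, dtype=float)
            if self.red_intensity.shape != (self.n_cells,):
                raise ValueError("red_intensity must be per-cell")
            if np.any(self.red_intensity < 0):
                raise ValueError("red_intensity must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.roi_traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.roi_traces.shape[1]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.animal_id, self.fov_id, self.day_label)


class CellRegistry:
    """Cross-day alignment of cell identities.

    Backed by a DataFrame with one row per cell: ``cell_id``, ``animal_id``,
    ``fov_id``, ``true_label`` and one ``idx_<day>`` column per day holding
    that cell's row index in the day's session (NaN if untracked that day).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        required = {"cell_id", "animal_id", "fov_id", "true_label"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"registry missing columns {sorted(missing)}")
        if table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in registry")
        table["true_label"] = table["true_label"].fillna("unknown")
        self.table = table.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    @property
    def days(self) -> list[str]:
        return sort_days(
            c[len("idx_"):] for c in self.table.columns if c.startswith("idx_")
        )

    def row_index(self, cell_id: str, day: str) -> int | None:
        col = f"idx_{day}"
        if col not in self.table.columns:
            return None
        v = self.table.loc[self.table["cell_id"] == cell_id, col]
        if v.empty or pd.isna(v.iloc[0]):
            return None
        return int(v.iloc[0])

    def true_label(self, cell_id: str) -> str:
        v = self.table.loc[self.table["cell_id"] == cell_id, "true_label"]
        return str(v.iloc[0]) if not v.empty else "unknown"

    def complete_cells(self, days) -> list[str]:
        """Cells tracked on every requested day.

        Cells missing any required day are excluded from cross-day analyses
        (untrackable neurons are discarded), with a warning naming them.
        """
        days = list(days)
        cols = [f"idx_{d}" for d in days]
        absent = [c for c in cols if c not in self.table.columns]
        if absent:
            warnings.warn(f"registry has no index for days {absent}")
        present = [c for c in cols if c in self.table.columns]
        if not present:
            return []
        ok = self.table[present].notna().all(axis=1)
        if len(present) < len(cols):
            ok[:] = False
        dropped = list(self.table.loc[~ok, "cell_id"])
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} cell(s) not tracked on all of "
                f"{days}: {dropped}"
            )
        return list(self.table.loc[ok, "cell_id"])


@dataclass
class Experiment:
    """A set of sessions plus the registry aligning cells across them."""

    sessions: list[Session]
    registry: CellRegistry

    def __post_init__(self):
        keys = [s.key for s in self.sessions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (animal, fov, day) session keys")

    @property
    def days(self) -> list[str]:
        return sort_days({s.day_label for s in self.sessions})

    def session(self, animal_id: str, fov_id: str, day_label: str) -> Session:
        for s in self.sessions:
            if s.key == (animal_id, fov_id, day_label):
                return s
        raise KeyError((animal_id, fov_id, day_label))

    def sessions_for_day(self, day_label: str) -> list[Session]:
        return [s for s in self.sessions if s.day_label == day_label]

    def fovs(self) -> list[tuple[str, str]]:
        return sorted({(s.animal_id, s.fov_id) for s in self.sessions})


def _session_dir(base: Path, s: Session) -> Path:
    return base / "sessions" / f"{s.animal_id}__{s.fov_id}__{s.day_label}"


def write_experiment(experiment: Experiment, path) -> None:
    """Serialize an experiment to ``path`` (CSV tables + JSON manifest).

    Round-trips bit-exactly for integer fields and to full float precision
    for traces (floats are written with 17 significant digits).
    """
    base = Path(path)
    base.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": 1, "sessions": []}
    for s in experiment.sessions:
        d = _session_dir(base, s)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "roi.csv", s.roi_traces, fmt="%.17g", delimiter=",")
        np.savetxt(d / "neuropil.csv", s.neuropil_traces, fmt="%.17g", delimiter=",")
        np.savetxt(d / "shifts.csv", s.frame_shifts, fmt="%d", delimiter=",")
        onsets = pd.DataFrame(s.trial_onsets, columns=["frame", "trial_type"])
        onsets.to_csv(d / "onsets.csv", index=False)
        entry = {
            "animal_id": s.animal_id,
            "fov_id": s.fov_id,
            "day_label": s.day_label,
            "frame_rate_hz": s.frame_rate_hz,
            "n_cells": s.n_cells,
            "n_frames": s.n_frames,
            "dir": str(d.relative_to(base)),
            "has_red": s.red_intensity is not None,
        }
        if s.red_intensity is not None:
            np.savetxt(d / "red.csv", s.red_intensity, fmt="%.17g", delimiter=",")
        manifest["sessions"].append(entry)
    reg = experiment.registry.table.copy()
    reg["true_label"] = reg["true_label"].fillna("unknown")
    reg.to_csv(base / "registry.csv", index=False)
    (base / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _load_matrix(path: Path, n_rows: int) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if n_rows == 1 and arr.shape[0] != 1:
        arr = arr.reshape(1, -1)
    return arr


def read_experiment(path) -> Experiment:
    """Load an experiment written by :func:`write_experiment`.

    Shape mismatches are hard errors; registry cells missing a recorded day
    trigger a warning at cross-day selection time (see
    :meth:`CellRegistry.complete_cells`).
    """
    base = Path(path)
    manifest = json.loads((base / "manifest.json").read_text())
    sessions = []
    for entry in manifest["sessions"]:
        d = base / entry["dir"]
        roi = _load_matrix(d / "roi.csv", entry["n_cells"])
        neuropil = _load_matrix(d / "neuropil.csv", entry["n_cells"])
        shifts = np.loadtxt(d / "shifts.csv", delimiter=",", dtype=int, ndmin=2)
        onsets_df = pd.read_csv(d / "onsets.csv")
        onsets = [
            (int(r.frame), str(r.trial_type)) for r in onsets_df.itertuples()
        ]
        red = None
        if entry.get("has_red"):
            red = np.loadtxt(d / "red.csv", delimiter=",", ndmin=1)
        sessions.append(
            Session(
                animal_id=entry["animal_id"],
                fov_id=entry["fov_id"],
                day_label=entry["day_label"],
                roi_traces=roi,
                neuropil_traces=neuropil,
                frame_shifts=shifts,
                trial_onsets=onsets,
                frame_rate_hz=float(entry["frame_rate_hz"]),
                red_intensity=red,
            )
        )
    reg_path = base / "registry.csv"
    if reg_path.exists() and reg_path.stat().st_size > 0:
        reg = pd.read_csv(reg_path)
        for col in ("cell_id", "animal_id", "fov_id"):
            if col in reg.columns:
                reg[col] = reg[col].astype(str)
    else:
        reg = pd.DataFrame(
            columns=["cell_id", "animal_id", "fov_id", "true_label"]
        )
    registry = CellRegistry(reg)
    return Experiment(sessions=sessions, registry=registry)
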