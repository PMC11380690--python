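"""Session containers and file round-trips.

A recording session is a cell-by-frame fluorescence matrix with a matched
neuropil matrix, a per-trial event table, and optional behavioral traces.
Sessions are stored as HDF5 (arrays) plus TSV (tables). Longitudinal
cell-correspondence tables map a global cell id to a within-session row
index so matched-cell analyses can align matrices across sessions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("popact")

TRIAL_TYPES = ("Go", "Nogo", "catch")
OUTCOMES = ("Hit", "Miss", "FA", "CR", "catch-FA", "catch-CR")
PHASES = ("initial-naive", "initial-expert", "reversal-naive", "reversal-expert")


class FormatError(ValueError):
    """A container is missing a required dataset or attribute."""


@dataclass
class SessionRecording:
    """Raw two-photon session: fluorescence and neuropil per cell.

    F and Fneu are (n_cells, n_frames) in arbitrary fluorescence units;
    frame_rate is in Hz. ``task_rule`` records which modality is the Go cue.
    """

    F: np.ndarray
    Fneu: np.ndarray
    frame_rate: float
    mouse_id: str = "m0"
    session_id: str = "s0"
    phase: str = "initial-naive"
    task_rule: str = "auditory-go"
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F)
        self.Fneu = np.asarray(self.Fneu)
        if not np.issubdtype(self.F.dtype, np.floating):
            self.F = self.F.astype(float)
        if not np.issubdtype(self.Fneu.dtype, np.floating):
            self.Fneu = self.Fneu.astype(float)
        if self.F.shape != self.Fneu.shape:
            raise ValueError(
                f"F {self.F.shape} and Fneu {self.Fneu.shape} shapes differ"
            )
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (cells x frames)")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.F.size and np.isnan(self.F).any():
            raise ValueError("F contains NaN")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.F.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape[0] != self.F.shape[0]:
                raise ValueError("cell_ids length must match number of cells")

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class BehavioralTraces:
    """Frame-clocked behavioral signals for one session.

    ``pupil_points`` is (n_frames, n_points, 2) with NaN rows for points the
    tracker did not resolve in that frame. ``lick_times`` are in seconds on
    the session clock.
    """

    locomotion: np.ndarray
    pupil_points: np.ndarray
    lick_times: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.locomotion = np.asarray(self.locomotion, dtype=float)
        self.pupil_points = np.asarray(self.pupil_points, dtype=float)
        self.lick_times = np.asarray(self.lick_times, dtype=float)


_TRIAL_COLUMNS = [
    "trial",
    "trial_type",
    "stimulus",
    "onset_frame",
    "outcome",
    "lick_times",
    "rewarded",
]


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a trial table.

    Onsets must be strictly increasing and outcomes consistent with trial
    type (a Miss can only occur on a Go trial, etc.).
    """
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table missing columns: {missing}")
    onsets = trials["onset_frame"].to_numpy()
    if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
        raise ValueError("trial onsets must be strictly increasing")
    valid = {
        "Go": {"Hit", "Miss"},
        "Nogo": {"FA", "CR"},
        "catch": {"catch-FA", "catch-CR"},
    }
    for ttype, group in trials.groupby("trial_type"):
        bad = set(group["outcome"]) - valid.get(str(ttype), set())
        if bad:
            raise ValueError(f"outcomes {bad} invalid for trial type {ttype}")
    return trials


def read_session(path) -> SessionRecording:
    """Read a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        rec_kwargs = {}
        for name in ("F", "Fneu", "cell_ids"):
            if name not in f:
                raise FormatError(f"session container missing dataset '{name}'")
            rec_kwargs[name] = f[name][()]
        for attr in ("frame_rate", "mouse_id", "session_id", "phase", "task_rule"):
            if attr not in f.attrs:
                raise FormatError(f"session container missing attribute '{attr}'")
            rec_kwargs[attr] = f.attrs[attr]
    rec_kwargs["frame_rate"] = float(rec_kwargs["frame_rate"])
    for key in ("mouse_id", "session_id", "phase", "task_rule"):
        rec_kwargs[key] = str(rec_kwargs[key])
    return SessionRecording(**rec_kwargs)


def write_session(rec: SessionRecording, path) -> str:
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=rec.F)
        f.create_dataset("Fneu", data=rec.Fneu)
        f.create_dataset("cell_ids", data=rec.cell_ids)
        f.attrs["frame_rate"] = rec.frame_rate
        f.attrs["mouse_id"] = rec.mouse_id
        f.attrs["session_id"] = rec.session_id
        f.attrs["phase"] = rec.phase
        f.attrs["task_rule"] = rec.task_rule
    return str(path)


def write_trial_table(trials: pd.DataFrame, path) -> str:
    out = trials.copy()
    out["lick_times"] = [
        ";".join(f"{t:.6g}" for t in np.atleast_1d(licks)) if len(np.atleast_1d(licks)) else ""
        for licks in trials["lick_times"]
    ]
    out.to_csv(path, sep="\t", index=False)
    return str(path)


def read_trial_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t", dtype={"lick_times": str})
    trials["lick_times"] = [
        np.array([float(t) for t in str(s).split(";") if t], dtype=float)
        if isinstance(s, str) and s
        else np.array([], dtype=float)
        for s in trials["lick_times"].fillna("")
    ]
    return validate_trial_table(trials)


def write_behavior(traces: BehavioralTraces, path) -> str:
    with h5py.File(path, "w") as f:
        f.create_dataset("locomotion", data=traces.locomotion)
        f.create_dataset("pupil_points", data=traces.pupil_points)
        f.create_dataset("lick_times", data=traces.lick_times)
        f.attrs["frame_rate"] = traces.frame_rate
    return str(path)


def read_behavior(path) -> BehavioralTraces:
    with h5py.File(path, "r") as f:
        for name in ("locomotion", "pupil_points", "lick_times"):
            if name not in f:
                raise FormatError(f"behavior container missing dataset '{name}'")
        return BehavioralTraces(
            locomotion=f["locomotion"][()],
            pupil_points=f["pupil_points"][()],
            lick_times=f["lick_times"][()],
            frame_rate=float(f.attrs["frame_rate"]),
        )


# ---------------------------------------------------------------------------
# Longitudinal cell tracking
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["mouse_id", "global_cell_id", "session_id", "cell_index"]


def validate_tracked_cell_map(cell_map: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _MAP_COLUMNS if c not in cell_map.columns]
    if missing:
        raise FormatError(f"tracked-cell map missing columns: {missing}")
    dup = cell_map.duplicated(subset=["global_cell_id", "session_id"])
    if dup.any():
        raise ValueError("duplicate (global_cell_id, session_id) mappings")
    return cell_map


def align_tracked_cells(
    cell_map: pd.DataFrame, sessions: list[SessionRecording]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Row selectors that put the same global cell on the same row everywhere.

    Returns ``(global_ids, selectors)`` where ``selectors[session_id]`` is an
    integer index array into that session's cell axis. Cells absent from any
    requested session are dropped; the dropped count is logged.
    """
    validate_tracked_cell_map(cell_map)
    session_ids = [s.session_id for s in sessions]
    known = set(cell_map["session_id"])
    unknown = [sid for sid in session_ids if sid not in known]
    if unknown:
        raise KeyError(f"tracked-cell map has no entries for sessions {unknown}")

    per_session = {
        sid: dict(
            zip(grp["global_cell_id"].to_numpy(), grp["cell_index"].to_numpy())
        )
        for sid, grp in cell_map.groupby("session_id")
        if sid in session_ids
    }
    common = set.intersection(*(set(m) for m in per_session.values()))
    total = set().union(*(set(m) for m in per_session.values()))
    if not common:
        raise ValueError("no cells matched across all requested sessions")
    dropped = len(total) - len(common)
    if dropped:
        logger.info("align_tracked_cells: dropped %d unmatched cells", dropped)

    global_ids = np.array(sorted(common))
    selectors = {
        sid: np.array([per_session[sid][g] for g in global_ids], dtype=int)
        for sid in session_ids
    }
    return global_ids, selectors


def identity_cell_map(
    mouse_id: str, session_ids: list[str], n_cells: int
) -> pd.DataFrame:
    """Correspondence table for sessions whose rows are already aligned."""
    rows = [
        (mouse_id, g, sid, g)
        for sid in session_ids
        for g in range(n_cells)
    ]
    return pd.DataFrame(rows, columns=_MAP_COLUMNS)
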