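"""Delimited-text I/O for events, sessions, hypnograms, and dendrograms.

Event tables are CSV with one row per unitary event
(mouse_id, neuron_id, session, time_s, amplitude); hypnograms are CSV
interval tables (start_s, end_s, state).  Validation errors report
1-based file line numbers (header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .events import SESSIONS, EventTrain
from .experiment import DEFAULT_SESSION_DURATIONS, STATES, Experiment, Hypnogram

EVENT_COLUMNS = ["mouse_id", "neuron_id", "session", "time_s", "amplitude"]
HYPNOGRAM_COLUMNS = ["start_s", "end_s", "state"]


def _lines(index) -> str:
    return ", ".join(str(i + 2) for i in list(index)[:10])


def write_events(experiment: Experiment, path) -> None:
    rows = []
    for mouse, neuron in experiment.neuron_index:
        for session in SESSIONS:
            train = experiment.get(mouse, neuron, session)
            if train is None:
                continue
            for t, a in zip(train.times, train.amplitudes):
                rows.append((mouse, neuron, session, t, a))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path, session_durations: dict | None = None,
                hypnogram: Hypnogram | None = None) -> Experiment:
    """Parse and validate an event table into an Experiment.

    Rows must be sorted by time within each (mouse, neuron, session)
    group; unknown sessions, non-positive amplitudes and unsorted times
    are rejected with line numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    durations = dict(session_durations or DEFAULT_SESSION_DURATIONS)

    bad = ~df["session"].isin(SESSIONS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown session labels at lines {_lines(df.index[bad])}"
        )
    bad = ~(df["amplitude"] > 0)
    if bad.any():
        raise ValueError(
            f"{path}: non-positive amplitudes at lines {_lines(df.index[bad])}"
        )
    grouped = df.groupby(["mouse_id", "neuron_id", "session"], sort=False)
    unsorted_lines = []
    for _, g in grouped:
        diffs = np.diff(g["time_s"].to_numpy())
        if np.any(diffs < 0):
            unsorted_lines.extend(g.index[1:][diffs < 0].tolist())
    if unsorted_lines:
        raise ValueError(
            f"{path}: unsorted event times at lines {_lines(unsorted_lines)}"
        )
    trains = {}
    for (mouse, neuron, session), g in grouped:
        mouse, neuron = str(mouse), str(neuron)
        trains[(mouse, neuron, session)] = EventTrain(
            neuron_id=neuron,
            mouse_id=mouse,
            session=session,
            times=g["time_s"].to_numpy(dtype=float),
            amplitudes=g["amplitude"].to_numpy(dtype=float),
        )
    return Experiment(
        trains=trains, session_durations=durations, hypnogram=hypnogram
    )


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    pd.DataFrame(hypnogram.intervals, columns=HYPNOGRAM_COLUMNS).to_csv(
        path, index=False
    )


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in HYPNOGRAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["state"].isin(STATES)
    if bad.any():
        raise ValueError(f"{path}: unknown states at lines {_lines(df.index[bad])}")
    try:
        return Hypnogram(
            tuple(
                (float(r.start_s), float(r.end_s), str(r.state))
                for r in df.itertuples()
            )
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_sessions(session_durations: dict, path) -> None:
    pd.DataFrame(
        sorted(session_durations.items()), columns=["session", "duration_s"]
    ).to_csv(path, index=False)


def read_sessions(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    return {str(r.session): float(r.duration_s) for r in df.itertuples()}


def save_experiment(experiment: Experiment, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_events(experiment, directory / "events.csv")
    write_sessions(experiment.session_durations, directory / "sessions.csv")
    if experiment.hypnogram is not None:
        write_hypnogram(experiment.hypnogram, directory / "hypnogram.csv")


def load_experiment(directory) -> Experiment:
    directory = Path(directory)
    durations = None
    if (directory / "sessions.csv").exists():
        durations = read_sessions(directory / "sessions.csv")
    hypnogram = None
    if (directory / "hypnogram.csv").exists():
        hypnogram = read_hypnogram(directory / "hypnogram.csv")
    return read_events(directory / "events.csv", durations, hypnogram)


def linkage_to_newick(linkage_matrix: np.ndarray, labels) -> str:
    """Serialize a scipy linkage as a Newick tree with height-difference
    branch lengths."""
    root = to_tree(linkage_matrix)
    labels = list(labels)

    def rec(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = node.left, node.right
        return (
            f"({rec(left)}:{max(node.dist - left.dist, 0.0):g},"
            f"{rec(right)}:{max(node.dist - right.dist, 0.0):g})"
        )

    return rec(root) + ";"
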