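"""Readers and writers for the pipeline's on-disk formats.

All tabular data are delimited text (comma or tab, auto-detected by
pandas); run summaries are JSON.  Time is in seconds everywhere and
intervals are half-open [start, stop).  Behavioral event logs are
accepted in two dialects: an interval table (behavior, start, stop)
and a BORIS-style point-event table (behavior, time, event_type with
START/STOP rows), which is paired into intervals on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fiberbehav.errors import (
    DataError,
    EmptyInputError,
    FormatError,
    PairingError,
)

__all__ = [
    "EventTable",
    "read_photometry",
    "write_photometry",
    "read_events",
    "write_events",
    "read_tracking",
    "write_tracking",
    "read_spikes",
    "write_spikes",
    "read_stim",
    "write_stim",
    "read_puncta",
    "write_puncta",
    "write_results",
]


@dataclass
class EventTable:
    """Labeled half-open behavioral intervals, sorted by start."""

    df: pd.DataFrame  # columns: behavior, start, stop

    def __post_init__(self) -> None:
        required = {"behavior", "start", "stop"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"event table missing column(s) {sorted(missing)}")
        if (self.df["stop"] < self.df["start"]).any():
            bad = self.df[self.df["stop"] < self.df["start"]].iloc[0]
            raise DataError(
                f"event {bad['behavior']!r} has stop {bad['stop']} < start "
                f"{bad['start']}")
        if (self.df["start"] < 0).any():
            raise DataError("event times must be non-negative")
        self.df = self.df.sort_values("start", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, behavior: str) -> "EventTable":
        return EventTable(self.df[self.df["behavior"] == behavior].copy())

    @property
    def onsets(self) -> np.ndarray:
        return self.df["start"].to_numpy(dtype=float)


def _read_table(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty input: {what} file {path} has no content")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip float parsing keeps write->read lossless on doubles
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if len(df) == 0:
        raise EmptyInputError(f"empty input: {what} file {path} has no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{what} file missing required column {col!r}")


# -- photometry --------------------------------------------------------

def read_photometry(path: str | Path):
    """Read a two-channel photometry session (time, signal_465, ref_405)."""
    from fiberbehav.photometry import PhotometrySession

    df = _read_table(path, "photometry")
    _require(df, ["time", "signal_465", "ref_405"], "photometry")
    t = df["time"].to_numpy(dtype=float)
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise DataError("photometry time column is not strictly increasing")
    return PhotometrySession(
        time=t,
        signal=df["signal_465"].to_numpy(dtype=float),
        reference=df["ref_405"].to_numpy(dtype=float),
    )


def write_photometry(session, path: str | Path) -> None:
    pd.DataFrame({
        "time": session.time,
        "signal_465": session.signal,
        "ref_405": session.reference,
    }).to_csv(path, index=False)


# -- events ------------------------------------------------------------

def read_events(path: str | Path) -> EventTable:
    """Read a behavioral event log in either dialect.

    Interval dialect: columns behavior, start, stop.  Point dialect:
    columns behavior, time, event_type with START/STOP rows, paired
    per behavior in time order.
    """
    df = _read_table(path, "events")
    if {"start", "stop"} <= set(df.columns):
        _require(df, ["behavior", "start", "stop"], "events")
        return EventTable(df[["behavior", "start", "stop"]].astype(
            {"start": float, "stop": float}))
    if {"time", "event_type"} <= set(df.columns):
        _require(df, ["behavior", "time", "event_type"], "events")
        return _pair_point_events(df)
    raise FormatError(
        "events file must have columns (behavior, start, stop) or "
        "(behavior, time, event_type)")


def _pair_point_events(df: pd.DataFrame) -> EventTable:
    rows = []
    open_starts: dict[str, list[float]] = {}
    for _, r in df.sort_values("time", kind="stable").iterrows():
        label = str(r["behavior"])
        kind = str(r["event_type"]).strip().upper()
        t = float(r["time"])
        if kind == "START":
            open_starts.setdefault(label, []).append(t)
        elif kind == "STOP":
            stack = open_starts.get(label, [])
            if not stack:
                raise PairingError(
                    f"STOP without matching START for {label!r} at t={t}")
            rows.append({"behavior": label, "start": stack.pop(0), "stop": t})
        else:
            raise FormatError(f"unknown event_type {kind!r} (expected START/STOP)")
    leftovers = {k: v for k, v in open_starts.items() if v}
    if leftovers:
        label, times = next(iter(leftovers.items()))
        raise PairingError(
            f"START without matching STOP for {label!r} at t={times[0]}")
    return EventTable(pd.DataFrame(rows, columns=["behavior", "start", "stop"]))


def write_events(table: EventTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


# -- tracking ----------------------------------------------------------

def read_tracking(path: str | Path, frame_rate: float,
                  arena: tuple[float, float] = (50.0, 50.0)):
    """Read arena tracking output (frame, time, x, y, motion)."""
    from fiberbehav.behavior import Trajectory

    df = _read_table(path, "tracking")
    _require(df, ["frame", "time", "x", "y", "motion"], "tracking")
    return Trajectory(
        frame=df["frame"].to_numpy(),
        time=df["time"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        motion=df["motion"].to_numpy(dtype=float),
        frame_rate=frame_rate,
        arena=arena,
    )


def write_tracking(traj, path: str | Path) -> None:
    pd.DataFrame({
        "frame": traj.frame.astype(int),
        "time": traj.time,
        "x": traj.x,
        "y": traj.y,
        "motion": traj.motion,
    }).to_csv(path, index=False)


# -- spikes and stimulation -------------------------------------------

def read_spikes(path: str | Path) -> dict[str, np.ndarray]:
    """Read sorted spike times (columns unit, time) into per-unit arrays."""
    df = _read_table(path, "spikes")
    _require(df, ["unit", "time"], "spikes")
    out = {}
    for unit, g in df.groupby("unit", sort=True):
        out[str(unit)] = np.sort(g["time"].to_numpy(dtype=float))
    return out


def write_spikes(spikes: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [{"unit": u, "time": t} for u, ts in spikes.items() for t in ts]
    pd.DataFrame(rows, columns=["unit", "time"]).to_csv(path, index=False)


def read_stim(path: str | Path) -> dict[str, np.ndarray]:
    """Read stimulus onsets (columns kind in {single, burst}, time)."""
    df = _read_table(path, "stim")
    _require(df, ["kind", "time"], "stim")
    kinds = set(df["kind"].astype(str))
    unknown = kinds - {"single", "burst"}
    if unknown:
        raise FormatError(f"unknown stim kind(s) {sorted(unknown)}")
    return {k: np.sort(df.loc[df["kind"] == k, "time"].to_numpy(dtype=float))
            for k in ("single", "burst")}


def write_stim(stim: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [{"kind": k, "time": t} for k in ("single", "burst")
            for t in stim.get(k, [])]
    pd.DataFrame(rows, columns=["kind", "time"]).to_csv(path, index=False)


# -- puncta ------------------------------------------------------------

def read_puncta(path: str | Path) -> pd.DataFrame:
    """Read a per-cell puncta-count table (cell_id, syp_count, vglut2_count)."""
    df = _read_table(path, "puncta")
    _require(df, ["cell_id", "syp_count", "vglut2_count"], "puncta")
    for col in ("syp_count", "vglut2_count"):
        vals = df[col].to_numpy()
        if not np.all(np.equal(np.mod(vals, 1), 0)) or (vals < 0).any():
            raise DataError(f"{col} must contain non-negative integers")
        df[col] = df[col].astype(int)
    return df[["cell_id", "syp_count", "vglut2_count"]].copy()


def write_puncta(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# -- results -----------------------------------------------------------

def write_results(table: pd.DataFrame, summary: dict, out_dir: str | Path,
                  stem: str = "results") -> tuple[Path, Path]:
    """Write a results table (CSV) plus a JSON summary; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    table.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return csv_path, json_path
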