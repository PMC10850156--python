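"""Behavioral-state classification and exploration metrics from arena tracking.

Implements threshold-based scoring of open-field and hole-board
sessions: immobility (speed < 6 cm/s and per-frame body-motion change
< 1 %, runs longer than 15 frames), locomotion (speed > 6 cm/s,
minimum 10 cm path per bout), pauses (speed < 3 cm/s for at least
1 s, with locomotion initiations at pause offset), thigmotaxis zones
(peripheral 25 % of the arena), focused-exploration episodes (two or
more head-dips chained by inter-dip gaps of at most 5 s), the
ethogram (immobility / grooming / surveying / rearing / locomotion)
and per-epoch metrics under an alternating baseline/stimulation
(Pre / ON / OFF) design with Pre-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from fiberbehav.config import Thresholds
from fiberbehav.errors import DataError, ParameterError
from fiberbehav.io_formats import EventTable

__all__ = [
    "Trajectory",
    "Ethogram",
    "EpochMetrics",
    "ETHOGRAM_LABELS",
    "velocity",
    "detect_immobility",
    "detect_locomotion",
    "detect_pauses",
    "zone_metrics",
    "detect_focused_exploration",
    "build_ethogram",
    "epoch_metrics",
]

ETHOGRAM_LABELS = ("immobility", "grooming", "surveying", "rearing", "locomotion")


@dataclass
class Trajectory:
    """Tracked center-of-mass path in a square arena.

    ``motion`` is the tracking software's per-frame percentage change of
    the animal's body pixels; ``arena`` is (width, height) in cm with
    the origin at one corner.
    """

    frame: np.ndarray
    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    motion: np.ndarray
    frame_rate: float
    arena: tuple[float, float] = (50.0, 50.0)

    def __post_init__(self) -> None:
        for name in ("frame", "time", "x", "y", "motion"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.frame)
        if n == 0:
            raise DataError("empty trajectory")
        for name in ("time", "x", "y", "motion"):
            if len(getattr(self, name)) != n:
                raise DataError(f"trajectory column {name} length mismatch")
        if self.frame_rate is None or self.frame_rate <= 0:
            raise ParameterError("trajectory frame_rate must be set and > 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def duration(self) -> float:
        """Session duration with half-open frames (n_frames / frame_rate)."""
        return len(self) / self.frame_rate


@dataclass
class Ethogram:
    """Exclusive behavioral-state intervals over one session."""

    intervals: pd.DataFrame  # columns: label, start, stop
    labels: tuple[str, ...] = ETHOGRAM_LABELS

    def duration_of(self, label: str) -> float:
        sel = self.intervals[self.intervals["label"] == label]
        return float((sel["stop"] - sel["start"]).sum())


@dataclass
class EpochMetrics:
    """Per-epoch behavioral metrics and their Pre-normalized values."""

    per_epoch: pd.DataFrame       # one row per epoch occurrence
    averaged: pd.DataFrame        # repetitions averaged within epoch label
    normalized_to_pre: pd.DataFrame  # averaged minus the Pre row
    mode: str = "subtract"


# ---------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------

def velocity(traj: Trajectory, smooth_window: float = 1.0) -> np.ndarray:
    """Instantaneous speed (cm/s) from Gaussian-smoothed position.

    Positions are smoothed with a Gaussian kernel whose +/-3 sigma
    support spans ``smooth_window`` seconds (sigma = window/6), then
    speed is frame-to-frame displacement times the frame rate.
    ``smooth_window=0`` gives the raw finite-difference speed.
    """
    if len(traj) < 2:
        raise ParameterError("velocity needs at least 2 frames")
    x, y = traj.x, traj.y
    if smooth_window > 0:
        sigma = smooth_window * traj.frame_rate / 6.0
        if sigma > 0:
            x = gaussian_filter1d(x, sigma, mode="nearest")
            y = gaussian_filter1d(y, sigma, mode="nearest")
    dx = np.diff(x)
    dy = np.diff(y)
    speed = np.hypot(dx, dy) * traj.frame_rate
    # first frame inherits the first displacement so the series has one
    # value per frame
    return np.concatenate([[speed[0]], speed])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs [i0, i1)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _frames_to_interval(traj: Trajectory, i0: int, i1: int) -> tuple[float, float]:
    """Half-open time interval covered by frames [i0, i1)."""
    dt = 1.0 / traj.frame_rate
    t0 = traj.time[0]
    return (t0 + i0 * dt, t0 + i1 * dt)


def detect_immobility(traj: Trajectory, speed: np.ndarray | None = None,
                      thresholds: Thresholds | None = None) -> list[tuple[float, float]]:
    """Immobility bouts: speed < 6 cm/s AND motion change < 1 %.

    Only maximal runs strictly longer than 15 frames count as bouts.
    """
    th = thresholds or Thresholds()
    if speed is None:
        speed = velocity(traj)
    mask = (speed < th.immobility_speed) & (traj.motion < th.immobility_motion)
    return [_frames_to_interval(traj, i0, i1) for i0, i1 in _runs(mask)
            if i1 - i0 > th.immobility_min_frames]


def detect_locomotion(traj: Trajectory, speed: np.ndarray | None = None,
                      thresholds: Thresholds | None = None,
                      ) -> tuple[list[tuple[float, float]], float]:
    """Locomotor bouts (speed > 6 cm/s, path >= 10 cm) and distance.

    A continuous supra-threshold run is one bout; runs whose path
    length falls below the 10-cm minimum are discarded.  Returns the
    surviving bout intervals and the summed path length over them.
    """
    th = thresholds or Thresholds()
    if speed is None:
        speed = velocity(traj)
    step = np.concatenate([[0.0], np.hypot(np.diff(traj.x), np.diff(traj.y))])
    bouts, total = [], 0.0
    for i0, i1 in _runs(speed > th.locomotion_speed):
        # displacement into frame i is step[i]; a run [i0, i1) covers
        # steps i0+1 .. i1-1 plus the entry step i0
        path = float(step[i0:i1].sum())
        if path >= th.locomotion_min_distance:
            bouts.append(_frames_to_interval(traj, i0, i1))
            total += path
    return bouts, total


def detect_pauses(traj: Trajectory, speed: np.ndarray | None = None,
                  thresholds: Thresholds | None = None,
                  ) -> tuple[list[tuple[float, float]], list[float]]:
    """Pauses (< 3 cm/s for >= 1 s) and locomotion-initiation times.

    Initiations are aligned at the termination of each pause; a pause
    still running at the end of the session yields no initiation.
    """
    th = thresholds or Thresholds()
    if speed is None:
        speed = velocity(traj)
    min_frames = int(np.ceil(th.pause_min_duration * traj.frame_rate))
    pauses, initiations = [], []
    for i0, i1 in _runs(speed < th.pause_speed):
        if i1 - i0 >= min_frames:
            start, stop = _frames_to_interval(traj, i0, i1)
            pauses.append((start, stop))
            if i1 < len(traj):
                initiations.append(stop)
    return pauses, initiations


def zone_metrics(traj: Trajectory, zone_fraction: float = 0.25,
                 zone_mode: str = "linear") -> dict:
    """Center vs thigmotactic-periphery occupancy and path length.

    The thigmotactic zone is the peripheral band along the walls.  In
    ``linear`` mode the band occupies ``zone_fraction`` of the arena's
    linear extent per axis (band width = zone_fraction/2 of the side
    at each wall); in ``area`` mode the band is widened so the
    periphery covers ``zone_fraction`` of the arena area.  Frames are
    half-open, so center and periphery times sum exactly to the
    session duration.
    """
    if not 0 < zone_fraction < 1:
        raise ParameterError(f"zone_fraction must be in (0, 1), got {zone_fraction}")
    w, h = traj.arena
    if zone_mode == "linear":
        fx = zone_fraction / 2.0
    elif zone_mode == "area":
        # inner rectangle side fraction s solves 1 - s^2 = zone_fraction
        fx = (1.0 - np.sqrt(1.0 - zone_fraction)) / 2.0
    else:
        raise ParameterError(f"unknown zone_mode {zone_mode!r}")
    bx, by = fx * w, fx * h
    in_center = ((traj.x >= bx) & (traj.x <= w - bx)
                 & (traj.y >= by) & (traj.y <= h - by))
    dt = 1.0 / traj.frame_rate
    step = np.concatenate([[0.0], np.hypot(np.diff(traj.x), np.diff(traj.y))])
    thigmo_intervals = [_frames_to_interval(traj, i0, i1)
                        for i0, i1 in _runs(~in_center)]
    return {
        "center_time": float(in_center.sum() * dt),
        "thigmo_time": float((~in_center).sum() * dt),
        "center_distance": float(step[in_center].sum()),
        "thigmo_distance": float(step[~in_center].sum()),
        "thigmo_intervals": thigmo_intervals,
    }


def detect_focused_exploration(dips: EventTable, max_gap: float = 5.0,
                               ) -> tuple[list[tuple[float, float]],
                                          list[tuple[float, float]]]:
    """Chain head-dips into focused-exploration episodes.

    Successive dips whose end-to-start gap is at most ``max_gap``
    seconds belong to one chain; chains of two or more dips become
    episodes spanning [first dip start, last dip end).  Singleton
    chains are returned as isolated dips.  Every input dip lands in
    exactly one category.
    """
    df = dips.df.sort_values("start").reset_index(drop=True)
    episodes: list[tuple[float, float]] = []
    isolated: list[tuple[float, float]] = []
    chain: list[tuple[float, float]] = []

    def flush():
        if len(chain) >= 2:
            episodes.append((chain[0][0], chain[-1][1]))
        elif chain:
            isolated.append(chain[0])

    for start, stop in zip(df["start"], df["stop"]):
        if chain and start - chain[-1][1] <= max_gap:
            chain.append((start, stop))
        else:
            flush()
            chain = [(start, stop)]
    flush()
    return episodes, isolated


def build_ethogram(traj: Trajectory, manual_events: EventTable | None = None,
                   thresholds: Thresholds | None = None) -> Ethogram:
    """Assign every frame one behavioral state.

    Precedence: manually annotated grooming/rearing > immobility >
    locomotion > surveying.  Surveying is the residual category — the
    animal stays in place with some movement, neither immobile nor
    locomoting.
    """
    th = thresholds or Thresholds()
    speed = velocity(traj)
    labels = np.full(len(traj), "surveying", dtype=object)

    step = np.concatenate([[0.0], np.hypot(np.diff(traj.x), np.diff(traj.y))])
    for i0, i1 in _runs(speed > th.locomotion_speed):
        path = float(step[i0:i1].sum())
        if path >= th.locomotion_min_distance:
            labels[i0:i1] = "locomotion"

    immo_mask = (speed < th.immobility_speed) & (traj.motion < th.immobility_motion)
    for i0, i1 in _runs(immo_mask):
        if i1 - i0 > th.immobility_min_frames:
            labels[i0:i1] = "immobility"

    if manual_events is not None:
        dt = 1.0 / traj.frame_rate
        frame_start = traj.time[0] + np.arange(len(traj)) * dt
        for _, row in manual_events.df.iterrows():
            if row["behavior"] in ("grooming", "rearing"):
                inside = (frame_start >= row["start"]) & (frame_start < row["stop"])
                labels[inside] = row["behavior"]

    rows = []
    i = 0
    dt = 1.0 / traj.frame_rate
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        start, stop = _frames_to_interval(traj, i, j)
        rows.append({"label": labels[i], "start": start, "stop": stop})
        i = j
    return Ethogram(intervals=pd.DataFrame(rows))


# ---------------------------------------------------------------------
# epoch design
# ---------------------------------------------------------------------

def _clip_interval(start: float, stop: float, lo: float, hi: float) -> float:
    return max(0.0, min(stop, hi) - max(start, lo))


def epoch_metrics(etho: Ethogram, traj: Trajectory,
                  dips: EventTable | None = None,
                  design: tuple[str, ...] = ("Pre", "ON", "OFF", "ON", "OFF"),
                  epoch_length: float = 180.0,
                  thresholds: Thresholds | None = None,
                  normalize: str = "subtract") -> EpochMetrics:
    """Per-epoch behavioral metrics under an alternating ON/OFF design.

    Epochs are consecutive half-open blocks of ``epoch_length``
    seconds following ``design``.  Metrics per epoch: duration of each
    ethogram label, locomotor bout count and distance, mean speed,
    center distance and time, head-dip count and duration.
    Repetitions of the same label are averaged, and the averaged table
    is normalized to the Pre epoch (subtraction by default; ``ratio``
    divides, leaving Pre at 1).
    """
    th = thresholds or Thresholds()
    t0 = traj.time[0]
    session_end = t0 + traj.duration
    if t0 + len(design) * epoch_length > session_end + 1e-9:
        raise ParameterError(
            f"design of {len(design)} x {epoch_length} s epochs extends past "
            f"session end ({traj.duration:.1f} s)")
    speed = velocity(traj)
    loco_bouts, _ = detect_locomotion(traj, speed, th)
    step = np.concatenate([[0.0], np.hypot(np.diff(traj.x), np.diff(traj.y))])
    zones = zone_metrics(traj, th.zone_fraction, th.zone_mode)
    dt = 1.0 / traj.frame_rate
    frame_start = t0 + np.arange(len(traj)) * dt
    w, h = traj.arena
    fx = (th.zone_fraction / 2.0 if th.zone_mode == "linear"
          else (1.0 - np.sqrt(1.0 - th.zone_fraction)) / 2.0)
    in_center = ((traj.x >= fx * w) & (traj.x <= w - fx * w)
                 & (traj.y >= fx * h) & (traj.y <= h - fx * h))

    rows = []
    for k, label in enumerate(design):
        lo = t0 + k * epoch_length
        hi = lo + epoch_length
        row = {"epoch": k, "label": label}
        for b in etho.labels:
            sel = etho.intervals[etho.intervals["label"] == b]
            row[f"dur_{b}"] = float(sum(
                _clip_interval(s, e, lo, hi) for s, e in zip(sel["start"], sel["stop"])))
        in_epoch = (frame_start >= lo) & (frame_start < hi)
        row["distance"] = float(step[in_epoch].sum())
        row["mean_speed"] = float(speed[in_epoch].mean()) if in_epoch.any() else 0.0
        row["locomotor_bouts"] = sum(
            1 for s, e in loco_bouts if lo <= s < hi)
        row["center_distance"] = float(step[in_epoch & in_center].sum())
        row["center_time"] = float((in_epoch & in_center).sum() * dt)
        if dips is not None:
            d = dips.df
            in_d = (d["start"] >= lo) & (d["start"] < hi)
            row["head_dip_count"] = int(in_d.sum())
            row["head_dip_duration"] = float(sum(
                _clip_interval(s, e, lo, hi)
                for s, e in zip(d["start"], d["stop"])))
        rows.append(row)
    per_epoch = pd.DataFrame(rows)

    metric_cols = [c for c in per_epoch.columns if c not in ("epoch", "label")]
    averaged = per_epoch.groupby("label", sort=False)[metric_cols].mean()
    if "Pre" not in averaged.index:
        raise ParameterError("design must contain a Pre epoch for normalization")
    pre_row = averaged.loc["Pre"]
    if normalize == "subtract":
        normalized = averaged - pre_row
    elif normalize == "ratio":
        normalized = averaged / pre_row.replace(0, np.nan)
    else:
        raise ParameterError(f"unknown normalize mode {normalize!r}")
    return EpochMetrics(per_epoch=per_epoch, averaged=averaged,
                        normalized_to_pre=normalized, mode=normalize)
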