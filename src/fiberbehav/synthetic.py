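"""Ground-truthed synthetic recordings for every pipeline stage.

Each generator emulates the statistical structure of one raw data
kind — two-channel photometry with photobleaching, shared motion
artifacts and event-locked calcium transients; arena trajectories
built from scripted behavioral bouts; tonically firing units with
short-latency optogenetic inhibition in a known responder subset; and
per-cell puncta tables with known positive fractions — and returns
the generating parameters as a :class:`GroundTruth` so pipeline
output can be compared against truth without re-derivation.

All generators are deterministic in (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fiberbehav.config import SessionConfig
from fiberbehav.ephys import BurstParams, StimExperiment
from fiberbehav.errors import ParameterError
from fiberbehav.io_formats import EventTable
from fiberbehav.photometry import (
    PhotometrySession,
    bleach_correct,
    lowpass,
    motion_correct,
)

__all__ = [
    "GroundTruth",
    "BoutSpec",
    "gen_photometry",
    "gen_tracking",
    "gen_spiketrains",
    "gen_puncta",
    "default_bout_script",
]


@dataclass
class GroundTruth:
    """Generating parameters of one synthetic dataset.

    Only the fields relevant to the generated kind are populated; the
    rest stay None.  Serialized alongside the data so recovery tests
    need no re-derivation.
    """

    event_schedule: EventTable | None = None
    transient_amplitude: float | None = None   # z units
    bleach_tau: float | None = None            # s
    artifact_times: list[float] = field(default_factory=list)
    ethogram: EventTable | None = None
    responder_flags: dict[str, bool] = field(default_factory=dict)
    baseline_rates: dict[str, float] = field(default_factory=dict)
    inhibition_latency: float | None = None    # s
    inhibition_depth: float | None = None      # fraction of baseline rate
    puncta_labels: pd.DataFrame | None = None  # per-cell is_syp_pos/is_vglut2_pos
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, EventTable):
                v = v.df.to_dict(orient="list")
            elif isinstance(v, pd.DataFrame):
                v = v.to_dict(orient="list")
            d[f.name] = v
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True, default=float)


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ParameterError("a seed is required for reproducible generation")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------

def _transient_kernel(rate: float, rise: float = 0.2, decay: float = 1.5
                      ) -> np.ndarray:
    """Peak-normalized double-exponential calcium-indicator kernel."""
    t = np.arange(0, decay * 6, 1.0 / rate)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def gen_photometry(config: SessionConfig | None = None, seed: int = 0,
                   duration: float = 600.0, n_events: int = 20,
                   transient_amplitude: float = 2.0, bleach_tau: float = 300.0,
                   baseline_level: float = 1.0, noise_sd: float = 0.01,
                   artifact_amplitude: float | None = None,
                   n_artifacts: int = 12, artifact_gain_ref: float = 0.8,
                   ) -> tuple[PhotometrySession, GroundTruth]:
    """Two-channel photometry with event-locked transients and shared artifacts.

    The 465-nm signal is an exponential photobleaching baseline plus a
    motion artifact shared with the reference, event-locked calcium
    transients and white noise; the 405-nm reference has its own
    bleaching baseline and the same artifact at gain
    ``artifact_gain_ref`` but no transients.

    ``transient_amplitude`` is expressed in z units of the processed
    trace: the generator runs the transient-free composition through
    the same low-pass / bleach-fit / reference-subtraction chain the
    pipeline applies, measures the resulting noise floor, and scales
    the raw transients (compensating the kernel's own low-pass
    attenuation) so that the full chain recovers the requested z
    amplitude.  ``artifact_amplitude`` defaults to 60x the post-filter
    noise sd (~10 % of the baseline fluorescence) — motion artifacts
    in freely moving animals dwarf the shot-noise floor — which also
    makes the artifact component dominate the reference variance the
    way the polynomial-fit subtraction assumes.  Artifacts are placed midway between event
    onsets so transient recovery and artifact suppression can be
    scored independently.
    """
    config = config or SessionConfig()
    rng = _rng(seed)
    rate = config.sample_rate_target
    if duration < 2 * config.zscore_window:
        raise ParameterError(
            f"duration {duration} s must be >= twice the z-score window "
            f"({config.zscore_window} s)")
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    noise_sig = rng.normal(0.0, noise_sd, n)
    noise_ref = rng.normal(0.0, noise_sd, n)
    filt_noise_sd = float(np.std(lowpass(noise_sig, rate, config.lowpass_cutoff)))
    kernel = _transient_kernel(rate)
    kernel_peak_filtered = float(
        np.max(lowpass(np.concatenate([np.zeros(int(rate * 5)), kernel,
                                       np.zeros(int(rate * 5))]),
                       rate, config.lowpass_cutoff)))

    # event schedule: onsets spread over the usable interior, jittered
    margin = config.zscore_window / 2 + 10.0
    onsets = np.array([])
    if n_events > 0:
        slots = np.linspace(margin, duration - margin, n_events)
        jitter = rng.uniform(-2.0, 2.0, n_events)
        onsets = np.sort(slots + jitter)

    # shared motion artifact: brief gaussian bumps midway between events
    if artifact_amplitude is None:
        artifact_amplitude = 60.0 * filt_noise_sd
    artifact = np.zeros(n)
    artifact_times: list[float] = []
    if n_artifacts > 0 and artifact_amplitude > 0:
        if len(onsets) >= 2:
            mids = (onsets[:-1] + onsets[1:]) / 2.0
        else:
            mids = np.linspace(margin, duration - margin, n_artifacts + 2)[1:-1]
        take = min(n_artifacts, len(mids))
        pick = np.sort(rng.choice(len(mids), size=take, replace=False))
        artifact_times = [float(c) for c in mids[pick]]
        width = 0.15  # s, gaussian sigma
        for c in artifact_times:
            lo = max(0, int((c - 1.0) * rate))
            hi = min(n, int((c + 1.0) * rate))
            artifact[lo:hi] += artifact_amplitude * np.exp(
                -0.5 * ((t[lo:hi] - c) / width) ** 2)

    bleach_sig = baseline_level * np.exp(-t / bleach_tau)
    bleach_ref = 0.7 * baseline_level * np.exp(-t / (bleach_tau * 1.2))
    reference = bleach_ref + artifact_gain_ref * artifact + noise_ref

    # measure the processed-noise floor on the transient-free composition
    sig_floor = bleach_correct(
        lowpass(bleach_sig + artifact + noise_sig, rate, config.lowpass_cutoff), t)
    ref_floor = bleach_correct(
        lowpass(reference, rate, config.lowpass_cutoff), t)
    floor_sd = float(np.std(motion_correct(sig_floor, ref_floor,
                                           config.motion_fit_degree)))
    raw_amp = transient_amplitude * floor_sd / kernel_peak_filtered

    transients = np.zeros(n)
    for onset in onsets:
        i0 = int(round(onset * rate))
        seg = min(len(kernel), n - i0)
        if seg > 0:
            transients[i0:i0 + seg] += raw_amp * kernel[:seg]

    signal = bleach_sig + artifact + transients + noise_sig

    session = PhotometrySession(time=t, signal=signal, reference=reference,
                                native_rate=rate)
    schedule = EventTable(pd.DataFrame({
        "behavior": ["event"] * len(onsets),
        "start": onsets,
        "stop": onsets + 1.0,
    }))
    truth = GroundTruth(
        event_schedule=schedule,
        transient_amplitude=transient_amplitude,
        bleach_tau=bleach_tau,
        artifact_times=artifact_times,
        params={
            "duration": duration, "n_events": n_events,
            "noise_sd": noise_sd, "raw_transient_amplitude": raw_amp,
            "artifact_amplitude": artifact_amplitude,
            "artifact_gain_ref": artifact_gain_ref,
            "filtered_noise_sd": filt_noise_sd,
            "processed_floor_sd": floor_sd, "seed": seed,
        })
    return session, truth


# ---------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------

@dataclass
class BoutSpec:
    """One scripted behavioral segment of a synthetic trajectory."""

    label: str          # immobility | locomotion | thigmotaxis | pause | surveying
    duration: float     # s
    speed: float = 0.0  # cm/s target


def default_bout_script(n_cycles: int = 13) -> list[BoutSpec]:
    """Alternating immobility, wall-following and center runs.

    Each 70-s cycle separates the two moving states by immobility so
    scripted bouts map one-to-one onto detectable bouts; 13 cycles
    cover a full 15-min Pre/ON/OFF session.
    """
    script = []
    for _ in range(n_cycles):
        script += [
            BoutSpec("immobility", 20.0, 0.0),
            BoutSpec("thigmotaxis", 20.0, 12.0),
            BoutSpec("immobility", 10.0, 0.0),
            BoutSpec("locomotion", 20.0, 10.0),
        ]
    return script


def gen_tracking(config: SessionConfig | None = None, seed: int = 0,
                 script: list[BoutSpec] | None = None,
                 frame_rate: float = 30.0,
                 position_noise: float = 0.0,
                 ) -> tuple["Trajectory", GroundTruth]:
    """Arena trajectory realizing a scripted bout sequence.

    Immobility/pause segments hold position (motion < 1 %, speed ~ 0);
    ``thigmotaxis`` segments follow the walls at the target speed
    inside the peripheral band; ``locomotion`` segments sweep through
    the center.  The per-frame motion column is consistent with speed
    (high when moving).  The scripted ethogram is returned as ground
    truth.
    """
    from fiberbehav.behavior import Trajectory

    config = config or SessionConfig()
    rng = _rng(seed)
    script = script or default_bout_script()
    w, h = config.arena_size
    max_speed = 0.45 * min(w, h) * frame_rate  # cannot cross the arena per frame
    for b in script:
        if b.speed > max_speed:
            raise ParameterError(
                f"scripted speed {b.speed} cm/s incompatible with arena "
                f"{w}x{h} cm at {frame_rate} fps")

    dt = 1.0 / frame_rate
    margin = 0.04 * min(w, h)  # wall-following offset inside the periphery
    cx, cy = w / 2, h / 2
    orbit_r = 0.25 * min(w, h)  # center-run orbit, well inside the center zone
    xs, ys, motions = [], [], []
    x, y = cx + orbit_r, cy
    rows = []
    t_cursor = 0.0
    for bout in script:
        n_frames = int(round(bout.duration * frame_rate))
        rows.append({"behavior": bout.label, "start": t_cursor,
                     "stop": t_cursor + n_frames * dt})
        for _ in range(n_frames):
            step = bout.speed * dt
            if bout.label in ("immobility", "pause"):
                motion = 0.2
            elif bout.label == "surveying":
                motion = 3.0
            else:
                motion = 8.0
            if bout.label == "thigmotaxis":
                # walk the wall rectangle at the margin offset
                x, y = _advance_on_walls(x, y, step, w, h, margin)
            elif step > 0:
                # approach the central orbit radially, then circle it, so
                # speed stays exactly at the scripted value
                dx, dy = x - cx, y - cy
                r = float(np.hypot(dx, dy))
                if r < 1e-9:
                    dx, r = 1e-9, 1e-9
                if abs(r - orbit_r) > step:
                    scale = (r - np.sign(r - orbit_r) * step) / r
                    x, y = cx + dx * scale, cy + dy * scale
                else:
                    phi = np.arctan2(dy, dx) + step / orbit_r
                    x = cx + orbit_r * np.cos(phi)
                    y = cy + orbit_r * np.sin(phi)
            px = x + (rng.normal(0, position_noise) if position_noise else 0.0)
            py = y + (rng.normal(0, position_noise) if position_noise else 0.0)
            xs.append(float(np.clip(px, 0, w)))
            ys.append(float(np.clip(py, 0, h)))
            motions.append(motion)
        t_cursor += n_frames * dt

    n = len(xs)
    traj = Trajectory(
        frame=np.arange(n), time=np.arange(n) * dt,
        x=np.array(xs), y=np.array(ys), motion=np.array(motions),
        frame_rate=frame_rate, arena=(w, h))
    truth = GroundTruth(
        ethogram=EventTable(pd.DataFrame(rows)),
        params={"frame_rate": frame_rate, "position_noise": position_noise,
                "seed": seed})
    return traj, truth


def _advance_on_walls(x: float, y: float, step: float, w: float, h: float,
                      margin: float) -> tuple[float, float]:
    """Move ``step`` cm counterclockwise along the wall rectangle."""
    lo_x, hi_x = margin, w - margin
    lo_y, hi_y = margin, h - margin
    x = float(np.clip(x, lo_x, hi_x))
    y = float(np.clip(y, lo_y, hi_y))
    while step > 0:
        if y <= lo_y and x < hi_x:        # bottom edge, heading right
            d = min(step, hi_x - x); x += d
        elif x >= hi_x and y < hi_y:      # right edge, heading up
            d = min(step, hi_y - y); y += d
        elif y >= hi_y and x > lo_x:      # top edge, heading left
            d = min(step, x - lo_x); x -= d
        elif x <= lo_x and y > lo_y:      # left edge, heading down
            d = min(step, y - lo_y); y -= d
        else:                             # off-rectangle start: snap to bottom
            y = lo_y
            continue
        step -= d
    return x, y


# ---------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------

def gen_spiketrains(n_units: int, config: SessionConfig | None = None,
                    seed: int = 0, responder_fraction: float = 0.0,
                    n_responders: int | None = None,
                    inhibition_depth: float = 1.0,
                    inhibition_latency: float = 0.02,
                    rate_range: tuple[float, float] = (2.2, 31.8),
                    responder_min_rate: float | None = None,
                    baseline_duration: float = 60.0, iti: float = 5.0,
                    ) -> tuple[StimExperiment, GroundTruth]:
    """Tonic units with optogenetically silenced responders.

    Each unit fires as a homogeneous Poisson process at a baseline
    rate drawn uniformly from ``rate_range`` (the tonic-firing range
    observed in the recorded population).  The protocol is a 1-min
    baseline, 6 single 10-ms pulses at 5-s intervals, then 6 bursts
    (5 pulses, 10 Hz).  Responder units multiply their rate by
    (1 - inhibition_depth) from ``inhibition_latency`` after each
    pulse/burst onset until 100 ms past its offset; non-responders are
    unmodulated.  Spikes are drawn by thinning a homogeneous train at
    the baseline rate, so identical seeds give identical trains.
    """
    if n_units < 1:
        raise ParameterError(f"n_units must be >= 1, got {n_units}")
    if not 0.0 <= inhibition_depth <= 1.0:
        raise ParameterError(
            f"inhibition_depth must be in [0, 1], got {inhibition_depth}")
    config = config or SessionConfig()
    rng = _rng(seed)
    bp = BurstParams()

    single_pulses = baseline_duration + iti * (1 + np.arange(6))
    bursts = single_pulses[-1] + iti * (1 + np.arange(6))
    total = float(bursts[-1] + iti)
    pulse_width = 0.010

    if n_responders is None:
        n_responders = int(round(responder_fraction * n_units))
    if n_responders > n_units:
        raise ParameterError("more responders requested than units")
    responder_idx = set(rng.choice(n_units, size=n_responders, replace=False)
                        .tolist())

    # inhibition windows shared by all responders
    windows = []
    for t0 in single_pulses:
        windows.append((t0 + inhibition_latency, t0 + pulse_width + 0.1))
    for t0 in bursts:
        windows.append((t0 + inhibition_latency, t0 + bp.duration + 0.1))

    units: dict[str, np.ndarray] = {}
    flags: dict[str, bool] = {}
    rates: dict[str, float] = {}
    for i in range(n_units):
        uid = f"unit{i:04d}"
        is_resp = i in responder_idx
        lo, hi = rate_range
        if is_resp and responder_min_rate is not None:
            lo = max(lo, responder_min_rate)
        lam = rng.uniform(lo, hi)
        n_exp = rng.poisson(lam * total)
        spikes = np.sort(rng.uniform(0.0, total, n_exp))
        if is_resp and inhibition_depth > 0:
            in_win = np.zeros(len(spikes), dtype=bool)
            for w0, w1 in windows:
                in_win |= (spikes >= w0) & (spikes < w1)
            keep = ~in_win | (rng.uniform(size=len(spikes))
                              < (1.0 - inhibition_depth))
            spikes = spikes[keep]
        units[uid] = spikes
        flags[uid] = is_resp
        rates[uid] = float(lam)

    exp = StimExperiment(units=units, baseline_window=(0.0, baseline_duration),
                         single_pulses=single_pulses, bursts=bursts,
                         burst_params=bp)
    truth = GroundTruth(
        responder_flags=flags, baseline_rates=rates,
        inhibition_latency=inhibition_latency,
        inhibition_depth=inhibition_depth,
        params={"n_units": n_units, "seed": seed,
                "rate_range": list(rate_range)})
    return exp, truth


# ---------------------------------------------------------------------
# puncta
# ---------------------------------------------------------------------

def gen_puncta(n_cells: int, p_syp: float, p_vglut2_given_syp: float,
               seed: int = 0, p_vglut2_given_not_syp: float = 0.5,
               threshold: int = 4, mean_extra: float = 4.0,
               ) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell puncta-count table with known positive fractions.

    Positive cells draw ``threshold`` + Poisson(``mean_extra``) puncta
    (always >= threshold); negative cells draw uniformly from
    0..threshold-1.  SYP positivity is Bernoulli(``p_syp``); vGLUT2
    positivity is Bernoulli(``p_vglut2_given_syp``) for SYP+ cells and
    Bernoulli(``p_vglut2_given_not_syp``) otherwise.
    """
    if n_cells < 1:
        raise ParameterError(f"n_cells must be >= 1, got {n_cells}")
    for name, p in (("p_syp", p_syp),
                    ("p_vglut2_given_syp", p_vglut2_given_syp),
                    ("p_vglut2_given_not_syp", p_vglut2_given_not_syp)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {p}")
    rng = _rng(seed)
    is_syp = rng.uniform(size=n_cells) < p_syp
    p_vg = np.where(is_syp, p_vglut2_given_syp, p_vglut2_given_not_syp)
    is_vg = rng.uniform(size=n_cells) < p_vg

    def counts(flags: np.ndarray) -> np.ndarray:
        pos = threshold + rng.poisson(mean_extra, n_cells)
        neg = rng.integers(0, threshold, n_cells)
        return np.where(flags, pos, neg)

    df = pd.DataFrame({
        "cell_id": [f"cell{i:04d}" for i in range(n_cells)],
        "syp_count": counts(is_syp),
        "vglut2_count": counts(is_vg),
    })
    labels = pd.DataFrame({"cell_id": df["cell_id"],
                           "is_syp_pos": is_syp, "is_vglut2_pos": is_vg})
    truth = GroundTruth(
        puncta_labels=labels,
        params={"n_cells": n_cells, "p_syp": p_syp,
                "p_vglut2_given_syp": p_vglut2_given_syp,
                "p_vglut2_given_not_syp": p_vglut2_given_not_syp,
                "threshold": threshold, "seed": seed})
    return df, truth
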