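"""Two-channel fiber-photometry processing chain.

Raw recordings carry a calcium-dependent signal (465 nm excitation)
and an isosbestic reference (405 nm) that sees the same motion and
hemodynamic artifacts but no calcium transients.  The chain transforms
a raw session into a normalized activity trace:

    decimate -> resample to 100 Hz -> artifact interpolation ->
    2 Hz low-pass -> exponential photobleaching correction ->
    reference-channel motion correction -> rolling z-score (f-f0)/f1

where f0 and f1 are the mean and standard deviation of the corrected
signal within a 60-s moving window.  Event-triggered statistics
(baseline over -5..-3 s before behavior initiation, corrected
max/min over 0..3 s after) quantify transients around behavioral
events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from fiberbehav.config import SessionConfig
from fiberbehav.errors import DataError, FitError, ParameterError

__all__ = [
    "PhotometrySession",
    "ProcessedTrace",
    "EventTriggeredResult",
    "decimate_raw",
    "resample_uniform",
    "interpolate_artifacts",
    "lowpass",
    "bleach_correct",
    "motion_correct",
    "rolling_zscore",
    "epoch_auc",
    "event_triggered",
    "process_session",
]


@dataclass
class PhotometrySession:
    """Raw (or partially processed) two-channel recording.

    ``signal`` is the 465-nm calcium-dependent channel, ``reference``
    the 405-nm isosbestic channel, both in acquisition units on the
    common ``time`` base (seconds).
    """

    time: np.ndarray
    signal: np.ndarray
    reference: np.ndarray
    native_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        n = len(self.time)
        if len(self.signal) != n or len(self.reference) != n:
            raise DataError("time, signal and reference must have equal length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise DataError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ProcessedTrace:
    """Uniformly sampled z-scored activity trace with step provenance."""

    time: np.ndarray
    z: np.ndarray
    rate: float
    f0: np.ndarray | None = None  # moving-window mean of the corrected signal
    f1: np.ndarray | None = None  # moving-window standard deviation
    steps_applied: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class EventTriggeredResult:
    """Peri-event average around behavior-initiation onsets."""

    lags: np.ndarray          # s, relative to alignment point
    mean_trace: np.ndarray    # z, averaged over events
    per_event_traces: np.ndarray  # (n_events, n_lags)
    baseline: float           # mean z over the pre-onset baseline window
    corrected_extremum: float  # extremum over post window minus baseline
    polarity: str             # "max" or "min"
    n_events_used: int
    n_events_dropped: int


# ---------------------------------------------------------------------
# chain steps
# ---------------------------------------------------------------------

def decimate_raw(session: PhotometrySession, factor: int = 100) -> PhotometrySession:
    """Decimate both channels by ``factor`` with anti-alias filtering.

    Mirrors the acquisition-side decimation applied to the demodulated
    signal and reference streams.  ``factor=1`` is the identity.
    """
    if factor < 1:
        raise ParameterError(f"decimation factor must be >= 1, got {factor}")
    if factor >= len(session):
        raise ParameterError(
            f"decimation factor {factor} >= trace length {len(session)}")
    if factor == 1:
        return session
    # polyphase FIR with linear edge padding: DC and ramps pass unchanged
    sig = signal.resample_poly(session.signal, 1, factor, padtype="line")
    ref = signal.resample_poly(session.reference, 1, factor, padtype="line")
    t = session.time[::factor][: len(sig)]
    rate = None
    if session.native_rate is not None:
        rate = session.native_rate / factor
    return PhotometrySession(t, sig, ref, native_rate=rate)


def resample_uniform(session: PhotometrySession, rate: float = 100.0) -> PhotometrySession:
    """Linear-interpolation resampling onto a uniform grid at ``rate`` Hz.

    The grid spans the original time range; jittered acquisition
    timestamps become an exactly regular 1/rate spacing.
    """
    if rate <= 0:
        raise ParameterError(f"target rate must be > 0, got {rate}")
    if len(session) < 2:
        raise ParameterError("resampling needs at least 2 samples")
    t0, t1 = session.time[0], session.time[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    sig = np.interp(grid, session.time, session.signal)
    ref = np.interp(grid, session.time, session.reference)
    return PhotometrySession(grid, sig, ref, native_rate=rate)


def interpolate_artifacts(values: np.ndarray, time: np.ndarray,
                          regions: list[tuple[float, float]]) -> np.ndarray:
    """Replace samples inside each [start, stop) region by a straight line.

    The line joins the last sample before the region to the first
    sample at/after its stop; samples outside all regions are untouched.
    """
    values = np.asarray(values, dtype=float).copy()
    time = np.asarray(time, dtype=float)
    for start, stop in regions:
        if start >= stop:
            raise ParameterError(f"artifact region [{start}, {stop}) is empty")
        if start < time[0] or stop > time[-1]:
            raise ParameterError(
                f"artifact region [{start}, {stop}) outside trace span "
                f"[{time[0]}, {time[-1]}]")
        inside = (time >= start) & (time < stop)
        if not inside.any():
            continue
        i0, i1 = np.flatnonzero(inside)[[0, -1]]
        left = max(i0 - 1, 0)
        right = min(i1 + 1, len(time) - 1)
        values[inside] = np.interp(time[inside], [time[left], time[right]],
                                   [values[left], values[right]])
    return values


def lowpass(values: np.ndarray, rate: float, cutoff: float = 2.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at ``cutoff`` Hz."""
    if cutoff >= rate / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz >= Nyquist {rate / 2} Hz")
    sos = signal.butter(4, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(values, dtype=float))


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def bleach_correct(values: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Subtract a fitted exponential decay a*exp(-t/tau)+c (photobleaching).

    A constant trace is the degenerate a -> 0 case and maps to ~0.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    t = time - time[0]
    span = values.max() - values.min()
    if span == 0:
        return values - values[0]
    a0 = values[0] - values[-1]
    if a0 == 0:
        a0 = span
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _exp_model, t, values, p0=[a0, tau0, values[-1]],
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError("exponential photobleaching fit failed",
                       details={"reason": str(exc), "n": len(values)}) from exc
    return values - _exp_model(t, *popt)


def motion_correct(signal_values: np.ndarray, reference_values: np.ndarray,
                   degree: int = 1) -> np.ndarray:
    """Subtract the reference channel after polynomial regression onto the signal.

    The isosbestic reference is fit to the signal with a least-squares
    polynomial (default linear) and the fitted reference is subtracted,
    removing artifact components shared by both channels.
    """
    sig = np.asarray(signal_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if len(sig) != len(ref):
        raise ParameterError("signal and reference must share one grid")
    if np.ptp(ref) == 0:
        raise DataError("reference channel flat")
    coeffs = np.polyfit(ref, sig, degree)
    fitted = np.polyval(coeffs, ref)
    return sig - fitted


def rolling_zscore(values: np.ndarray, rate: float,
                   window: float = 60.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize as (f - f0) / f1 over a centered moving window.

    f0 and f1 are the mean and standard deviation of the trace within a
    ``window``-second window centered on each sample; windows truncate
    at the trace edges.  Returns (z, f0, f1).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n / rate < window:
        raise ParameterError(
            f"trace duration {n / rate:.1f} s shorter than window {window} s")
    half = int(round(window * rate / 2))
    w = 2 * half + 1
    s = pd.Series(values)
    f0 = s.rolling(w, center=True, min_periods=2).mean().to_numpy()
    f1 = s.rolling(w, center=True, min_periods=2).std(ddof=1).to_numpy()
    if np.any(f1 == 0) or np.any(~np.isfinite(f1)):
        raise DataError("zero-variance window in rolling z-score")
    return (values - f0) / f1, f0, f1


def epoch_auc(trace: ProcessedTrace, start: float, stop: float) -> float:
    """Mean z over [start, stop): the per-epoch "area under the curve".

    The quantity is a normalized average (mean z-score between the
    epoch start and stop), not a time integral.
    """
    if stop <= start:
        raise ParameterError(f"empty epoch [{start}, {stop})")
    inside = (trace.time >= start) & (trace.time < stop)
    if not inside.any():
        raise ParameterError(f"epoch [{start}, {stop}) contains no samples")
    return float(np.mean(trace.z[inside]))


def event_triggered(trace: ProcessedTrace, onsets, pre: float = 5.0,
                    post: float = 5.0, polarity: str = "max",
                    baseline_window: tuple[float, float] = (-5.0, -3.0),
                    extremum_window: tuple[float, float] = (0.0, 3.0),
                    ) -> EventTriggeredResult:
    """Average the z trace around behavior-initiation onsets.

    Snippets spanning [-pre, +post] s are aligned at lag 0 and averaged.
    The baseline is the mean of the average trace over
    ``baseline_window`` (default -5..-3 s before initiation); the
    corrected extremum is the max (activation analyses) or min
    (suppression analyses) of the average trace over
    ``extremum_window`` (default 0..3 s) minus that baseline.
    Onsets too close to the trace edge are dropped with a warning.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    if onsets.size == 0:
        raise ParameterError("no event onsets supplied")
    if polarity not in ("max", "min"):
        raise ParameterError(f"polarity must be 'max' or 'min', got {polarity!r}")
    dt = 1.0 / trace.rate
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    lags = np.arange(-n_pre, n_post + 1) * dt

    snippets, dropped = [], 0
    for onset in onsets:
        idx = int(round((onset - trace.time[0]) / dt))
        if idx - n_pre < 0 or idx + n_post >= len(trace):
            dropped += 1
            continue
        snippets.append(trace.z[idx - n_pre: idx + n_post + 1])
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) too close to trace edge",
                      stacklevel=2)
    if not snippets:
        raise ParameterError("all events fell outside the trace")
    per_event = np.vstack(snippets)
    mean_trace = per_event.mean(axis=0)

    b0, b1 = baseline_window
    in_base = (lags >= b0) & (lags <= b1)
    baseline = float(mean_trace[in_base].mean())
    e0, e1 = extremum_window
    in_ext = (lags >= e0) & (lags <= e1)
    extremum = float(mean_trace[in_ext].max() if polarity == "max"
                     else mean_trace[in_ext].min())
    return EventTriggeredResult(
        lags=lags, mean_trace=mean_trace, per_event_traces=per_event,
        baseline=baseline, corrected_extremum=extremum - baseline,
        polarity=polarity, n_events_used=len(snippets),
        n_events_dropped=dropped)


# ---------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------

def process_session(session: PhotometrySession,
                    config: SessionConfig | None = None,
                    artifact_regions: list[tuple[float, float]] | None = None,
                    decimate_factor: int = 1,
                    skip_motion_correct: bool = False) -> ProcessedTrace:
    """Run the full processing chain on a raw two-channel session.

    Order is fixed: decimate, resample to the target rate, artifact
    interpolation, low-pass, photobleaching correction (each channel),
    reference-channel motion correction, rolling z-score.  Each step is
    recorded in ``steps_applied`` with its parameters.
    """
    config = config or SessionConfig()
    steps: list = []

    if decimate_factor > 1:
        session = decimate_raw(session, decimate_factor)
        steps.append(("decimate", {"factor": decimate_factor}))

    rate = config.sample_rate_target
    session = resample_uniform(session, rate)
    steps.append(("resample", {"rate": rate}))
    time = session.time
    sig, ref = session.signal, session.reference

    if artifact_regions:
        sig = interpolate_artifacts(sig, time, artifact_regions)
        ref = interpolate_artifacts(ref, time, artifact_regions)
        steps.append(("interpolate_artifacts", {"regions": list(artifact_regions)}))

    sig = lowpass(sig, rate, config.lowpass_cutoff)
    ref = lowpass(ref, rate, config.lowpass_cutoff)
    steps.append(("lowpass", {"cutoff": config.lowpass_cutoff}))

    sig = bleach_correct(sig, time)
    ref = bleach_correct(ref, time)
    steps.append(("bleach_correct", {"model": "a*exp(-t/tau)+c"}))

    if not skip_motion_correct:
        sig = motion_correct(sig, ref, degree=config.motion_fit_degree)
        steps.append(("motion_correct", {"degree": config.motion_fit_degree}))

    z, f0, f1 = rolling_zscore(sig, rate, config.zscore_window)
    steps.append(("rolling_zscore", {"window": config.zscore_window}))

    return ProcessedTrace(time=time, z=z, rate=rate, f0=f0, f1=f1,
                          steps_applied=steps)
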