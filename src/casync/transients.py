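"""Single Ca²⁺-transient detection and per-event measurements.

Events are supra-threshold peaks on the four-frame-smoothed ΔF/F trace.
Amplitude is the peak value minus the minimum over the preceding inter-event
interval (measured on the smoothed, pre-baseline-adjustment trace).  Two
exclusion rules strip events whose measurements would be contaminated by
preceding activity: a 2 s refractory rule and an elevated-baseline rule
(amplitude below half the peak's absolute ΔF/F).  Event boundaries, duration,
trapezoidal AUC and half-decay time are measured on the baseline-adjusted
trace; boundaries are the 0.5 %ΔF/F crossings around the peak, with an early
termination when the decay is interrupted by a >1 %ΔF/F rise signalling the
next event.  Excluded peaks stay in the event list — they still count for
frequency and inter-event intervals — but carry no amplitude, duration or AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import peak_prominences

from .preprocessing import TraceMatrix, adjust_baseline, smooth_traces


@dataclass(frozen=True)
class DetectionParams:
    """Detection and network thresholds; defaults are the analysis constants.

    ΔF/F thresholds are in percent.  ``peak_criterion`` selects whether the
    0.5 % floor gates the peak's absolute height (default) or its prominence;
    ``fwhm_reference`` selects the level defining active intervals
    (half-prominence, the standard width convention, or half of the absolute
    peak height).  ``count_flagged_in_frequency`` keeps excluded peaks in the
    frequency statistic (they remain detected events, merely unmeasurable).
    """

    smooth_window_frames: int = 4
    peak_min_height_pct: float = 0.5
    refractory_s: float = 2.0
    elevated_baseline_ratio: float = 0.5
    bound_threshold_pct: float = 0.5
    interruption_rise_pct: float = 1.0
    baseline_window_s: float = 15.0
    baseline_percentile: float = 1.0
    fwhm_min_prominence_pct: float = 0.5
    network_fraction_threshold: float = 0.20
    network_min_duration_s: float = 2.5
    peak_criterion: str = "height"  # or "prominence"
    fwhm_reference: str = "half_prominence"  # or "half_height"
    count_flagged_in_frequency: bool = True

    def __post_init__(self):
        for f in ("peak_min_height_pct", "refractory_s", "bound_threshold_pct",
                  "interruption_rise_pct", "baseline_window_s",
                  "fwhm_min_prominence_pct", "network_min_duration_s"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0 < self.elevated_baseline_ratio <= 1:
            raise ValueError("elevated_baseline_ratio must lie in (0, 1]")
        if not 0 < self.network_fraction_threshold < 1:
            raise ValueError("network_fraction_threshold must lie in (0, 1)")
        if self.smooth_window_frames < 1:
            raise ValueError("smooth_window_frames must be >= 1")
        if self.peak_criterion not in ("height", "prominence"):
            raise ValueError("peak_criterion must be 'height' or 'prominence'")
        if self.fwhm_reference not in ("half_prominence", "half_height"):
            raise ValueError("fwhm_reference must be 'half_prominence' or 'half_height'")


def get_default_params() -> DetectionParams:
    """The default analysis constants."""
    return DetectionParams()


@dataclass
class Transient:
    """One detected Ca²⁺ event.  Undefined measurements are ``None``.

    Frames are 0-based; ``start_frame``/``end_frame`` are half-open on the
    baseline-adjusted trace.  Excluded events (refractory, elevated baseline,
    or without clear boundaries) carry no amplitude/duration/AUC.
    """

    neuron_id: int
    peak_frame: int
    peak_dff_pct: float
    amplitude_pct: float | None = None
    start_frame: int | None = None
    end_frame: int | None = None
    duration_s: float | None = None
    auc_pct_s: float | None = None
    iei_prev_s: float | None = None
    half_decay_s: float | None = None
    refractory_excluded: bool = False
    elevated_baseline_excluded: bool = False
    no_clear_bounds: bool = False

    @property
    def excluded(self) -> bool:
        return self.refractory_excluded or self.elevated_baseline_excluded

    @property
    def measured(self) -> bool:
        """True for events that enter amplitude/duration/AUC analysis."""
        return not self.excluded and not self.no_clear_bounds


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; a flat plateau reports its first frame.

    A frame belongs to a maximum iff the last preceding change was a rise and
    the next following change is a fall, so edge frames never qualify.
    """
    x = np.asarray(x, dtype=float)
    d = np.diff(x)
    idx = np.flatnonzero(d != 0)
    if len(idx) < 2:
        return np.empty(0, dtype=int)
    s = np.sign(d[idx])
    hits = np.flatnonzero((s[:-1] > 0) & (s[1:] < 0))
    return idx[hits] + 1


def detect_peaks(smoothed: TraceMatrix, params: DetectionParams) -> list[np.ndarray]:
    """Per-neuron supra-threshold peak frames (ascending) on the smoothed trace."""
    if smoothed.stage != "smoothed":
        raise ValueError(f"expected stage 'smoothed', got {smoothed.stage!r}")
    out = []
    for row in smoothed.values:
        peaks = local_maxima(row)
        if len(peaks):
            if params.peak_criterion == "height":
                peaks = peaks[row[peaks] > params.peak_min_height_pct]
            else:
                prom = peak_prominences(row, peaks)[0]
                peaks = peaks[prom > params.peak_min_height_pct]
        out.append(peaks)
    return out


def measure_amplitude(trace_row: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Peak value minus the minimum over the preceding inter-event interval.

    The interval for peak k runs from just after peak k-1 up to (excluding)
    peak k; the first peak's interval starts at frame 0.
    """
    trace_row = np.asarray(trace_row, dtype=float)
    amps = np.empty(len(peaks))
    for k, p in enumerate(peaks):
        lo = 0 if k == 0 else int(peaks[k - 1]) + 1
        seg = trace_row[lo:p]
        amps[k] = trace_row[p] - seg.min() if seg.size else 0.0
    return amps


def flag_exclusions(
    peaks: np.ndarray,
    amplitudes: np.ndarray,
    trace_row: np.ndarray,
    params: DetectionParams,
    fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(refractory, elevated_baseline) flags per peak.

    Refractory: the peak follows the previous one by less than ``refractory_s``.
    Elevated baseline: amplitude below ``elevated_baseline_ratio`` times the
    peak's absolute ΔF/F value.
    """
    refractory = np.zeros(len(peaks), dtype=bool)
    if len(peaks) > 1:
        refractory[1:] = np.diff(peaks) / fs < params.refractory_s
    elevated = amplitudes < params.elevated_baseline_ratio * np.asarray(trace_row)[peaks]
    return refractory, elevated


def delineate_event(
    adj_row: np.ndarray,
    peak_frame: int,
    params: DetectionParams,
    fs: float | None = None,
) -> tuple[int, int] | None:
    """Event boundaries on the baseline-adjusted trace, or None if unclear.

    Start: the last upward crossing of the boundary threshold before the peak
    (the first frame at/above threshold).  End: scanning forward while
    tracking the running minimum since the peak, the first frame at/below
    threshold — or, if the trace first rises more than the interruption
    threshold above the running minimum (the next event beginning), the
    running-minimum frame.  Intervals are half-open ``[start, end)``.
    """
    x = np.asarray(adj_row, dtype=float)
    thr = params.bound_threshold_pct
    start = None
    for s in range(peak_frame, 0, -1):
        if x[s] >= thr and x[s - 1] < thr:
            start = s
            break
        if x[s] < thr:  # fell below threshold without an upward crossing ahead
            break
    if start is None:
        return None
    run_min = x[peak_frame]
    run_min_frame = peak_frame
    for t in range(peak_frame + 1, len(x)):
        if x[t] <= thr:
            return start, t
        if x[t] < run_min:
            run_min, run_min_frame = x[t], t
        elif x[t] - run_min > params.interruption_rise_pct:
            return start, max(run_min_frame, peak_frame + 1)
    return None


def compute_auc(
    adj_row: np.ndarray, start_frame: int, end_frame: int, fs: float
) -> float:
    """Trapezoidal area under the adjusted trace over [start, end), percent·s."""
    x = np.asarray(adj_row, dtype=float)
    if not 0 <= start_frame < end_frame <= len(x):
        raise ValueError("event bounds outside trace")
    return float(np.trapezoid(x[start_frame:end_frame], dx=1.0 / fs))


def compute_iei(peaks: np.ndarray, fs: float) -> np.ndarray:
    """Inter-event intervals: time between consecutive peaks, seconds."""
    return np.diff(np.asarray(peaks)) / fs


def half_decay_time(
    adj_row: np.ndarray,
    peak_frame: int,
    amplitude: float,
    fs: float,
    end_frame: int | None = None,
) -> float | None:
    """Time from the peak to the half-amplitude crossing of the decay.

    The crossing level is the peak's adjusted value minus half the measured
    amplitude; the crossing time is linearly interpolated between the
    bracketing frames.  ``None`` if the level is not reached before
    ``end_frame`` (or the trace end).
    """
    x = np.asarray(adj_row, dtype=float)
    stop = len(x) if end_frame is None else min(end_frame, len(x))
    level = x[peak_frame] - amplitude / 2.0
    for t in range(peak_frame + 1, stop):
        if x[t] <= level:
            prev = x[t - 1]
            frac = 1.0 if prev == x[t] else (prev - level) / (prev - x[t])
            return ((t - 1) + frac - peak_frame) / fs
    return None


def detect_transients(
    traces: TraceMatrix,
    params: DetectionParams | None = None,
) -> list[Transient]:
    """Full per-neuron transient detection on raw or smoothed traces.

    Raw traces are smoothed first; the baseline-adjusted trace (windowed
    percentile subtraction) is derived internally for boundary, AUC and decay
    measurements.  Returns transients ordered by (neuron row, peak frame).
    """
    if params is None:
        params = get_default_params()
    if traces.stage == "raw":
        smoothed = smooth_traces(traces, params.smooth_window_frames)
    elif traces.stage == "smoothed":
        smoothed = traces
    else:
        raise ValueError("detect_transients expects raw or smoothed traces")
    adjusted = adjust_baseline(
        smoothed, params.baseline_window_s, params.baseline_percentile
    )
    fs = traces.fs_hz
    all_peaks = detect_peaks(smoothed, params)
    out: list[Transient] = []
    for i, peaks in enumerate(all_peaks):
        srow = smoothed.values[i]
        arow = adjusted.values[i]
        amps = measure_amplitude(srow, peaks)
        refractory, elevated = flag_exclusions(peaks, amps, srow, params, fs)
        ieis = compute_iei(peaks, fs)
        for k, p in enumerate(peaks):
            tr = Transient(
                neuron_id=smoothed.neuron_ids[i],
                peak_frame=int(p),
                peak_dff_pct=float(srow[p]),
                iei_prev_s=float(ieis[k - 1]) if k > 0 else None,
                refractory_excluded=bool(refractory[k]),
                elevated_baseline_excluded=bool(elevated[k]),
            )
            if not tr.excluded:
                tr.amplitude_pct = float(amps[k])
                bounds = delineate_event(arow, int(p), params, fs)
                if bounds is None:
                    tr.no_clear_bounds = True
                else:
                    tr.start_frame, tr.end_frame = bounds
                    tr.duration_s = (tr.end_frame - tr.start_frame) / fs
                    tr.auc_pct_s = compute_auc(arow, tr.start_frame, tr.end_frame, fs)
                    tr.half_decay_s = half_decay_time(
                        arow, int(p), float(amps[k]), fs, end_frame=tr.end_frame
                    )
            out.append(tr)
    return out
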