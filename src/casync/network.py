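"""Network-synchrony analysis: active intervals, coactive fraction, network events.

A neuron is "active" over the full-width-at-half-maximum interval around each
peak of its smoothed ΔF/F trace with prominence ≥ 0.5 %ΔF/F.  A network event
is a maximal run of frames during which strictly more than 20 % of the ROIs in
the field of view are simultaneously active; runs shorter than 2.5 s are
discarded.  No standard-deviation-based activity threshold is offered: such a
threshold would scale with each trace's own variance and so would selectively
suppress detection in persistently active (knockout-like) cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .preprocessing import TraceMatrix
from .transients import DetectionParams, get_default_params


@dataclass(frozen=True)
class ActiveInterval:
    """Half-open frame interval [start, end) during which one neuron is active."""

    neuron_id: int
    start_frame: int
    end_frame: int
    peak_frame: int

    def __post_init__(self):
        if self.start_frame >= self.end_frame:
            raise ValueError("active interval must satisfy start < end")


@dataclass
class NetworkEvent:
    """A half-open frame interval of supra-threshold coactivity."""

    start_frame: int
    end_frame: int
    duration_s: float
    peak_coactive_fraction: float
    participation_pct: float | None = None


def _half_height_bounds(row: np.ndarray, peak: int, level: float) -> tuple[float, float]:
    """Interpolated crossing positions of ``level`` left and right of ``peak``."""
    left = float(peak)
    for t in range(peak, 0, -1):
        if row[t - 1] < level <= row[t]:
            left = (t - 1) + (level - row[t - 1]) / (row[t] - row[t - 1])
            break
        left = float(t - 1)
    right = float(peak)
    for t in range(peak, len(row) - 1):
        if row[t + 1] < level <= row[t]:
            right = t + (row[t] - level) / (row[t] - row[t + 1])
            break
        right = float(t + 1)
    return left, right


def _merge(intervals: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Merge overlapping (start, end, peak) triples; keeps the first peak."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e, p in intervals[1:]:
        ls, le, lp = merged[-1]
        if s < le:
            merged[-1] = (ls, max(le, e), lp)
        else:
            merged.append((s, e, p))
    return merged


def active_intervals(
    smoothed: TraceMatrix, params: DetectionParams | None = None
) -> list[ActiveInterval]:
    """FWHM active intervals around prominence-gated peaks, per neuron.

    The reference level is half-prominence by default (``params.fwhm_reference``
    switches to half of the absolute peak height).  Interpolated crossings are
    rounded outward to whole frames — a neuron is active for every frame its
    half-height span touches — and overlapping intervals of one neuron merge.
    """
    if params is None:
        params = get_default_params()
    if smoothed.stage != "smoothed":
        raise ValueError(f"expected stage 'smoothed', got {smoothed.stage!r}")
    out: list[ActiveInterval] = []
    n_frames = smoothed.n_frames
    for i in range(smoothed.n_neurons):
        row = smoothed.values[i]
        peaks, props = find_peaks(row, prominence=params.fwhm_min_prominence_pct)
        triples: list[tuple[int, int, int]] = []
        if len(peaks):
            if params.fwhm_reference == "half_prominence":
                prom_data = (props["prominences"], props["left_bases"],
                             props["right_bases"])
                _, _, left_ips, right_ips = peak_widths(
                    row, peaks, rel_height=0.5, prominence_data=prom_data
                )
            else:
                left_ips, right_ips = [], []
                for p in peaks:
                    l, r = _half_height_bounds(row, int(p), row[p] / 2.0)
                    left_ips.append(l)
                    right_ips.append(r)
            for p, l, r in zip(peaks, left_ips, right_ips):
                start = max(int(np.floor(l)), 0)
                end = min(int(np.floor(r)) + 1, n_frames)
                if start < end:
                    triples.append((start, end, int(p)))
        for s, e, p in _merge(triples):
            out.append(ActiveInterval(smoothed.neuron_ids[i], s, e, p))
    return out


def coactive_fraction(
    intervals: list[ActiveInterval], n_neurons: int, n_frames: int
) -> np.ndarray:
    """Fraction of distinct neurons active at each frame, in [0, 1]."""
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    per_neuron: dict[int, list[tuple[int, int, int]]] = {}
    for iv in intervals:
        if not 0 <= iv.start_frame < iv.end_frame <= n_frames:
            raise ValueError(
                f"interval [{iv.start_frame}, {iv.end_frame}) outside "
                f"[0, {n_frames})"
            )
        per_neuron.setdefault(iv.neuron_id, []).append(
            (iv.start_frame, iv.end_frame, iv.peak_frame)
        )
    delta = np.zeros(n_frames + 1)
    for ivs in per_neuron.values():
        for s, e, _ in _merge(ivs):  # distinct-neuron count: merge first
            delta[s] += 1
            delta[e] -= 1
    return np.cumsum(delta[:-1]) / n_neurons


def detect_network_events(
    fraction: np.ndarray,
    params: DetectionParams | None = None,
    fs: float = 8.91,
) -> list[NetworkEvent]:
    """Maximal runs with coactive fraction strictly above threshold, >= 2.5 s.

    The fraction threshold is strict — frames at exactly the threshold do not
    count — and runs shorter than ``network_min_duration_s`` are dropped.
    """
    if params is None:
        params = get_default_params()
    fraction = np.asarray(fraction, dtype=float)
    above = fraction > params.network_fraction_threshold
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events = []
    for s, e in zip(starts, ends):
        duration = (e - s) / fs
        if duration < params.network_min_duration_s:
            continue
        events.append(
            NetworkEvent(
                start_frame=int(s),
                end_frame=int(e),
                duration_s=float(duration),
                peak_coactive_fraction=float(fraction[s:e].max()),
            )
        )
    return events


def participation(
    intervals: list[ActiveInterval], event: NetworkEvent, n_neurons: int
) -> float:
    """Percent of neurons active at any time during the event."""
    members = {
        iv.neuron_id
        for iv in intervals
        if iv.start_frame < event.end_frame and iv.end_frame > event.start_frame
    }
    return 100.0 * len(members) / n_neurons


def network_time_fraction(
    events: list[NetworkEvent], n_frames: int, fs: float
) -> float:
    """Percent of the recording spent in network events."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return 100.0 * sum(e.duration_s for e in events) / (n_frames / fs)


def analyze_network(
    smoothed: TraceMatrix, params: DetectionParams | None = None
) -> tuple[list[ActiveInterval], np.ndarray, list[NetworkEvent]]:
    """Intervals, coactive-fraction signal, and network events with participation."""
    if params is None:
        params = get_default_params()
    intervals = active_intervals(smoothed, params)
    fraction = coactive_fraction(intervals, smoothed.n_neurons, smoothed.n_frames)
    events = detect_network_events(fraction, params, smoothed.fs_hz)
    for ev in events:
        ev.participation_pct = participation(intervals, ev, smoothed.n_neurons)
    return intervals, fraction, events
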