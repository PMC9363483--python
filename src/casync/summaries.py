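"""Per-neuron and per-FOV descriptive summaries of detected events.

Summaries are purely descriptive — frequencies, means of event metrics,
network participation — so group-level inference can be done downstream in
any statistics environment.  Event frequency is reported in events·min⁻¹.
Excluded (flagged) events count toward frequency and inter-event intervals
but never toward amplitude, duration, AUC or decay means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import NetworkEvent, network_time_fraction
from .transients import Transient


def _mean(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


@dataclass
class NeuronSummary:
    neuron_id: int
    event_frequency_per_min: float
    mean_amplitude_pct: float | None
    mean_duration_s: float | None
    mean_auc_pct_s: float | None
    mean_iei_s: float | None
    mean_half_decay_s: float | None
    n_events_total: int
    n_events_measured: int


@dataclass
class FovSummary:
    fov_id: str
    group: str
    mean_event_frequency_per_min: float | None
    network_event_rate_per_min: float
    network_time_pct: float
    mean_participation_pct: float | None
    n_neurons: int


def summarize_neurons(
    transients: list[Transient],
    recording_duration_s: float,
    neuron_ids: list[int] | None = None,
    count_flagged_in_frequency: bool = True,
) -> list[NeuronSummary]:
    """One summary per neuron; neurons without events get zero frequency.

    ``neuron_ids`` fixes the roster (so silent neurons appear); by default the
    roster is the set of neurons with at least one event.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording_duration_s must be positive")
    by_neuron: dict[int, list[Transient]] = {}
    for tr in transients:
        by_neuron.setdefault(tr.neuron_id, []).append(tr)
    if neuron_ids is None:
        neuron_ids = sorted(by_neuron)
    out = []
    for nid in neuron_ids:
        evs = sorted(by_neuron.get(nid, []), key=lambda t: t.peak_frame)
        if count_flagged_in_frequency:
            n_total = len(evs)
        else:
            n_total = sum(1 for t in evs if not t.excluded)
        measured = [t for t in evs if t.measured]
        out.append(
            NeuronSummary(
                neuron_id=nid,
                event_frequency_per_min=60.0 * n_total / recording_duration_s,
                mean_amplitude_pct=_mean(
                    [t.amplitude_pct for t in evs
                     if not t.excluded and t.amplitude_pct is not None]
                ),
                mean_duration_s=_mean(
                    [t.duration_s for t in measured if t.duration_s is not None]
                ),
                mean_auc_pct_s=_mean(
                    [t.auc_pct_s for t in measured if t.auc_pct_s is not None]
                ),
                mean_iei_s=_mean(
                    [t.iei_prev_s for t in evs if t.iei_prev_s is not None]
                ),
                mean_half_decay_s=_mean(
                    [t.half_decay_s for t in measured if t.half_decay_s is not None]
                ),
                n_events_total=n_total,
                n_events_measured=len(measured),
            )
        )
    return out


def summarize_fov(
    neuron_summaries: list[NeuronSummary],
    network_events: list[NetworkEvent],
    recording_duration_s: float,
    group: str = "",
    fov_id: str = "fov0",
    fs_hz: float = 8.91,
) -> FovSummary:
    """Unweighted across-neuron means plus field-wide network metrics."""
    if recording_duration_s <= 0:
        raise ValueError("recording_duration_s must be positive")
    n_frames = int(round(recording_duration_s * fs_hz))
    parts = [
        e.participation_pct for e in network_events if e.participation_pct is not None
    ]
    return FovSummary(
        fov_id=fov_id,
        group=group,
        mean_event_frequency_per_min=_mean(
            [s.event_frequency_per_min for s in neuron_summaries]
        ),
        network_event_rate_per_min=60.0 * len(network_events) / recording_duration_s,
        network_time_pct=network_time_fraction(network_events, n_frames, fs_hz),
        mean_participation_pct=_mean(parts),
        n_neurons=len(neuron_summaries),
    )
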