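"""Synthetic calcium-activity generator for the three genotype regimes.

Ground-truth activity schedules (per-neuron bursts plus field-wide network
events) are drawn from Poisson processes, rendered into ΔF/F traces through a
difference-of-exponentials indicator kernel, and optionally rendered further
into a toy movie stack so the full movie -> trace -> event pipeline can be
exercised end to end against known truth.

The three presets (WT, Tsc1-KO, Tsc1-KO;Raptor-Het) are calibrated only to the
qualitative regime structure observed in such cultures — knockout neurons fire
more frequent, larger, longer transients and recruit a larger fraction of the
field into synchronized network events, with the double mutant intermediate —
not to any published absolute rates.

Model sketch
------------
* Solo bursts: homogeneous Poisson per neuron at ``burst_rate_per_min``; each
  burst carries ``1 + Poisson(mean - 1)`` spikes packed densely (80 ms apart),
  so a burst renders as a single transient whose amplitude grows with its
  spike count.
* Network events: an independent Poisson process per field of view; each event
  recruits every neuron independently with ``participation_prob``.  Recruited
  neurons receive an extended volley (spikes 0.4 s apart, at least
  ``NETWORK_MIN_SPIKES``) starting within ±0.1 s of the event time, producing
  the multi-second plateaus of coactivity that define detectable network
  events.
* Each spike adds ``a * (exp(-t/tau_d) - exp(-t/tau_r))`` normalized to peak
  ``amplitude_per_spike_pct``; contributions sum linearly.  A slow sinusoidal
  drift (period 60 s, independent phase per neuron) and white Gaussian noise
  are added on top.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .preprocessing import DEFAULT_FS_HZ, MovieStack, Roi, RoiSet, TraceMatrix

SCHEMA_VERSION = 1

#: Spike spacing within an ordinary (solo) burst, seconds.  Sub-frame at
#: 8.91 Hz, so a solo burst renders as one compact transient.
SOLO_SPIKE_INTERVAL_S = 0.08
#: Spike spacing within a network-event volley, seconds.  Short enough that
#: the smoothed trace stays above half maximum between spikes (tau_decay
#: 0.8 s), long enough to stretch the volley over several seconds.
NETWORK_SPIKE_INTERVAL_S = 0.4
#: Minimum spikes per network volley: 8 spikes at 0.4 s span 2.8 s, keeping a
#: recruited neuron's FWHM interval above the 2.5 s network-event floor.
NETWORK_MIN_SPIKES = 8
#: Uniform jitter (± seconds) of each participant's volley onset.
NETWORK_JITTER_S = 0.1
#: Period of the slow sinusoidal baseline drift, seconds.
DRIFT_PERIOD_S = 60.0

DEFAULT_TAU_RISE_S = 0.1
DEFAULT_TAU_DECAY_S = 0.8


@dataclass(frozen=True)
class RegimePreset:
    """Activity regime of one genotype (rates per neuron unless noted)."""

    name: str
    burst_rate_per_min: float
    spikes_per_burst_mean: float
    network_rate_per_min: float  # per field of view
    participation_prob: float
    amplitude_per_spike_pct: float
    noise_sd_pct: float
    drift_amplitude_pct: float

    def __post_init__(self):
        for f in ("burst_rate_per_min", "spikes_per_burst_mean",
                  "network_rate_per_min", "amplitude_per_spike_pct",
                  "noise_sd_pct", "drift_amplitude_pct"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must lie in [0, 1]")
        if self.spikes_per_burst_mean and self.spikes_per_burst_mean < 1:
            raise ValueError("spikes_per_burst_mean must be >= 1")


#: Genotype presets.  Ordered strictly KO > KO_HET > WT in burst rate, spikes
#: per burst, and network participation; noise and drift are acquisition
#: properties and identical across genotypes (a fixed absolute 0.5 %ΔF/F
#: detection threshold presupposes a smoothed-noise floor well below it, which
#: pins raw noise SD near 0.2 %).
PRESETS: dict[str, RegimePreset] = {
    "WT": RegimePreset(
        name="WT", burst_rate_per_min=0.8, spikes_per_burst_mean=2.0,
        network_rate_per_min=0.4, participation_prob=0.30,
        amplitude_per_spike_pct=2.0, noise_sd_pct=0.2, drift_amplitude_pct=0.2,
    ),
    "KO_HET": RegimePreset(
        name="KO_HET", burst_rate_per_min=1.6, spikes_per_burst_mean=3.5,
        network_rate_per_min=0.8, participation_prob=0.50,
        amplitude_per_spike_pct=2.0, noise_sd_pct=0.2, drift_amplitude_pct=0.2,
    ),
    "KO": RegimePreset(
        name="KO", burst_rate_per_min=2.8, spikes_per_burst_mean=5.0,
        network_rate_per_min=1.5, participation_prob=0.75,
        amplitude_per_spike_pct=2.0, noise_sd_pct=0.2, drift_amplitude_pct=0.2,
    ),
}


@dataclass(frozen=True)
class Burst:
    """One burst: onset time, spike count, and intra-burst spike spacing."""

    time_s: float
    n_spikes: int
    spike_interval_s: float = SOLO_SPIKE_INTERVAL_S


@dataclass(frozen=True)
class NetworkEventSchedule:
    time_s: float
    participants: tuple[int, ...]


@dataclass
class GroundTruth:
    """The generator's activity schedule; reproducible bit-identically from seed."""

    seed: int
    fs_hz: float
    n_frames: int
    n_neurons: int
    bursts: list[list[Burst]]  # one sorted list per neuron
    network: list[NetworkEventSchedule]
    tau_rise_s: float = DEFAULT_TAU_RISE_S
    tau_decay_s: float = DEFAULT_TAU_DECAY_S
    amplitude_per_spike_pct: float = 2.0
    version: int = SCHEMA_VERSION

    def __post_init__(self):
        if len(self.bursts) != self.n_neurons:
            raise ValueError("bursts must hold one list per neuron")
        dur = self.duration_s
        for per_neuron in self.bursts:
            for b in per_neuron:
                if not 0 <= b.time_s < dur:
                    raise ValueError("burst time outside recording")
        for ev in self.network:
            if not 0 <= ev.time_s < dur:
                raise ValueError("network event time outside recording")
            if any(not 0 <= p < self.n_neurons for p in ev.participants):
                raise ValueError("network participant outside neuron id range")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_hz

    def spike_times(self, neuron: int) -> np.ndarray:
        """All spike times of one neuron, clipped to the recording, sorted."""
        out = []
        for b in self.bursts[neuron]:
            for k in range(b.n_spikes):
                t = b.time_s + k * b.spike_interval_s
                if t < self.duration_s:
                    out.append(t)
        return np.sort(np.asarray(out))

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "version": self.version,
            "seed": self.seed,
            "fs_hz": self.fs_hz,
            "n_frames": self.n_frames,
            "n_neurons": self.n_neurons,
            "tau_rise_s": self.tau_rise_s,
            "tau_decay_s": self.tau_decay_s,
            "amplitude_per_spike_pct": self.amplitude_per_spike_pct,
            "bursts": [[asdict(b) for b in per] for per in self.bursts],
            "network": [
                {"time_s": ev.time_s, "participants": list(ev.participants)}
                for ev in self.network
            ],
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"], fs_hz=d["fs_hz"], n_frames=d["n_frames"],
            n_neurons=d["n_neurons"],
            bursts=[[Burst(**b) for b in per] for per in d["bursts"]],
            network=[
                NetworkEventSchedule(ev["time_s"], tuple(ev["participants"]))
                for ev in d["network"]
            ],
            tau_rise_s=d["tau_rise_s"], tau_decay_s=d["tau_decay_s"],
            amplitude_per_spike_pct=d["amplitude_per_spike_pct"],
            version=d["version"],
        )


def generate_ground_truth(
    preset: RegimePreset,
    fs: float = DEFAULT_FS_HZ,
    duration_s: float = 300.0,
    n_neurons: int = 40,
    seed: int = 0,
) -> GroundTruth:
    """Draw a ground-truth activity schedule for one field of view.

    Solo bursts are a homogeneous Poisson process per neuron; spike counts are
    shifted Poisson (minimum one spike); network events are an independent
    Poisson process that recruits each neuron with ``participation_prob``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fs))
    dur = n_frames / fs
    mean_spikes = max(preset.spikes_per_burst_mean, 1.0)

    def draw_n_spikes() -> int:
        return 1 + int(rng.poisson(mean_spikes - 1.0))

    bursts: list[list[Burst]] = []
    for _ in range(n_neurons):
        n_b = rng.poisson(preset.burst_rate_per_min * dur / 60.0)
        times = np.sort(rng.uniform(0.0, dur, size=n_b))
        bursts.append(
            [Burst(float(t), draw_n_spikes(), SOLO_SPIKE_INTERVAL_S) for t in times]
        )

    network: list[NetworkEventSchedule] = []
    n_ev = rng.poisson(preset.network_rate_per_min * dur / 60.0)
    for t in np.sort(rng.uniform(0.0, dur, size=n_ev)):
        members = np.flatnonzero(rng.random(n_neurons) < preset.participation_prob)
        network.append(NetworkEventSchedule(float(t), tuple(int(m) for m in members)))
        for m in members:
            onset = float(
                np.clip(t + rng.uniform(-NETWORK_JITTER_S, NETWORK_JITTER_S),
                        0.0, np.nextafter(dur, 0.0))
            )
            bursts[m].append(
                Burst(onset, max(draw_n_spikes(), NETWORK_MIN_SPIKES),
                      NETWORK_SPIKE_INTERVAL_S)
            )

    bursts = [sorted(per, key=lambda b: b.time_s) for per in bursts]
    return GroundTruth(
        seed=seed, fs_hz=fs, n_frames=n_frames, n_neurons=n_neurons,
        bursts=bursts, network=network,
        amplitude_per_spike_pct=preset.amplitude_per_spike_pct,
    )


def kernel_peak_lag(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time from spike to kernel maximum for the difference of exponentials."""
    r, d = tau_rise_s, tau_decay_s
    return r * d / (d - r) * np.log(d / r)


def indicator_kernel(
    t: np.ndarray, tau_rise_s: float, tau_decay_s: float
) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t <= 0."""
    if tau_rise_s >= tau_decay_s:
        raise ValueError("tau_rise must be smaller than tau_decay")
    tpk = kernel_peak_lag(tau_rise_s, tau_decay_s)
    norm = np.exp(-tpk / tau_decay_s) - np.exp(-tpk / tau_rise_s)
    out = np.zeros_like(t, dtype=float)
    m = t > 0
    out[m] = (np.exp(-t[m] / tau_decay_s) - np.exp(-t[m] / tau_rise_s)) / norm
    return out


def render_traces(
    truth: GroundTruth,
    noise_sd: float = 0.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
) -> TraceMatrix:
    """Render a ground-truth schedule into ΔF/F traces (percent, stage raw).

    Each spike contributes the unit-peak indicator kernel scaled to
    ``amplitude_per_spike_pct``; contributions sum linearly.  A sinusoidal
    drift of period 60 s and white Gaussian noise are added.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.tau_rise_s >= truth.tau_decay_s:
        raise ValueError("tau_rise must be smaller than tau_decay")
    rng = np.random.default_rng(seed)
    n, f = truth.n_neurons, truth.n_frames
    fs = truth.fs_hz
    t_axis = np.arange(f) / fs
    # kernel support: the tail below exp(-30) is far under float precision
    support = int(np.ceil(30.0 * truth.tau_decay_s * fs))
    amp = truth.amplitude_per_spike_pct
    values = np.zeros((n, f))
    for i in range(n):
        row = values[i]
        for ts in truth.spike_times(i):
            lo = int(np.floor(ts * fs)) + 1  # first frame strictly after the spike
            if lo >= f:
                continue
            hi = min(lo + support, f)
            row[lo:hi] += amp * indicator_kernel(
                t_axis[lo:hi] - ts, truth.tau_rise_s, truth.tau_decay_s
            )
    if drift_amplitude:
        # independent phase per neuron: slow baseline wander is a per-cell
        # nuisance, not field-wide coherent activity
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
        values += drift_amplitude * np.sin(
            2.0 * np.pi * t_axis[None, :] / DRIFT_PERIOD_S + phases[:, None]
        )
    if noise_sd:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    return TraceMatrix(values, fs_hz=fs, stage="raw")


@dataclass(frozen=True)
class GridLayout:
    """Square-grid ROI layout for rendered movies."""

    spacing_px: int = 12
    radius_px: float = 4.0
    margin_px: int = 8

    def __post_init__(self):
        if self.spacing_px <= 2 * self.radius_px:
            raise ValueError("ROIs overlap: spacing must exceed the ROI diameter")


def render_movie(
    traces: TraceMatrix,
    layout: GridLayout | None = None,
    baseline_intensity: float = 1000.0,
    shot_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[MovieStack, RoiSet]:
    """Render ΔF/F traces into a toy movie stack plus the matching ROI table.

    Pixels inside ROI i at frame t carry
    ``baseline_intensity * (1 + dff_i(t)/100) * falloff(r)`` with a quadratic
    radial falloff; background pixels sit at the zero-activity baseline.
    Gaussian shot noise is added per pixel and frame.  The falloff cancels in
    the ΔF/F ratio, so preprocessing recovers the input traces exactly when
    noise is zero and every trace touches its own baseline.
    """
    if layout is None:
        layout = GridLayout()
    if baseline_intensity <= 0:
        raise ValueError("baseline_intensity must be positive")
    if shot_noise_sd < 0:
        raise ValueError("shot_noise_sd must be >= 0")
    n, f = traces.n_neurons, traces.n_frames
    if n < 1:
        raise ValueError("need at least one trace to render a movie")
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    width = 2 * layout.margin_px + (cols - 1) * layout.spacing_px + 1
    height = 2 * layout.margin_px + (rows - 1) * layout.spacing_px + 1
    rois = RoiSet(
        [
            Roi(
                id=traces.neuron_ids[i],
                center_x=float(layout.margin_px + (i % cols) * layout.spacing_px),
                center_y=float(layout.margin_px + (i // cols) * layout.spacing_px),
                radius=layout.radius_px,
            )
            for i in range(n)
        ],
        width=width,
        height=height,
    )
    yy, xx = np.mgrid[0:height, 0:width]
    base = np.full((height, width), baseline_intensity)
    masks = []
    for roi in rois.rois:
        d2 = (xx - roi.center_x) ** 2 + (yy - roi.center_y) ** 2
        mask = d2 <= roi.radius**2
        falloff = 1.0 - 0.6 * d2 / roi.radius**2
        base[mask] = baseline_intensity * falloff[mask]
        masks.append(mask)
    data = np.broadcast_to(base, (f, height, width)).copy()
    for i, mask in enumerate(masks):
        # falloff cancels in the later dff ratio; gain is baseline*falloff/100
        data[:, mask] += np.outer(traces.values[i], base[mask] / 100.0)
    if shot_noise_sd:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, shot_noise_sd, size=data.shape)
    return MovieStack(data, fs_hz=traces.fs_hz), rois


def isolated_event_truth(
    fs: float = DEFAULT_FS_HZ,
    duration_s: float = 300.0,
    n_neurons: int = 40,
    amplitude_pct: float = 5.0,
    min_gap_s: float = 4.0,
    mean_extra_gap_s: float = 3.0,
    seed: int = 0,
) -> GroundTruth:
    """A detection benchmark schedule: single-spike events with enforced gaps.

    Each neuron fires lone spikes of fixed amplitude whose onsets are spaced
    by ``min_gap_s`` plus an exponential waiting time, so every transient is
    isolated and unambiguous to match against detections.  No network events.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fs))
    dur = n_frames / fs
    bursts: list[list[Burst]] = []
    for _ in range(n_neurons):
        per: list[Burst] = []
        t = rng.uniform(1.0, 1.0 + min_gap_s)
        # stop 4 s short of the end so every transient can decay back below
        # the boundary threshold and be delineated
        while t < dur - 4.0:
            per.append(Burst(float(t), 1, SOLO_SPIKE_INTERVAL_S))
            t += min_gap_s + rng.exponential(mean_extra_gap_s)
        bursts.append(per)
    return GroundTruth(
        seed=seed, fs_hz=fs, n_frames=n_frames, n_neurons=n_neurons,
        bursts=bursts, network=[], amplitude_per_spike_pct=amplitude_pct,
    )


def simulate_fov(
    preset: RegimePreset,
    fs: float = DEFAULT_FS_HZ,
    duration_s: float = 300.0,
    n_neurons: int = 40,
    seed: int = 0,
) -> tuple[GroundTruth, TraceMatrix]:
    """Ground truth plus rendered traces for one field of view (one seed)."""
    truth = generate_ground_truth(preset, fs=fs, duration_s=duration_s,
                                  n_neurons=n_neurons, seed=seed)
    traces = render_traces(
        truth, noise_sd=preset.noise_sd_pct,
        drift_amplitude=preset.drift_amplitude_pct, seed=seed + 1,
    )
    return truth, traces
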