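"""Movie-to-trace preprocessing: ΔF/F, ROI extraction, smoothing, baseline adjustment.

The recorded fluorescence stack is normalized against its per-pixel
minimum-intensity projection (the baseline estimate that stays valid even for
cultures with nearly continuous activity and therefore few quiet frames),
averaged within circular somatic ROIs, smoothed with a short moving mean, and
finally flattened by subtracting a windowed low-percentile baseline so that
event duration and area measurements do not inherit slow drift or the tail of
preceding activity.

All ΔF/F values are carried in percent so that the detection thresholds
(0.5 %, 1 %, the 50 % ratio) apply literally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateBaselineError

logger = logging.getLogger(__name__)

STAGES = ("raw", "smoothed", "baseline_adjusted")

DEFAULT_FS_HZ = 8.91
DEFAULT_N_ROIS = 40


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition defaults: 8.91 Hz frame rate, 40 somatic ROIs per field of view."""

    fs_hz: float = DEFAULT_FS_HZ
    n_rois: int = DEFAULT_N_ROIS

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")


@dataclass
class MovieStack:
    """A movie as a (frames, height, width) array of non-negative intensities."""

    data: np.ndarray
    fs_hz: float = DEFAULT_FS_HZ

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be 3-D (frames, height, width)")
        if self.data.shape[0] < 2:
            raise ValueError("movie must contain at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("movie contains negative intensities")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class Roi:
    """A circular ROI over one neuronal soma (0-based pixel coordinates)."""

    id: int
    center_x: float
    center_y: float
    radius: float


@dataclass
class RoiSet:
    rois: list[Roi]
    width: int
    height: int

    def __post_init__(self):
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")
        for r in self.rois:
            if r.radius <= 0:
                raise ValueError(f"ROI {r.id}: radius must be positive")
            if (
                r.center_x - r.radius < -0.5
                or r.center_x + r.radius > self.width - 0.5
                or r.center_y - r.radius < -0.5
                or r.center_y + r.radius > self.height - 0.5
            ):
                raise ValueError(f"ROI {r.id} does not lie fully inside the image")

    def __len__(self) -> int:
        return len(self.rois)

    def sorted_by_id(self) -> list[Roi]:
        return sorted(self.rois, key=lambda r: r.id)

    def mask(self, roi: Roi) -> np.ndarray:
        """Boolean pixel mask: a pixel belongs to the ROI iff its center lies
        within the disc (radius inclusive)."""
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        return (xx - roi.center_x) ** 2 + (yy - roi.center_y) ** 2 <= roi.radius**2


@dataclass
class TraceMatrix:
    """ΔF/F traces (percent), one row per neuron, one column per frame."""

    values: np.ndarray
    fs_hz: float
    stage: str = "raw"
    neuron_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.neuron_ids:
            self.neuron_ids = list(range(self.values.shape[0]))
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match number of rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fs_hz


def round_half_away(x: float) -> int:
    """Round half away from zero (15 s at 8.91 Hz -> 134 frames)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_dff_movie(movie: MovieStack) -> MovieStack:
    """Normalize a movie to ΔF/F percent against the per-pixel minimum projection.

    output(t, y, x) = 100 * (F(t,y,x) - Fmin(y,x)) / Fmin(y,x), Fmin taken over
    all frames.  Raises :class:`DegenerateBaselineError` if any pixel's minimum
    is <= 0.
    """
    fmin = movie.data.min(axis=0)
    n_bad = int(np.count_nonzero(fmin <= 0))
    if n_bad:
        raise DegenerateBaselineError(n_bad)
    dff = 100.0 * (movie.data - fmin) / fmin
    return MovieStack(dff, fs_hz=movie.fs_hz)


def extract_traces(dff_movie: MovieStack, rois: RoiSet) -> TraceMatrix:
    """Mean ΔF/F within each ROI disc at each frame (stage ``raw``).

    Rows follow ascending ROI id.  An empty ROI set yields a zero-row matrix.
    """
    n_frames, h, w = dff_movie.shape
    if rois.height != h or rois.width != w:
        raise ValueError(
            f"RoiSet image dimensions ({rois.width}x{rois.height}) do not match "
            f"movie ({w}x{h})"
        )
    order = rois.sorted_by_id()
    out = np.empty((len(order), n_frames))
    flat = dff_movie.data.reshape(n_frames, -1)
    for i, roi in enumerate(order):
        m = rois.mask(roi).ravel()
        if not m.any():
            raise ValueError(f"ROI {roi.id} covers no pixel centers")
        out[i] = flat[:, m].mean(axis=1)
    if not order:
        out = np.empty((0, n_frames))
    return TraceMatrix(out, fs_hz=dff_movie.fs_hz, stage="raw",
                       neuron_ids=[r.id for r in order])


def smooth_traces(traces: TraceMatrix, window: int = 4) -> TraceMatrix:
    """Centered moving mean of width ``window`` frames (stage raw -> smoothed).

    At the edges the mean shrinks to the available samples, so no padded values
    enter the threshold logic.  For even windows the extra sample sits on the
    right: frame t averages frames [t - (window-1)//2, t + window//2].
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if traces.stage != "raw":
        raise ValueError(f"expected stage 'raw', got {traces.stage!r}")
    n = traces.n_frames
    right = window // 2
    kernel = np.ones(window)
    counts = np.convolve(np.ones(n), kernel, mode="full")[right : right + n]
    out = np.empty_like(traces.values)
    for i in range(traces.n_neurons):
        s = np.convolve(traces.values[i], kernel, mode="full")[right : right + n]
        out[i] = s / counts
    return TraceMatrix(out, fs_hz=traces.fs_hz, stage="smoothed",
                       neuron_ids=list(traces.neuron_ids))


def _window_baseline(x: np.ndarray, nwin: int, percentile: float) -> np.ndarray:
    """Piecewise-linear baseline through per-window percentile anchors.

    Consecutive non-overlapping windows of ``nwin`` frames (last may be
    shorter); each window's anchor sits at its center frame and holds the
    window's ``percentile``-th percentile; constant extrapolation beyond the
    first/last anchor.
    """
    n = len(x)
    starts = np.arange(0, n, nwin)
    anchors_t = []
    anchors_v = []
    for s in starts:
        e = min(s + nwin, n)
        anchors_t.append((s + e - 1) / 2.0)
        anchors_v.append(np.percentile(x[s:e], percentile))
    return np.interp(np.arange(n), anchors_t, anchors_v)


def adjust_baseline(
    traces: TraceMatrix, window_s: float = 15.0, percentile: float = 1.0
) -> TraceMatrix:
    """Shift the within-window low percentile of each trace to zero.

    The trace is split into consecutive windows of round(window_s * fs) frames;
    the 1st percentile of each window, anchored at the window center, defines a
    piecewise-linear baseline that is subtracted (stage smoothed ->
    baseline_adjusted).  Recordings shorter than one window fall back to a
    single global percentile shift (logged).
    """
    if traces.stage != "smoothed":
        raise ValueError(f"expected stage 'smoothed', got {traces.stage!r}")
    nwin = round_half_away(window_s * traces.fs_hz)
    if nwin < 2:
        raise ValueError("baseline window must span at least 2 frames")
    n = traces.n_frames
    out = np.empty_like(traces.values)
    if n < nwin:
        logger.info(
            "recording (%d frames) shorter than one %g s baseline window "
            "(%d frames); applying a single global percentile shift",
            n, window_s, nwin,
        )
        for i in range(traces.n_neurons):
            out[i] = traces.values[i] - np.percentile(traces.values[i], percentile)
    else:
        for i in range(traces.n_neurons):
            out[i] = traces.values[i] - _window_baseline(
                traces.values[i], nwin, percentile
            )
    return TraceMatrix(out, fs_hz=traces.fs_hz, stage="baseline_adjusted",
                       neuron_ids=list(traces.neuron_ids))


def preprocess_movie(movie: MovieStack, rois: RoiSet) -> TraceMatrix:
    """Convenience composition: ΔF/F movie then ROI trace extraction."""
    return extract_traces(compute_dff_movie(movie), rois)


def as_smoothed(traces: TraceMatrix, window: int = 4) -> TraceMatrix:
    """Return a smoothed view of ``traces`` whatever their current stage allows."""
    if traces.stage == "raw":
        return smooth_traces(traces, window)
    if traces.stage == "smoothed":
        return traces
    raise ValueError("baseline-adjusted traces cannot be re-smoothed")
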