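"""Delimited-table and TIFF I/O.

All tables are comma-separated text with metadata lines prefixed by ``#``
(key=value) ahead of the header row, so every file is self-describing:
trace tables carry their frame rate and processing stage, event tables their
frame rate.  Undefined measurements are written as empty cells; flags as 0/1.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .network import ActiveInterval, NetworkEvent
from .preprocessing import MovieStack, Roi, RoiSet, TraceMatrix
from .summaries import FovSummary, NeuronSummary
from .transients import Transient

FLOAT_FMT = "%.10g"


def _read_metadata(path) -> tuple[dict[str, str], str]:
    meta = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def _write_table(df: pd.DataFrame, path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


# -- traces -----------------------------------------------------------------

def write_trace_table(traces: TraceMatrix, path) -> None:
    df = pd.DataFrame(
        traces.values, columns=[f"f{t}" for t in range(traces.n_frames)]
    )
    df.insert(0, "neuron_id", traces.neuron_ids)
    _write_table(df, path, {"fs_hz": repr(traces.fs_hz), "stage": traces.stage})


def read_trace_table(path) -> TraceMatrix:
    meta, body = _read_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    return TraceMatrix(
        df.drop(columns="neuron_id").to_numpy(dtype=float),
        fs_hz=float(meta["fs_hz"]),
        stage=meta.get("stage", "raw"),
        neuron_ids=[int(i) for i in df["neuron_id"]],
    )


# -- ROIs -------------------------------------------------------------------

def write_roi_table(rois: RoiSet, path) -> None:
    df = pd.DataFrame(
        [(r.id, r.center_x, r.center_y, r.radius) for r in rois.sorted_by_id()],
        columns=["id", "center_x_px", "center_y_px", "radius_px"],
    )
    _write_table(df, path, {"width_px": rois.width, "height_px": rois.height})


def read_roi_table(path) -> RoiSet:
    meta, body = _read_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    rois = [
        Roi(int(r.id), float(r.center_x_px), float(r.center_y_px), float(r.radius_px))
        for r in df.itertuples()
    ]
    return RoiSet(rois, width=int(meta["width_px"]), height=int(meta["height_px"]))


# -- movies -----------------------------------------------------------------

def write_movie(movie: MovieStack, path) -> None:
    tifffile.imwrite(path, movie.data.astype(np.float32))


def read_movie(path, fs_hz: float) -> MovieStack:
    return MovieStack(tifffile.imread(path).astype(float), fs_hz=fs_hz)


# -- transients -------------------------------------------------------------

TRANSIENT_COLUMNS = [
    "neuron_id", "peak_frame", "peak_dff_pct", "amplitude_pct", "start_frame",
    "end_frame", "duration_s", "auc_pct_s", "iei_prev_s", "half_decay_s",
    "refractory_excluded", "elevated_baseline_excluded", "no_clear_bounds",
]


def transients_to_frame(transients: list[Transient]) -> pd.DataFrame:
    rows = []
    for t in transients:
        rows.append({
            "neuron_id": t.neuron_id,
            "peak_frame": t.peak_frame,
            "peak_dff_pct": t.peak_dff_pct,
            "amplitude_pct": t.amplitude_pct,
            "start_frame": t.start_frame,
            "end_frame": t.end_frame,
            "duration_s": t.duration_s,
            "auc_pct_s": t.auc_pct_s,
            "iei_prev_s": t.iei_prev_s,
            "half_decay_s": t.half_decay_s,
            "refractory_excluded": int(t.refractory_excluded),
            "elevated_baseline_excluded": int(t.elevated_baseline_excluded),
            "no_clear_bounds": int(t.no_clear_bounds),
        })
    return pd.DataFrame(rows, columns=TRANSIENT_COLUMNS)


def write_transient_table(transients: list[Transient], path, fs_hz: float) -> None:
    _write_table(transients_to_frame(transients), path, {"fs_hz": repr(fs_hz)})


# -- intervals & network events --------------------------------------------

def write_interval_table(intervals: list[ActiveInterval], path, fs_hz: float) -> None:
    df = pd.DataFrame(
        [(iv.neuron_id, iv.start_frame, iv.end_frame, iv.peak_frame)
         for iv in intervals],
        columns=["neuron_id", "start_frame", "end_frame", "peak_frame"],
    )
    _write_table(df, path, {"fs_hz": repr(fs_hz)})


def write_network_event_table(events: list[NetworkEvent], path, fs_hz: float) -> None:
    df = pd.DataFrame(
        [(e.start_frame, e.end_frame, e.duration_s, e.peak_coactive_fraction,
          e.participation_pct) for e in events],
        columns=["start_frame", "end_frame", "duration_s",
                 "peak_coactive_fraction", "participation_pct"],
    )
    _write_table(df, path, {"fs_hz": repr(fs_hz)})


def read_network_event_table(path) -> list[NetworkEvent]:
    meta, body = _read_metadata(path)
    df = pd.read_csv(_io.StringIO(body))
    return [
        NetworkEvent(
            start_frame=int(r.start_frame), end_frame=int(r.end_frame),
            duration_s=float(r.duration_s),
            peak_coactive_fraction=float(r.peak_coactive_fraction),
            participation_pct=(None if pd.isna(r.participation_pct)
                               else float(r.participation_pct)),
        )
        for r in df.itertuples()
    ]


def write_fraction_table(fraction: np.ndarray, path, fs_hz: float) -> None:
    """The coactive-fraction signal as a one-row trace table."""
    df = pd.DataFrame([np.asarray(fraction)],
                      columns=[f"f{t}" for t in range(len(fraction))])
    df.insert(0, "signal", ["coactive_fraction"])
    _write_table(df, path, {"fs_hz": repr(fs_hz)})


# -- summaries --------------------------------------------------------------

def write_neuron_summary_table(summaries: list[NeuronSummary], path) -> None:
    df = pd.DataFrame([s.__dict__ for s in summaries])
    _write_table(df, path, {"frequency_unit": "events_per_min"})


def write_fov_summary_table(summary: FovSummary, path) -> None:
    df = pd.DataFrame([summary.__dict__])
    _write_table(df, path, {"frequency_unit": "events_per_min"})
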