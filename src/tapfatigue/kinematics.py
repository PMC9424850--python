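"""Cycle segmentation, time normalization and kinematic variability.

Acceleration streams are cut into cycles at successive TS1 taps, each
cycle is linearly resampled to 100 phase points (stages to 25 points
each), and the kinematic variability (KV) of a bin is the mean across
phase points of the between-cycle standard deviation, per axis; each
sensor's KV is the Euclidean norm of its three axis values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ACCEL_SENSORS, STAGES, AccelRecording, SchemaError, TapLog

log = logging.getLogger(__name__)

__all__ = ["CycleSet", "NormalizedCycleSet", "segment_cycles", "time_normalize",
           "time_normalize_stages", "kinematic_variability"]


@dataclass
class CycleSet:
    """Cycle and stage boundaries over an acceleration recording.

    ``stage_times[i]`` holds the TS2, TS3, TS4 tap times inside cycle i,
    so stage ST1 of cycle i spans [start_times[i], stage_times[i, 0]) and
    ST4 spans [stage_times[i, 2], end_times[i]).  Cycles missing an
    intermediate tap are flagged invalid and excluded downstream.
    """

    recording: AccelRecording
    start_times: np.ndarray  # (n_cycles,)
    end_times: np.ndarray  # (n_cycles,)
    stage_times: np.ndarray  # (n_cycles, 3)
    valid: np.ndarray  # (n_cycles,) bool

    @property
    def n_cycles(self) -> int:
        return self.start_times.size

    def stage_bounds(self, i: int) -> np.ndarray:
        """(4, 2) array of [t0, t1) for ST1..ST4 of cycle i."""
        edges = np.concatenate(([self.start_times[i]], self.stage_times[i], [self.end_times[i]]))
        return np.column_stack([edges[:-1], edges[1:]])


@dataclass
class NormalizedCycleSet:
    """Cycles resampled onto a common phase grid: (n_cycles, n_phase, 9)."""

    tensor: np.ndarray
    labels: tuple[str, ...]
    cycle_index: np.ndarray  # original cycle index of each tensor row

    @property
    def n_cycles(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_phase(self) -> int:
        return self.tensor.shape[1]


def segment_cycles(accel: AccelRecording, taps: TapLog) -> CycleSet:
    """Cut the recording into cycles at successive TS1 taps.

    Requires at least two TS1 events and every tap within the recording's
    time range.  A cycle lacking exactly one TS2, TS3 and TS4 tap in
    order is flagged invalid (and logged), not an error.
    """
    ts1 = taps.ts1_times()
    if ts1.size < 2:
        raise ValueError("need at least 2 TS1 events to form a cycle")
    lo, hi = accel.start_time, accel.end_time
    out_of_range = (taps.times < lo) | (taps.times > hi)
    if np.any(out_of_range):
        i = int(np.argmax(out_of_range))
        raise ValueError(
            f"tap event {i} ({taps.screens[i]} at t={taps.times[i]:.3f}s) lies outside "
            f"the acceleration record [{lo:.3f}, {hi:.3f}]s"
        )
    n_cycles = ts1.size - 1
    starts, ends = ts1[:-1], ts1[1:]
    stage_times = np.full((n_cycles, 3), np.nan)
    valid = np.ones(n_cycles, dtype=bool)
    for i in range(n_cycles):
        sel = (taps.times > starts[i]) & (taps.times < ends[i])
        mid = taps.screens[sel]
        tmid = taps.times[sel]
        if list(mid) == ["TS2", "TS3", "TS4"]:
            stage_times[i] = tmid
        else:
            valid[i] = False
            log.warning("cycle %d invalid: intermediate taps %s", i, list(mid))
    if not np.all(valid):
        log.info("excluded %d invalid cycle(s)", int(np.sum(~valid)))
    return CycleSet(accel, starts, ends, stage_times, valid)


def _resample(accel: AccelRecording, t_query: np.ndarray) -> np.ndarray:
    t = accel.times
    return np.column_stack([np.interp(t_query, t, accel.data[:, c])
                            for c in range(accel.data.shape[1])])


def time_normalize(cycles: CycleSet, n: int = 100) -> NormalizedCycleSet:
    """Resample each valid cycle onto ``n`` equally spaced phase points.

    Linear interpolation of each channel from cycle start to cycle end
    (endpoints included).  Degenerate zero-duration cycles are excluded.
    """
    if n < 2:
        raise ValueError("need at least 2 phase points")
    keep = cycles.valid & (cycles.end_times > cycles.start_times)
    n_dropped = int(np.sum(cycles.valid & ~keep))
    if n_dropped:
        log.warning("excluded %d zero-duration cycle(s)", n_dropped)
    idx = np.where(keep)[0]
    tensor = np.empty((idx.size, n, len(cycles.recording.labels)))
    for row, i in enumerate(idx):
        tq = np.linspace(cycles.start_times[i], cycles.end_times[i], n)
        tensor[row] = _resample(cycles.recording, tq)
    return NormalizedCycleSet(tensor, cycles.recording.labels, idx)


def time_normalize_stages(cycles: CycleSet, n_stage: int = 25) -> NormalizedCycleSet:
    """Resample each of the four stages of each valid cycle to ``n_stage`` points.

    The stage segments are concatenated, so the result has 4 * n_stage
    phase points per cycle with stage s occupying points
    [s * n_stage, (s + 1) * n_stage).
    """
    keep = cycles.valid & (cycles.end_times > cycles.start_times)
    idx = np.where(keep)[0]
    tensor = np.empty((idx.size, 4 * n_stage, len(cycles.recording.labels)))
    for row, i in enumerate(idx):
        bounds = cycles.stage_bounds(i)
        tq = np.concatenate([np.linspace(t0, t1, n_stage) for t0, t1 in bounds])
        tensor[row] = _resample(cycles.recording, tq)
    return NormalizedCycleSet(tensor, cycles.recording.labels, idx)


def kinematic_variability(ncycles: NormalizedCycleSet,
                          bins: np.ndarray | None = None,
                          ddof: int = 1) -> dict:
    """Per-bin kinematic variability, per axis and per sensor.

    For each bin: sample standard deviation (ddof=1) across the bin's
    cycles at each phase point, averaged over phase points, per channel;
    the sensor KV is the Euclidean norm of its three axis KVs.  Bins with
    fewer than 2 cycles give NaN.

    ``bins`` assigns a bin index to each cycle in the set (default: one
    bin holding everything).  Returns ``{"axis": (n_bins, 9) array,
    "sensor": (n_bins, 3) array, "bins": sorted bin ids}``.
    """
    tensor = ncycles.tensor
    if bins is None:
        bins = np.zeros(tensor.shape[0], dtype=int)
    bins = np.asarray(bins, dtype=int)
    if bins.size != tensor.shape[0]:
        raise ValueError("bins must assign one bin per cycle")
    bin_ids = np.unique(bins[bins >= 0])
    axis_kv = np.full((bin_ids.size, tensor.shape[2]), np.nan)
    for bi, b in enumerate(bin_ids):
        sub = tensor[bins == b]
        if sub.shape[0] < 2:
            log.warning("bin %d has under 2 cycles; KV undefined", b)
            continue
        sd = np.std(sub, axis=0, ddof=ddof)  # (n_phase, 9)
        axis_kv[bi] = sd.mean(axis=0)
    sensor_kv = np.full((bin_ids.size, len(ACCEL_SENSORS)), np.nan)
    for si, sensor in enumerate(ACCEL_SENSORS):
        cols = [i for i, lab in enumerate(ncycles.labels) if lab.startswith(sensor + "_")]
        if len(cols) != 3:
            raise SchemaError(f"sensor {sensor} does not have 3 axes")
        sensor_kv[:, si] = np.sqrt(np.sum(axis_kv[:, cols] ** 2, axis=1))
    return {"axis": axis_kv, "sensor": sensor_kv, "bins": bin_ids}
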