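"""Core data containers and configuration for tapping-session analysis.

The containers mirror what a recording session produces: multichannel
surface EMG over the deltoid (anterior/medial/posterior), a maximum
voluntary contraction (MVC) reference, 9-channel gravity-removed
acceleration from three body segments (lower arm, upper arm, trunk), and
the ordered tap-event log from the four touch screens that defines the
cycle structure (TS1 -> TS2 -> TS3 -> TS4, counterclockwise).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

EMG_CHANNELS = ("ANT", "MED", "POS")
ACCEL_SENSORS = ("LA", "UA", "TR")
ACCEL_AXES = ("X", "Y", "Z")
ACCEL_CHANNELS = tuple(f"{s}_{a}" for s in ACCEL_SENSORS for a in ACCEL_AXES)
SCREENS = ("TS1", "TS2", "TS3", "TS4")
STAGES = ("ST1", "ST2", "ST3", "ST4")


class SchemaError(ValueError):
    """Raised when an input file or container violates its schema."""


def _as_2d(data, n_channels: int, what: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != n_channels:
        raise SchemaError(f"{what}: expected (n_samples, {n_channels}) array, got {arr.shape}")
    return arr


@dataclass
class EmgRecording:
    """Raw or conditioned surface EMG, one column per deltoid channel."""

    data: np.ndarray  # (n_samples, 3), amplitude in uV-like units
    fs: float  # Hz
    labels: tuple[str, ...] = EMG_CHANNELS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = _as_2d(self.data, len(self.labels), "EmgRecording")
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("EmgRecording: channel labels must be unique")
        if self.fs <= 0:
            raise SchemaError("EmgRecording: sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[:, self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown EMG channel {label!r}; have {self.labels}") from None

    def with_data(self, data: np.ndarray) -> "EmgRecording":
        return replace(self, data=data)


@dataclass
class MvcReference:
    """Per-channel maximum voluntary contraction reference RMS amplitude."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for ch, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise SchemaError(f"MvcReference: channel {ch} must be strictly positive, got {v}")

    def __getitem__(self, channel: str) -> float:
        try:
            return self.values[channel]
        except KeyError:
            raise KeyError(f"unknown MVC channel {channel!r}; have {sorted(self.values)}") from None


@dataclass
class AccelRecording:
    """Gravity-removed 3-axis acceleration for three body segments (9 channels)."""

    data: np.ndarray  # (n_samples, 9), m/s^2
    fs: float
    labels: tuple[str, ...] = ACCEL_CHANNELS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = _as_2d(self.data, len(self.labels), "AccelRecording")
        if len(self.labels) != 9:
            raise SchemaError("AccelRecording: expected 9 channels (3 sensors x 3 axes)")
        if self.fs <= 0:
            raise SchemaError("AccelRecording: sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) / self.fs

    def sensor_columns(self, sensor: str) -> list[int]:
        cols = [i for i, lab in enumerate(self.labels) if lab.startswith(sensor + "_")]
        if len(cols) != 3:
            raise KeyError(f"sensor {sensor!r} does not have 3 axes in {self.labels}")
        return cols


@dataclass
class TapLog:
    """Ordered tap events: screen id, timestamp (s), pixel coordinates.

    Screens must advance cyclically TS1 -> TS2 -> TS3 -> TS4 -> TS1 and a
    cycle is the span between successive TS1 taps.
    """

    screens: np.ndarray  # str array
    times: np.ndarray  # s, strictly increasing
    x: np.ndarray  # pixels
    y: np.ndarray  # pixels

    def __post_init__(self) -> None:
        self.screens = np.asarray(self.screens, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.screens)
        if not (len(self.times) == len(self.x) == len(self.y) == n):
            raise SchemaError("TapLog: all columns must have equal length")
        bad = np.where(np.diff(self.times) <= 0)[0]
        if bad.size:
            row = int(bad[0]) + 1
            raise SchemaError(
                f"TapLog: timestamps must be strictly increasing; violation at event {row} "
                f"(t={self.times[row]:.6f} after t={self.times[row - 1]:.6f})"
            )
        order = {s: i for i, s in enumerate(SCREENS)}
        for i, s in enumerate(self.screens):
            if s not in order:
                raise SchemaError(f"TapLog: unknown screen id {s!r} at event {i}")
        idx = np.array([order[s] for s in self.screens])
        if n > 1:
            step = np.diff(idx) % 4
            bad = np.where(step != 1)[0]
            if bad.size:
                row = int(bad[0]) + 1
                raise SchemaError(
                    f"TapLog: screens must cycle TS1..TS4; event {row} is "
                    f"{self.screens[row]!r} after {self.screens[row - 1]!r}"
                )

    def __len__(self) -> int:
        return len(self.times)

    def ts1_times(self) -> np.ndarray:
        return self.times[self.screens == "TS1"]

    @property
    def n_cycles(self) -> int:
        """Number of complete cycles (TS1 -> next TS1)."""
        return max(len(self.ts1_times()) - 1, 0)


@dataclass(frozen=True)
class CircleSpec:
    """Geometry of the target circle drawn on each 2.4-inch touch screen.

    The default follows the hardware: 320 x 240 resolution with a pixel
    pitch of 0.153 mm and a 110-pixel circle diameter (16.83 mm).
    """

    center: tuple[float, float] = (160.0, 120.0)
    radius_px: float = 55.0
    pixel_pitch_mm: float = 0.153
    resolution: tuple[int, int] = (320, 240)

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise SchemaError("CircleSpec: radius must be positive")
        cx, cy = self.center
        w, h = self.resolution
        if not (self.radius_px <= cx <= w - self.radius_px and self.radius_px <= cy <= h - self.radius_px):
            raise SchemaError("CircleSpec: circle must lie fully on screen")

    @property
    def radius_mm(self) -> float:
        return self.radius_px * self.pixel_pitch_mm

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the analysis chain.

    window_s/overlap drive both the RMS and median-frequency estimators
    (0.125 s windows, 50% overlap = 0.0625 s step). band is the EMG
    band-pass (Hz). Cycles are grouped into ``n_bins`` bins of
    ``bin_size`` cycles; each cycle is resampled to ``n_phase`` points
    (and each of the four stages to ``stage_phase`` points) before
    variability and state-space work. LLE horizons are expressed in
    normalized samples (1 sample = 1% of a cycle).
    """

    window_s: float = 0.125
    overlap: float = 0.5
    band: tuple[float, float] = (10.0, 950.0)
    filter_order: int = 4
    bin_size: int = 40
    n_bins: int = 10
    n_phase: int = 100
    stage_phase: int = 25
    lle_horizons: tuple[int, ...] = (5, 10, 25, 50)
    theiler: int = 100
    curve_k: int = 50
    confine_to_cycles: bool = True
    alpha: float = 0.05
    n_followups: int = 4
    incomplete_bin: str = "include"  # or "drop"
    td_mode: str = "centroid"  # or "center_sd"
    circle: CircleSpec = field(default_factory=CircleSpec)

    def __post_init__(self) -> None:
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        if list(self.lle_horizons) != sorted(self.lle_horizons):
            raise ValueError("lle_horizons must be sorted ascending")
        if self.curve_k < max(self.lle_horizons):
            raise ValueError("curve_k must cover the largest LLE horizon")
        if self.incomplete_bin not in ("include", "drop"):
            raise ValueError("incomplete_bin must be 'include' or 'drop'")
        if self.td_mode not in ("centroid", "center_sd"):
            raise ValueError("td_mode must be 'centroid' or 'center_sd'")


@dataclass
class WindowedSeries:
    """A scalar index evaluated over sliding windows (RMS, %MVC or MF)."""

    times: np.ndarray  # window centers, s
    values: np.ndarray
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise SchemaError("WindowedSeries: times and values must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise SchemaError("WindowedSeries: window times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class BinSeries:
    """Per-bin scalar values (mean over the windows/cycles in each bin)."""

    values: np.ndarray  # (n_bins,)
    counts: np.ndarray  # contributing items per bin
    complete: np.ndarray  # bool, bin had its full cycle complement

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.complete = np.asarray(self.complete, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.size


def cycle_of_times(times: Sequence[float], cycle_starts: np.ndarray) -> np.ndarray:
    """Map timestamps to 0-based cycle indices given TS1 boundary times.

    Times before the first or at/after the last boundary get index -1.
    """
    starts = np.asarray(cycle_starts, dtype=float)
    t = np.asarray(times, dtype=float)
    idx = np.searchsorted(starts, t, side="right") - 1
    idx[(idx < 0) | (idx >= starts.size - 1)] = -1
    return idx
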