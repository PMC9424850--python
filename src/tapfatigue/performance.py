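"""End-point task performance: accuracy score, tapping deviation, task time.

The accuracy score of a tap at distance d (mm) from the center of a
target circle of radius r is AS = 100 * (r - d) / r: 100 at the center,
0 on the rim, negative outside the circle (not clamped).  Tapping
deviation (TD) is a precision measure: the mean distance of a bin's taps
from their own centroid (or, optionally, the RMS distance from the
circle center).  Task time is the span between successive TS1 taps.
"""
from __future__ import annotations

import numpy as np

from .core import SCREENS, CircleSpec, TapLog, cycle_of_times
from .emg import bin_series

__all__ = ["accuracy_score", "tapping_deviation", "cycle_times",
           "as_table", "td_table", "time_table"]


def accuracy_score(x, y, circle: CircleSpec) -> np.ndarray:
    """AS for tap pixel coordinates; vectorized over taps."""
    cx, cy = circle.center
    d_mm = np.hypot(np.asarray(x, float) - cx, np.asarray(y, float) - cy) * circle.pixel_pitch_mm
    return (circle.radius_mm - d_mm) / circle.radius_mm * 100.0


def tapping_deviation(x, y, circle: CircleSpec, mode: str = "centroid") -> float:
    """Dispersion (mm) of one screen's taps within one bin.

    'centroid' (default): mean Euclidean distance from the taps' own
    centroid, a pure precision measure independent of any aim bias.
    'center_sd': RMS distance from the circle center, which mixes bias
    and spread.  Fewer than 2 taps -> NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        return float("nan")
    if mode == "centroid":
        dx, dy = x - x.mean(), y - y.mean()
        d_px = np.mean(np.hypot(dx, dy))
    elif mode == "center_sd":
        cx, cy = circle.center
        d_px = np.sqrt(np.mean((x - cx) ** 2 + (y - cy) ** 2))
    else:
        raise ValueError(f"unknown TD mode {mode!r}")
    return float(d_px * circle.pixel_pitch_mm)


def cycle_times(taps: TapLog) -> np.ndarray:
    """Per-cycle duration: successive TS1 timestamp differences (s)."""
    ts1 = taps.ts1_times()
    if ts1.size < 2:
        raise ValueError("need at least 2 TS1 events for a cycle time")
    return np.diff(ts1)


def _tap_cycles(taps: TapLog) -> np.ndarray:
    return cycle_of_times(taps.times, taps.ts1_times())


def as_table(taps: TapLog, circle: CircleSpec, bin_size: int = 40,
             n_bins: int | None = None, incomplete: str = "include") -> dict[str, np.ndarray]:
    """Mean AS per screen per bin: {'TS1': (n_bins,), ...}."""
    scores = accuracy_score(taps.x, taps.y, circle)
    cycles = _tap_cycles(taps)
    out = {}
    for s in SCREENS:
        sel = taps.screens == s
        bs = bin_series(scores[sel], cycles=cycles[sel], bin_size=bin_size,
                        n_bins=n_bins, incomplete=incomplete)
        out[s] = bs.values
    return out


def td_table(taps: TapLog, circle: CircleSpec, bin_size: int = 40,
             n_bins: int | None = None, mode: str = "centroid") -> dict[str, np.ndarray]:
    """Tapping deviation (mm) per screen per bin."""
    cycles = _tap_cycles(taps)
    n_cycles = len(taps.ts1_times()) - 1
    total_bins = int(np.ceil(n_cycles / bin_size))
    if n_bins is not None:
        total_bins = min(total_bins, n_bins)
    out = {}
    for s in SCREENS:
        vals = np.full(total_bins, np.nan)
        for b in range(total_bins):
            sel = (taps.screens == s) & (cycles // bin_size == b) & (cycles >= 0)
            vals[b] = tapping_deviation(taps.x[sel], taps.y[sel], circle, mode)
        out[s] = vals
    return out


def time_table(taps: TapLog, bin_size: int = 40, n_bins: int | None = None,
               incomplete: str = "include") -> np.ndarray:
    """Mean cycle duration (s) per bin."""
    durations = cycle_times(taps)
    bs = bin_series(durations, cycles=np.arange(durations.size), bin_size=bin_size,
                    n_bins=n_bins, incomplete=incomplete)
    return bs.values
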