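"""EMG conditioning, activity, fatigue and cocontraction indices.

The chain is: 4th-order zero-phase Butterworth band-pass (10-950 Hz),
moving RMS in 0.125 s rectangular windows with 50% overlap expressed as
a percentage of the MVC reference, and the windowed median frequency
(MF) -- the frequency that splits each window's power spectral density
into two equal-power halves.  MF declines as muscle fatigue accumulates,
which is what the per-bin MF trajectory tracks.

The cocontraction index (CCI) quantifies simultaneous agonist/antagonist
activation over an interval [t0, t1]:

    CCI = 100 * integral(min(EMG_ago, EMG_ant)) / integral(EMG_ago + EMG_ant)

computed on the windowed %MVC envelopes of the anterior (agonist) and
posterior (antagonist) deltoid, per stage (ST1..ST4) and per full cycle.
For two nonnegative signals CCI lies in [0, 50], reaching 50 only when
the envelopes coincide.
"""
from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .core import (
    BinSeries,
    EmgRecording,
    MvcReference,
    WindowedSeries,
    cycle_of_times,
)

__all__ = [
    "bandpass",
    "moving_rms",
    "percent_mvc",
    "median_frequency",
    "mvc_reference",
    "cci",
    "cci_series_interval",
    "bin_series",
]


def bandpass(rec: EmgRecording, low: float | None = None, high: float | None = None,
             order: int = 4) -> EmgRecording:
    """Zero-phase (forward-backward) Butterworth band-pass, per channel.

    Defaults to the 10-950 Hz conditioning band.  ``high`` must stay
    below the Nyquist frequency; at fs = 1926 Hz the Nyquist is 963 Hz,
    so the default 950 Hz upper edge is legal but near-edge.
    """
    low = 10.0 if low is None else float(low)
    high = 950.0 if high is None else float(high)
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"band edges must satisfy 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(
            f"upper band edge {high} Hz must be below the Nyquist frequency "
            f"{nyq:.1f} Hz; lower it or resample the recording"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return rec.with_data(out)


def _window_params(n: int, fs: float, window_s: float, overlap: float) -> tuple[int, int, int]:
    nper = int(window_s * fs)
    stride = max(int(round(nper * (1.0 - overlap))), 1)
    n_win = (n - nper) // stride + 1 if n >= nper else 0
    return nper, stride, n_win


def _frames(x: np.ndarray, nper: int, stride: int, n_win: int) -> np.ndarray:
    return sliding_window_view(x, nper)[:: stride][:n_win]


def _window_times(t0: float, fs: float, nper: int, stride: int, n_win: int) -> np.ndarray:
    return t0 + (np.arange(n_win) * stride + (nper - 1) / 2.0) / fs


def moving_rms(x: np.ndarray, fs: float, window_s: float = 0.125,
               overlap: float = 0.5, start_time: float = 0.0) -> WindowedSeries:
    """RMS over rectangular sliding windows; partial trailing window dropped."""
    x = np.asarray(x, dtype=float)
    nper, stride, n_win = _window_params(x.size, fs, window_s, overlap)
    if nper < 2:
        raise ValueError(f"window of {window_s} s at fs={fs} has under 2 samples")
    if n_win == 0:
        warnings.warn("signal shorter than one window; returning empty series")
        return WindowedSeries(np.empty(0), np.empty(0), window_s, overlap)
    frames = _frames(x, nper, stride, n_win)
    vals = np.sqrt(np.mean(frames ** 2, axis=1))
    times = _window_times(start_time, fs, nper, stride, n_win)
    return WindowedSeries(times, vals, window_s, overlap)


def percent_mvc(rms: WindowedSeries, mvc: MvcReference, channel: str) -> WindowedSeries:
    """Express a moving-RMS series as a percentage of the channel's MVC RMS."""
    ref = mvc[channel]
    return WindowedSeries(rms.times, 100.0 * rms.values / ref, rms.window_s, rms.overlap)


def mvc_reference(rec: EmgRecording, window_s: float = 0.125,
                  overlap: float = 0.5, edge_exclude_s: float = 0.25) -> MvcReference:
    """Reduce an MVC trial to one reference value per channel.

    The reference is the maximum of the moving-RMS series over the trial,
    the conventional reduction for a sustained maximal effort.  Windows
    whose centers fall within ``edge_exclude_s`` of either record edge
    are ignored so that zero-phase filter startup transients cannot
    inflate the maximum (they are skipped only if enough interior
    windows remain).
    """
    values = {}
    for lab in rec.labels:
        ws = moving_rms(rec.channel(lab), rec.fs, window_s, overlap, rec.start_time)
        if len(ws) == 0:
            raise ValueError(f"MVC trial too short for one {window_s} s window")
        vals = ws.values
        interior = (ws.times >= rec.start_time + edge_exclude_s) & \
                   (ws.times <= rec.start_time + rec.duration - edge_exclude_s)
        if np.sum(interior) >= 3:
            vals = vals[interior]
        values[lab] = float(np.max(vals))
    return MvcReference(values)


def median_frequency(x: np.ndarray, fs: float, window_s: float = 0.125,
                     overlap: float = 0.5, start_time: float = 0.0) -> WindowedSeries:
    """Windowed median frequency of the power spectral density.

    Each window gets a Hamming-tapered periodogram; MF is the frequency
    where cumulative power first reaches half of the total, linearly
    interpolated between adjacent frequency bins.  All-zero windows give
    NaN (undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    nper, stride, n_win = _window_params(x.size, fs, window_s, overlap)
    if nper < 8:
        raise ValueError(f"window of {window_s} s at fs={fs} has under 8 samples")
    if n_win == 0:
        warnings.warn("signal shorter than one window; returning empty series")
        return WindowedSeries(np.empty(0), np.empty(0), window_s, overlap)
    frames = _frames(x, nper, stride, n_win)
    taper = signal.get_window("hamming", nper, fftbins=True)
    psd = np.abs(np.fft.rfft(frames * taper, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    cum = np.cumsum(psd, axis=1)
    total = cum[:, -1]
    mf = np.full(n_win, np.nan)
    ok = total > 0
    if np.any(ok):
        # bin k's power occupies [f_k - df/2, f_k + df/2]; the cumulative sum
        # through bin k is therefore reached at the bin's right edge, and the
        # median is interpolated linearly inside the crossing bin
        df = freqs[1] - freqs[0]
        half = 0.5 * total[ok]
        c = cum[ok]
        j = np.argmax(c >= half[:, None], axis=1)
        rows = np.arange(c.shape[0])
        cj = c[rows, j]
        cprev = np.where(j > 0, c[rows, np.maximum(j - 1, 0)], 0.0)
        denom = cj - cprev
        frac = np.where(denom > 0, (half - cprev) / denom, 0.5)
        left = np.maximum(freqs[j] - df / 2.0, 0.0)
        width = freqs[j] + df / 2.0 - left
        mf[ok] = left + frac * width
    times = _window_times(start_time, fs, nper, stride, n_win)
    return WindowedSeries(times, mf, window_s, overlap)


def _interval_slice(times: np.ndarray, t0: float, t1: float) -> slice:
    i0 = int(np.searchsorted(times, t0, side="left"))
    i1 = int(np.searchsorted(times, t1, side="right"))
    return slice(i0, i1)


def cci(ago: WindowedSeries, ant: WindowedSeries, interval: tuple[float, float]) -> float:
    """Cocontraction index over [t0, t1] from two aligned %MVC envelopes.

    Trapezoidal integration of min(ago, ant) over trapezoidal integration
    of (ago + ant), times 100.  Returns NaN (with a warning) when the
    denominator vanishes or fewer than two windows fall in the interval.
    """
    if ago.times.shape != ant.times.shape or not np.allclose(ago.times, ant.times):
        raise ValueError("agonist and antagonist series must share the same window grid")
    t0, t1 = interval
    sl = _interval_slice(ago.times, t0, t1)
    t = ago.times[sl]
    if t.size < 2:
        warnings.warn(f"CCI interval [{t0:.3f}, {t1:.3f}] covers fewer than 2 windows")
        return float("nan")
    a, b = ago.values[sl], ant.values[sl]
    denom = np.trapezoid(a + b, t)
    if denom == 0 or not np.isfinite(denom):
        warnings.warn("CCI denominator integral is zero; returning NaN")
        return float("nan")
    return float(100.0 * np.trapezoid(np.minimum(a, b), t) / denom)


def cci_series_interval(ago: WindowedSeries, ant: WindowedSeries,
                        intervals: np.ndarray) -> np.ndarray:
    """CCI for each (t0, t1) row of ``intervals``; NaN where undefined."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([cci(ago, ant, (t0, t1)) for t0, t1 in intervals])


def bin_series(values: np.ndarray, *, cycles: np.ndarray | None = None,
               times: np.ndarray | None = None,
               cycle_starts: np.ndarray | None = None,
               bin_size: int = 40, n_bins: int | None = None,
               incomplete: str = "include") -> BinSeries:
    """Average per-cycle or per-window values into bins of ``bin_size`` cycles.

    Either pass ``cycles`` (0-based cycle index per value) directly, or
    ``times`` plus ``cycle_starts`` (TS1 boundary times) to assign each
    window to the cycle containing its center.  NaN values are ignored in
    the bin means.  A final bin with fewer than ``bin_size`` cycles is
    included but flagged incomplete, or dropped when
    ``incomplete='drop'``.
    """
    values = np.asarray(values, dtype=float)
    if cycles is None:
        if times is None or cycle_starts is None:
            raise ValueError("need either cycles or (times and cycle_starts)")
        cycles = cycle_of_times(times, np.asarray(cycle_starts, dtype=float))
        n_cycles = len(cycle_starts) - 1
    else:
        cycles = np.asarray(cycles, dtype=int)
        n_cycles = int(cycles.max()) + 1 if cycles.size else 0
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    keep = cycles >= 0
    cycles, values = cycles[keep], values[keep]
    total_bins = int(np.ceil(n_cycles / bin_size)) if n_cycles else 0
    if n_bins is not None:
        total_bins = min(total_bins, n_bins)
    bins = cycles // bin_size
    out = np.full(total_bins, np.nan)
    counts = np.zeros(total_bins, dtype=int)
    complete = np.zeros(total_bins, dtype=bool)
    for b in range(total_bins):
        sel = (bins == b) & np.isfinite(values)
        counts[b] = int(np.sum(sel))
        if counts[b]:
            out[b] = float(np.mean(values[sel]))
        complete[b] = (b + 1) * bin_size <= n_cycles
    if incomplete == "drop":
        keep_b = complete
        out, counts, complete = out[keep_b], counts[keep_b], complete[keep_b]
    return BinSeries(out, counts, complete)
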