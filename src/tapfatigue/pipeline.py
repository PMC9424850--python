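"""End-to-end per-session analysis: recordings in, per-bin index tables out.

For each height the chain computes, per bin: median frequency and %MVC
RMS per deltoid, cocontraction per stage and full cycle, kinematic
variability per sensor (whole-cycle and per-stage), the four
local-dynamic-stability exponents, accuracy score and tapping deviation
per screen, and mean cycle time.
"""
from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import performance as perf
from .core import ACCEL_SENSORS, EMG_CHANNELS, SCREENS, PipelineConfig, TapLog
from .kinematics import kinematic_variability, segment_cycles, time_normalize, time_normalize_stages
from .stability import build_state_space, divergence_curve, estimate_lle
from .synthetic import SessionData

log = logging.getLogger(__name__)

__all__ = ["analyze_height", "analyze_sessions", "write_results", "lle_label"]


def lle_label(h: int, n_phase: int) -> str:
    if h == n_phase // 4:
        return "LLEQ"
    if h == n_phase // 2:
        return "LLEH"
    return f"LLE{h}"


def _stage_intervals(taps: TapLog) -> np.ndarray:
    """(n_cycles, 5, 2) intervals: ST1..ST4 and the full cycle; NaN if malformed."""
    ts1 = taps.ts1_times()
    n_cycles = ts1.size - 1
    out = np.full((n_cycles, 5, 2), np.nan)
    for i in range(n_cycles):
        sel = (taps.times > ts1[i]) & (taps.times < ts1[i + 1])
        if list(taps.screens[sel]) != ["TS2", "TS3", "TS4"]:
            continue
        edges = np.concatenate(([ts1[i]], taps.times[sel], [ts1[i + 1]]))
        out[i, :4, 0] = edges[:-1]
        out[i, :4, 1] = edges[1:]
        out[i, 4] = (ts1[i], ts1[i + 1])
    return out


def _timed(name: str, t0: float, shape) -> float:
    t1 = time.perf_counter()
    log.info("%s: input %s, %.2fs", name, shape, t1 - t0)
    return t1


def analyze_height(sess: SessionData, cfg: PipelineConfig | None = None) -> dict:
    """Full analysis of one height's recordings.

    Returns ``{"bins": DataFrame(index, bin, value),
    "variance_fractions": (3,) array}`` with 1-based bin numbers.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    rows: list[tuple[str, int, float]] = []

    def add(name: str, values: np.ndarray) -> None:
        for b, v in enumerate(np.asarray(values, dtype=float), start=1):
            rows.append((name, b, v))

    band = emg_mod.bandpass(sess.emg, *cfg.band, order=cfg.filter_order)
    mvc_band = emg_mod.bandpass(sess.mvc_trial, *cfg.band, order=cfg.filter_order)
    mvc_ref = emg_mod.mvc_reference(mvc_band, cfg.window_s, cfg.overlap)
    t0 = _timed("bandpass+mvc", t0, sess.emg.data.shape)

    taps = sess.taps
    starts = taps.ts1_times()
    bin_kw = dict(cycle_starts=starts, bin_size=cfg.bin_size,
                  n_bins=cfg.n_bins, incomplete=cfg.incomplete_bin)

    pct = {}
    for lab in EMG_CHANNELS:
        x = band.channel(lab)
        rms = emg_mod.moving_rms(x, band.fs, cfg.window_s, cfg.overlap, band.start_time)
        pct[lab] = emg_mod.percent_mvc(rms, mvc_ref, lab)
        mf = emg_mod.median_frequency(x, band.fs, cfg.window_s, cfg.overlap, band.start_time)
        add(f"RMS_{lab}", emg_mod.bin_series(pct[lab].values, times=pct[lab].times, **bin_kw).values)
        add(f"MF_{lab}", emg_mod.bin_series(mf.values, times=mf.times, **bin_kw).values)
    t0 = _timed("emg windows", t0, band.data.shape)

    intervals = _stage_intervals(taps)
    stage_names = ("CCI_ST1", "CCI_ST2", "CCI_ST3", "CCI_ST4", "CCI_ALL")
    for si, name in enumerate(stage_names):
        vals = emg_mod.cci_series_interval(pct["ANT"], pct["POS"], intervals[:, si, :])
        bs = emg_mod.bin_series(vals, cycles=np.arange(vals.size), bin_size=cfg.bin_size,
                                n_bins=cfg.n_bins, incomplete=cfg.incomplete_bin)
        add(name, bs.values)
    t0 = _timed("cci", t0, intervals.shape)

    cs = segment_cycles(sess.accel, taps)
    ncs = time_normalize(cs, cfg.n_phase)
    cyc_bins = np.where(ncs.cycle_index // cfg.bin_size < cfg.n_bins,
                        ncs.cycle_index // cfg.bin_size, -1)
    kv = kinematic_variability(ncs, cyc_bins)
    n_bins_present = kv["bins"].size
    for si, sensor in enumerate(ACCEL_SENSORS):
        add(f"KV_{sensor}", kv["sensor"][:, si])
    ncs_st = time_normalize_stages(cs, cfg.stage_phase)
    for st in range(4):
        sub = ncs_st.tensor[:, st * cfg.stage_phase:(st + 1) * cfg.stage_phase, :]
        kv_st = kinematic_variability(
            type(ncs_st)(sub, ncs_st.labels, ncs_st.cycle_index), cyc_bins)
        for si, sensor in enumerate(ACCEL_SENSORS):
            add(f"KV_{sensor}_ST{st + 1}", kv_st["sensor"][:, si])
    t0 = _timed("kinematic variability", t0, ncs.tensor.shape)

    space = build_state_space(ncs)
    lle = {h: np.full(n_bins_present, np.nan) for h in cfg.lle_horizons}
    sample_bins = np.repeat(cyc_bins, cfg.n_phase)
    for bi, b in enumerate(kv["bins"]):
        sc = space.scores[sample_bins == b]
        try:
            curve = divergence_curve(
                sc, theiler=cfg.theiler, K=cfg.curve_k,
                segment_len=cfg.n_phase if cfg.confine_to_cycles else None)
        except ValueError as e:
            log.warning("bin %d: divergence curve failed (%s)", b, e)
            continue
        est = estimate_lle(curve, cfg.lle_horizons)
        for h in cfg.lle_horizons:
            lle[h][bi] = est[h]
    for h in cfg.lle_horizons:
        add(lle_label(h, cfg.n_phase), lle[h])
    t0 = _timed("local dynamic stability", t0, space.scores.shape)

    for s, vals in perf.as_table(taps, cfg.circle, cfg.bin_size, cfg.n_bins,
                                 cfg.incomplete_bin).items():
        add(f"AS_{s}", vals)
    for s, vals in perf.td_table(taps, cfg.circle, cfg.bin_size, cfg.n_bins,
                                 cfg.td_mode).items():
        add(f"TD_{s}", vals)
    add("TIME", perf.time_table(taps, cfg.bin_size, cfg.n_bins, cfg.incomplete_bin))
    _timed("performance", t0, (len(taps),))

    bins_df = pd.DataFrame(rows, columns=["index", "bin", "value"])
    return {"bins": bins_df, "variance_fractions": space.variance_fractions}


def analyze_sessions(sessions: dict[str, SessionData],
                     cfg: PipelineConfig | None = None) -> dict:
    """Analyze every height; returns combined long tables."""
    cfg = cfg or PipelineConfig()
    frames = []
    var_rows = []
    for height, sess in sessions.items():
        res = analyze_height(sess, cfg)
        df = res["bins"].copy()
        df.insert(0, "height", height)
        frames.append(df)
        var_rows.append({"height": height,
                         **{f"PC{i + 1}": v for i, v in enumerate(res["variance_fractions"])}})
    return {"bins": pd.concat(frames, ignore_index=True),
            "variance_fractions": pd.DataFrame(var_rows)}


def write_results(results: dict, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["bins"].to_csv(out / "bins.csv", index=False)
    results["variance_fractions"].to_csv(out / "variance_fractions.csv", index=False)
    return out
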