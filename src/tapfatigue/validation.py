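"""Parameter-recovery and calibration experiments.

Each function generates synthetic data with a known planted value, runs
the corresponding slice of the analysis chain, and returns both the
planted and the recovered quantity.  These experiments are what make
the pipeline trustworthy: if the chain cannot recover what was planted,
it cannot be trusted on recordings.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import emg as em
from . import synthetic as syn
from .core import EmgRecording, PipelineConfig, SCREENS
from .kinematics import kinematic_variability, segment_cycles, time_normalize
from .performance import tapping_deviation
from .pipeline import analyze_sessions
from .stability import build_state_space, divergence_curve, estimate_lle
from .stats import followup_bonferroni, paired_height_test, rm_anova_periods, to_ratio

__all__ = [
    "recover_lambda5", "recover_median_frequency", "recover_kinematic_variability",
    "recover_tapping_deviation", "paired_t_type1", "anova_gate_type1",
    "directional_session_check", "closed_form_checks",
]


def recover_lambda5(seed: int = 0, gamma: float = 0.05, n_cycles: int = 400,
                    cfg: PipelineConfig | None = None) -> dict:
    """Estimate lambda5 per bin on a session with a planted exponent."""
    cfg = cfg or PipelineConfig()
    scfg = syn.recovery_lle_config(seed=seed, gamma=gamma, n_cycles=n_cycles)
    taps = syn.generate_taps(scfg, "LOW")
    accel, gt = syn.generate_accel_session(scfg, "LOW", taps)
    ncs = time_normalize(segment_cycles(accel, taps), cfg.n_phase)
    space = build_state_space(ncs)
    lams = []
    for b in range(n_cycles // cfg.bin_size):
        sc = space.scores[b * cfg.bin_size * cfg.n_phase:(b + 1) * cfg.bin_size * cfg.n_phase]
        curve = divergence_curve(sc, theiler=cfg.theiler, K=cfg.curve_k,
                                 segment_len=cfg.n_phase)
        lams.append(estimate_lle(curve, cfg.lle_horizons)[5])
    lam5 = float(np.mean(lams))
    return {"planted_gamma": gamma, "lambda5": lam5, "lambda5_per_bin": np.array(lams),
            "rel_err": abs(lam5 / gamma - 1.0)}


def recover_median_frequency(seed: int = 0, n_cycles: int = 400,
                             mf_start: float = 80.0, mf_end: float = 70.0,
                             cfg: PipelineConfig | None = None) -> dict:
    """Per-bin MF estimates against the planted declining trajectory."""
    cfg = cfg or PipelineConfig()
    scfg = syn.recovery_kv_config(seed=seed, n_cycles=n_cycles)
    taps = syn.generate_taps(scfg, "LOW")
    starts = taps.ts1_times()
    total = float(starts[-1])
    rng = np.random.default_rng([seed, 77])
    x = syn.generate_emg_channel(total + 0.25, scfg.fs_emg, (mf_start, mf_end),
                                 1.0, seed=rng)
    rec = EmgRecording(x[:, None], scfg.fs_emg, labels=("ANT",))
    band = em.bandpass(rec, *cfg.band, order=cfg.filter_order)
    mf = em.median_frequency(band.channel("ANT"), band.fs, cfg.window_s, cfg.overlap)
    bs = em.bin_series(mf.values, times=mf.times, cycle_starts=starts,
                       bin_size=cfg.bin_size, n_bins=cfg.n_bins)
    mids = (starts[:-1:cfg.bin_size] + starts[cfg.bin_size::cfg.bin_size]) / 2.0
    planted = mf_start + (mf_end - mf_start) * mids / total
    rel_err = np.abs(bs.values / planted - 1.0)
    return {"planted": planted, "estimated": bs.values, "max_rel_err": float(rel_err.max())}


def recover_kinematic_variability(seed: int = 0, kv_sigma: float = 0.2,
                                  n_cycles: int = 400,
                                  cfg: PipelineConfig | None = None) -> dict:
    """Per-bin KV against the planted per-axis noise level."""
    cfg = cfg or PipelineConfig()
    scfg = syn.recovery_kv_config(seed=seed, kv_sigma=kv_sigma, n_cycles=n_cycles)
    taps = syn.generate_taps(scfg, "LOW")
    accel, _ = syn.generate_accel_session(scfg, "LOW", taps)
    ncs = time_normalize(segment_cycles(accel, taps), cfg.n_phase)
    bins = np.minimum(ncs.cycle_index // cfg.bin_size, cfg.n_bins - 1)
    kv = kinematic_variability(ncs, bins)
    axis_kv = float(kv["axis"].mean())
    sensor_kv = float(kv["sensor"].mean())
    return {
        "planted_sigma": kv_sigma,
        "axis_kv": axis_kv, "axis_rel_err": abs(axis_kv / kv_sigma - 1.0),
        "sensor_kv": sensor_kv,
        "sensor_rel_err": abs(sensor_kv / (kv_sigma * np.sqrt(3)) - 1.0),
    }


def recover_tapping_deviation(seed: int = 0, sigma_mm: float = 1.2,
                              n_cycles: int = 400) -> dict:
    """TD of each screen's 400 taps against sigma * sqrt(pi/2)."""
    scfg = syn.recovery_kv_config(seed=seed, n_cycles=n_cycles)
    import dataclasses
    hp = dataclasses.replace(scfg.low, tap_sigma_mm=sigma_mm)
    scfg = syn.SyntheticSessionConfig(seed=seed, n_cycles=n_cycles, low=hp, high=hp)
    taps = syn.generate_taps(scfg, "LOW")
    expected = sigma_mm * np.sqrt(np.pi / 2.0)
    tds = np.array([
        tapping_deviation(taps.x[taps.screens == s], taps.y[taps.screens == s], scfg.circle)
        for s in SCREENS])
    td = float(tds.mean())
    return {"expected": expected, "td_per_screen": tds, "td": td,
            "rel_err": abs(td / expected - 1.0)}


def paired_t_type1(seed: int = 0, reps: int = 1000, n_pairs: int = 180,
                   alpha: float = 0.05) -> float:
    """Empirical type-I error of the paired height t-test under the null."""
    rng = np.random.default_rng([seed, 501])
    a = rng.standard_normal((reps, n_pairs))
    b = rng.standard_normal((reps, n_pairs))
    _, p = sps.ttest_rel(a, b, axis=1)
    return float(np.mean(p < alpha))


def anova_gate_type1(seed: int = 0, reps: int = 1000, n_subjects: int = 18,
                     alpha: float = 0.05) -> dict:
    """Calibration of the gated follow-up procedure under the global null.

    Returns the ANOVA gate's rejection rate (nominal alpha) and the
    family-wise rate of the full procedure (gate + any Bonferroni
    follow-up), which the gating keeps at or below alpha.
    """
    rng = np.random.default_rng([seed, 502])
    gate = 0
    family = 0
    for _ in range(reps):
        wide = rng.standard_normal((n_subjects, 5))
        res = rm_anova_periods(wide, alpha)
        if res.significant:
            gate += 1
            if any(r.significant for r in followup_bonferroni(wide, alpha)):
                family += 1
    return {"anova_rate": gate / reps, "familywise_rate": family / reps}


def directional_session_check(seed: int = 0, n_cycles: int = 400,
                              cfg: PipelineConfig | None = None) -> dict:
    """Run the full two-height pipeline and compare normalized indices.

    Under the study conditions the HIGH worktable plants faster fatigue,
    higher activation, larger tap scatter and faster cycles; the
    returned signed differences (mean HIGH ratio minus mean LOW ratio)
    must reproduce that pattern: MF and AS and TIME negative, RMS and TD
    positive.
    """
    cfg = cfg or PipelineConfig()
    dataset = syn.generate_session(syn.default_config(seed=seed, n_cycles=n_cycles))
    results = analyze_sessions(dataset.sessions, cfg)
    table = results["bins"].copy()
    table.insert(0, "participant", "P01")
    ratios = to_ratio(table)

    def mean_diff(prefix: str) -> float:
        sub = ratios[ratios["index"].str.match(prefix)]
        wide = sub.pivot_table(index=["index", "bin"], columns="height", values="value")
        return float((wide["HIGH"] - wide["LOW"]).mean())

    diffs = {
        "mf": mean_diff(r"MF_"),
        "rms": mean_diff(r"RMS_"),
        "as": mean_diff(r"AS_"),
        "td": mean_diff(r"TD_"),
        "time": mean_diff(r"TIME"),
    }
    diffs["pattern_ok"] = (diffs["mf"] < 0 and diffs["rms"] > 0 and
                           diffs["as"] < 0 and diffs["td"] > 0 and diffs["time"] < 0)
    diffs["bins"] = table
    diffs["variance_fractions"] = results["variance_fractions"]
    return diffs


def closed_form_checks(seed: int = 0) -> dict:
    """Closed-form identities of the elementary estimators."""
    fs = 1926.0
    # moving RMS of a sine with an integer number of periods per window
    f = 8 * fs / 240
    t = np.arange(int(4 * fs)) / fs
    amp = 2.0
    rms = em.moving_rms(amp * np.sin(2 * np.pi * f * t), fs)
    rms_ratio = float(np.mean(rms.values) / (amp / np.sqrt(2.0)))
    # MF of flat-band [10, 190] noise
    x = syn.generate_emg_channel(40.0, fs, 100.0, 1.0, seed=np.random.default_rng([seed, 601]),
                                 band_halfwidth=90.0)
    mf = float(np.nanmean(em.median_frequency(x, fs).values[5:-5]))
    # CCI of equal constants
    times = np.arange(9) * 0.0625
    from .core import WindowedSeries
    const = WindowedSeries(times, np.full(9, 3.0), 0.125, 0.5)
    cci_equal = em.cci(const, const, (0.0, 0.5))
    # AS at center and at the rim
    from .core import CircleSpec
    from .performance import accuracy_score
    circle = CircleSpec()
    # corrected level actually applied by the follow-up procedure
    followups = followup_bonferroni(np.zeros((3, 5)) + np.arange(3)[:, None],
                                    alpha=0.05, m=4)
    return {
        "rms_sine_ratio": rms_ratio,
        "mf_flat_band_hz": mf,
        "cci_equal_constants": float(cci_equal),
        "as_center": float(accuracy_score(*circle.center, circle)),
        "as_rim": float(accuracy_score(circle.center[0] + circle.radius_px,
                                       circle.center[1], circle)),
        "circle_diameter_mm": circle.diameter_mm,
        "pixel_pitch_mm": circle.diameter_mm / (2 * circle.radius_px),
        "bonferroni_alpha": followups[0].alpha,
    }
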