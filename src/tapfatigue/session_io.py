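"""On-disk session layout: plain CSV signals plus YAML metadata.

A session directory holds one subdirectory per height::

    session/
      session.yml          sample rates, cycle count, seed
      ground_truth.yml     planted generator values (synthetic sessions)
      low/  emg.csv  mvc.csv  accel.csv  taps.csv
      high/ ...

All tables are column-oriented CSV with a one-line header; timestamps
are seconds as decimals; the pixel origin is top-left with x rightward
and y downward.  Readers validate schema and reject malformed input
rather than coercing it; valid data round-trips identically.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ACCEL_CHANNELS,
    EMG_CHANNELS,
    AccelRecording,
    EmgRecording,
    SchemaError,
    TapLog,
)
from .synthetic import (
    HeightParams,
    MuscleParams,
    SessionData,
    SyntheticDataset,
    SyntheticSessionConfig,
)

log = logging.getLogger(__name__)

__all__ = ["write_session", "read_session", "read_dataset",
           "synthetic_config_to_dict", "synthetic_config_from_dict",
           "load_synthetic_config"]

_FLOAT_FMT = "%.17g"  # full double precision for exact round-trips


def _write_signal(path: Path, data: np.ndarray, fs: float, labels, start_time: float) -> None:
    t = start_time + np.arange(data.shape[0]) / fs
    df = pd.DataFrame({"t": t})
    for i, lab in enumerate(labels):
        df[lab] = data[:, i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"{path}: file missing")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _read_signal(path: Path, labels, fs: float) -> np.ndarray:
    df = _read_csv(path)
    missing = [lab for lab in ("t", *labels) if lab not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError(f"{path}: non-increasing timestamp at row {int(bad[0]) + 2}")
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
        raise SchemaError(f"{path}: sample spacing does not match fs={fs} Hz from session.yml")
    return df[list(labels)].to_numpy(dtype=float)


def _read_taps(path: Path) -> TapLog:
    df = _read_csv(path)
    missing = [c for c in ("screen", "t", "x", "y") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    try:
        return TapLog(df["screen"].to_numpy(dtype=object), df["t"].to_numpy(dtype=float),
                      df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float))
    except SchemaError as e:
        raise SchemaError(f"{path}: {e}") from None


def synthetic_config_to_dict(cfg: SyntheticSessionConfig) -> dict:
    d = {
        "seed": cfg.seed, "n_cycles": cfg.n_cycles, "fs_emg": cfg.fs_emg,
        "fs_accel": cfg.fs_accel, "mixing_matrix_seed": cfg.mixing_matrix_seed,
        "mvc_rms": cfg.mvc_rms, "mvc_duration": cfg.mvc_duration,
        "band_halfwidth": cfg.band_halfwidth,
    }
    for name, hp in (("low", cfg.low), ("high", cfg.high)):
        hd = dataclasses.asdict(hp)
        hd["tap_bias_mm"] = list(hp.tap_bias_mm)
        hd["muscles"] = {m: dataclasses.asdict(mp) for m, mp in hp.muscles.items()}
        d[name] = hd
    return d


def synthetic_config_from_dict(d: dict) -> SyntheticSessionConfig:
    """Build a generator config from a (possibly partial) mapping.

    Unspecified keys keep the study-condition defaults.
    """
    d = dict(d or {})
    heights = {}
    for name, default in (("low", SyntheticSessionConfig().low),
                          ("high", SyntheticSessionConfig().high)):
        hd = dict(d.pop(name, {}) or {})
        muscles = dict(default.muscles)
        for m, mp in (hd.pop("muscles", {}) or {}).items():
            m = m.upper()
            base = dataclasses.asdict(muscles.get(m, MuscleParams(80, 78, 0.1)))
            base.update(mp)
            muscles[m] = MuscleParams(**base)
        base = {f.name: getattr(default, f.name) for f in dataclasses.fields(HeightParams)
                if f.name != "muscles"}
        unknown = set(hd) - set(base)
        if unknown:
            raise SchemaError(f"unknown height config key(s): {sorted(unknown)}")
        base.update(hd)
        if "tap_bias_mm" in base:
            base["tap_bias_mm"] = tuple(base["tap_bias_mm"])
        heights[name] = HeightParams(muscles=muscles, **base)
    known = {f.name for f in dataclasses.fields(SyntheticSessionConfig)} - {"low", "high", "circle"}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    return SyntheticSessionConfig(low=heights["low"], high=heights["high"], **d)


def load_synthetic_config(path: str | Path) -> SyntheticSessionConfig:
    with open(path) as fh:
        return synthetic_config_from_dict(yaml.safe_load(fh))


def write_session(dataset: SyntheticDataset, path: str | Path) -> Path:
    """Write a generated dataset to the session layout; returns the path."""
    root = Path(path)
    try:
        root.mkdir(parents=True, exist_ok=True)
        cfg = dataset.config
        with open(root / "session.yml", "w") as fh:
            yaml.safe_dump(synthetic_config_to_dict(cfg), fh, sort_keys=False)
        gt_doc = {}
        for height, gt in dataset.ground_truth.items():
            gt_doc[height] = {
                "rms_pct": {k: float(v) for k, v in gt.rms_pct.items()},
                "cci_full": float(gt.cci_full),
                "tap_sigma_mm": float(gt.tap_sigma_mm),
                "tap_bias_mm": [float(v) for v in gt.tap_bias_mm],
                "kv_sigma": float(gt.kv_sigma),
                "gamma": float(gt.gamma),
                "pert_amp": float(gt.pert_amp),
                "mf_bins": gt.mf_bins.round(6).tolist(),
                "mf_channels": list(EMG_CHANNELS),
            }
        with open(root / "ground_truth.yml", "w") as fh:
            yaml.safe_dump(gt_doc, fh, sort_keys=False)
        for height, sess in dataset.sessions.items():
            hdir = root / height.lower()
            hdir.mkdir(exist_ok=True)
            _write_signal(hdir / "emg.csv", sess.emg.data, sess.emg.fs,
                          EMG_CHANNELS, sess.emg.start_time)
            _write_signal(hdir / "mvc.csv", sess.mvc_trial.data, sess.mvc_trial.fs,
                          EMG_CHANNELS, sess.mvc_trial.start_time)
            _write_signal(hdir / "accel.csv", sess.accel.data, sess.accel.fs,
                          ACCEL_CHANNELS, sess.accel.start_time)
            taps = sess.taps
            pd.DataFrame({"screen": taps.screens, "t": taps.times,
                          "x": taps.x, "y": taps.y}).to_csv(
                hdir / "taps.csv", index=False, float_format=_FLOAT_FMT)
            log.info("wrote %s session to %s", height, hdir)
    except OSError as e:
        raise OSError(f"failed writing session under {root}: {e}") from e
    return root


def _session_meta(root: Path) -> dict:
    meta_path = root / "session.yml"
    if not meta_path.exists():
        raise SchemaError(f"{meta_path}: file missing")
    with open(meta_path) as fh:
        return yaml.safe_load(fh) or {}


def read_session(path: str | Path, height: str) -> SessionData:
    """Read one height's recordings; validates schema and invariants."""
    root = Path(path)
    meta = _session_meta(root)
    fs_emg = float(meta.get("fs_emg", 1926.0))
    fs_accel = float(meta.get("fs_accel", 100.0))
    hdir = root / height.lower()
    if not hdir.is_dir():
        raise SchemaError(f"{hdir}: height directory missing")
    emg = EmgRecording(_read_signal(hdir / "emg.csv", EMG_CHANNELS, fs_emg), fs_emg)
    mvc = EmgRecording(_read_signal(hdir / "mvc.csv", EMG_CHANNELS, fs_emg), fs_emg)
    accel = AccelRecording(_read_signal(hdir / "accel.csv", ACCEL_CHANNELS, fs_accel), fs_accel)
    taps = _read_taps(hdir / "taps.csv")
    log.info("read %s session from %s: emg %s, accel %s, %d taps",
             height, hdir, emg.data.shape, accel.data.shape, len(taps))
    return SessionData(emg=emg, mvc_trial=mvc, accel=accel, taps=taps)


def read_dataset(path: str | Path) -> tuple[dict[str, SessionData], SyntheticSessionConfig]:
    """Read every height present under a session directory."""
    root = Path(path)
    cfg = synthetic_config_from_dict(_session_meta(root))
    sessions = {}
    for height in ("LOW", "HIGH"):
        if (root / height.lower()).is_dir():
            sessions[height] = read_session(root, height)
    if not sessions:
        raise SchemaError(f"{root}: no low/ or high/ session directories found")
    return sessions, cfg
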