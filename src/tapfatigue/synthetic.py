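"""Synthetic two-height tapping sessions with planted ground truth.

Every downstream index has a knob whose value the analysis chain must
recover:

* EMG: Gaussian noise shaped, in short overlap-added segments, by a flat
  band-pass whose midpoint tracks the target median frequency -- the MF
  of a flat band is analytically its midpoint -- then amplitude-scaled
  so the windowed RMS matches the target %MVC level.  A linear MF
  profile emulates spectral compression under fatigue.
* Acceleration: 9 channels = (9 x 3 mixing matrix) @ latent(t) + noise.
  The latent is a 3-D cyclic template (an ellipse-like closed curve, so
  distinct phases never come close in state space) plus a per-cycle
  re-seeded perturbation whose log-magnitude grows at the configured
  divergence rate within each cycle, giving an exact planted Lyapunov
  exponent.  The additive noise is smooth (low-passed) with an exact
  per-sample standard deviation, so the kinematic-variability estimate
  converges to the configured sigma despite cycle-length resampling.
* Taps: bivariate normal scatter (configured sigma, bias) around each
  circle center; cycle durations follow a linear trend.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    ACCEL_CHANNELS,
    EMG_CHANNELS,
    SCREENS,
    AccelRecording,
    CircleSpec,
    EmgRecording,
    MvcReference,
    TapLog,
)

__all__ = [
    "MuscleParams", "HeightParams", "SyntheticSessionConfig",
    "HeightGroundTruth", "SessionData", "SyntheticDataset",
    "generate_emg_channel", "generate_taps", "generate_accel_session",
    "generate_session", "default_config", "recovery_lle_config",
    "recovery_kv_config", "cyclic_template",
]

# Latent template amplitudes (m/s^2).  The first two harmonics trace an
# ellipse, which keeps every pair of distinct phases separated in state
# space (no self-intersections), so nearest neighbors are phase-aligned.
_TEMPLATE_AMP = (3.6, 3.0, 1.5)


@dataclass(frozen=True)
class MuscleParams:
    """Planted EMG behavior of one muscle at one height."""

    mf_start: float  # Hz, session start
    mf_end: float  # Hz, session end
    rms_level: float  # fraction of MVC

    def validate(self, fs_emg: float) -> None:
        for v in (self.mf_start, self.mf_end):
            if not 10.0 < v < fs_emg / 2.0:
                raise ValueError(f"median frequency {v} Hz outside (10, fs/2) at fs={fs_emg}")
        if self.rms_level <= 0:
            raise ValueError("rms_level must be positive")


@dataclass(frozen=True)
class HeightParams:
    """All planted conditions for one worktable height."""

    muscles: dict[str, MuscleParams]
    tap_sigma_mm: float = 1.2
    tap_bias_mm: tuple[float, float] = (0.0, 0.0)
    cycle_duration_start: float = 2.2  # s
    cycle_duration_end: float = 2.0
    kv_noise_sigma: float = 0.15  # m/s^2 per channel
    divergence_gamma: float = 0.03  # ln-divergence per normalized sample
    pert_amp: float = 0.01  # m/s^2, perturbation magnitude at cycle start

    def validate(self, fs_emg: float) -> None:
        if set(self.muscles) != set(EMG_CHANNELS):
            raise ValueError(f"muscles must cover {EMG_CHANNELS}")
        for m in self.muscles.values():
            m.validate(fs_emg)
        if self.tap_sigma_mm < 0:
            raise ValueError("tap_sigma_mm must be >= 0")
        if min(self.cycle_duration_start, self.cycle_duration_end) <= 0:
            raise ValueError("cycle durations must be positive")
        if self.kv_noise_sigma < 0:
            raise ValueError("kv_noise_sigma must be >= 0")
        if self.pert_amp < 0:
            raise ValueError("pert_amp must be >= 0")
        # divergence_gamma may be negative (contracting perturbations)

    def durations(self, n_cycles: int) -> np.ndarray:
        return np.linspace(self.cycle_duration_start, self.cycle_duration_end, n_cycles)


@dataclass(frozen=True)
class SyntheticSessionConfig:
    seed: int = 0
    n_cycles: int = 400
    fs_emg: float = 1926.0
    fs_accel: float = 100.0
    mixing_matrix_seed: int = 20220816
    mvc_rms: float = 1.0  # amplitude units; MVC trial level
    mvc_duration: float = 5.0  # s
    band_halfwidth: float = 90.0  # Hz, EMG synthesis band half-width
    circle: CircleSpec = field(default_factory=CircleSpec)
    low: HeightParams = field(default_factory=lambda: _DEFAULT_LOW)
    high: HeightParams = field(default_factory=lambda: _DEFAULT_HIGH)

    def __post_init__(self) -> None:
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if self.mvc_rms <= 0:
            raise ValueError("mvc_rms must be positive")
        self.low.validate(self.fs_emg)
        self.high.validate(self.fs_emg)

    def height(self, name: str) -> HeightParams:
        try:
            return {"LOW": self.low, "HIGH": self.high}[name.upper()]
        except KeyError:
            raise ValueError(f"height must be LOW or HIGH, got {name!r}") from None


# Study conditions: at the HIGH worktable the deltoids fatigue faster
# (steeper MF decline), work harder (higher %MVC with more antagonist
# coactivation), taps scatter more, and cycles run slightly faster.
_DEFAULT_LOW = HeightParams(
    muscles={
        "ANT": MuscleParams(80.0, 77.0, 0.10),
        "MED": MuscleParams(78.0, 76.0, 0.09),
        "POS": MuscleParams(82.0, 80.0, 0.05),
    },
    tap_sigma_mm=1.2, tap_bias_mm=(0.2, -0.1),
    cycle_duration_start=2.2, cycle_duration_end=2.0,
    kv_noise_sigma=0.15, divergence_gamma=0.03, pert_amp=0.01,
)
_DEFAULT_HIGH = HeightParams(
    muscles={
        "ANT": MuscleParams(80.0, 70.0, 0.14),
        "MED": MuscleParams(78.0, 70.0, 0.13),
        "POS": MuscleParams(82.0, 76.0, 0.08),
    },
    tap_sigma_mm=1.7, tap_bias_mm=(0.4, -0.2),
    cycle_duration_start=2.05, cycle_duration_end=1.95,
    kv_noise_sigma=0.22, divergence_gamma=0.035, pert_amp=0.01,
)


def default_config(seed: int = 0, n_cycles: int = 400) -> SyntheticSessionConfig:
    """The two-height study conditions."""
    return SyntheticSessionConfig(seed=seed, n_cycles=n_cycles)


def recovery_lle_config(seed: int = 0, gamma: float = 0.05,
                        n_cycles: int = 400) -> SyntheticSessionConfig:
    """Validation design isolating the planted divergence exponent.

    Sensor noise is made negligible so nearest-neighbor distances are
    dominated by the exponentially growing perturbation pairs.
    """
    hp = HeightParams(
        muscles=_DEFAULT_LOW.muscles,
        tap_sigma_mm=1.2,
        cycle_duration_start=2.0, cycle_duration_end=2.0,
        kv_noise_sigma=2e-4, divergence_gamma=gamma, pert_amp=0.01,
    )
    return SyntheticSessionConfig(seed=seed, n_cycles=n_cycles, low=hp, high=hp)


def recovery_kv_config(seed: int = 0, kv_sigma: float = 0.2,
                       n_cycles: int = 400) -> SyntheticSessionConfig:
    """Validation design isolating the planted variability (perturbation off)."""
    hp = HeightParams(
        muscles=_DEFAULT_LOW.muscles,
        tap_sigma_mm=1.2,
        cycle_duration_start=2.0, cycle_duration_end=2.0,
        kv_noise_sigma=kv_sigma, divergence_gamma=0.0, pert_amp=0.0,
    )
    return SyntheticSessionConfig(seed=seed, n_cycles=n_cycles, low=hp, high=hp)


@dataclass
class HeightGroundTruth:
    """Planted values for one height, on the scales the pipeline reports."""

    mf_bins: np.ndarray  # (n_bins, 3) Hz, muscle order = EMG_CHANNELS
    rms_pct: dict[str, float]  # %MVC per muscle
    cci_full: float  # % planted cocontraction (ANT vs POS)
    tap_sigma_mm: float
    tap_bias_mm: tuple[float, float]
    durations: np.ndarray  # (n_cycles,) s
    kv_sigma: float  # m/s^2 per axis
    gamma: float  # per normalized sample
    pert_amp: float
    pert_dirs: np.ndarray  # (n_cycles, 3) unit perturbation directions

    def latent_perturbation(self, phase_samples: np.ndarray) -> np.ndarray:
        """Planted perturbation (n_cycles, len(phase), 3) at the given
        within-cycle phase samples (0..100)."""
        growth = self.pert_amp * np.exp(self.gamma * np.asarray(phase_samples, float))
        return growth[None, :, None] * self.pert_dirs[:, None, :]


@dataclass
class SessionData:
    """One height's recordings: task EMG, MVC trial, accelerations, taps."""

    emg: EmgRecording
    mvc_trial: EmgRecording
    accel: AccelRecording
    taps: TapLog


@dataclass
class SyntheticDataset:
    config: SyntheticSessionConfig
    sessions: dict[str, SessionData]  # keys LOW, HIGH
    ground_truth: dict[str, HeightGroundTruth]


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(list(keys))


def _profile(target, duration: float):
    """Normalize a scalar / (start, end) pair / callable into f(t)."""
    if callable(target):
        return target
    if np.isscalar(target):
        return lambda t: np.full_like(np.asarray(t, float), float(target))
    start, end = target
    return lambda t: start + (end - start) * np.asarray(t, float) / duration


def generate_emg_channel(duration: float, fs: float, mf_profile, rms_profile,
                         seed, window_s: float = 0.125, overlap: float = 0.5,
                         band_halfwidth: float = 90.0) -> np.ndarray:
    """One synthetic EMG channel whose windowed MF and RMS track targets.

    ``mf_profile`` / ``rms_profile`` may be scalars, (start, end) pairs
    interpreted linearly over ``duration``, or callables of time.  The
    signal is built from white noise shaped by a flat pass-band centered
    on the target MF (half-width ``band_halfwidth`` Hz, shrunk near the
    10 Hz floor or the Nyquist ceiling to stay symmetric), then each
    stride-length chunk is rescaled so windowed RMS matches the target.

    Analyzed at matching window settings, windowed MF lands within +-5%
    of the profile and windowed RMS within +-3%, away from record edges.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    mf = _profile(mf_profile, duration)
    rms = _profile(rms_profile, duration)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nyq = fs / 2.0

    # overlap-add spectral synthesis in 0.5 s Hann segments; a one-segment
    # guard at each end is synthesized and trimmed so the OLA taper never
    # reaches the returned samples
    nseg = int(0.5 * fs)
    nseg -= nseg % 2
    hop = nseg // 2
    freqs = np.fft.rfftfreq(nseg, 1.0 / fs)
    win = signal.get_window("hann", nseg, fftbins=True)
    pad = nseg
    x = np.zeros(n + 2 * pad + nseg)
    for start in range(0, n + 2 * pad, hop):
        t_c = float(np.clip((start - pad + nseg / 2.0) / fs, 0.0, duration))
        m = float(mf(t_c))
        if not 10.0 < m < nyq:
            raise ValueError(
                f"target median frequency {m:.1f} Hz at t={t_c:.2f}s outside the "
                f"Nyquist-safe band (10, {nyq:.0f}) Hz"
            )
        hw = min(band_halfwidth, m - 10.0, 0.97 * nyq - m)
        if hw <= 1.0:
            raise ValueError(
                f"target median frequency {m:.1f} Hz leaves no room for a symmetric "
                f"pass-band below the Nyquist frequency {nyq:.0f} Hz"
            )
        mask = (freqs >= m - hw) & (freqs <= m + hw)
        spectrum = np.zeros(freqs.size, dtype=complex)
        k = int(mask.sum())
        spectrum[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
        x[start:start + nseg] += np.fft.irfft(spectrum, nseg) * win
    x = x[pad:pad + n]

    # exact windowed-RMS control: rescale each stride-length chunk
    nper = int(window_s * fs)
    stride = max(int(round(nper * (1.0 - overlap))), 1)
    for start in range(0, n, stride):
        chunk = x[start:start + stride]
        target = float(rms(min((start + stride / 2.0) / fs, duration)))
        actual = np.sqrt(np.mean(chunk ** 2))
        chunk *= target / actual if actual > 0 else 0.0
    return x


def _emg_recording(cfg: SyntheticSessionConfig, hp: HeightParams, total: float,
                   height_key: int) -> EmgRecording:
    duration = total + 0.25
    chans = []
    for ci, lab in enumerate(EMG_CHANNELS):
        mp = hp.muscles[lab]
        rng = _rng(cfg.seed, height_key, 10 + ci)
        chans.append(generate_emg_channel(
            duration, cfg.fs_emg,
            mf_profile=(mp.mf_start, mp.mf_end),
            rms_profile=mp.rms_level * cfg.mvc_rms,
            seed=rng, band_halfwidth=cfg.band_halfwidth))
    return EmgRecording(np.column_stack(chans), cfg.fs_emg)


def _mvc_recording(cfg: SyntheticSessionConfig, hp: HeightParams,
                   height_key: int) -> EmgRecording:
    chans = []
    for ci, lab in enumerate(EMG_CHANNELS):
        mp = hp.muscles[lab]
        rng = _rng(cfg.seed, height_key, 20 + ci)
        chans.append(generate_emg_channel(
            cfg.mvc_duration, cfg.fs_emg,
            mf_profile=(mp.mf_start + mp.mf_end) / 2.0,
            rms_profile=cfg.mvc_rms,
            seed=rng, band_halfwidth=cfg.band_halfwidth))
    return EmgRecording(np.column_stack(chans), cfg.fs_emg)


def generate_taps(cfg: SyntheticSessionConfig, height: str = "LOW") -> TapLog:
    """Tap log for one height: 4 events per cycle plus the closing TS1.

    TS1 times follow the configured duration trend; TS2..TS4 fall at the
    quarter points of each cycle.  Tap coordinates are bivariate normal
    (bias, sigma^2 I) around the circle center, in pixels.
    """
    hp = cfg.height(height)
    h_key = 0 if height.upper() == "LOW" else 1
    rng = _rng(cfg.seed, h_key, 30)
    durations = hp.durations(cfg.n_cycles)
    starts = np.concatenate(([0.0], np.cumsum(durations)))
    times = (starts[:-1, None] + durations[:, None] * np.array([0, 0.25, 0.5, 0.75])).ravel()
    times = np.append(times, starts[-1])  # closing TS1
    screens = np.array(list(SCREENS) * cfg.n_cycles + ["TS1"], dtype=object)
    n_taps = times.size
    pitch = cfg.circle.pixel_pitch_mm
    bias_px = np.asarray(hp.tap_bias_mm) / pitch
    sigma_px = hp.tap_sigma_mm / pitch
    cx, cy = cfg.circle.center
    xy = rng.normal(size=(n_taps, 2)) * sigma_px + bias_px
    return TapLog(screens, times, cx + xy[:, 0], cy + xy[:, 1])


def cyclic_template(phase: np.ndarray) -> np.ndarray:
    """3-D latent template at phase in [0, 1); shape (..., 3)."""
    phase = np.asarray(phase, dtype=float)
    a1, a2, a3 = _TEMPLATE_AMP
    return np.stack([
        a1 * np.sin(2 * np.pi * phase),
        a2 * np.cos(2 * np.pi * phase),
        a3 * np.sin(4 * np.pi * phase + 0.8),
    ], axis=-1)


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sigma: float,
                  n_ch: int, cutoff: float = 10.0) -> np.ndarray:
    """Stationary low-passed Gaussian noise with per-sample std sigma.

    Smoothness (cutoff well below fs/2) makes the noise survive linear
    resampling onto the phase grid with its pointwise std intact.
    """
    if sigma == 0:
        return np.zeros((n, n_ch))
    white = rng.standard_normal((n, n_ch))
    sos = signal.butter(2, cutoff, fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, white, axis=0)
    smooth /= smooth.std(axis=0, ddof=0)
    return smooth * sigma


def mixing_matrix(seed: int) -> np.ndarray:
    """9 x 3 latent-to-channel mixing matrix; rejected if rank < 3."""
    m = np.random.default_rng(seed).normal(size=(9, 3)) / np.sqrt(3.0)
    svals = np.linalg.svd(m, compute_uv=False)
    if svals[2] <= svals[0] * 1e-9:
        raise ValueError(f"mixing matrix from seed {seed} has rank < 3; choose another seed")
    return m


def generate_accel_session(cfg: SyntheticSessionConfig, height: str = "LOW",
                           taps: TapLog | None = None
                           ) -> tuple[AccelRecording, HeightGroundTruth]:
    """9-channel acceleration for one height, boundaries aligned with taps."""
    hp = cfg.height(height)
    h_key = 0 if height.upper() == "LOW" else 1
    if taps is None:
        taps = generate_taps(cfg, height)
    ts1 = taps.ts1_times()
    durations = np.diff(ts1)
    total = ts1[-1]
    n = int(np.ceil((total + 0.2) * cfg.fs_accel)) + 1
    t = np.arange(n) / cfg.fs_accel

    cyc = np.clip(np.searchsorted(ts1, t, side="right") - 1, 0, cfg.n_cycles - 1)
    phase = (t - ts1[cyc]) / durations[cyc]  # continuous, may exceed 1 in the tail

    rng = _rng(cfg.seed, h_key, 40)
    dirs = rng.standard_normal((cfg.n_cycles, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    latent = cyclic_template(phase)
    if hp.pert_amp > 0:
        growth = hp.pert_amp * np.exp(hp.divergence_gamma * 100.0 * phase)
        latent = latent + growth[:, None] * dirs[cyc]

    mix = mixing_matrix(cfg.mixing_matrix_seed)
    data = latent @ mix.T
    noise_rng = _rng(cfg.seed, h_key, 41)
    data = data + _smooth_noise(noise_rng, n, cfg.fs_accel, hp.kv_noise_sigma, 9)

    accel = AccelRecording(data, cfg.fs_accel, ACCEL_CHANNELS)
    gt = _ground_truth(cfg, hp, durations, dirs)
    return accel, gt


def _ground_truth(cfg: SyntheticSessionConfig, hp: HeightParams,
                  durations: np.ndarray, dirs: np.ndarray) -> HeightGroundTruth:
    starts = np.concatenate(([0.0], np.cumsum(durations)))
    total = starts[-1]
    n_bins = int(np.ceil(cfg.n_cycles / 40))
    mf_bins = np.empty((n_bins, len(EMG_CHANNELS)))
    for b in range(n_bins):
        c0, c1 = b * 40, min((b + 1) * 40, cfg.n_cycles)
        mid = (starts[c0] + starts[c1]) / 2.0
        for ci, lab in enumerate(EMG_CHANNELS):
            mp = hp.muscles[lab]
            mf_bins[b, ci] = mp.mf_start + (mp.mf_end - mp.mf_start) * mid / total
    ago = hp.muscles["ANT"].rms_level
    ant = hp.muscles["POS"].rms_level
    cci_full = 100.0 * min(ago, ant) / (ago + ant)
    rms_pct = {lab: 100.0 * hp.muscles[lab].rms_level for lab in EMG_CHANNELS}
    return HeightGroundTruth(
        mf_bins=mf_bins, rms_pct=rms_pct, cci_full=cci_full,
        tap_sigma_mm=hp.tap_sigma_mm, tap_bias_mm=hp.tap_bias_mm,
        durations=durations, kv_sigma=hp.kv_noise_sigma,
        gamma=hp.divergence_gamma, pert_amp=hp.pert_amp, pert_dirs=dirs,
    )


def generate_session(cfg: SyntheticSessionConfig) -> SyntheticDataset:
    """Complete LOW + HIGH dataset: EMG, MVC trial, accelerations, taps."""
    sessions: dict[str, SessionData] = {}
    truth: dict[str, HeightGroundTruth] = {}
    for h_key, height in enumerate(("LOW", "HIGH")):
        hp = cfg.height(height)
        taps = generate_taps(cfg, height)
        accel, gt = generate_accel_session(cfg, height, taps)
        total = taps.ts1_times()[-1]
        emg = _emg_recording(cfg, hp, total, h_key)
        mvc = _mvc_recording(cfg, hp, h_key)
        sessions[height] = SessionData(emg=emg, mvc_trial=mvc, accel=accel, taps=taps)
        truth[height] = gt
    return SyntheticDataset(config=cfg, sessions=sessions, ground_truth=truth)
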