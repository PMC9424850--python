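"""EMG conditioning, RMS/MVC, median frequency, CCI and binning."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tapfatigue.core import EmgRecording, MvcReference, WindowedSeries
from tapfatigue import emg as em

FS = 1926.0


def _rec(x):
    return EmgRecording(np.column_stack([x, x, x]), FS)


class TestBandpass:
    def test_dc_offset_removed(self):
        x = np.full(int(FS * 2), 3.7)
        out = em.bandpass(_rec(x)).channel("ANT")
        assert np.max(np.abs(out[500:-500])) < 1e-6

    def test_inband_sine_preserved(self):
        t = np.arange(int(FS * 4)) / FS
        x = np.sin(2 * np.pi * 100 * t)
        out = em.bandpass(_rec(x)).channel("ANT")
        amp = np.max(np.abs(out[2000:-2000]))
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_idempotent_in_passband(self):
        t = np.arange(int(FS * 4)) / FS
        x = np.sin(2 * np.pi * 100 * t)
        once = em.bandpass(_rec(x))
        twice = em.bandpass(once)
        mid = slice(2000, -2000)
        assert np.allclose(twice.channel("ANT")[mid], once.channel("ANT")[mid], atol=0.02)

    def test_rejects_edge_at_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            em.bandpass(_rec(np.zeros(4000)), 10, 963.0)

    def test_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert em.bandpass(_rec(x)).n_samples == 5000


class TestMovingRms:
    def test_constant_gives_abs_value(self):
        ws = em.moving_rms(np.full(2400, -2.5), FS)
        assert np.allclose(ws.values, 2.5)

    def test_sine_gives_a_over_sqrt2(self):
        # window of 240 samples; pick a frequency with an integer number
        # of periods per window: 8 periods -> f = 8 * fs / 240
        f = 8 * FS / 240
        t = np.arange(4800) / FS
        ws = em.moving_rms(3.0 * np.sin(2 * np.pi * f * t), FS)
        assert np.allclose(ws.values, 3.0 / np.sqrt(2), rtol=1e-6)

    def test_zeros_give_zeros(self):
        ws = em.moving_rms(np.zeros(2400), FS)
        assert np.allclose(ws.values, 0.0)

    def test_window_spacing(self):
        ws = em.moving_rms(np.ones(2400), FS)
        assert np.allclose(np.diff(ws.times), 120 / FS)

    def test_short_signal_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            ws = em.moving_rms(np.ones(10), FS)
        assert len(ws) == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_scaling_homogeneous(self, k):
        x = np.random.default_rng(7).standard_normal(1000)
        base = em.moving_rms(x, FS)
        scaled = em.moving_rms(k * x, FS)
        assert np.allclose(scaled.values, k * base.values)


class TestPercentMvc:
    mvc = MvcReference({"ANT": 2.0, "MED": 1.0, "POS": 0.5})

    def _ws(self, v):
        return WindowedSeries(np.array([0.1]), np.array([v]), 0.125, 0.5)

    @pytest.mark.parametrize("rms,expected", [(2.0, 100.0), (0.0, 0.0), (1.0, 50.0)])
    def test_ratio(self, rms, expected):
        out = em.percent_mvc(self._ws(rms), self.mvc, "ANT")
        assert out.values[0] == pytest.approx(expected)

    def test_unknown_channel(self):
        with pytest.raises(KeyError, match="unknown"):
            em.percent_mvc(self._ws(1.0), self.mvc, "BICEPS")

    def test_mvc_must_be_positive(self):
        with pytest.raises(Exception, match="positive"):
            MvcReference({"ANT": 0.0})


def _flat_band_noise(lo, hi, seconds=40, seed=3):
    n = int(FS * seconds)
    rng = np.random.default_rng(seed)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1 / FS)
    spectrum[(freqs < lo) | (freqs > hi)] = 0
    return np.fft.irfft(spectrum, n)


class TestMedianFrequency:
    def test_flat_band_10_190_is_100(self):
        x = _flat_band_noise(10, 190)
        mf = em.median_frequency(x, FS)
        assert np.nanmean(mf.values) == pytest.approx(100.0, abs=5.0)

    def test_flat_band_10_90_is_50(self):
        x = _flat_band_noise(10, 90)
        mf = em.median_frequency(x, FS)
        assert np.nanmean(mf.values) == pytest.approx(50.0, abs=3.0)

    def test_pure_sine_within_bin_width(self):
        t = np.arange(int(FS * 10)) / FS
        mf = em.median_frequency(np.sin(2 * np.pi * 50 * t), FS)
        bin_width = FS / 240
        assert abs(np.nanmean(mf.values) - 50.0) < bin_width

    def test_all_zero_window_is_nan(self):
        x = np.concatenate([np.zeros(480), _flat_band_noise(10, 190, seconds=1)])
        mf = em.median_frequency(x, FS)
        assert np.isnan(mf.values[0])
        assert np.isfinite(mf.values[-1])

    def test_amplitude_invariant(self):
        x = _flat_band_noise(10, 190, seconds=5)
        a = em.median_frequency(x, FS).values
        b = em.median_frequency(100.0 * x, FS).values
        assert np.allclose(a, b)

    def test_bias_shrinks_with_window_count(self):
        # estimator consistency: averaging more windows tightens the MF
        short = np.nanmean(em.median_frequency(_flat_band_noise(10, 190, 2), FS).values)
        long = np.nanmean(em.median_frequency(_flat_band_noise(10, 190, 80), FS).values)
        assert abs(long - 100.0) <= abs(short - 100.0) + 1.0


def _const_series(values, n=9, dt=0.0625):
    t = np.arange(n) * dt
    return WindowedSeries(t, np.full(n, float(values)), 0.125, 0.5)


class TestCci:
    interval = (0.0, 0.5)

    def test_equal_constants_give_50(self):
        assert em.cci(_const_series(3.0), _const_series(3.0), self.interval) == pytest.approx(50.0)

    def test_zero_antagonist_gives_0(self):
        assert em.cci(_const_series(2.0), _const_series(0.0), self.interval) == pytest.approx(0.0)

    def test_two_to_one_gives_third(self):
        got = em.cci(_const_series(2.0), _const_series(1.0), self.interval)
        assert got == pytest.approx(100.0 / 3.0)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(UserWarning, match="denominator"):
            got = em.cci(_const_series(0.0), _const_series(0.0), self.interval)
        assert np.isnan(got)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(12) * 0.0625
        a = WindowedSeries(t, rng.uniform(0, 5, 12), 0.125, 0.5)
        b = WindowedSeries(t, rng.uniform(0, 5, 12), 0.125, 0.5)
        iv = (0.0, 0.7)
        ab = em.cci(a, b, iv)
        assert ab == pytest.approx(em.cci(b, a, iv))
        assert 0.0 <= ab <= 50.0 + 1e-9

    def test_50_only_when_equal(self):
        t = np.arange(12) * 0.0625
        a = WindowedSeries(t, np.linspace(1, 2, 12), 0.125, 0.5)
        b = WindowedSeries(t, np.linspace(2, 1, 12), 0.125, 0.5)
        assert em.cci(a, b, (0.0, 0.7)) < 50.0


class TestBinSeries:
    def test_identical_values(self):
        bs = em.bin_series(np.full(400, 7.0), cycles=np.arange(400), bin_size=40)
        assert bs.n_bins == 10
        assert np.allclose(bs.values, 7.0)
        assert bs.complete.all()

    def test_cycle_index_means(self):
        # cycle index 1..400 averaged in bins of 40: 20.5, 60.5, ...
        vals = np.arange(1, 401, dtype=float)
        bs = em.bin_series(vals, cycles=np.arange(400), bin_size=40)
        assert np.allclose(bs.values, 20.5 + 40 * np.arange(10))

    def test_incomplete_final_bin_dropped(self):
        vals = np.ones(390)
        bs = em.bin_series(vals, cycles=np.arange(390), bin_size=40, incomplete="drop")
        assert bs.n_bins == 9

    def test_incomplete_final_bin_flagged(self):
        vals = np.ones(390)
        bs = em.bin_series(vals, cycles=np.arange(390), bin_size=40)
        assert bs.n_bins == 10
        assert not bs.complete[-1]

    def test_window_time_assignment(self):
        starts = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # 4 cycles
        times = np.array([0.5, 1.5, 2.5, 3.5])
        bs = em.bin_series(np.array([1.0, 2.0, 3.0, 4.0]), times=times,
                           cycle_starts=starts, bin_size=2)
        assert np.allclose(bs.values, [1.5, 3.5])

    def test_nan_values_ignored(self):
        vals = np.array([1.0, np.nan, 3.0, np.nan])
        bs = em.bin_series(vals, cycles=np.array([0, 0, 1, 1]), bin_size=1)
        assert np.allclose(bs.values, [1.0, 3.0])
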