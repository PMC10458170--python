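"""IBI spectral chain: beat detection, resampling, periodogram, band powers,
segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvfun import (
    DurationError,
    IBISequence,
    InputError,
    NoBeatsError,
    PPGTrace,
    ResampledSeries,
    UndefinedRatioError,
    band_powers,
    compute_spectrum,
    mean_hr,
    ppg_to_ibi,
    resample_ibi,
    segment_session,
)

from conftest import brute_force_power_spectrum


def make_tone_series(freq_hz, n=512, rate_hz=4.0, amp=1.0, phase=0.0):
    t = np.arange(n) / rate_hz
    x = amp * np.sin(2 * np.pi * freq_hz * t + phase)
    x = x - x.mean()
    return ResampledSeries(values=x, rate_hz=rate_hz, n_pad=0, mean_ms=0.0)


class TestPPGToIBI:
    def test_pure_sinusoid_gives_constant_intervals(self):
        # 1 Hz heartbeat sampled at 50 Hz for 10 s -> 9 intervals of 1000 ms
        rate = 50.0
        t = np.arange(0, 10, 1 / rate)
        trace = PPGTrace(times=t, values=np.sin(2 * np.pi * t), rate=rate)
        ibi = ppg_to_ibi(trace)
        assert len(ibi) == 9
        # peak times are quantized to the 20 ms sample grid and the moving-
        # average baseline distorts the first/last cycle slightly
        np.testing.assert_allclose(ibi.intervals, 1000.0, atol=50)

    def test_constructed_beat_times_recovered(self):
        # Gaussian pulses centred at known beat times on a sloping baseline
        rate = 100.0
        t = np.arange(0, 3.5, 1 / rate)
        beat_times = [0.3, 1.1, 2.0, 3.0]  # intervals 800, 900, 1000 ms
        v = 0.2 * t  # baseline drift
        for b in beat_times:
            v = v + np.exp(-((t - b) ** 2) / (2 * 0.05**2))
        trace = PPGTrace(times=t, values=v, rate=rate)
        ibi = ppg_to_ibi(trace)
        np.testing.assert_allclose(ibi.intervals, [800, 900, 1000], atol=15)

    def test_flat_line_raises_no_beats(self):
        t = np.arange(0, 5, 0.02)
        with pytest.raises(NoBeatsError):
            ppg_to_ibi(PPGTrace(times=t, values=np.ones_like(t), rate=50.0))

    def test_non_monotone_times_rejected(self):
        with pytest.raises(InputError):
            PPGTrace(times=np.array([0.0, 0.2, 0.1]), values=np.zeros(3), rate=10.0)


class TestResample:
    def test_constant_intervals_resample_to_zero_after_mean_subtraction(self):
        ibi = IBISequence(np.full(100, 1000.0))
        series = resample_ibi(ibi, rate_hz=4.0)
        grid_part = series.values[: len(series) - series.n_pad]
        np.testing.assert_allclose(grid_part, 0.0, atol=1e-9)
        assert series.mean_ms == pytest.approx(1000.0)

    def test_linear_interpolation_between_two_beats(self):
        # beats of 800 and 1200 ms at onsets 0.8 s and 2.0 s
        ibi = IBISequence(np.array([800.0, 1200.0]))
        series = resample_ibi(ibi, rate_hz=4.0)
        n_grid = len(series) - series.n_pad
        grid = 0.8 + np.arange(n_grid) / 4.0
        expected = 800.0 + (grid - 0.8) / 1.2 * 400.0  # hand linear interpolant
        np.testing.assert_allclose(series.values[:n_grid] + series.mean_ms, expected)
        # the interpolant's midpoint (t = 1.4 s) is 1000 ms pre-subtraction
        assert np.interp(1.4, grid, series.values[:n_grid] + series.mean_ms) == pytest.approx(1000.0)

    def test_two_minute_segment_pads_to_512(self):
        ibi = IBISequence(np.full(120, 1000.0))  # exactly 2 min of beats
        series = resample_ibi(ibi, rate_hz=4.0)
        assert len(series) == 512
        assert series.exponent == 9

    def test_uniform_series_reproduced_exactly(self):
        # beats already on the 4 Hz grid (250 ms intervals): idempotent
        vals = 250.0 + np.sin(np.arange(64))  # wiggly but positive
        # construct onset times = cumsum; spacing varies, so instead use
        # constant 250 ms spacing with varying values is impossible for IBI
        # (value IS the spacing); use constant intervals at exactly 1/R
        ibi = IBISequence(np.full(64, 250.0))
        series = resample_ibi(ibi, rate_hz=4.0)
        n_grid = len(series) - series.n_pad
        np.testing.assert_allclose(series.values[:n_grid] + series.mean_ms, 250.0)

    def test_single_beat_rejected(self):
        with pytest.raises(InputError):
            resample_ibi(IBISequence(np.array([800.0])), rate_hz=4.0)


class TestSpectrum:
    def test_zero_series_gives_zero_powers(self):
        s = ResampledSeries(values=np.zeros(64), rate_hz=4.0, n_pad=0, mean_ms=0.0)
        spec = compute_spectrum(s)
        np.testing.assert_array_equal(spec.powers, 0.0)

    def test_impulse_gives_flat_spectrum(self):
        x = np.zeros(8)
        x[0] = 1.0
        spec = compute_spectrum(ResampledSeries(values=x, rate_hz=4.0, n_pad=0, mean_ms=0.0))
        np.testing.assert_allclose(spec.powers, 1.0)

    @pytest.mark.parametrize("n", [2, 4, 8, 16, 32, 64])
    def test_matches_brute_force_dft(self, n, rng):
        x = rng.normal(size=n)
        spec = compute_spectrum(ResampledSeries(values=x, rate_hz=4.0, n_pad=0, mean_ms=0.0))
        freqs, powers = brute_force_power_spectrum(x, 4.0)
        np.testing.assert_allclose(spec.powers, powers, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(spec.freqs, freqs)

    def test_parseval(self, rng):
        # two-sided spectral power sums to N times the signal energy
        x = rng.normal(size=256)
        spec = compute_spectrum(ResampledSeries(values=x, rate_hz=4.0, n_pad=0, mean_ms=0.0))
        p = spec.powers
        two_sided = p[0] + p[-1] + 2 * p[1:-1].sum()
        assert two_sided == pytest.approx(256 * (x**2).sum(), rel=1e-6)

    def test_tone_lands_in_nearest_bin(self):
        spec = compute_spectrum(make_tone_series(0.25))
        peak_bin = int(np.argmax(spec.powers))
        assert spec.freqs[peak_bin] == pytest.approx(0.25, abs=4.0 / 512)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(InputError):
            ResampledSeries(values=np.zeros(100), rate_hz=4.0, n_pad=0, mean_ms=0.0)


class TestBandPowers:
    def test_lf_tone_dominates(self):
        spec = band_powers(compute_spectrum(make_tone_series(0.10)))
        assert spec.lhr > 10

    def test_hf_tone_dominates(self):
        spec = band_powers(compute_spectrum(make_tone_series(0.30)))
        assert spec.lhr < 0.1

    def test_equal_mixture_gives_unit_ratio(self):
        t = np.arange(512) / 4.0
        x = np.sin(2 * np.pi * 0.10 * t) + np.sin(2 * np.pi * 0.30 * t)
        x = x - x.mean()
        series = ResampledSeries(values=x, rate_hz=4.0, n_pad=0, mean_ms=0.0)
        spec = band_powers(compute_spectrum(series))
        assert spec.lhr == pytest.approx(1.0, rel=0.05)
        # cross-check both band sums against the brute-force DFT oracle
        freqs, powers = brute_force_power_spectrum(x, 4.0)
        lf = powers[(freqs >= 0.04) & (freqs < 0.15)].sum()
        hf = powers[(freqs >= 0.15) & (freqs <= 0.40)].sum()
        assert spec.lf == pytest.approx(lf, rel=1e-9)
        assert spec.hf == pytest.approx(hf, rel=1e-9)

    @pytest.mark.parametrize("freq,band", [
        (0.08, "lf"), (0.10, "lf"), (0.12, "lf"),
        (0.20, "hf"), (0.25, "hf"), (0.30, "hf"), (0.35, "hf"),
    ])
    def test_interior_tone_localizes_to_its_band(self, freq, band):
        spec = band_powers(compute_spectrum(make_tone_series(freq)))
        non_dc = spec.powers[1:].sum()
        in_band = spec.lf if band == "lf" else spec.hf
        assert in_band / non_dc >= 0.95

    def test_zero_hf_power_raises(self):
        s = ResampledSeries(values=np.zeros(64), rate_hz=4.0, n_pad=0, mean_ms=0.0)
        with pytest.raises(UndefinedRatioError):
            band_powers(compute_spectrum(s))

    def test_boundary_bin_counted_once(self):
        # a bin exactly at 0.15 Hz belongs to HF only: LF+HF == total in [0.04, 0.40]
        n, rate = 512, 4.8  # 0.15 Hz is bin 16 exactly
        x = np.random.default_rng(0).normal(size=n)
        spec = band_powers(compute_spectrum(
            ResampledSeries(values=x, rate_hz=rate, n_pad=0, mean_ms=0.0)))
        f = spec.freqs
        total = spec.powers[(f >= 0.04) & (f <= 0.40)].sum()
        assert spec.lf + spec.hf == pytest.approx(total, rel=1e-12)


class TestSegmentation:
    def test_thirty_minute_session_gives_15_segments(self):
        ibi = IBISequence(np.full(1800, 1000.0))  # 30 min of 60 bpm
        seg = segment_session(ibi, window_s=120.0)
        assert seg.n_segments == 15
        # beat onsets sit at the end of each interval, so the first window
        # holds 119 beats and every later one 120
        assert [len(s) for s in seg.segments] == [119] + [120] * 14

    def test_trailing_partial_window_dropped(self):
        ibi = IBISequence(np.full(300, 1000.0))  # 5 min
        seg = segment_session(ibi, window_s=120.0)
        assert seg.n_segments == 2

    def test_short_session_raises_duration_error(self):
        with pytest.raises(DurationError):
            segment_session(IBISequence(np.full(90, 1000.0)), window_s=120.0)

    def test_sparse_segment_flagged_invalid(self):
        # second window has 2-second beats -> 60 beats... use 5 s beats: 24
        intervals = np.concatenate([np.full(120, 1000.0), np.full(24, 5000.0)])
        with pytest.warns(UserWarning, match="excluded"):
            seg = segment_session(IBISequence(intervals), window_s=120.0, min_beats=30)
        assert seg.valid == (True, False)
        assert seg.n_segments == 1

    @given(duration_s=st.integers(120, 4000), window_s=st.integers(60, 300))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_segment_count_is_floor_of_duration_over_window(self, duration_s, window_s):
        n_beats = duration_s  # 1000 ms beats
        ibi = IBISequence(np.full(n_beats, 1000.0))
        if duration_s < window_s:
            with pytest.raises(DurationError):
                segment_session(ibi, window_s=float(window_s))
        else:
            seg = segment_session(ibi, window_s=float(window_s), min_beats=1)
            assert seg.n_windows == duration_s // window_s


class TestMeanHR:
    @pytest.mark.parametrize("interval_ms,bpm", [(1000.0, 60.0), (750.0, 80.0)])
    def test_constant_intervals(self, interval_ms, bpm):
        assert mean_hr(IBISequence(np.full(10, interval_ms))) == pytest.approx(bpm)

    def test_arithmetic_mean(self):
        assert mean_hr(IBISequence(np.array([800.0, 1000.0, 1200.0]))) == pytest.approx(60.0)
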