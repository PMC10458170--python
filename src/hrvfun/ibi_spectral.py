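"""Frequency-domain HRV analysis of inter-beat-interval (IBI) sequences.

The processing chain implemented here is the classical fixed-rate-resampling
periodogram estimate of heart-rate-variability band powers:

1. (optional) detect heartbeats in a raw PPG trace and difference the peak
   times to obtain an IBI sequence in milliseconds;
2. treat the IBI sequence as an irregularly sampled time series (beat *j*
   carries value ``x_j`` ms at its onset time), interpolate it onto a uniform
   grid at rate ``R`` Hz (default 4 Hz), subtract the mean, and zero-pad to
   the next power of two;
3. take the squared magnitude of the discrete Fourier transform as the power
   spectrum (unnormalised one-sided periodogram, ms^2 per bin);
4. sum bins over the low-frequency band LF = [0.04, 0.15) Hz and the
   high-frequency band HF = [0.15, 0.40] Hz and form the sympathovagal
   ratio LHR = LF/HF.

The LF band is half-open on the right so that the 0.15 Hz bin is counted
exactly once (in HF), preserving total power across the two bands.

A 30-minute play session is analysed in consecutive non-overlapping 2-minute
windows, yielding one LHR value per window (15 per session).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .errors import (
    DurationError,
    InputError,
    NoBeatsError,
    UndefinedRatioError,
)

__all__ = [
    "PPGTrace",
    "IBISequence",
    "ResampledSeries",
    "HRVSpectrum",
    "SegmentedSession",
    "PeakDetectionConfig",
    "ppg_to_ibi",
    "resample_ibi",
    "compute_spectrum",
    "band_powers",
    "segment_session",
    "mean_hr",
    "LF_BAND",
    "HF_BAND",
    "DEFAULT_RESAMPLE_RATE_HZ",
    "DEFAULT_WINDOW_S",
    "DEFAULT_MIN_BEATS_PER_SEGMENT",
]

#: LF and HF band edges in Hz.  LF is half-open [lo, hi), HF is closed
#: [lo, hi] so the shared 0.15 Hz edge belongs to HF only.
LF_BAND: tuple[float, float] = (0.04, 0.15)
HF_BAND: tuple[float, float] = (0.15, 0.40)

DEFAULT_RESAMPLE_RATE_HZ: float = 4.0
DEFAULT_WINDOW_S: float = 120.0
DEFAULT_MIN_BEATS_PER_SEGMENT: int = 30


@dataclass(frozen=True)
class PPGTrace:
    """A raw photoplethysmography trace.

    Parameters
    ----------
    times : array-like of float
        Sample times in seconds, strictly increasing.
    values : array-like of float
        Signal amplitude in arbitrary units, same length as ``times``.
    rate : float
        Nominal sampling rate in samples/second.
    """

    times: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise InputError("times and values must be 1-D and equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise InputError("PPG times must be strictly increasing")
        if not self.rate > 0:
            raise InputError("sampling rate must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IBISequence:
    """A sequence of inter-beat intervals in milliseconds.

    Beat *j* (1-based) is anchored at its onset time, the cumulative sum of
    the preceding intervals, measured from session start.
    """

    intervals: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.intervals, dtype=float)
        if x.ndim != 1 or len(x) == 0:
            raise InputError("IBI sequence must be a non-empty 1-D array")
        if not np.all(x > 0):
            raise InputError("all IBI values must be positive")
        object.__setattr__(self, "intervals", x)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def onset_times_ms(self) -> np.ndarray:
        """Cumulative beat onset times in ms (onset of beat j = sum of
        intervals 1..j)."""
        return np.cumsum(self.intervals)

    @property
    def duration_s(self) -> float:
        """Total recorded span in seconds."""
        return float(self.intervals.sum()) / 1000.0


@dataclass(frozen=True)
class ResampledSeries:
    """A uniformly resampled, mean-subtracted, zero-padded IBI series.

    ``len(values)`` is always an exact power of two; ``n_pad`` zeros were
    appended to reach it.  ``mean_ms`` records the level subtracted before
    padding so the original scale is recoverable.
    """

    values: np.ndarray
    rate_hz: float
    n_pad: int
    mean_ms: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(v)
        if n == 0 or (n & (n - 1)) != 0:
            raise InputError("resampled series length must be a power of 2")
        if not self.rate_hz > 0:
            raise InputError("resampling rate must be positive")
        if self.n_pad < 0:
            raise InputError("padding count cannot be negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def exponent(self) -> int:
        """M such that 2**M equals the series length."""
        return int(np.log2(len(self.values)))


@dataclass(frozen=True)
class HRVSpectrum:
    """One-sided HRV power spectrum with band summaries.

    ``powers`` holds the squared DFT magnitude (unnormalised periodogram) at
    the non-negative frequencies ``freqs`` = R*j/N for j = 0..N/2.  Units are
    ms^2 per bin.  ``lf``, ``hf`` and ``lhr`` are filled by
    :func:`band_powers`.
    """

    freqs: np.ndarray
    powers: np.ndarray
    rate_hz: float
    n_fft: int
    lf: float | None = None
    hf: float | None = None
    lhr: float | None = None
    normalization: str = "onesided |DFT|^2, unnormalized"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.powers, dtype=float)
        if len(f) != len(p):
            raise InputError("freqs and powers must have equal length")
        if np.any(p < -1e-12):
            raise InputError("spectral powers must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "powers", np.maximum(p, 0.0))


@dataclass(frozen=True)
class SegmentedSession:
    """A session partitioned into consecutive fixed-length windows.

    ``segments`` holds one :class:`IBISequence` per *valid* window, in order;
    ``valid`` marks, for each of the ``floor(duration/window)`` windows,
    whether it met the minimum-beat requirement.
    """

    segments: tuple[IBISequence, ...]
    window_s: float
    valid: tuple[bool, ...] = field(default=())

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_windows(self) -> int:
        """Total windows considered, floor(duration / window), valid or not."""
        return len(self.valid)


@dataclass(frozen=True)
class PeakDetectionConfig:
    """Settings for PPG heartbeat detection.

    ``baseline_window_s`` is the span of the moving-average used for
    baseline-drift removal; ``refractory_ms`` the minimum beat-to-beat
    distance (physiological upper HR bound of 200 bpm at 300 ms);
    ``min_height_frac`` the minimum peak prominence as a fraction of the
    detrended signal's peak-to-peak range.
    """

    baseline_window_s: float = 1.0
    refractory_ms: float = 300.0
    min_height_frac: float = 0.25


def ppg_to_ibi(trace: PPGTrace, config: PeakDetectionConfig | None = None) -> IBISequence:
    """Detect heartbeats in a PPG trace and return the inter-beat intervals.

    Baseline drift is removed with a centred moving average, then local
    maxima are located subject to a refractory period and a relative
    prominence threshold; each interval is the time in ms between two
    consecutive detected peaks.

    Raises
    ------
    NoBeatsError
        If fewer than two peaks are detectable.
    """
    if config is None:
        config = PeakDetectionConfig()
    v = trace.values
    if len(v) < 3:
        raise NoBeatsError("trace too short for peak detection")

    win = max(3, int(round(config.baseline_window_s * trace.rate)))
    kernel = np.ones(win) / win
    baseline = np.convolve(np.pad(v, win // 2, mode="edge"), kernel, mode="same")
    baseline = baseline[win // 2 : win // 2 + len(v)]
    detrended = v - baseline

    ptp = float(np.ptp(detrended))
    if ptp <= 0:
        raise NoBeatsError("flat trace: no heartbeats detectable")
    distance = max(1, int(round(config.refractory_ms / 1000.0 * trace.rate)))
    idx, _ = find_peaks(
        detrended,
        distance=distance,
        prominence=config.min_height_frac * ptp,
    )
    if len(idx) < 2:
        raise NoBeatsError(f"only {len(idx)} peak(s) detected; need at least 2")
    peak_times_s = trace.times[idx]
    return IBISequence(np.diff(peak_times_s) * 1000.0)


def _next_pow2(n: int) -> int:
    return 1 << max(0, int(np.ceil(np.log2(max(1, n)))))


def resample_ibi(
    ibi: IBISequence,
    rate_hz: float = DEFAULT_RESAMPLE_RATE_HZ,
    method: str = "linear",
) -> ResampledSeries:
    """Resample an IBI sequence onto a uniform grid and pad to a power of 2.

    The sequence is treated as an irregular time series (value ``x_j`` ms at
    onset time ``t_j``), interpolated at spacing ``1/rate_hz`` over
    ``[t_1, t_n]``, mean-subtracted, then zero-padded so the total length is
    an exact power of two.  Mean subtraction before padding makes the padding
    value equal to the series' mean level, avoiding the step artefact that
    zero-padding a ~1000 ms baseline would create; the DC bin is not used by
    any band of interest.

    Parameters
    ----------
    method : {"linear", "cubic"}
        Interpolation scheme.  Linear is the default: deterministic and free
        of overshoot on the short segments used here.
    """
    if len(ibi) < 2:
        raise InputError("need at least 2 beats to interpolate")
    if not rate_hz > 0:
        raise InputError("resampling rate must be positive")

    t = ibi.onset_times_ms / 1000.0
    x = ibi.intervals
    n_grid = int(np.floor((t[-1] - t[0]) * rate_hz)) + 1
    grid = t[0] + np.arange(n_grid) / rate_hz
    if method == "linear":
        resampled = np.interp(grid, t, x)
    elif method == "cubic":
        resampled = CubicSpline(t, x)(grid)
    else:
        raise InputError(f"unknown interpolation method: {method!r}")

    mean_ms = float(resampled.mean())
    centred = resampled - mean_ms
    total = _next_pow2(n_grid)
    n_pad = total - n_grid
    padded = np.concatenate([centred, np.zeros(n_pad)])
    return ResampledSeries(values=padded, rate_hz=rate_hz, n_pad=n_pad, mean_ms=mean_ms)


def compute_spectrum(series: ResampledSeries, window: str = "rectangular") -> HRVSpectrum:
    """Compute the one-sided power spectrum of a resampled IBI series.

    Power is the squared magnitude of the discrete Fourier transform,
    reported at the non-negative frequencies ``f_j = R*j/N`` for
    j = 0..N/2 with no normalisation factor (the band ratio LHR is invariant
    to any common scaling).  Optionally a Hann taper can be applied, which
    trades main-lobe width for far smaller spectral leakage near band edges.
    """
    x = series.values
    n = len(x)
    if window == "hann":
        x = x * np.hanning(n)
    elif window != "rectangular":
        raise InputError(f"unknown window: {window!r}")
    coeffs = np.fft.rfft(x)
    powers = np.abs(coeffs) ** 2
    freqs = np.arange(len(coeffs)) * series.rate_hz / n
    return HRVSpectrum(
        freqs=freqs,
        powers=powers,
        rate_hz=series.rate_hz,
        n_fft=n,
        normalization=f"onesided |DFT|^2, unnormalized, {window} window",
    )


def band_powers(
    spec: HRVSpectrum,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> HRVSpectrum:
    """Sum spectral power over the LF and HF bands and form LHR = LF/HF.

    LF sums bins with ``lf_band[0] <= f < lf_band[1]`` and HF those with
    ``hf_band[0] <= f <= hf_band[1]``: the half-open LF edge ensures a bin
    falling exactly on the shared boundary is counted once.

    Returns a new :class:`HRVSpectrum` with ``lf``, ``hf`` and ``lhr`` set.

    Raises
    ------
    UndefinedRatioError
        If the HF band power is zero.
    InputError
        If either band contains no frequency bin at this resolution.
    """
    f = spec.freqs
    lf_mask = (f >= lf_band[0]) & (f < lf_band[1])
    hf_mask = (f >= hf_band[0]) & (f <= hf_band[1])
    if not lf_mask.any() or not hf_mask.any():
        raise InputError(
            "spectral resolution too coarse: a band contains no frequency bin"
        )
    lf = float(spec.powers[lf_mask].sum())
    hf = float(spec.powers[hf_mask].sum())
    if hf == 0.0:
        raise UndefinedRatioError("HF band power is zero; LF/HF undefined")
    return HRVSpectrum(
        freqs=spec.freqs,
        powers=spec.powers,
        rate_hz=spec.rate_hz,
        n_fft=spec.n_fft,
        lf=lf,
        hf=hf,
        lhr=lf / hf,
        normalization=spec.normalization,
    )


def segment_session(
    ibi: IBISequence,
    window_s: float = DEFAULT_WINDOW_S,
    min_beats: int = DEFAULT_MIN_BEATS_PER_SEGMENT,
) -> SegmentedSession:
    """Partition a session into consecutive non-overlapping windows.

    Beats are assigned by onset time to half-open windows
    ``[k*window_s, (k+1)*window_s)``; a trailing partial window is dropped.
    A 30-minute session at the default 120 s window yields 15 segments.
    Windows with fewer than ``min_beats`` beats are flagged invalid and
    excluded with a warning (a spectral estimate from a handful of beats is
    meaningless).

    Raises
    ------
    DurationError
        If the session is shorter than one window.
    """
    if not window_s > 0:
        raise InputError("window length must be positive")
    duration_s = ibi.duration_s
    n_windows = int(np.floor(duration_s / window_s))
    if n_windows < 1:
        raise DurationError(
            f"session of {duration_s:.1f} s shorter than one {window_s:.0f} s window"
        )
    onsets_s = ibi.onset_times_ms / 1000.0
    window_idx = np.floor(onsets_s / window_s).astype(int)

    segments: list[IBISequence] = []
    valid: list[bool] = []
    for k in range(n_windows):
        seg_intervals = ibi.intervals[window_idx == k]
        if len(seg_intervals) >= min_beats:
            segments.append(IBISequence(seg_intervals))
            valid.append(True)
        else:
            warnings.warn(
                f"segment {k}: only {len(seg_intervals)} beats "
                f"(< {min_beats}); excluded",
                stacklevel=2,
            )
            valid.append(False)
    return SegmentedSession(
        segments=tuple(segments), window_s=window_s, valid=tuple(valid)
    )


def mean_hr(ibi: IBISequence) -> float:
    """Mean heart rate in beats/minute: 60000 / mean(IBI in ms)."""
    return 60000.0 / float(np.mean(ibi.intervals))
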