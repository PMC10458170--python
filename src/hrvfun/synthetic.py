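"""Synthetic sessions, curves and datasets with known ground truth.

Real recordings of the kind this package analyses (30-minute play sessions
from wrist-worn PPG) are rarely shareable, so every downstream module is
exercised against generators whose ground truth is controllable:

* :func:`generate_session` builds a beat-by-beat IBI sequence whose interval
  length is additively modulated by one LF-band and one HF-band sinusoid
  (amplitudes programmable per 2-minute segment) plus Gaussian jitter — an
  "IPFM-lite" model whose in-band spectral content is known analytically;
* :func:`generate_lhr_curve` constructs a short positive curve whose peak
  count matches a target exactly and whose standard deviation and average
  peak amplitude land within 5% of targets;
* :func:`generate_dataset` draws feature triples uniformly and scores them
  through the linear fun model (optionally with Gaussian noise), providing
  exact ground truth for regression-recovery tests.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curve_features import (
    FunFeatures,
    LHRCurve,
    average_amplitude,
    classify_group,
    count_peaks,
    curve_sd,
)
from .errors import SpecError
from .fun_model import FunModel, ScoredSample, predict_score
from .ibi_spectral import IBISequence

__all__ = [
    "SegmentTones",
    "SessionSpec",
    "DatasetSpec",
    "generate_session",
    "generate_lhr_curve",
    "generate_dataset",
    "ramp_amplitude_schedule",
]


@dataclass(frozen=True)
class SegmentTones:
    """LF and HF modulation tones for one segment.

    Frequencies are in Hz and must lie inside their bands (LF: [0.04, 0.15),
    HF: [0.15, 0.40]); amplitudes are the peak interval modulation in ms.
    """

    lf_freq: float = 0.10
    lf_amp: float = 30.0
    hf_freq: float = 0.30
    hf_amp: float = 30.0

    def __post_init__(self) -> None:
        if not 0.04 <= self.lf_freq < 0.15:
            raise SpecError(f"LF tone {self.lf_freq} Hz outside [0.04, 0.15)")
        if not 0.15 <= self.hf_freq <= 0.40:
            raise SpecError(f"HF tone {self.hf_freq} Hz outside [0.15, 0.40]")
        if self.lf_amp < 0 or self.hf_amp < 0:
            raise SpecError("tone amplitudes must be non-negative")


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic play session.

    Defaults emulate the study protocol: a 30-minute session analysed in
    2-minute segments, resting-adult base interval of 800 ms (75 bpm), and
    beat-to-beat jitter of 5 ms.
    """

    duration_s: float = 1800.0
    base_ibi_ms: float = 800.0
    segments: tuple[SegmentTones, ...] = field(
        default_factory=lambda: tuple(SegmentTones() for _ in range(15))
    )
    segment_window_s: float = 120.0
    jitter_sd_ms: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise SpecError("duration must be positive")
        if not 400.0 <= self.base_ibi_ms <= 1500.0:
            raise SpecError("base IBI must lie in [400, 1500] ms")
        if self.jitter_sd_ms < 0:
            raise SpecError("jitter SD must be non-negative")
        if len(self.segments) == 0:
            raise SpecError("need at least one segment schedule entry")


@dataclass(frozen=True)
class DatasetSpec:
    """Parameters of a synthetic scored-feature dataset.

    Scores are the linear fun model evaluated at ``coefficients`` plus
    Gaussian noise of SD ``noise_sd``.  Feature ranges default to the spread
    observed on short LF/HF curves: LHSD in [0.5, 3], LHP in {0..7}, LHA in
    [0, 4].
    """

    n_samples: int = 50
    coefficients: tuple[float, float, float, float] = (3.10, 2.03, 2.29, 54.27)
    lhsd_range: tuple[float, float] = (0.5, 3.0)
    lhp_range: tuple[int, int] = (0, 7)
    lha_range: tuple[float, float] = (0.0, 4.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise SpecError("need at least one sample")
        if self.lhsd_range[0] <= 0:
            raise SpecError("LHSD range must be strictly positive")
        if self.noise_sd < 0:
            raise SpecError("noise SD must be non-negative")


def generate_session(spec: SessionSpec) -> IBISequence:
    """Generate a beat sequence with per-segment sinusoidal IBI modulation.

    Beat k occurring at cumulative time t_k has interval

        x_k = base + A_LF(t_k) sin(2 pi f_LF t_k)
                   + A_HF(t_k) sin(2 pi f_HF t_k) + jitter_k

    where the amplitudes follow the per-segment schedule and the next beat
    occurs at t_k + x_k (the interval stream defines its own clock).
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    intervals: list[float] = []
    t_ms = 0.0
    duration_ms = spec.duration_s * 1000.0
    window_ms = spec.segment_window_s * 1000.0
    n_seg = len(spec.segments)
    while t_ms < duration_ms:
        seg = spec.segments[min(int(t_ms // window_ms), n_seg - 1)]
        t_s = t_ms / 1000.0
        x = (
            spec.base_ibi_ms
            + seg.lf_amp * np.sin(2 * np.pi * seg.lf_freq * t_s)
            + seg.hf_amp * np.sin(2 * np.pi * seg.hf_freq * t_s)
        )
        if spec.jitter_sd_ms > 0:
            x += rng.normal(0.0, spec.jitter_sd_ms)
        if x < 200.0:  # < 200 ms (300 bpm) is physiologically impossible
            raise SpecError(
                f"spec produced an interval of {x:.1f} ms; reduce amplitudes/jitter"
            )
        intervals.append(x)
        t_ms += x
    if len(intervals) < 2:
        raise SpecError("spec produced fewer than 2 beats")
    return IBISequence(np.asarray(intervals))


def ramp_amplitude_schedule(
    n_segments: int = 15,
    lf_amp_start: float = 5.0,
    lf_amp_end: float = 50.0,
    hf_amp: float = 25.0,
    lf_freq: float = 0.10,
    hf_freq: float = 0.30,
) -> tuple[SegmentTones, ...]:
    """A monotone per-segment schedule: LF amplitude ramps up while HF stays
    fixed, so the programmed LF/HF power ratio increases segment by segment.
    Useful for end-to-end recovery checks."""
    amps = np.linspace(lf_amp_start, lf_amp_end, n_segments)
    return tuple(
        SegmentTones(lf_freq=lf_freq, lf_amp=float(a), hf_freq=hf_freq, hf_amp=hf_amp)
        for a in amps
    )


def _lhr_curve_shape(length: int, n_peaks: int, peak_height: float, rise: float) -> np.ndarray:
    """Monotone ramp of total ``rise`` plus ``n_peaks`` single-point spikes of
    height ``peak_height`` at evenly spaced interior odd indices."""
    base = np.linspace(0.0, rise, length)
    v = base.copy()
    if n_peaks > 0:
        positions = np.linspace(1, length - 2, n_peaks).round().astype(int)
        # enforce separation: peaks need a non-peak neighbour on each side
        positions = np.unique(np.clip(positions, 1, length - 2))
        taken: list[int] = []
        for p in positions:
            while p in taken or (p - 1) in taken or (p + 1) in taken:
                p += 2
            if p > length - 2:
                raise SpecError("cannot place that many separated peaks")
            taken.append(int(p))
        for p in taken:
            v[p] += peak_height
    return v


def generate_lhr_curve(
    length: int = 15,
    lhp: int = 3,
    lhsd: float | None = None,
    lha: float | None = None,
    segment_window_s: float = 120.0,
) -> LHRCurve:
    """Construct a positive curve hitting target feature values.

    The measured peak count equals ``lhp`` exactly; when ``lhsd`` / ``lha``
    targets are given the measured values land within 5% (achieved by
    setting spike heights from ``lha`` and tuning a monotone ramp component
    by bisection to reach ``lhsd``).

    Raises
    ------
    SpecError
        If the target is infeasible (``lhp > floor((length-1)/2)``, an
        ``lha`` target with zero peaks, or an ``lhsd`` below what the
        requested peaks alone impose).
    """
    if length < 3:
        raise SpecError("curve length must be at least 3")
    if lhp < 0 or lhp > (length - 1) // 2:
        raise SpecError(f"cannot fit {lhp} peaks in a curve of length {length}")
    if lhp == 0 and lha not in (None, 0, 0.0):
        raise SpecError("lha target requires at least one peak")

    height = float(lha) if (lha is not None and lhp > 0) else (1.0 if lhp > 0 else 0.0)
    if lhp > 0 and height <= 0:
        raise SpecError("lha target must be positive when peaks are requested")

    def solve_rise(h: float) -> float:
        """Ramp total rise matching the lhsd target for spike height h."""
        def sd_of(rise: float) -> float:
            return curve_sd(_lhr_curve_shape(length, lhp, h, rise))

        if lhsd is None:
            return 1.0 if lhp == 0 else 0.0
        sd_floor = sd_of(0.0)
        if lhsd < sd_floor * 0.95:
            raise SpecError(
                f"target lhsd {lhsd} below the floor {sd_floor:.3f} set by "
                f"{lhp} peaks of amplitude {h}"
            )
        # a ramp step steeper than the spike height would destroy peaks
        max_rise = 1e6 if lhp == 0 else 0.99 * h * (length - 1)
        if sd_of(max_rise) < lhsd:
            raise SpecError("target lhsd unreachable without destroying peaks")
        lo, hi = 0.0, max_rise
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if sd_of(mid) < lhsd:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # closed loop: the ramp raises the measured peak amplitude above the
    # spike height, so alternate height correction and rise re-solving
    rise = solve_rise(height)
    if lha is not None and lhp > 0:
        for _ in range(30):
            meas = average_amplitude(_lhr_curve_shape(length, lhp, height, rise))
            if abs(meas - lha) <= 0.01 * lha:
                break
            height *= lha / meas
            if height <= 0 or not np.isfinite(height):
                raise SpecError("lha target infeasible for this curve shape")
            rise = solve_rise(height)

    v = _lhr_curve_shape(length, lhp, height, rise)
    v = v - v.min() + 0.1  # positivity; shift leaves all three features alone
    curve = LHRCurve(v, segment_window_s=segment_window_s)
    assert count_peaks(curve) == lhp
    return curve


def generate_dataset(spec: DatasetSpec) -> list[ScoredSample]:
    """Draw feature triples uniformly and score them with the linear model.

    Scores are clipped to [0, 100] only at the export boundary (the
    :class:`ScoredSample` contract); with ``noise_sd`` = 0 and coefficient
    vectors in the bundled presets' range the raw scores already lie inside.
    Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    a, b, g, e = spec.coefficients
    model = FunModel(alpha=a, beta=b, gamma=g, epsilon=e)
    samples: list[ScoredSample] = []
    for i in range(spec.n_samples):
        f = FunFeatures(
            lhsd=float(rng.uniform(*spec.lhsd_range)),
            lhp=int(rng.integers(spec.lhp_range[0], spec.lhp_range[1] + 1)),
            lha=float(rng.uniform(*spec.lha_range)),
        )
        score = predict_score(model, f)
        if spec.noise_sd > 0:
            score += float(rng.normal(0.0, spec.noise_sd))
        score = float(np.clip(score, 0.0, 100.0))
        samples.append(
            ScoredSample(
                features=f,
                score=score,
                group=classify_group(f.lhsd),
                sample_id=f"synth-{i:04d}",
            )
        )
    return samples
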