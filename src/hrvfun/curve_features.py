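"""Objective game-fun indicators extracted from an LF/HF-ratio curve.

A play session yields one LF/HF ratio per 2-minute segment; the resulting
short curve (typically 15 points for a 30-minute session) is summarised by
three indicators:

* **LHSD** — sample standard deviation of the curve values (overall
  dispersion of sympathovagal balance);
* **LHP** — number of local maxima, counting each oscillation "wave" once;
* **LHA** — average peak amplitude, each peak measured against the mean of
  its flanking local minima (a prominence-like peak-to-valley excursion).

Sessions are routed to one of two prediction models by thresholding LHSD:
below 1.47 the sample is treated as low-score, otherwise high-score.

Peaks are strict local maxima; a plateau counts once, at its first index,
when it exceeds both flanks.  No prominence filter is applied: curves at this
length are already heavily smoothed by the 2-minute windowing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "LHRCurve",
    "FunFeatures",
    "curve_sd",
    "detect_peaks",
    "count_peaks",
    "average_amplitude",
    "extract_features",
    "classify_group",
    "LOW_SCORE",
    "HIGH_SCORE",
    "DEFAULT_SD_THRESHOLD",
]

LOW_SCORE = "low_score"
HIGH_SCORE = "high_score"

#: LHSD threshold for group differentiation: strictly below -> low_score.
DEFAULT_SD_THRESHOLD = 1.47


@dataclass(frozen=True)
class LHRCurve:
    """Per-segment LF/HF ratio values for one session, in segment order."""

    values: np.ndarray
    segment_window_s: float = 120.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise InputError("curve must be a non-empty 1-D array")
        if not np.all(v > 0):
            raise InputError("LF/HF ratios must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FunFeatures:
    """The (LHSD, LHP, LHA) indicator triple for one session."""

    lhsd: float
    lhp: int
    lha: float

    def __post_init__(self) -> None:
        if self.lhsd < 0 or self.lha < 0 or self.lhp < 0:
            raise InputError("features must be non-negative")


def _as_curve(curve: LHRCurve | np.ndarray) -> np.ndarray:
    if isinstance(curve, LHRCurve):
        return curve.values
    return np.asarray(curve, dtype=float)


def curve_sd(curve: LHRCurve | np.ndarray) -> float:
    """Sample standard deviation (denominator n-1) of the curve values."""
    v = _as_curve(curve)
    if len(v) < 2:
        raise InputError("need at least 2 values for a standard deviation")
    return float(np.std(v, ddof=1))


def detect_peaks(curve: LHRCurve | np.ndarray) -> list[tuple[int, float]]:
    """Locate local maxima as (index, value) pairs.

    An interior index i is a peak when values[i] > values[i-1] and
    values[i] > values[i+1].  A plateau of equal values is a single peak,
    reported at its first index, when the plateau level exceeds both flanks.
    Endpoints are never peaks.
    """
    v = _as_curve(curve)
    n = len(v)
    if n < 3:
        raise InputError("need at least 3 values for peak detection")
    peaks: list[tuple[int, float]] = []
    i = 1
    while i < n - 1:
        # run of equal values starting at i
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j < n - 1 and v[i] > v[i - 1] and v[i] > v[j + 1]:
            peaks.append((i, float(v[i])))
        i = j + 1
    return peaks


def count_peaks(curve: LHRCurve | np.ndarray) -> int:
    """Number of peaks (LHP)."""
    return len(detect_peaks(curve))


def _flank_minimum(v: np.ndarray, peak: int, step: int) -> float:
    """Value of the nearest local minimum walking from ``peak`` in direction
    ``step`` (+1 right, -1 left); an endpoint serves as the minimum when the
    descent reaches the curve boundary."""
    i = peak
    n = len(v)
    while True:
        nxt = i + step
        if nxt < 0 or nxt >= n:
            break
        if v[nxt] <= v[i]:
            i = nxt
        else:
            break
    return float(v[i])


def average_amplitude(curve: LHRCurve | np.ndarray) -> float:
    """Average peak amplitude (LHA).

    Each peak's amplitude is its value minus the mean of the nearest local
    minima on its left and right (boundary endpoints stand in when a side has
    no interior minimum).  Returns 0 when the curve has no peaks.
    """
    v = _as_curve(curve)
    peaks = detect_peaks(v)
    if not peaks:
        return 0.0
    amps = []
    for idx, val in peaks:
        left = _flank_minimum(v, idx, -1)
        right = _flank_minimum(v, idx, +1)
        amps.append(val - 0.5 * (left + right))
    return float(np.mean(amps))


def extract_features(curve: LHRCurve | np.ndarray) -> FunFeatures:
    """Compute the full (LHSD, LHP, LHA) triple for a session curve."""
    return FunFeatures(
        lhsd=curve_sd(curve),
        lhp=count_peaks(curve),
        lha=average_amplitude(curve),
    )


def classify_group(lhsd: float, threshold: float = DEFAULT_SD_THRESHOLD) -> str:
    """Group-differentiation rule: ``low_score`` when LHSD < threshold,
    ``high_score`` otherwise (the threshold value itself is high-score)."""
    if lhsd < 0:
        raise InputError("LHSD cannot be negative")
    return LOW_SCORE if lhsd < threshold else HIGH_SCORE
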