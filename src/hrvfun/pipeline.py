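"""End-to-end session processing: IBI sequence in, fun score out.

Composes the module chain: segment the session into 2-minute windows,
estimate LF/HF band powers per window, assemble the per-segment LHR curve,
extract the (LHSD, LHP, LHA) indicators, and route to the group-appropriate
linear model for the score prediction.
"""

from __future__ import annotations

from typing import Mapping

from .config import PipelineConfig
from .curve_features import LHRCurve, extract_features
from .errors import DataQualityError
from .fun_model import FunModel, route_and_predict
from .ibi_spectral import (
    IBISequence,
    band_powers,
    compute_spectrum,
    mean_hr,
    resample_ibi,
    segment_session,
)

__all__ = ["session_lhr_curve", "process_session"]


def session_lhr_curve(ibi: IBISequence, config: PipelineConfig | None = None) -> LHRCurve:
    """Per-segment LF/HF ratio curve for a session.

    Raises
    ------
    DataQualityError
        If no segment passed the minimum-beat validity check.
    """
    if config is None:
        config = PipelineConfig()
    segmented = segment_session(
        ibi, window_s=config.window_s, min_beats=config.min_beats_per_segment
    )
    if segmented.n_segments == 0:
        raise DataQualityError("every segment failed the minimum-beat check")
    lhr_values = []
    for seg in segmented.segments:
        series = resample_ibi(seg, rate_hz=config.resample_rate_hz, method=config.interpolation)
        spec = compute_spectrum(series, window=config.fft_window)
        spec = band_powers(spec, lf_band=config.lf_band, hf_band=config.hf_band)
        lhr_values.append(spec.lhr)
    return LHRCurve(lhr_values, segment_window_s=config.window_s)


def process_session(
    ibi: IBISequence,
    models: Mapping[str, FunModel],
    config: PipelineConfig | None = None,
) -> dict:
    """Full pipeline: returns LHR curve, features, group and predicted score
    in a JSON-ready dict together with the resolved configuration."""
    if config is None:
        config = PipelineConfig()
    curve = session_lhr_curve(ibi, config)
    features = extract_features(curve)
    score, group = route_and_predict(models, features, clamp=config.clamp_predictions)
    return {
        "mean_hr_bpm": mean_hr(ibi),
        "lhr_curve": curve.values.tolist(),
        "features": {
            "lhsd": features.lhsd,
            "lhp": features.lhp,
            "lha": features.lha,
        },
        "group": group,
        "predicted_score": score,
        "config": config.to_dict(),
    }
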