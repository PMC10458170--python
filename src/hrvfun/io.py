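"""CSV / JSON readers and writers for the pipeline's file formats.

Formats:

* IBI CSV — header ``ibi_ms`` (one interval per row) or ``t_ms,ibi_ms``;
  ``#`` starts a comment line.
* PPG CSV — header ``t_s,amplitude``.
* Feature table CSV — ``sample_id,lhsd,lhp,lha,group,score`` (``score``
  optional); round-trips losslessly.
* Spectrum JSON — band powers plus provenance metadata (resampling rate,
  band edges, normalisation).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curve_features import FunFeatures
from .errors import InputError
from .fun_model import ScoredSample
from .ibi_spectral import HRVSpectrum, IBISequence, PPGTrace

__all__ = [
    "read_ibi_csv",
    "write_ibi_csv",
    "read_ppg_csv",
    "read_feature_csv",
    "write_feature_csv",
    "spectrum_to_dict",
]


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot parse CSV {path}: {exc}") from exc


def read_ibi_csv(path: str | Path) -> IBISequence:
    """Read an IBI CSV (``ibi_ms`` or ``t_ms,ibi_ms`` header)."""
    df = _read_csv(path)
    if "ibi_ms" not in df.columns:
        raise InputError(f"{path}: expected an 'ibi_ms' column, got {list(df.columns)}")
    return IBISequence(df["ibi_ms"].to_numpy(dtype=float))


def write_ibi_csv(path: str | Path, ibi: IBISequence, cumulative_time: bool = True) -> None:
    """Write an IBI sequence; with ``cumulative_time`` a ``t_ms`` column of
    beat onset times is included."""
    if cumulative_time:
        df = pd.DataFrame({"t_ms": ibi.onset_times_ms, "ibi_ms": ibi.intervals})
    else:
        df = pd.DataFrame({"ibi_ms": ibi.intervals})
    df.to_csv(path, index=False, float_format="%.17g")


def read_ppg_csv(path: str | Path, rate: float | None = None) -> PPGTrace:
    """Read a PPG CSV (``t_s,amplitude``); rate inferred from the median
    sample spacing when not given."""
    df = _read_csv(path)
    for col in ("t_s", "amplitude"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    if rate is None:
        if len(t) < 2:
            raise InputError(f"{path}: cannot infer sampling rate from <2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
    return PPGTrace(times=t, values=df["amplitude"].to_numpy(dtype=float), rate=rate)


def read_feature_csv(path: str | Path) -> list[ScoredSample]:
    """Read a feature table into scored samples (score defaults to 0 when
    the column is absent — fit/evaluate callers require it explicitly)."""
    df = _read_csv(path)
    required = {"sample_id", "lhsd", "lhp", "lha"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    has_score = "score" in df.columns
    has_group = "group" in df.columns
    has_pred = "predicted" in df.columns
    samples = []
    for _, row in df.iterrows():
        samples.append(
            ScoredSample(
                features=FunFeatures(
                    lhsd=float(row["lhsd"]), lhp=int(row["lhp"]), lha=float(row["lha"])
                ),
                score=float(row["score"]) if has_score else 0.0,
                group=(str(row["group"]) if has_group and pd.notna(row["group"]) else None),
                predicted=(float(row["predicted"]) if has_pred and pd.notna(row["predicted"]) else None),
                sample_id=str(row["sample_id"]),
            )
        )
    return samples


def write_feature_csv(path: str | Path, samples: Sequence[ScoredSample]) -> None:
    """Write scored samples as a feature table CSV."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "lhsd": [s.features.lhsd for s in samples],
            "lhp": [s.features.lhp for s in samples],
            "lha": [s.features.lha for s in samples],
            "group": [s.group for s in samples],
            "score": [s.score for s in samples],
            "predicted": [s.predicted for s in samples],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def spectrum_to_dict(spec: HRVSpectrum, include_bins: bool = True) -> dict:
    """JSON-ready dict of a spectrum with provenance metadata."""
    d: dict = {
        "lf_ms2": spec.lf,
        "hf_ms2": spec.hf,
        "lhr": spec.lhr,
        "meta": {
            "rate_hz": spec.rate_hz,
            "n_fft": spec.n_fft,
            "normalization": spec.normalization,
        },
    }
    if include_bins:
        d["freqs_hz"] = spec.freqs.tolist()
        d["powers_ms2"] = spec.powers.tolist()
    return d


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
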