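"""Linear game-fun score prediction from LF/HF-ratio curve indicators.

The predictor is linear in a transformed feature vector:

    G' = alpha * (1 / LHSD) + beta * LHP + gamma * LHA + epsilon

where LHSD enters reciprocally (dispersion of the LF/HF curve falls as fun
rises), LHP is the peak count, LHA the average peak amplitude, and epsilon an
error-compensation intercept.  Two published coefficient presets ship with
the package: ``model1`` (fitted on high-score sessions only) and ``model2``
(fitted on all sessions); at prediction time a session is routed to a model
by the LHSD group rule (see :func:`hrvfun.curve_features.classify_group`).

Fitting is ordinary least squares on the design matrix with columns
(1/LHSD, LHP, LHA, 1).  Evaluation reports MAE, RMSE and class accuracy for
the 10-class (width 10) and 5-class (width 20) rating systems, where a
prediction counts as correct when it falls in the same class as the
subjective score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .curve_features import (
    DEFAULT_SD_THRESHOLD,
    FunFeatures,
    classify_group,
)
from .errors import ConfigurationError, InputError, SingularFitError

__all__ = [
    "FunModel",
    "ScoredSample",
    "FitResult",
    "EvalReport",
    "predict_score",
    "fit_model",
    "route_and_predict",
    "evaluate",
    "class_accuracy",
    "nrs_level",
    "load_preset",
]

SCOPE_HIGH_ONLY = "high_score_only"
SCOPE_ALL = "all"


@dataclass(frozen=True)
class FunModel:
    """Linear score model coefficients.

    ``scope`` records which group(s) the model was fitted on
    (``"high_score_only"`` or ``"all"``); ``threshold_lhsd`` the LHSD value
    used for routing between paired models.
    """

    alpha: float
    beta: float
    gamma: float
    epsilon: float
    scope: str = SCOPE_ALL
    threshold_lhsd: float = DEFAULT_SD_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "epsilon"):
            if not np.isfinite(getattr(self, name)):
                raise InputError(f"coefficient {name} must be finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FunModel":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d[k] for k in
                      ("alpha", "beta", "gamma", "epsilon", "scope", "threshold_lhsd")
                      if k in d})


@dataclass(frozen=True)
class ScoredSample:
    """One session: features, subjective score, optional prediction/group."""

    features: FunFeatures
    score: float
    predicted: float | None = None
    group: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise InputError(f"score {self.score} outside [0, 100]")


@dataclass(frozen=True)
class FitResult:
    """An OLS fit: the model plus goodness of fit."""

    model: FunModel
    r_squared: float
    n: int


@dataclass(frozen=True)
class EvalReport:
    """Prediction-quality summary: MAE, RMSE and class accuracies, overall
    and per group where group labels are available."""

    mae: float
    rmse: float
    accuracy_10class: float
    accuracy_5class: float
    n: int
    per_group: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def predict_score(
    model: FunModel, f: FunFeatures, clamp: bool = False
) -> float:
    """Evaluate G' = alpha/LHSD + beta*LHP + gamma*LHA + epsilon.

    With ``clamp`` the prediction is clipped to [0, 100]; by default the raw
    linear value is returned (it may leave the score range).
    """
    if f.lhsd == 0:
        raise InputError("LHSD is zero: reciprocal term undefined")
    g = model.alpha / f.lhsd + model.beta * f.lhp + model.gamma * f.lha + model.epsilon
    if clamp:
        g = float(np.clip(g, 0.0, 100.0))
    return float(g)


def _design_matrix(samples: Sequence[ScoredSample]) -> np.ndarray:
    rows = []
    for s in samples:
        if s.features.lhsd == 0:
            raise InputError("sample with LHSD = 0: reciprocal term undefined")
        rows.append([1.0 / s.features.lhsd, s.features.lhp, s.features.lha, 1.0])
    return np.asarray(rows, dtype=float)


def fit_model(
    samples: Sequence[ScoredSample], scope: str = SCOPE_ALL
) -> FitResult:
    """Ordinary least squares fit of the linear score model.

    Requires at least 5 samples and a full-rank design (the four columns
    1/LHSD, LHP, LHA, 1 must be linearly independent across samples).

    Raises
    ------
    SingularFitError
        If the design matrix is rank deficient.
    """
    if len(samples) < 5:
        raise InputError(f"need at least 5 samples to fit, got {len(samples)}")
    X = _design_matrix(samples)
    y = np.asarray([s.score for s in samples], dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    model = FunModel(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        gamma=float(coef[2]),
        epsilon=float(coef[3]),
        scope=scope,
    )
    return FitResult(model=model, r_squared=r2, n=len(samples))


def route_and_predict(
    models: Mapping[str, FunModel], f: FunFeatures, clamp: bool = False
) -> tuple[float, str]:
    """Select a model by the LHSD group rule and predict.

    ``models`` maps group labels (``"low_score"``, ``"high_score"``) to
    fitted models.  Returns (prediction, selected group label).
    """
    threshold = next(iter(models.values())).threshold_lhsd if models else DEFAULT_SD_THRESHOLD
    group = classify_group(f.lhsd, threshold=threshold)
    if group not in models:
        raise ConfigurationError(f"no model configured for group {group!r}")
    return predict_score(models[group], f, clamp=clamp), group


def _class_index(score: float, width: int) -> int:
    # 100 joins the top class so exactly 100/width evenly spaced classes exist
    n_classes = 100 // width
    return min(int(score // width), n_classes - 1)


def class_accuracy(
    truths: Iterable[float],
    predictions: Iterable[float],
    n_classes: int = 10,
    clamp: bool = False,
) -> float:
    """Fraction of predictions falling in the same rating class as the truth.

    Scores are binned as floor(score / width) with width 10 (10 classes) or
    20 (5 classes); a score of exactly 100 belongs to the top class.  Out of
    range values raise unless ``clamp`` is set.
    """
    if n_classes not in (10, 5):
        raise InputError("n_classes must be 10 or 5")
    width = 100 // n_classes
    t = np.asarray(list(truths), dtype=float)
    p = np.asarray(list(predictions), dtype=float)
    if len(t) != len(p) or len(t) == 0:
        raise InputError("need equal-length, non-empty truth/prediction lists")
    if clamp:
        t = np.clip(t, 0.0, 100.0)
        p = np.clip(p, 0.0, 100.0)
    if np.any((t < 0) | (t > 100) | (p < 0) | (p > 100)):
        raise InputError("scores outside [0, 100]; use clamp to clip")
    tc = np.minimum((t // width).astype(int), n_classes - 1)
    pc = np.minimum((p // width).astype(int), n_classes - 1)
    return float(np.mean(tc == pc))


def evaluate(samples: Sequence[ScoredSample], clamp: bool = False) -> EvalReport:
    """Compute MAE, RMSE and class accuracies for predicted samples.

    MAE = mean |G' - G|; RMSE = sqrt(mean (G' - G)^2).  When group labels are
    present the report carries a per-group breakdown of the same metrics.
    """
    if len(samples) == 0:
        raise InputError("cannot evaluate an empty sample list")
    if any(s.predicted is None for s in samples):
        raise InputError("all samples must carry a prediction")
    t = np.asarray([s.score for s in samples], dtype=float)
    p = np.asarray([s.predicted for s in samples], dtype=float)
    err = p - t
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    acc10 = class_accuracy(t, p, n_classes=10, clamp=clamp)
    acc5 = class_accuracy(t, p, n_classes=5, clamp=clamp)

    per_group: dict = {}
    groups = {s.group for s in samples if s.group is not None}
    for g in sorted(groups):
        sub = [s for s in samples if s.group == g]
        tg = np.asarray([s.score for s in sub])
        pg = np.asarray([s.predicted for s in sub])
        eg = pg - tg
        per_group[g] = {
            "mae": float(np.mean(np.abs(eg))),
            "rmse": float(np.sqrt(np.mean(eg**2))),
            "accuracy_10class": class_accuracy(tg, pg, 10, clamp=clamp),
            "accuracy_5class": class_accuracy(tg, pg, 5, clamp=clamp),
            "n": len(sub),
        }
    return EvalReport(
        mae=mae,
        rmse=rmse,
        accuracy_10class=acc10,
        accuracy_5class=acc5,
        n=len(samples),
        per_group=per_group,
    )


#: NRS level edges: (upper bound inclusive, label).
_NRS_LEVELS = [(30.0, "very_low"), (50.0, "low"), (70.0, "moderate"), (100.0, "high")]


def nrs_level(score: float) -> str:
    """Map a 0-100 fun score to its numeric-rating-scale level.

    0-30 very_low, 31-50 low, 51-70 moderate, 71-100 high; non-integer
    scores bucket by <= on the upper edges.
    """
    if not 0.0 <= score <= 100.0:
        raise InputError(f"score {score} outside [0, 100]")
    for upper, label in _NRS_LEVELS:
        if score <= upper:
            return label
    raise AssertionError("unreachable")


def load_preset(name: str) -> FunModel:
    """Load a bundled coefficient preset (``"model1"`` or ``"model2"``).

    ``model1`` was fitted on high-score sessions only; ``model2`` on all
    sessions.
    """
    try:
        text = (resources.files("hrvfun") / "models" / f"{name}.json").read_text()
    except FileNotFoundError:
        raise ConfigurationError(f"no bundled model named {name!r}") from None
    d = json.loads(text)
    return FunModel(**{k: d[k] for k in
                       ("alpha", "beta", "gamma", "epsilon", "scope", "threshold_lhsd")
                       if k in d})
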