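"""Dataset splitting, regression/classification metrics and model grading.

Conventions (NIR chemometrics):

* R-squared is the squared Pearson correlation between reference and
  predicted values ("curve correlation coefficient"); the
  coefficient-of-determination alternative is available via ``r2_mode``.
* RMSEC/RMSEP are root-mean-squared errors on the calibration / prediction
  set respectively.
* RPD (residual predictive deviation) is the reference-value SD of the
  evaluated set (ddof=1) divided by that set's RMSE; > 3 marks a very good
  calibration.

Model grades combine an R-squared band with an RPD band and resolve
disagreements pessimistically (the lower band wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateTargetError,
    InvalidLabelsError,
    InvalidParameterError,
)

GRADES = ("insufficient", "usable", "good", "very good")


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/prediction partitioning: calibration fraction, optional
    stratification column, seed."""

    ratio: float
    stratify_by: str | None = "origin"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ratio < 1:
            raise InvalidParameterError("split ratio must be in (0, 1)")


def split(samples: pd.DataFrame, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive calibration/prediction row indices.

    With stratification, each stratum contributes ``round(ratio * size)``
    calibration members (clamped so both sets stay nonempty); assignment
    within a stratum is a seeded shuffle.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(samples)
    if spec.stratify_by is None:
        groups = [np.arange(n)]
    else:
        if spec.stratify_by not in samples.columns:
            raise InvalidParameterError(f"no column {spec.stratify_by!r} to stratify by")
        codes = samples[spec.stratify_by].to_numpy()
        groups = [np.flatnonzero(codes == g) for g in pd.unique(codes)]
        sizes = [len(g) for g in groups]
        if min(sizes) < 2:
            raise InvalidParameterError("every stratum needs at least 2 members")
    cal, pred = [], []
    for idx in groups:
        size = len(idx)
        n_cal = int(round(spec.ratio * size))
        n_cal = min(max(n_cal, 1), size - 1)
        perm = rng.permutation(idx)
        cal.append(perm[:n_cal])
        pred.append(perm[n_cal:])
    return np.sort(np.concatenate(cal)), np.sort(np.concatenate(pred))


def regression_metrics(
    y_true,
    y_pred,
    r2_mode: str = "pearson",
) -> dict:
    """R-squared, RMSE and RPD of one evaluated set.

    Returns ``{"r2": ..., "rmse": ..., "rpd": ..., "n": ...}``.  A perfect
    fit reports ``rpd = inf``; a constant prediction reports ``r2 = nan``
    (undefined correlation).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise DataError("need at least 2 observations")
    sd_true = float(np.std(y_true, ddof=1))
    if sd_true == 0:
        raise DegenerateTargetError("reference values are constant")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_pred) == 0:
        r2 = float("nan")
    elif r2_mode == "pearson":
        r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    elif r2_mode == "determination":
        r2 = float(1.0 - np.sum((y_true - y_pred) ** 2) / np.sum((y_true - y_true.mean()) ** 2))
    else:
        raise InvalidParameterError(f"unknown r2_mode {r2_mode!r}")
    rpd = float("inf") if rmse == 0 else sd_true / rmse
    return {"r2": r2, "rmse": rmse, "rpd": rpd, "n": int(y_true.size)}


def _r2_band(r2: float) -> int:
    if r2 > 0.90:
        return 3
    if r2 >= 0.80:
        return 2
    if r2 >= 0.60:
        return 1
    return 0


def _rpd_band(rpd: float) -> int:
    if rpd > 3.0:
        return 3
    if rpd >= 2.5:
        return 2
    if rpd >= 2.0:
        return 1
    return 0


def grade_model(r2_pred: float, rpd: float) -> str:
    """Grade a calibration from prediction-set R-squared and RPD.

    Bands: very good (R2 > 0.90 and RPD > 3.0), good (0.80-0.90 / 2.5-3.0),
    usable (0.60-0.80 / 2.0-2.5), else insufficient.  When the two bands
    disagree the lower one wins.
    """
    if not (np.isfinite(r2_pred) and (np.isfinite(rpd) or rpd == float("inf"))):
        raise InvalidParameterError("grade_model requires finite r2 (rpd may be +inf)")
    return GRADES[min(_r2_band(r2_pred), _rpd_band(rpd))]


@dataclass
class RegressionReport:
    """Calibration + prediction metrics for one target/pretreatment/model."""

    target: str
    pretreatment: str
    model: str
    r2_cal: float
    rmsec: float
    r2_pred: float
    rmsep: float
    rpd: float
    grade: str = field(default="")

    def __post_init__(self) -> None:
        if not self.grade:
            self.grade = grade_model(self.r2_pred, self.rpd)


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = truth, columns = predicted) and accuracy %."""

    confusion: pd.DataFrame
    accuracy_percent: float


def classification_metrics(truth_labels, predicted_labels, class_order=None) -> ClassificationReport:
    """Confusion counts and accuracy (percent, reported to 2 decimals)."""
    truth = np.asarray(truth_labels)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape:
        raise DataError("label vectors must have equal length")
    if truth.size == 0:
        raise DataError("empty label vectors")
    if class_order is None:
        class_order = list(pd.unique(np.concatenate([truth, pred])))
    class_order = list(class_order)
    unknown = set(np.unique(truth)) | set(np.unique(pred))
    if not unknown <= set(class_order):
        raise InvalidLabelsError(
            f"labels {sorted(unknown - set(class_order))} not in class_order"
        )
    k = len(class_order)
    pos = {c: i for i, c in enumerate(class_order)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        conf[pos[t], pos[p]] += 1
    confusion = pd.DataFrame(conf, index=class_order, columns=class_order)
    accuracy = round(100.0 * np.trace(conf) / truth.size, 2)
    return ClassificationReport(confusion=confusion, accuracy_percent=accuracy)
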