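"""Repeat-scan aggregation, consistency, threshold curves and ROC/AUC.

Three aggregation schemes are supported: keeping every scan (3N), taking
the repeat with the highest confidence, and a confidence-weighted mean
score. Confidence thresholding marks low-CI cores indeterminate and traces
accuracy against the excluded fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (EmptyInputError, InvalidScoreError, ShapeError,
                     UndefinedAggregateError, UndefinedAUCError,
                     UnreachableTargetError)
from .net import Prediction

DEFAULT_THRESHOLDS = np.linspace(0.0, 1.0, 101)


@dataclass
class RepeatSet:
    """Predictions for the repeats of one core plus its true label."""

    core_id: str
    predictions: list[Prediction]
    true_label: int = -1
    repeat_indices: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.predictions:
            raise EmptyInputError("a repeat set needs at least one prediction")
        if self.repeat_indices is None:
            self.repeat_indices = list(range(1, len(self.predictions) + 1))
        order = np.argsort(self.repeat_indices, kind="stable")
        self.predictions = [self.predictions[i] for i in order]
        self.repeat_indices = [self.repeat_indices[i] for i in order]

    @property
    def scores(self) -> list[int]:
        return [p.score for p in self.predictions]

    @property
    def cis(self) -> list[float]:
        return [p.ci for p in self.predictions]


@dataclass(frozen=True)
class AggregatedScore:
    score: int
    ci: float
    raw_value: float = float("nan")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def aggregate_max_ci(rs: RepeatSet) -> Prediction:
    """The repeat with maximal CI; ties go to the lowest repeat index."""
    cis = np.asarray(rs.cis)
    return rs.predictions[int(np.argmax(cis))]


def aggregate_weighted(rs: RepeatSet, normalize: bool = True,
                       n_classes: int = 4) -> AggregatedScore:
    """CI-weighted mean score, rounded half away from zero and clamped.

    With ``normalize`` (the default) the CI-weighted sum is divided by the
    total CI; the literal unnormalized sum is available behind the flag.
    The reported CI is the CI-weighted mean of the repeat CIs.
    """
    cis = np.asarray(rs.cis, dtype=np.float64)
    scores = np.asarray(rs.scores, dtype=np.float64)
    total = cis.sum()
    if total <= 0:
        raise UndefinedAggregateError("all CIs are zero")
    value = float((scores * cis).sum())
    if normalize:
        value /= total
    score = min(max(_round_half_away(value), 0), n_classes - 1)
    agg_ci = float((cis * cis).sum() / total)
    return AggregatedScore(score=score, ci=agg_ci, raw_value=value)


def consistency(rs: RepeatSet) -> float:
    """Fraction of repeats matching the modal score (lowest score on ties)."""
    scores = np.asarray(rs.scores)
    values, counts = np.unique(scores, return_counts=True)
    mode = values[np.argmax(counts)]  # ties -> lowest score (values sorted)
    return float((scores == mode).mean())


@dataclass
class ThresholdCurve:
    """Accuracy over determinate cores vs indeterminate fraction per theta."""

    thresholds: np.ndarray
    accuracy: np.ndarray              # NaN where no core is determinate
    indeterminate_fraction: np.ndarray

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.thresholds,
                             "accuracy": self.accuracy,
                             "indeterminate_frac": self.indeterminate_fraction})


def threshold_curve(y_true: Sequence[int], y_pred: Sequence[int],
                    ci: Sequence[float],
                    thresholds: Optional[np.ndarray] = None) -> ThresholdCurve:
    """Sweep theta: cores with CI < theta become indeterminate."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    ci = np.asarray(ci, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(ci)):
        raise ShapeError("y_true, y_pred and ci must have equal length")
    if len(y_true) == 0:
        raise EmptyInputError("need at least one prediction")
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds)

    correct = (y_true == y_pred)
    acc = np.full(len(thresholds), np.nan)
    indet = np.empty(len(thresholds))
    for i, theta in enumerate(thresholds):
        keep = ci >= theta
        indet[i] = 1.0 - keep.mean()
        if keep.any():
            acc[i] = correct[keep].mean()
    return ThresholdCurve(thresholds=thresholds, accuracy=acc,
                          indeterminate_fraction=indet)


def threshold_at_indeterminate(curve: ThresholdCurve,
                               target_fraction: float) -> float:
    """Smallest theta whose indeterminate fraction reaches the target."""
    if len(curve) == 0:
        raise EmptyInputError("empty curve")
    ok = curve.indeterminate_fraction >= target_fraction
    if not ok.any():
        raise UnreachableTargetError(
            f"no threshold reaches indeterminate fraction {target_fraction}")
    return float(curve.thresholds[np.argmax(ok)])


def binarize(score_4class: int) -> int:
    """Merge {0, 1+} -> 0 (negative) and {2+, 3+} -> 1 (positive)."""
    if score_4class not in (0, 1, 2, 3):
        raise InvalidScoreError(f"score must be in 0..3, got {score_4class!r}")
    return 0 if score_4class in (0, 1) else 1


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K), rows = true, cols = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        k = len(self.counts)
        return pd.DataFrame(self.counts,
                            index=[f"true_{i}" for i in range(k)],
                            columns=[f"pred_{i}" for i in range(k)])


def confusion_and_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                          n_classes: int) -> tuple[ConfusionMatrix, dict]:
    """Count matrix plus accuracy (and sensitivity/specificity for K=2).

    For the binary task class 1 (merged 2+/3+) is the positive class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ShapeError("y_true and y_pred must have the same length")
    if len(y_true) == 0:
        raise EmptyInputError("need at least one prediction")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[int(t), int(p)] += 1
    cm = ConfusionMatrix(counts=counts)
    metrics = {"accuracy": cm.accuracy}
    if n_classes == 2:
        tp, fn = counts[1, 1], counts[1, 0]
        tn, fp = counts[0, 0], counts[0, 1]
        metrics["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
        metrics["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    return cm, metrics


def roc_auc(positive_probabilities: Sequence[float],
            labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep; AUC by trapezoid; ties step simultaneously.

    Returns (fpr, tpr, auc) with class 1 positive.
    """
    p = np.asarray(positive_probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if len(p) != len(y):
        raise ShapeError("probabilities and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present")

    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == 0)
    # collapse tied scores onto a single operating point
    distinct = np.r_[np.nonzero(np.diff(p_sorted))[0], len(p_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# --------------------------------------------------------------------------- #
# dataframe plumbing used by the CLI


def repeat_sets_from_frame(predictions: pd.DataFrame,
                           labels: pd.DataFrame) -> list[RepeatSet]:
    """Build RepeatSets from a predictions table (core_id, repeat_index,
    score, ci, p0..pK) joined with a labels table (core_id, her2_score)."""
    prob_cols = sorted(c for c in predictions.columns if c.startswith("p")
                       and c[1:].isdigit())
    label_map = dict(zip(labels["core_id"], labels["her2_score"]))
    out = []
    for core_id, grp in predictions.groupby("core_id", sort=True):
        preds, reps = [], []
        for _, row in grp.iterrows():
            if prob_cols:
                probs = row[prob_cols].to_numpy(dtype=np.float64)
            else:
                k = int(predictions["score"].max()) + 1
                probs = np.zeros(max(k, 2))
                probs[int(row["score"])] = float(row["ci"])
                rest = (1.0 - float(row["ci"])) / (len(probs) - 1)
                probs[probs == 0] = rest
            preds.append(Prediction(probabilities=probs,
                                    score=int(row["score"]),
                                    ci=float(row["ci"])))
            reps.append(int(row.get("repeat_index", len(reps) + 1)))
        out.append(RepeatSet(core_id=str(core_id), predictions=preds,
                             true_label=int(label_map.get(core_id, -1)),
                             repeat_indices=reps))
    return out


def aggregate_sets(repeat_sets: Sequence[RepeatSet],
                   method: str) -> pd.DataFrame:
    """Aggregate each core with one scheme -> (core_id, score, ci, label).

    ``method``: 'all' keeps every scan as its own row (3N), 'maxci' keeps
    the highest-CI repeat, 'weighted' uses the CI-weighted mean score.
    """
    rows = []
    for rs in repeat_sets:
        if method == "all":
            for rep, pred in zip(rs.repeat_indices, rs.predictions):
                rows.append({"core_id": rs.core_id, "repeat_index": rep,
                             "score": pred.score, "ci": pred.ci,
                             "true_label": rs.true_label})
        elif method == "maxci":
            pred = aggregate_max_ci(rs)
            rows.append({"core_id": rs.core_id, "repeat_index": 0,
                         "score": pred.score, "ci": pred.ci,
                         "true_label": rs.true_label})
        elif method == "weighted":
            agg = aggregate_weighted(rs)
            rows.append({"core_id": rs.core_id, "repeat_index": 0,
                         "score": agg.score, "ci": agg.ci,
                         "true_label": rs.true_label})
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows)
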