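"""Two-stage surgical decision cascade and its evaluation suite.

Stage 1 (diagnosis) classifies every eye as ptotic or not; stage 2
(surgical plan), evaluated only for eyes that truly need surgery,
chooses between levator resection and frontalis suspension.  Positive
classes are fixed: stage 1 positive = "has ptosis" (so recall means
missed disease), stage 2 positive = frontalis suspension (so precision
tracks the costlier procedure).  Each stage is an independently trained
and tuned boosted-tree binary classifier over one feature scheme (2D,
3D, or both distance blocks).

Metrics are the five standard binary-classification indicators — ACC,
precision, recall, F1 and AUC — reported per task and scheme in a fixed
3 x 2 x 5 grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import LABEL_COLUMN, FeatureScheme, balance_training_set
from .errors import EvaluationError, FitError, PredictError
from .gbm import BoostConfig, BoostedEnsemble, HyperGrid, boost_fit, grid_search, predict_proba
from .synthcohort import SurgeryLabel

TASKS: tuple[str, ...] = ("diagnosis", "plan")
METRIC_NAMES: tuple[str, ...] = ("acc", "auc", "f1", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """ACC/precision/recall/F1/AUC for one task under one feature scheme."""

    acc: float
    precision: float
    recall: float
    f1: float
    auc: float
    task: str = ""
    scheme: FeatureScheme | None = None

    def as_dict(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in METRIC_NAMES}


@dataclass
class CascadeModel:
    """Diagnosis model + plan model sharing one feature scheme."""

    stage1: BoostedEnsemble
    stage2: BoostedEnsemble
    scheme: FeatureScheme
    threshold1: float = 0.5
    threshold2: float = 0.5
    stage1_config: BoostConfig | None = None
    stage2_config: BoostConfig | None = None


# ---------------------------------------------------------------------------
# metrics


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Standard binary confusion counts (positive class = 1)."""
    y = np.asarray(labels).astype(int).ravel()
    p = np.asarray(predictions).astype(int).ravel()
    if len(y) != len(p):
        raise EvaluationError("labels and predictions have different lengths")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2 P R / (P + R); 0 when both rates are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve, tie-corrected.

    Computed as the Mann-Whitney pairwise-ranking statistic (mid-ranks
    for ties), which equals the trapezoidal area under the ROC traced
    over all score thresholds.
    """
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if len(y) != len(s):
        raise EvaluationError("labels and scores have different lengths")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    task: str = "",
    scheme: FeatureScheme | None = None,
) -> MetricsReport:
    """Assemble the five-indicator report from counts (and scores for AUC).

    Zero-denominator rates are reported as 0 with a warning; AUC is NaN
    when no scores are supplied.
    """
    n = counts.total
    acc = (counts.tp + counts.tn) / n if n else 0.0
    if counts.tp + counts.fp == 0 or counts.tp + counts.fn == 0:
        if counts.tp + counts.fp == 0:
            warnings.warn("no predicted positives: precision set to 0", stacklevel=2)
        if counts.tp + counts.fn == 0:
            warnings.warn("no true positives present: recall set to 0", stacklevel=2)
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    auc = roc_auc(labels, scores) if scores is not None and labels is not None else float("nan")
    return MetricsReport(
        acc=acc,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        auc=auc,
        task=task,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# cascade training and prediction


def _stage_frames(train: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary working frames: stage 1 over all rows, stage 2 over surgical rows."""
    s1 = train.copy()
    s1["y"] = (s1[LABEL_COLUMN] != SurgeryLabel.NO_SURGERY.value).astype(int)
    surgical = train[train[LABEL_COLUMN] != SurgeryLabel.NO_SURGERY.value].copy()
    surgical["y"] = (
        surgical[LABEL_COLUMN] == SurgeryLabel.FRONTALIS_SUSPENSION.value
    ).astype(int)
    return s1, surgical


def train_cascade(
    train: pd.DataFrame,
    scheme: FeatureScheme,
    config: BoostConfig | HyperGrid | None = None,
    seed: int = 0,
) -> CascadeModel:
    """Train both cascade stages on one feature scheme.

    Each stage's training rows are balanced by minority oversampling;
    when ``config`` is a :class:`HyperGrid` the hyperparameters of each
    stage are tuned independently by grid search before the final fit.
    """
    present = set(train[LABEL_COLUMN].unique())
    needed = {lab.value for lab in SurgeryLabel}
    if not needed <= present:
        raise FitError(f"training rows must contain all three labels, missing {needed - present}")
    cols = list(scheme.columns)
    if config is None:
        config = BoostConfig()

    stages: list[tuple[BoostedEnsemble, BoostConfig]] = []
    for stage_idx, frame in enumerate(_stage_frames(train)):
        balanced = balance_training_set(frame, seed=seed + stage_idx, label_column="y")
        X = balanced[cols].to_numpy(dtype=float)
        y = balanced["y"].to_numpy(dtype=int)
        if isinstance(config, HyperGrid):
            cfg = grid_search(X, y, config, seed=seed + stage_idx)
        else:
            cfg = config
        stages.append((boost_fit(X, y, cfg), cfg))
    return CascadeModel(
        stage1=stages[0][0],
        stage2=stages[1][0],
        scheme=scheme,
        stage1_config=stages[0][1],
        stage2_config=stages[1][1],
    )


def cascade_scores(model: CascadeModel, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Stage-1 and stage-2 positive probabilities for each row."""
    missing = [c for c in model.scheme.columns if c not in rows.columns]
    if missing:
        raise PredictError(f"rows missing feature columns {missing}")
    X = rows[list(model.scheme.columns)].to_numpy(dtype=float)
    return predict_proba(model.stage1, X), predict_proba(model.stage2, X)


def predict_cascade(model: CascadeModel, rows: pd.DataFrame) -> list[SurgeryLabel]:
    """Cascade decision per row.

    Below the stage-1 threshold the eye is ruled healthy and stage 2 is
    never consulted; otherwise stage 2 picks frontalis suspension (its
    positive class) or levator resection.
    """
    p1, p2 = cascade_scores(model, rows)
    out: list[SurgeryLabel] = []
    for a, b in zip(p1, p2):
        if a < model.threshold1:
            out.append(SurgeryLabel.NO_SURGERY)
        elif b >= model.threshold2:
            out.append(SurgeryLabel.FRONTALIS_SUSPENSION)
        else:
            out.append(SurgeryLabel.LEVATOR_RESECTION)
    return out


# ---------------------------------------------------------------------------
# reporting


def evaluate_cascade(model: CascadeModel, test: pd.DataFrame) -> dict[str, MetricsReport]:
    """Five-metric reports for both tasks on held-out rows.

    Diagnosis is scored on every test row.  The surgical-plan task is
    scored only on rows whose *true* label is surgical, isolating plan
    quality from diagnostic errors.
    """
    p1, p2 = cascade_scores(model, test)
    y_dx = (test[LABEL_COLUMN] != SurgeryLabel.NO_SURGERY.value).to_numpy(dtype=int)
    pred_dx = (p1 >= model.threshold1).astype(int)
    dx = metrics(confusion(y_dx, pred_dx), p1, y_dx, task="diagnosis", scheme=model.scheme)

    surgical = y_dx == 1
    y_plan = (
        test.loc[surgical, LABEL_COLUMN] == SurgeryLabel.FRONTALIS_SUSPENSION.value
    ).to_numpy(dtype=int)
    pred_plan = (p2[surgical] >= model.threshold2).astype(int)
    plan = metrics(
        confusion(y_plan, pred_plan), p2[surgical], y_plan, task="plan", scheme=model.scheme
    )
    return {"diagnosis": dx, "plan": plan}


def build_report(
    test: pd.DataFrame, models: dict[FeatureScheme, CascadeModel]
) -> pd.DataFrame:
    """Evaluation grid: 3 schemes x 2 tasks x 5 metrics as a tidy frame."""
    for scheme in FeatureScheme:
        if scheme not in models:
            raise EvaluationError(f"no trained cascade for scheme {scheme.value!r}")
    rows = []
    for scheme in (FeatureScheme.THREE_D, FeatureScheme.TWO_D, FeatureScheme.BOTH):
        reports = evaluate_cascade(models[scheme], test)
        for task in TASKS:
            rows.append(
                {"task": task, "scheme": scheme.value, **reports[task].as_dict()}
            )
    return pd.DataFrame(rows, columns=["task", "scheme", *METRIC_NAMES])


_PRETTY = {
    "acc": "ACC",
    "auc": "AUC",
    "f1": "F1-score",
    "precision": "Precision",
    "recall": "Recall",
}
_SCHEME_ORDER = ("3d", "2d", "both")


def report_to_text(report: pd.DataFrame) -> str:
    """Render the evaluation grid as an aligned two-task text table."""
    head1 = f"{'Metric':<10}" + "Diagnostic discrimination".ljust(30) + "Surgical procedure classification"
    head2 = f"{'':<10}" + "".join(f"{s.upper():<10}" for s in _SCHEME_ORDER) * 2
    lines = [head1, head2]
    for metric in ("acc", "auc", "f1", "precision", "recall"):
        cells = []
        for task in TASKS:
            for s in _SCHEME_ORDER:
                row = report[(report["task"] == task) & (report["scheme"] == s)]
                cells.append(f"{float(row[metric].iloc[0]):<10.4f}")
        lines.append(f"{_PRETTY[metric]:<10}" + "".join(cells))
    return "\n".join(lines)
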