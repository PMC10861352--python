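"""Per-marker ROC characterization and leave-one-out panel validation.

The AUC is the empirical (nonparametric) one: the normalized Mann–Whitney U
statistic, i.e. the probability that a random case scores above a random
control with ties counted half. Each marker's direction is oriented so the
reported AUC is >= 0.5, encoding whether high or low values indicate a
case. The Youden-optimal cutoff maximizes J = sensitivity + specificity - 1
over midpoints between consecutive observed values (plus the two trivial
extremes), with ties broken toward higher specificity.

LOOCV refits the panel's unpenalized logistic coefficients on each n-1
subset and classifies the held-out subject at probability >= cutoff. The
panel itself is fixed — marker selection is *not* repeated inside the loop,
so the resulting accuracy still carries post-selection optimism; it removes
coefficient overfitting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic
from .io import GroupLabels

HIGH_IS_CASE = "high_is_case"
LOW_IS_CASE = "low_is_case"


@dataclass
class ClassificationMetrics:
    """Confusion counts with the derived accuracy/sensitivity/specificity."""

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = 0.5

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @classmethod
    def from_predictions(cls, y_true, y_pred, cutoff: float = 0.5
                         ) -> "ClassificationMetrics":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if set(np.unique(y_true)) != {0, 1}:
            raise ValueError("labels must contain both classes")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            cutoff=cutoff,
        )

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "cutoff": self.cutoff,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


@dataclass
class MarkerRoc:
    """Oriented AUC plus the Youden-optimal cutoff for one marker."""

    marker_id: str
    auc: float
    direction: str
    youden_threshold: float
    youden_j: float
    sensitivity_at_threshold: float
    specificity_at_threshold: float
    degenerate: bool = False

    @property
    def rule(self) -> str:
        op = ">=" if self.direction == HIGH_IS_CASE else "<="
        return f"case if value {op} {self.youden_threshold:g}"


@dataclass
class LoocvResult:
    """Held-out probability/prediction per subject plus aggregate metrics."""

    subject_ids: list[str]
    probabilities: np.ndarray
    predicted: np.ndarray
    true: np.ndarray
    metrics: ClassificationMetrics
    ridged_folds: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "held_out_probability": self.probabilities,
                "predicted": self.predicted,
                "true": self.true,
            }
        )


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    status = labels.status if isinstance(labels, GroupLabels) else np.asarray(labels)
    status = np.asarray(status, dtype=int)
    if scores.shape != status.shape:
        raise ValueError("scores and labels differ in length")
    case, control = scores[status == 1], scores[status == 0]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be nonempty")
    return case, control


def empirical_auc(scores, labels) -> float:
    """Normalized Mann–Whitney U via midranks: P(case > control) + ties/2."""
    case, control = _split(scores, labels)
    n1, n0 = len(case), len(control)
    ranks = stats.rankdata(np.r_[case, control])
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def roc_and_youden(values, labels, marker_id: str = "") -> MarkerRoc:
    """Orient a marker, then find its Youden-optimal cutoff.

    Direction is chosen so the oriented AUC >= 0.5 (``high_is_case`` wins
    exact 0.5 ties). Candidate thresholds are midpoints between consecutive
    sorted unique values plus the two infinite extremes; at the returned
    threshold the classification rule is inclusive (>= for high_is_case,
    <= for low_is_case). J-ties break toward higher specificity, then
    toward the more extreme threshold.
    """
    values = np.asarray(values, dtype=float)
    case, control = _split(values, labels)
    auc_raw = empirical_auc(values, labels)
    if np.ptp(values) == 0:
        return MarkerRoc(marker_id, 0.5, HIGH_IS_CASE, float(values[0]), 0.0,
                         1.0, 0.0, degenerate=True)
    direction = HIGH_IS_CASE if auc_raw >= 0.5 else LOW_IS_CASE
    auc = max(auc_raw, 1.0 - auc_raw)
    sgn = 1.0 if direction == HIGH_IS_CASE else -1.0
    s_case, s_control = sgn * case, sgn * control

    uniq = np.unique(np.r_[s_case, s_control])
    cand = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2.0, np.inf]
    sens = (s_case[:, None] >= cand[None, :]).mean(axis=0)
    spec = (s_control[:, None] < cand[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    # max J, ties -> higher specificity, then the larger (stricter) threshold
    best = max(range(len(cand)), key=lambda i: (j[i], spec[i], cand[i]))
    thr = sgn * cand[best]
    return MarkerRoc(
        marker_id=marker_id, auc=auc, direction=direction,
        youden_threshold=float(thr), youden_j=float(j[best]),
        sensitivity_at_threshold=float(sens[best]),
        specificity_at_threshold=float(spec[best]),
    )


def roc_table(rocs: list[MarkerRoc]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in rocs],
            "auc": [r.auc for r in rocs],
            "direction": [r.direction for r in rocs],
            "youden_threshold": [r.youden_threshold for r in rocs],
            "youden_j": [r.youden_j for r in rocs],
            "sens": [r.sensitivity_at_threshold for r in rocs],
            "spec": [r.specificity_at_threshold for r in rocs],
        }
    )


def loocv_panel(
    X: pd.DataFrame,
    labels: GroupLabels,
    panel: list[str],
    cutoff: float = 0.5,
    ridge_fallback: float = 1e-6,
) -> LoocvResult:
    """Leave-one-out validation of a fixed marker panel.

    For each subject, the unpenalized logistic model on ``panel`` is refit
    on the other n-1 subjects and the held-out subject is classified at
    probability >= ``cutoff``. An empty panel gives the intercept-only
    model (each fold predicts its training prevalence). Accuracy is the
    fraction of correct held-out predictions.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with marker columns")
    missing = [m for m in panel if m not in X.columns]
    if missing:
        raise KeyError(f"panel marker(s) absent from X: {missing}")
    n = len(X)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3 subjects")
    if list(X.index.astype(str)) != labels.subject_ids:
        raise ValueError("X rows and labels must share the same subject order")
    Xp = X[list(panel)].to_numpy(dtype=float) if panel else np.empty((n, 0))
    y = labels.status.astype(float)

    probs = np.empty(n)
    ridged: list[str] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        fit = fit_logistic(Xp[mask], y[mask], ridge_fallback=ridge_fallback)
        probs[i] = fit.predict_proba(Xp[i:i + 1])[0]
        if fit.ridged:
            ridged.append(labels.subject_ids[i])
        mask[i] = True
    predicted = (probs >= cutoff).astype(int)
    metrics = ClassificationMetrics.from_predictions(labels.status, predicted, cutoff)
    return LoocvResult(
        subject_ids=list(labels.subject_ids), probabilities=probs,
        predicted=predicted, true=labels.status.copy(), metrics=metrics,
        ridged_folds=ridged,
    )
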