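"""Performance metrics, ROC/AUC and the Friedman–Nemenyi model comparison.

The binary task treats P1B (dysplasia) as the positive/abnormal class and
A1 as the negative/normal class. Precision, recall, F1 and accuracy are
reported as percentages; AUC as a fraction in [0, 1].

Model comparison uses the Friedman rank test with models as treatments and
evaluation metrics as blocks (rank 1 = best within each block, average
ranks on ties), followed by the Nemenyi post-hoc critical difference:
two models differ significantly when their mean ranks are further apart
than CD = q_alpha(k) * sqrt(k(k+1)/(6n)), where q_alpha is the Studentized
range quantile at infinite degrees of freedom divided by sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .types import POSITIVE_LABEL, ValidationError

__all__ = [
    "ConfusionMatrix",
    "PredictionSet",
    "RankTestResult",
    "METRIC_COLUMNS",
    "FRIEDMAN_DEFAULT_BLOCKS",
    "confusion_counts",
    "metrics_from_cm",
    "roc_points",
    "auc_trapezoid",
    "auc_from_predictions",
    "friedman_test",
    "nemenyi_critical_difference",
    "plot_cd_diagram",
    "plot_roc",
]

#: Canonical metric column names for comparison tables.
METRIC_COLUMNS = ("precision", "recall", "f1", "accuracy", "auc")

#: Default Friedman block set: the four percentage metrics. AUC can be
#: included by passing ``blocks`` explicitly to :func:`friedman_test`.
FRIEDMAN_DEFAULT_BLOCKS = ("precision", "recall", "f1", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with P1B/abnormal as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PredictionSet:
    """Per-image true labels, predicted labels and positive-class scores."""

    y_true: np.ndarray  # label strings
    scores: np.ndarray  # P(positive) in [0, 1]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.y_true.shape != self.scores.shape:
            raise ValidationError("y_true and scores must have equal length")
        if self.y_true.size == 0:
            raise ValidationError("prediction set must be nonempty")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValidationError("scores must lie in [0, 1]")

    @property
    def y_pred(self) -> np.ndarray:
        """Predicted labels: score >= threshold maps to the positive class."""
        return np.where(self.scores >= self.threshold, POSITIVE_LABEL, "A1")

    @property
    def y_true_binary(self) -> np.ndarray:
        return (self.y_true == POSITIVE_LABEL).astype(int)


def confusion_counts(predictions: PredictionSet) -> ConfusionMatrix:
    """Partition predictions into TP/FP/FN/TN counts."""
    truth = predictions.y_true == POSITIVE_LABEL
    pred = predictions.y_pred == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(truth & pred)),
        fp=int(np.sum(~truth & pred)),
        fn=int(np.sum(truth & ~pred)),
        tn=int(np.sum(~truth & ~pred)),
    )


def metrics_from_cm(cm: ConfusionMatrix) -> dict[str, float]:
    """Precision, recall, F1 and accuracy as percentages.

    Zero-denominator metrics are defined as 0 with a warning, so that
    averaging over cross-validation folds stays total.
    """
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} denominator is zero; defining {name} = 0", stacklevel=3)
            return 0.0
        return 100.0 * num / den

    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision + recall == 0:
        warnings.warn("precision + recall is zero; defining f1 = 0", stacklevel=2)
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


def roc_points(predictions: PredictionSet) -> np.ndarray:
    """ROC curve as ordered (FPR, TPR) points from (0,0) to (1,1).

    Equal scores are grouped into a single threshold step.
    """
    y = predictions.y_true_binary
    if y.min() == y.max():
        raise ValidationError("ROC requires both classes present in the true labels")
    fpr, tpr, _ = roc_curve(y, predictions.scores)
    return np.column_stack([fpr, tpr])


def auc_trapezoid(points: np.ndarray) -> float:
    """Area under an ROC polyline by the trapezoidal rule."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def auc_from_predictions(predictions: PredictionSet) -> float:
    return auc_trapezoid(roc_points(predictions))


@dataclass(frozen=True)
class RankTestResult:
    """Friedman test output plus the Nemenyi critical difference."""

    mean_ranks: pd.Series  # index = model names, rank 1 = best
    chi_square: float
    p_value: float
    critical_difference: float
    alpha: float
    n_blocks: int
    k_models: int


def _rank_matrix(table: pd.DataFrame) -> np.ndarray:
    """Within-block ranks (rows = models, cols = blocks); 1 = best score."""
    values = table.to_numpy(dtype=float)
    return np.apply_along_axis(lambda col: stats.rankdata(-col), 0, values)


def friedman_test(
    table: pd.DataFrame | np.ndarray,
    blocks: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> RankTestResult:
    """Friedman rank test over a models x metrics table.

    Rows are models (treatments), columns are evaluation metrics (blocks).
    Higher scores are better and receive lower ranks; ties get average
    ranks. The statistic is chi2 = 12/(n*k*(k+1)) * sum(R_j^2) - 3n(k+1)
    over per-model rank sums R_j, referred to a chi-square distribution
    with k-1 degrees of freedom. The Nemenyi critical difference at the
    same alpha is attached for convenience.

    Parameters
    ----------
    table
        Metric table; a DataFrame indexed by model name, or a 2-D array.
    blocks
        Column subset to use as blocks. Defaults to the four percentage
        metrics when those columns are present, else all columns.
    """
    if not isinstance(table, pd.DataFrame):
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("metric table must be rectangular (2-D)")
        table = pd.DataFrame(arr, index=[f"model_{i}" for i in range(arr.shape[0])])
    if blocks is None and set(FRIEDMAN_DEFAULT_BLOCKS).issubset(table.columns):
        blocks = FRIEDMAN_DEFAULT_BLOCKS
    if blocks is not None:
        table = table.loc[:, list(blocks)]
    if table.isna().any().any():
        raise ValidationError("metric table must be rectangular with no missing cells")
    k, n = table.shape[0], table.shape[1]
    if k < 2 or n < 2:
        raise ValidationError(f"Friedman test needs >=2 models and >=2 blocks, got {k}x{n}")

    ranks = _rank_matrix(table)
    rank_sums = ranks.sum(axis=1)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    cd = nemenyi_critical_difference(k=k, n=n, alpha=alpha)
    return RankTestResult(
        mean_ranks=pd.Series(rank_sums / n, index=table.index, name="mean_rank"),
        chi_square=float(chi2),
        p_value=p,
        critical_difference=cd,
        alpha=alpha,
        n_blocks=n,
        k_models=k,
    )


def nemenyi_critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference in rank units.

    CD = q_alpha(k) * sqrt(k(k+1)/(6n)), with q_alpha(k) the Studentized
    range quantile at infinite degrees of freedom divided by sqrt(2).
    """
    if k < 2:
        raise ValidationError(f"Nemenyi CD needs k >= 2 models, got {k}")
    if n < 1:
        raise ValidationError(f"Nemenyi CD needs n >= 1 blocks, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    q = float(stats.studentized_range.ppf(1.0 - alpha, k, np.inf)) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def plot_cd_diagram(mean_ranks: pd.Series, cd: float, path) -> None:
    """Critical-difference diagram: best (lowest mean rank) leftmost.

    Models sit on a rank axis at their mean ranks; a reference bar shows
    the CD length, and thick horizontal bars connect groups of models
    whose mean ranks differ by less than CD (statistically
    indistinguishable at the test's alpha).
    """
    ranks = pd.Series(mean_ranks).sort_values()
    k = len(ranks)
    lo = np.floor(ranks.min() - 0.25)
    hi = np.ceil(ranks.max() + 0.25)

    fig, ax = plt.subplots(figsize=(7, 1.6 + 0.5 * k))
    ax.set_xlim(lo, hi)
    ax.set_ylim(-k - 1.5, 1.8)
    ax.spines[["left", "right", "bottom"]].set_visible(False)
    ax.xaxis.set_ticks_position("top")
    ax.yaxis.set_visible(False)
    ax.set_xlabel("")

    # model stems, best (lowest rank) leftmost
    for i, (name, r) in enumerate(ranks.items()):
        y = -(i + 1)
        ax.plot([r, r], [0, y], color="k", lw=1)
        ax.text(r, y - 0.15, f"{name} ({r:.2f})", ha="center", va="top", fontsize=9)

    # CD reference bar
    ax.plot([lo, lo + cd], [1.2, 1.2], color="k", lw=2)
    ax.text(lo + cd / 2, 1.35, f"CD = {cd:.3f}", ha="center", va="bottom", fontsize=9)

    # connect maximal groups of mutually indistinguishable models
    if k > 1:
        vals = ranks.to_numpy()
        groups = []
        for i in range(k):
            j = i
            while j + 1 < k and vals[j + 1] - vals[i] < cd:
                j += 1
            if j > i:
                groups.append((i, j))
        groups = [g for g in groups if not any(o[0] <= g[0] and g[1] <= o[1] and o != g for o in groups)]
        for level, (i, j) in enumerate(groups):
            y = 0.35 + 0.3 * level
            ax.plot([vals[i] - 0.03, vals[j] + 0.03], [y, y], color="k", lw=3)

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(prediction_sets: dict[str, PredictionSet], path) -> None:
    """Overlay ROC curves for several models, AUC in the legend."""
    if not prediction_sets:
        raise ValidationError("plot_roc requires at least one prediction set")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for name, preds in prediction_sets.items():
        pts = roc_points(preds)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC = {auc_trapezoid(pts):.3f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
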