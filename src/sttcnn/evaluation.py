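"""Classification metrics, model comparison tests and ablation reports.

Accuracy, precision, recall and F1 are computed from the confusion
matrix with the usual one-vs-rest reduction: for class ``i``,
``TP = cm[i, i]``, ``FP`` = other rows predicted as ``i``, ``FN`` =
class-``i`` rows predicted elsewhere.  Multi-class summaries use macro
averaging (the unweighted class mean).  Undefined ratios (a class never
predicted, or absent) are reported as 0 rather than NaN so downstream
tables stay numeric.

Model-vs-model comparisons use a two-tailed Student t-test on accuracy
vectors — unpaired with pooled variance by default, paired optionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .training import FoldResult

__all__ = ["MetricsReport", "CVReport", "ComparisonResult", "AblationReport",
           "confusion_matrix", "metrics_from_confusion", "compare_models",
           "ablation_report"]


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> np.ndarray:
    """Counts[i, j] = number of class-``i`` items predicted as class ``j``."""
    t = np.asarray(true_labels, dtype=np.int64).ravel()
    p = np.asarray(predicted_labels, dtype=np.int64).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape} vs {p.shape}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    if t.size == 0:
        return cm
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    np.add.at(cm, (t, p), 1)
    return cm


@dataclass
class MetricsReport:
    """Accuracy plus per-class and macro precision / recall / F1."""

    accuracy: float
    precision: np.ndarray      # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    support: np.ndarray        # true count per class

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "f1": self.f1.tolist(),
                "support": self.support.tolist(),
            },
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """Accuracy / precision / recall / F1 via one-vs-rest reduction."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return MetricsReport(
        accuracy=float(tp.sum() / total),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        support=cm.sum(axis=1),
    )


@dataclass
class CVReport:
    """Cross-validation summary for one model variant on one task."""

    fold_accuracies: list[float]
    mean_accuracy: float
    variance: float                      # population variance of fold accuracies
    confusion: np.ndarray                # pooled over held-out folds
    metrics: MetricsReport
    variant: str
    task: str
    fold_results: "list[FoldResult]" = field(default_factory=list, repr=False)

    def recomputed_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def recomputed_variance(self) -> float:
        return float(np.var(self.fold_accuracies))


@dataclass
class ComparisonResult:
    """Two-tailed Student t-test between two accuracy vectors."""

    t_value: float
    p_value: float
    df: float
    paired: bool


def compare_models(accs_a, accs_b, paired: bool = False) -> ComparisonResult:
    """Student t-test on two accuracy vectors (two-tailed).

    Unpaired uses the pooled-variance two-sample form; ``paired=True``
    uses the paired t-test and requires equal lengths.  Two constant
    samples have an undefined statistic and raise ``ValueError``.
    """
    a = np.asarray(accs_a, dtype=np.float64)
    b = np.asarray(accs_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each accuracy vector needs at least 2 entries")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal-length vectors")
        if np.var(a - b) == 0 and not np.allclose(a, b):
            raise ValueError("degenerate paired test: constant nonzero differences")
        res = stats.ttest_rel(a, b)
        df = a.size - 1
    else:
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                return ComparisonResult(0.0, 1.0, a.size + b.size - 2, paired)
            raise ValueError("degenerate t-test: both samples have zero variance")
        res = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    return ComparisonResult(float(res.statistic), float(res.pvalue), float(df), paired)


@dataclass
class AblationReport:
    """Per-variant summary plus the pairwise t-test grid."""

    task: str
    summary_rows: list[dict]             # one per variant
    comparison_rows: list[dict]          # one per variant pair

    _SUMMARY_COLS = ("variant", "mean_accuracy", "variance",
                     "macro_precision", "macro_recall", "macro_f1")
    _COMPARISON_COLS = ("model_a", "model_b", "t_value", "p_value", "df")

    def to_delimited(self, sep: str = "\t") -> str:
        lines = [sep.join(self._SUMMARY_COLS)]
        for row in self.summary_rows:
            lines.append(sep.join(_fmt(row[c]) for c in self._SUMMARY_COLS))
        if self.comparison_rows:
            lines.append("")
            lines.append(sep.join(self._COMPARISON_COLS))
            for row in self.comparison_rows:
                lines.append(sep.join(_fmt(row[c]) for c in self._COMPARISON_COLS))
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:
        out = [f"Ablation report — task: {self.task}", ""]
        out.append(f"{'variant':<10}{'acc':>8}{'var':>10}{'P':>8}{'R':>8}{'F1':>8}")
        for r in self.summary_rows:
            out.append(f"{r['variant']:<10}{r['mean_accuracy']:>8.4f}{r['variance']:>10.6f}"
                       f"{r['macro_precision']:>8.4f}{r['macro_recall']:>8.4f}"
                       f"{r['macro_f1']:>8.4f}")
        if self.comparison_rows:
            out += ["", f"{'comparison':<22}{'t':>9}{'p':>9}{'df':>5}"]
            for r in self.comparison_rows:
                out.append(f"{r['model_a'] + ' vs ' + r['model_b']:<22}"
                           f"{r['t_value']:>9.3f}{r['p_value']:>9.4f}{r['df']:>5.0f}")
        return "\n".join(out)


def _fmt(v) -> str:
    return f"{v:.10g}" if isinstance(v, float) else str(v)


def ablation_report(cv_reports: "list[CVReport]", paired: bool = False) -> AblationReport:
    """Summarise several variants' CV results and compare them pairwise."""
    if not cv_reports:
        raise ValueError("no CV reports given")
    tasks = {r.task for r in cv_reports}
    if len(tasks) > 1:
        raise ValueError(f"reports mix tasks: {sorted(tasks)}")
    summary = [{
        "variant": r.variant,
        "mean_accuracy": r.mean_accuracy,
        "variance": r.variance,
        "macro_precision": r.metrics.macro_precision,
        "macro_recall": r.metrics.macro_recall,
        "macro_f1": r.metrics.macro_f1,
    } for r in cv_reports]
    comparisons = []
    for i in range(len(cv_reports)):
        for j in range(i + 1, len(cv_reports)):
            a, b = cv_reports[i], cv_reports[j]
            try:
                res = compare_models(a.fold_accuracies, b.fold_accuracies, paired=paired)
                row = {"t_value": res.t_value, "p_value": res.p_value, "df": res.df}
            except ValueError:
                row = {"t_value": float("nan"), "p_value": float("nan"), "df": float("nan")}
            comparisons.append({"model_a": a.variant, "model_b": b.variant, **row})
    return AblationReport(task=tasks.pop(), summary_rows=summary,
                          comparison_rows=comparisons)
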