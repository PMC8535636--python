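"""Evaluation metrics and report conventions.

Conventions used throughout (they match how multi-class clinical tables are
usually printed):

* The per-class "Accuracy" column of a report is that class's **recall**
  (each table row scores one disease one-vs-rest, and the row accuracy is
  computed on the cases truly of that class).
* The "Total" row mixes conventions: total accuracy is **micro** (fraction
  of all cases predicted correctly), while total recall/precision/F1 are
  unweighted **macro** means over the classes.
* One-vs-rest AUC uses the Mann-Whitney construction with half credit for
  ties; the total AUC is the macro mean.
* Displayed rates are rounded half-up to 2 decimals (3 for AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .utils import round_half_up


class MetricError(ValueError):
    """Raised on invalid metric inputs (zero variance, shape mismatch...)."""


# ---------------------------------------------------------------------------
# Quality / restoration metrics


def plcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson linear correlation COV(X,Y)/(sd(X)*sd(Y)).

    Symmetric and invariant to positive affine rescaling of either argument.
    Raises :class:`MetricError` on zero-variance input rather than
    returning NaN.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or x.size != y.size:
        raise MetricError(f"length mismatch or empty: {x.size} vs {y.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc**2))
    sy = np.sqrt(np.mean(yc**2))
    if sx == 0 or sy == 0:
        raise MetricError("zero-variance vector in PLCC")
    return float(np.mean(xc * yc) / (sx * sy))


def mse_image(i: np.ndarray, k: np.ndarray) -> float:
    """Mean squared pixel difference; channel stacks average over channels."""
    i = np.asarray(i, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if i.shape != k.shape:
        raise MetricError(f"shape mismatch: {i.shape} vs {k.shape}")
    return float(np.mean((i - k) ** 2))


# ---------------------------------------------------------------------------
# Classification metrics


def f1(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); defined 0 when both inputs are 0."""
    if not (0.0 <= precision <= 1.0) or not (0.0 <= recall <= 1.0):
        raise MetricError(f"precision/recall outside [0,1]: {precision}, {recall}")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_auc_ovr(
    true_labels: np.ndarray, scores: np.ndarray, positive_label
) -> float:
    """One-vs-rest AUC via the normalized Mann-Whitney U (ties get 1/2).

    ``scores`` are the positive-class scores, one per sample.
    """
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=np.float64)
    if true_labels.shape[0] != scores.shape[0]:
        raise MetricError("label/score length mismatch")
    pos = true_labels == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError(
            f"one-vs-rest for {positive_label!r} needs both classes present"
        )
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2 credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Confusion matrix plus the per-class and total table quantities."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # (K, K), rows = true, cols = predicted
    n: int
    per_class: dict[str, dict[str, float]]
    totals: dict[str, float]
    extra: dict = field(default_factory=dict)

    def row(self, name: str) -> dict[str, float]:
        return self.per_class[name]


def confusion_matrix(
    true_labels: np.ndarray, pred_labels: np.ndarray, classes: tuple[str, ...]
) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        cm[lut[t], lut[p]] += 1
    return cm


def classification_report(
    true_labels,
    pred_labels,
    scores: np.ndarray | None = None,
    classes: tuple[str, ...] | None = None,
) -> MetricsReport:
    """Build the full table from labels and (optionally) an n x K score matrix.

    Per class: recall, precision, F1, one-vs-rest AUC, and the "accuracy"
    column equal to recall. Totals: micro accuracy, macro recall/precision/
    F1, macro AUC.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise MetricError("label vector length mismatch")
    if classes is None:
        classes = tuple(np.unique(true_labels).tolist())
    unseen = set(np.unique(pred_labels)) - set(classes)
    if unseen:
        raise MetricError(f"predictions contain unseen classes: {sorted(unseen)}")
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (true_labels.shape[0], len(classes)):
            raise MetricError(
                f"scores must be (n, K) = ({true_labels.shape[0]}, {len(classes)}), "
                f"got {scores.shape}"
            )
    cm = confusion_matrix(true_labels, pred_labels, classes)
    n = int(cm.sum())
    per_class: dict[str, dict[str, float]] = {}
    for k, name in enumerate(classes):
        tp = float(cm[k, k])
        support = float(cm[k].sum())
        predicted = float(cm[:, k].sum())
        recall = tp / support if support else 0.0
        precision = tp / predicted if predicted else 0.0
        row = {
            "n": support,
            "accuracy": recall,
            "recall": recall,
            "precision": precision,
            "f1": f1(precision, recall),
        }
        if scores is not None:
            row["auc"] = roc_auc_ovr(true_labels, scores[:, k], name)
        per_class[name] = row
    totals = {
        "n": float(n),
        "micro_accuracy": float(np.trace(cm)) / n if n else 0.0,
        "macro_recall": float(np.mean([r["recall"] for r in per_class.values()])),
        "macro_precision": float(np.mean([r["precision"] for r in per_class.values()])),
        "macro_f1": float(np.mean([r["f1"] for r in per_class.values()])),
    }
    if scores is not None:
        totals["macro_auc"] = float(np.mean([r["auc"] for r in per_class.values()]))
    return MetricsReport(
        classes=tuple(classes), confusion=cm, n=n, per_class=per_class, totals=totals
    )


# ---------------------------------------------------------------------------
# Accuracy comparison


def compare_accuracy(
    correct_a: np.ndarray, correct_b: np.ndarray, paired: bool = True
) -> dict[str, float]:
    """Chi-square comparison of two models' per-case correctness.

    ``paired=True`` (two models scored on the same cases) runs McNemar's
    test on the discordant pairs; ``paired=False`` runs the plain Pearson
    chi-square on the 2x2 correct/incorrect totals. Returns statistic,
    degrees of freedom and p-value.
    """
    a = np.asarray(correct_a).astype(bool)
    b = np.asarray(correct_b).astype(bool)
    if paired:
        if a.shape != b.shape:
            raise MetricError("paired comparison requires equal-length vectors")
        n01 = int(np.sum(~a & b))
        n10 = int(np.sum(a & ~b))
        if n01 + n10 == 0:
            import warnings

            warnings.warn("no discordant pairs; p = 1", stacklevel=2)
            return {"statistic": 0.0, "df": 1.0, "p_value": 1.0, "n01": 0.0, "n10": 0.0}
        stat = (n10 - n01) ** 2 / (n10 + n01)
        p = float(stats.chi2.sf(stat, df=1))
        return {
            "statistic": float(stat),
            "df": 1.0,
            "p_value": p,
            "n01": float(n01),
            "n10": float(n10),
        }
    table = np.array(
        [
            [int(a.sum()), int((~a).sum())],
            [int(b.sum()), int((~b).sum())],
        ],
        dtype=np.float64,
    )
    if np.any(table.sum(axis=1) == 0):
        raise MetricError("empty correctness vector")
    res = stats.chi2_contingency(table, correction=False)
    return {
        "statistic": float(res.statistic),
        "df": float(res.dof),
        "p_value": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# Display helpers


def rounded_row(row: dict[str, float]) -> dict[str, float]:
    """Apply the table rounding convention (2 d.p., AUC 3 d.p.)."""
    out = {}
    for key, val in row.items():
        if key == "n":
            out[key] = int(val)
        elif key == "auc":
            out[key] = round_half_up(val, 3)
        else:
            out[key] = round_half_up(val, 2)
    return out
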