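"""The two multi-task regimes, end to end.

*Common cascade*: quality assessment -> conditional de-blurring (7-channel
restoration net trained on plain blurred/sharp pairs) -> classification.

*Guided regime (MTL-IF)*: the classifier is trained on sharp data first and
frozen; Grad-CAM maps from the frozen classifier on the blurred inputs are
channel-concatenated onto them, and an 8-channel restoration net is trained
against the sharp targets — only the restoration weights update. At
inference blurred-routed cases are guided-restored and re-classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .case import IFCase, ValidationError, case_labels, stack_cases
from .gradcam import gradcam_batch
from .metrics import MetricsReport, classification_report, compare_accuracy
from .models import DeblurNetwork, IQARegressor, StackClassifier
from .models.iqa import QualityScore


@dataclass
class CaseResult:
    """Outcome of one case through a cascade."""

    case_id: str
    true_label: str
    quality_score: float
    routed: bool
    probs: np.ndarray
    predicted_label: str
    restored: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.routed != (self.restored is not None):
            raise ValidationError("restored stack must be present iff routed")


def _check_models(
    iqa: IQARegressor, deblur: DeblurNetwork, classifier: StackClassifier, mode: str
) -> None:
    expected = 8 if mode == "mtl_if" else 7
    if deblur.in_channels != expected:
        raise ValidationError(
            f"{mode} cascade needs a {expected}-channel de-blur net, "
            f"got {deblur.in_channels}"
        )
    if classifier.in_channels != 7 or iqa.in_channels != 7:
        raise ValidationError("IQA and classifier must take 7-channel stacks")


def run_cascade(
    iqa: IQARegressor,
    deblur: DeblurNetwork,
    classifier: StackClassifier,
    cases: list[IFCase],
    mode: str = "common",
) -> list[CaseResult]:
    """Run IQA -> route -> (guided) de-blur -> classify over ``cases``."""
    if mode not in ("common", "mtl_if"):
        raise ValidationError(f"unknown mode {mode!r}")
    _check_models(iqa, deblur, classifier, mode)
    if not cases:
        return []
    X = stack_cases(cases)
    scores = iqa.predict_scores(X)
    routed = scores < iqa.threshold  # ties count as non-blurred
    final = X.copy()
    restored_stacks: dict[int, np.ndarray] = {}
    idx = np.flatnonzero(routed)
    if idx.size:
        Xb = X[idx]
        if mode == "mtl_if":
            cams = gradcam_batch(classifier, Xb, target="argmax")
            Xb = np.concatenate([Xb, cams[:, None]], axis=1)
        restored = deblur.transform(Xb)
        final[idx] = restored
        for j, i in enumerate(idx):
            restored_stacks[int(i)] = restored[j]
    probs = classifier.predict_proba(final)
    preds = classifier.classes_[probs.argmax(axis=1)]
    results = []
    for i, case in enumerate(cases):
        results.append(
            CaseResult(
                case_id=case.case_id,
                true_label=case.label,
                quality_score=float(scores[i]),
                routed=bool(routed[i]),
                probs=probs[i],
                predicted_label=str(preds[i]),
                restored=restored_stacks.get(i),
            )
        )
    return results


run_common_mtl = run_cascade  # common regime is the default mode


def run_mtl_if(
    frozen_classifier: StackClassifier,
    guided_deblur: DeblurNetwork,
    iqa: IQARegressor,
    cases: list[IFCase],
) -> list[CaseResult]:
    return run_cascade(iqa, guided_deblur, frozen_classifier, cases, mode="mtl_if")


def train_mtl_if(
    frozen_classifier: StackClassifier,
    deblur_model: DeblurNetwork,
    X_blurred: np.ndarray,
    Y_sharp: np.ndarray,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
) -> DeblurNetwork:
    """Guided de-blurring training with a frozen classifier.

    Grad-CAM maps are taken from the frozen classifier on the blurred
    inputs (argmax class — no label leakage) and concatenated as an 8th
    channel; the de-blur net alone is then fit against the sharp targets.
    The classifier is frozen throughout, so the maps are fixed and are
    computed once up front — identical to recomputing them every batch.
    Classifier weights are verified bit-identical before/after.
    """
    if not hasattr(frozen_classifier, "classes_"):
        raise ValidationError("classifier must be trained (frozen) before guidance")
    if deblur_model.in_channels != 8:
        raise ValidationError(
            f"guided de-blur net needs 8 input channels, got {deblur_model.in_channels}"
        )
    checksum_before = frozen_classifier.weight_checksum()
    X_blurred = np.asarray(X_blurred, dtype=np.float32)
    cams = gradcam_batch(frozen_classifier, X_blurred, target="argmax")
    Xg = np.concatenate([X_blurred, cams[:, None]], axis=1)
    if X_val is not None:
        cams_val = gradcam_batch(frozen_classifier, np.asarray(X_val, np.float32))
        X_val = np.concatenate([np.asarray(X_val, np.float32), cams_val[:, None]], axis=1)
    deblur_model.fit(Xg, Y_sharp, X_val=X_val, y_val=Y_val)
    checksum_after = frozen_classifier.weight_checksum()
    if checksum_before != checksum_after:  # pragma: no cover - structural guarantee
        raise RuntimeError("classifier weights changed during guided training")
    return deblur_model


def guided_transform(
    frozen_classifier: StackClassifier, guided_deblur: DeblurNetwork, X: np.ndarray
) -> np.ndarray:
    """Guided restoration of blurred stacks (N, 7, H, W) -> (N, 7, H, W)."""
    X = np.asarray(X, dtype=np.float32)
    cams = gradcam_batch(frozen_classifier, X, target="argmax")
    return guided_deblur.transform(np.concatenate([X, cams[:, None]], axis=1))


def evaluate_results(
    results: list[CaseResult],
    classes: tuple[str, ...] | None = None,
    baseline: list[CaseResult] | None = None,
) -> tuple[MetricsReport, dict | None]:
    """Build the standard report; optionally a paired accuracy comparison.

    When ``baseline`` is given it must cover the same cases (same ids, same
    order); the McNemar chi-square on per-case correctness is returned as
    the second element.
    """
    if not results:
        raise ValidationError("no results to evaluate")
    true = np.array([r.true_label for r in results])
    pred = np.array([r.predicted_label for r in results])
    scores = np.stack([r.probs for r in results])
    report = classification_report(true, pred, scores=scores, classes=classes)
    comparison = None
    if baseline is not None:
        if [r.case_id for r in baseline] != [r.case_id for r in results]:
            raise ValidationError("comparison requires identical case sets in order")
        correct_a = np.array([r.predicted_label == r.true_label for r in results])
        correct_b = np.array([r.predicted_label == r.true_label for r in baseline])
        comparison = compare_accuracy(correct_a, correct_b, paired=True)
    return report, comparison
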