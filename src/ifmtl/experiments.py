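"""Reference synthetic benchmark: one full run of both cascades.

This is the package's standard desk-scale experiment — 200 synthetic cases
(50 per disease) at 64 x 64 px, split 8:2 into 160 training / 40 test
cases, every image additionally degraded with per-case Gaussian defocus
(sigma uniform in [1, 3]). On top of that one draw it trains all three
subnets, the plain and the attention-guided restoration nets under equal
budgets, and measures every headline quantity of the method:

* classifier accuracy on sharp vs blurred test stacks,
* IQA correlation (PLCC) and binary quality accuracy,
* held-out restoration MSE of blurred / plain-restored / guided-restored
  stacks (globally and inside the ground-truth deposit masks),
* cascade accuracies of the common and the guided (MTL-IF) regimes with a
  paired McNemar comparison,
* Grad-CAM overlap with the ground-truth deposit masks,
* the classifier freeze checksum across guided training.

Training schedules here are deliberately smaller than the estimator
defaults (fewer epochs, higher learning rate) so the whole run fits in a
few minutes on one CPU core; all schedule choices are fixed constants of
the benchmark, not tuned per seed.
"""

from __future__ import annotations

import numpy as np

from .case import IFCase, stack_cases
from .gradcam import gradcam_map
from .metrics import mse_image, plcc
from .models import DeblurNetwork, IQARegressor, StackClassifier
from .pipeline import evaluate_results, run_cascade, train_mtl_if

#: Benchmark study conditions.
N_PER_CLASS = 50
IMAGE_SIZE = 64
SPLIT_RATIO = 0.8
SIGMA_RANGE = (1.0, 3.0)

#: Desk-scale training schedules (fixed).
CLF_KW = dict(epochs=40, batch_size=16, learning_rate=1.5e-3)
IQA_KW = dict(epochs=15, batch_size=32, learning_rate=1e-3)
DEBLUR_KW = dict(
    n_blocks=4,
    layers_per_block=2,
    growth_rate=8,
    base_channels=16,
    epochs=10,
    batch_size=16,
    learning_rate=1.5e-3,
)


def _masked_mse(restored: np.ndarray, sharp: np.ndarray, masks: np.ndarray) -> float:
    """MSE restricted to deposit-mask pixels (averaged over all channels)."""
    diff2 = (restored.astype(np.float64) - sharp.astype(np.float64)) ** 2
    m = masks[:, None, :, :]
    return float((diff2 * m).sum() / (m.sum() * restored.shape[1]))


def gradcam_mask_overlap(
    classifier: StackClassifier, cases: list[IFCase]
) -> tuple[float, int]:
    """Fraction of correctly classified cases whose Grad-CAM map is denser
    inside the deposit mask than outside. Returns (fraction, n_correct)."""
    preds = classifier.predict(stack_cases(cases))
    hits = 0
    n_correct = 0
    for case, pred in zip(cases, preds):
        if pred != case.label or case.deposit_mask is None:
            continue
        n_correct += 1
        heat = gradcam_map(classifier, case, target_class="argmax").map
        if heat[case.deposit_mask].mean() > heat[~case.deposit_mask].mean():
            hits += 1
    return (hits / n_correct if n_correct else 0.0), n_correct


def run_benchmark(seed: int, n_per_class: int = N_PER_CLASS) -> dict:
    """Run the full benchmark once; returns a flat dict of measurements."""
    from .synthetic import SynthSpec, blur_dataset, generate_dataset, split_dataset

    seed = int(seed) % (2**31 - 10_000)
    cases = generate_dataset(
        SynthSpec(n_per_class=n_per_class, image_size=IMAGE_SIZE, seed=seed)
    )
    train, test = split_dataset(cases, SPLIT_RATIO, seed=seed)
    train_b = blur_dataset(train, SIGMA_RANGE, seed=seed + 1000)
    test_b = blur_dataset(test, SIGMA_RANGE, seed=seed + 2000)

    Xtr, Xtr_b = stack_cases(train), stack_cases(train_b)
    Xte, Xte_b = stack_cases(test), stack_cases(test_b)
    ytr = np.array([c.label for c in train])
    yte = np.array([c.label for c in test])
    masks_te = np.stack([c.deposit_mask for c in test])

    out: dict[str, float] = {"n_train": len(train), "n_test": len(test)}

    # -- classifier on sharp data, evaluated sharp vs blurred ----------
    clf = StackClassifier(seed=seed, **CLF_KW)
    clf.fit(Xtr, ytr)
    out["clf_sharp_accuracy"] = float((clf.predict(Xte) == yte).mean())
    out["clf_blurred_accuracy"] = float((clf.predict(Xte_b) == yte).mean())

    # -- IQA ----------------------------------------------------------
    iqa = IQARegressor(seed=seed, **IQA_KW)
    X_iqa = np.concatenate([Xtr, Xtr_b])
    y_iqa = np.concatenate([np.ones(len(train)), np.zeros(len(train_b))])
    iqa.fit(X_iqa, y_iqa)
    scores = iqa.predict_scores(np.concatenate([Xte, Xte_b]))
    truth = np.concatenate([np.ones(len(test)), np.zeros(len(test_b))])
    out["iqa_plcc"] = plcc(scores, truth)
    out["iqa_accuracy"] = float(((scores >= iqa.threshold) == truth).mean())

    # -- restoration: plain vs guided under identical budgets ----------
    deblur7 = DeblurNetwork(in_channels=7, seed=seed, **DEBLUR_KW)
    deblur7.fit(Xtr_b, Xtr)
    restored_common = deblur7.transform(Xte_b)

    checksum_before = clf.weight_checksum()
    deblur8 = DeblurNetwork(in_channels=8, guidance_channels=1, seed=seed, **DEBLUR_KW)
    train_mtl_if(clf, deblur8, Xtr_b, Xtr)
    out["clf_frozen_through_guided_training"] = float(
        clf.weight_checksum() == checksum_before
    )
    from .pipeline import guided_transform

    restored_guided = guided_transform(clf, deblur8, Xte_b)

    out["mse_blurred"] = mse_image(Xte_b, Xte)
    out["mse_restored_common"] = mse_image(restored_common, Xte)
    out["mse_restored_guided"] = mse_image(restored_guided, Xte)
    out["mse_mask_blurred"] = _masked_mse(Xte_b, Xte, masks_te)
    out["mse_mask_common"] = _masked_mse(restored_common, Xte, masks_te)
    out["mse_mask_guided"] = _masked_mse(restored_guided, Xte, masks_te)

    # -- cascades on the blurred test set ------------------------------
    res_common = run_cascade(iqa, deblur7, clf, test_b, mode="common")
    res_guided = run_cascade(iqa, deblur8, clf, test_b, mode="mtl_if")
    rep_common, _ = evaluate_results(res_common)
    rep_guided, comparison = evaluate_results(res_guided, baseline=res_common)
    out["common_mtl_accuracy"] = rep_common.totals["micro_accuracy"]
    out["mtl_if_accuracy"] = rep_guided.totals["micro_accuracy"]
    out["common_mtl_auc"] = rep_common.totals["macro_auc"]
    out["mtl_if_auc"] = rep_guided.totals["macro_auc"]
    out["mcnemar_p_guided_vs_common"] = comparison["p_value"]
    out["routed_fraction"] = float(np.mean([r.routed for r in res_common]))

    # -- Grad-CAM localization on sharp test cases ---------------------
    overlap, n_correct = gradcam_mask_overlap(clf, test)
    out["gradcam_mask_overlap_fraction"] = overlap
    out["gradcam_n_correct_cases"] = float(n_correct)
    return out


def summarize_benchmarks(results: list[dict]) -> dict:
    """Mean of each numeric field over seeds."""
    keys = results[0].keys()
    return {k: float(np.mean([r[k] for r in results])) for k in keys}
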