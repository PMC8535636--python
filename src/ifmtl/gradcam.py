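"""Grad-CAM attention maps used as guidance channels for de-blurring.

For a target class score :math:`y^c` (the pre-softmax logit) and final-conv
activations :math:`A^k`, the channel weights are the spatial means
:math:`w_k = \\overline{\\partial y^c / \\partial A^k}` and the map is
:math:`\\mathrm{ReLU}(\\sum_k w_k A^k)`, bilinearly upsampled to the input
size and max-normalized to [0, 1]. An identically-zero map stays zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .case import IFCase, ValidationError
from .models.classifier import StackClassifier


@dataclass
class HeatMap:
    """Per-pixel class-attention map in [0, 1] at input resolution."""

    map: np.ndarray  # (H, W), float32 in [0, 1]
    target_class: int

    def validate(self) -> "HeatMap":
        m = self.map
        if m.ndim != 2 or not np.all(np.isfinite(m)):
            raise ValidationError("heat map must be a finite 2-D array")
        if m.min() < 0 or m.max() > 1:
            raise ValidationError("heat map values outside [0, 1]")
        return self


def _cam_from_arrays(A: np.ndarray, dA: np.ndarray) -> np.ndarray:
    """Raw CAMs (N, h, w) from activations and logit gradients (N, h, w, C)."""
    weights = dA.mean(axis=(1, 2))  # (N, C)
    cam = np.einsum("nc,nhwc->nhw", weights, A)
    return np.maximum(cam, 0.0)


def _normalize_upsample(cam: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    if cam.shape != out_hw:
        cam = resize(
            cam, out_hw, order=1, mode="edge", anti_aliasing=False, preserve_range=True
        )
        peak = cam.max()
        if peak > 0:
            cam = cam / peak  # keep max exactly 1 after interpolation
    return np.clip(cam, 0.0, 1.0).astype(np.float32)


def gradcam_map(
    model: StackClassifier,
    case: IFCase | np.ndarray,
    target_class: int | str = "argmax",
) -> HeatMap:
    """Class-discriminative localization map for one case."""
    channels = case.channels if isinstance(case, IFCase) else np.asarray(case)
    if channels.ndim != 3:
        raise ValidationError(f"expected a single (C, H, W) case, got {channels.shape}")
    A, dA, logits = model.gradcam_arrays(channels[None], target=target_class)
    tgt = int(logits.argmax(axis=1)[0]) if target_class == "argmax" else int(target_class)
    cam = _cam_from_arrays(A, dA)[0]
    out = _normalize_upsample(cam, channels.shape[1:])
    return HeatMap(map=out, target_class=tgt).validate()


def gradcam_batch(
    model: StackClassifier, X: np.ndarray, target: np.ndarray | str = "argmax"
) -> np.ndarray:
    """Maps for a batch (N, C, H, W) -> (N, H, W); each max-normalized."""
    X = np.asarray(X, dtype=np.float32)
    out = np.empty((X.shape[0], X.shape[2], X.shape[3]), dtype=np.float32)
    for start in range(0, X.shape[0], 128):
        chunk = X[start : start + 128]
        t = target if isinstance(target, str) else target[start : start + 128]
        A, dA, _ = model.gradcam_arrays(chunk, target=t)
        cams = _cam_from_arrays(A, dA)
        for i, cam in enumerate(cams):
            out[start + i] = _normalize_upsample(cam, X.shape[2:])
    return out


def concat_guidance(case: IFCase | np.ndarray, heat: HeatMap | np.ndarray) -> np.ndarray:
    """Append the heat map as channel 8; stain channels pass through untouched."""
    channels = case.channels if isinstance(case, IFCase) else np.asarray(case)
    hmap = heat.map if isinstance(heat, HeatMap) else np.asarray(heat)
    if channels.ndim != 3:
        raise ValidationError(f"expected (C, H, W) channels, got {channels.shape}")
    if hmap.shape != channels.shape[1:]:
        raise ValidationError(
            f"heat map shape {hmap.shape} does not match image {channels.shape[1:]}"
        )
    return np.concatenate(
        [channels, hmap[None].astype(channels.dtype)], axis=0
    )
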