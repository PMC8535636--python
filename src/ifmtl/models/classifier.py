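"""Multi-channel CNN disease classifier.

An AlexNet-style topology — five convolutional layers feeding three linear
layers, with global average pooling between the two stages — shrunk for
desk-scale inputs. All seven stain images of a case enter together as
input channels, so the network can weigh cross-stain positivity patterns
(e.g. the LN "full house") and not just morphology.

The final convolutional activations and the gradient of any class logit
with respect to them are exposed for Grad-CAM.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .. import nn
from ..case import ValidationError


class StackClassifier(ClassifierMixin, BaseEstimator):
    """CNN classifier over (N, in_channels, H, W) stacks.

    Parameters
    ----------
    conv_channels : tuple of 5 ints
        Widths of the five convolutional layers.
    conv_strides : tuple of 5 ints
        Strides; the default halves the resolution four times.
    hidden : tuple of 2 ints
        Widths of the first two linear layers (the third maps to classes).
    epochs, batch_size, learning_rate
        Adam training schedule. The full-scale defaults are 150 epochs,
        batch 64, lr 2e-4; pass smaller values for desk-scale runs.
    classes : tuple or None
        Expected label set; if given, ``fit`` raises when a class is absent
        from the training labels. ``None`` infers classes from ``y``.
    """

    def __init__(
        self,
        conv_channels: tuple[int, ...] = (16, 32, 48, 48, 32),
        conv_strides: tuple[int, ...] = (2, 2, 2, 1, 1),
        hidden: tuple[int, int] = (128, 64),
        in_channels: int = 7,
        epochs: int = 150,
        batch_size: int = 64,
        learning_rate: float = 2e-4,
        classes: tuple | None = None,
        seed: int = 0,
    ) -> None:
        self.conv_channels = conv_channels
        self.conv_strides = conv_strides
        self.hidden = hidden
        self.in_channels = in_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.classes = classes
        self.seed = seed

    # -- construction -------------------------------------------------

    def _build(self, image_hw: tuple[int, int], n_classes: int) -> None:
        rng = np.random.default_rng(self.seed)
        chans = [self.in_channels, *self.conv_channels]
        feats: list[nn.Module] = []
        h, w = image_hw
        for i, stride in enumerate(self.conv_strides):
            conv = nn.Conv2d(
                chans[i], chans[i + 1], 3, stride=stride, rng=rng, name=f"conv{i+1}"
            )
            feats += [conv, nn.ReLU()]
            h, w = conv.out_size(h), conv.out_size(w)
        self._features = nn.Sequential(*feats)
        # global average pooling ahead of the linear stack keeps the class
        # score a linear readout of spatially pooled final-conv features,
        # which makes the Grad-CAM maps sharply class-localized
        self._head = nn.Sequential(
            nn.GlobalAvgPool(),
            nn.Linear(chans[-1], self.hidden[0], rng=rng, name="fc1"),
            nn.ReLU(),
            nn.Linear(self.hidden[0], self.hidden[1], rng=rng, name="fc2"),
            nn.ReLU(),
            nn.Linear(self.hidden[1], n_classes, rng=rng, name="fc3"),
        )
        self._image_hw = image_hw
        self._n_classes = n_classes

    def _all_params(self) -> list[nn.Parameter]:
        return self._features.parameters() + self._head.parameters()

    # -- sklearn API ---------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StackClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[1] != self.in_channels:
            raise ValidationError(
                f"X must be (N, {self.in_channels}, H, W), got {X.shape}"
            )
        present = np.unique(y)
        if self.classes is not None:
            missing = sorted(set(self.classes) - set(present.tolist()))
            if missing:
                raise ValidationError(f"classes absent from training data: {missing}")
            self.classes_ = np.asarray(self.classes)
        else:
            if present.size < 2:
                raise ValidationError("training data must contain at least 2 classes")
            self.classes_ = present
        lut = {c: i for i, c in enumerate(self.classes_.tolist())}
        yi = np.array([lut[v] for v in y.tolist()], dtype=np.int64)

        self._build(X.shape[2:], len(self.classes_))
        Xn = nn.to_nhwc(X)
        self.loss_history_ = []
        self.accuracy_history_ = []
        rng = np.random.default_rng(self.seed + 1)
        if self.epochs > 0:
            opt = nn.Adam(self._all_params(), lr=self.learning_rate)
            n = Xn.shape[0]
            for _ in range(self.epochs):
                perm = rng.permutation(n)
                losses, correct = [], 0
                for start in range(0, n, self.batch_size):
                    idx = perm[start : start + self.batch_size]
                    logits = self._head.forward(self._features.forward(Xn[idx]))
                    loss, dlogits, probs = nn.softmax_cross_entropy(logits, yi[idx])
                    opt.zero_grad()
                    self._features.backward(self._head.backward(dlogits))
                    opt.step()
                    losses.append(loss * len(idx))
                    correct += int((probs.argmax(axis=1) == yi[idx]).sum())
                self.loss_history_.append(sum(losses) / n)
                self.accuracy_history_.append(correct / n)
        self.n_parameters_ = sum(p.size for p in self._all_params())
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Pre-softmax logits, (N, K)."""
        X = self._check_X(X)
        out = []
        for start in range(0, X.shape[0], 256):
            chunk = nn.to_nhwc(X[start : start + 256])
            out.append(self._head.forward(self._features.forward(chunk)))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "classes_"):
            raise ValidationError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.ndim != 4 or X.shape[1] != self.in_channels:
            raise ValidationError(
                f"X must be (N, {self.in_channels}, H, W), got {X.shape}"
            )
        return X

    # -- Grad-CAM plumbing --------------------------------------------

    def gradcam_arrays(
        self, X: np.ndarray, target: np.ndarray | str = "argmax"
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Final-conv activations A, dlogit/dA (both (N, h, w, C)), logits.

        ``target`` is either "argmax" (per-sample predicted class) or an
        integer array of class indices. Gradients are taken on the
        pre-softmax logit of the target class.
        """
        X = self._check_X(X)
        A = self._features.forward(nn.to_nhwc(X))
        logits = self._head.forward(A)
        n, k = logits.shape
        if isinstance(target, str):
            if target != "argmax":
                raise ValidationError(f"unknown target {target!r}")
            tgt = logits.argmax(axis=1)
        else:
            tgt = np.asarray(target, dtype=np.int64)
            if tgt.ndim == 0:
                tgt = np.full(n, int(tgt), dtype=np.int64)
            if np.any(tgt < 0) or np.any(tgt >= k):
                raise ValidationError(f"target class out of range [0, {k})")
        onehot = np.zeros_like(logits)
        onehot[np.arange(n), tgt] = 1.0
        dA = self._head.backward(onehot)
        # head param grads from this probe are irrelevant; discard them
        for p in self._head.parameters():
            p.grad[...] = 0.0
        return A, dA, logits

    def weight_checksum(self) -> float:
        """Order-sensitive checksum over all weights (freeze audits)."""
        return float(
            sum(np.float64(i + 1) * np.abs(p.value).sum() for i, p in enumerate(self._all_params()))
        )
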