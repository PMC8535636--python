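"""Image quality assessment subnet.

A small CNN regresses a 7-channel stack to a scalar quality score in
[0, 1]; ground truth is binary (0 = blurred, 1 = sharp). The score gates
the restoration stage: cases judged blurred are routed to de-blurring,
everything else passes straight to classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .. import nn
from ..case import ValidationError


@dataclass
class QualityScore:
    """Predicted quality with its routing decision."""

    value: float
    is_blurred: bool

    @staticmethod
    def from_value(value: float, threshold: float = 0.5) -> "QualityScore":
        v = float(np.clip(value, 0.0, 1.0))
        # ties at the threshold count as non-blurred
        return QualityScore(value=v, is_blurred=v < threshold)


def route(score: QualityScore) -> str:
    """Routing decision: ``"deblur"`` iff the case is judged blurred."""
    return "deblur" if score.is_blurred else "passthrough"


class IQARegressor(BaseEstimator):
    """Quality-score regressor: conv feature extractor + linear scorer.

    Three stride-2 conv/ReLU blocks, global average pooling, two linear
    layers and a sigmoid. Trained with MSE against the {0, 1} quality
    targets by default (``loss="bce"`` switches to binary cross-entropy).
    """

    def __init__(
        self,
        conv_channels: tuple[int, ...] = (16, 32, 64),
        hidden: int = 32,
        in_channels: int = 7,
        threshold: float = 0.5,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        loss: str = "mse",
        seed: int = 0,
    ) -> None:
        self.conv_channels = conv_channels
        self.hidden = hidden
        self.in_channels = in_channels
        self.threshold = threshold
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss = loss
        self.seed = seed

    def _build(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValidationError(f"threshold must be in (0,1), got {self.threshold}")
        if self.loss not in ("mse", "bce"):
            raise ValidationError(f"loss must be 'mse' or 'bce', got {self.loss!r}")
        rng = np.random.default_rng(self.seed)
        chans = [self.in_channels, *self.conv_channels]
        layers: list[nn.Module] = []
        for i in range(len(self.conv_channels)):
            layers += [
                nn.Conv2d(chans[i], chans[i + 1], 3, stride=2, rng=rng, name=f"iqa_conv{i+1}"),
                nn.ReLU(),
            ]
        layers += [
            nn.GlobalAvgPool(),
            nn.Linear(chans[-1], self.hidden, rng=rng, name="iqa_fc1"),
            nn.ReLU(),
            nn.Linear(self.hidden, 1, rng=rng, name="iqa_fc2"),
        ]
        self._net = nn.Sequential(*layers)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "IQARegressor":
        """Train on stacks ``X`` (N, C, H, W) with quality targets ``y`` in {0,1}."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32).ravel()
        if X.ndim != 4 or X.shape[1] != self.in_channels:
            raise ValidationError(f"X must be (N, {self.in_channels}, H, W), got {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X/y length mismatch")
        if np.unique(y).size < 2:
            raise ValidationError(
                "training set must contain both blurred and sharp cases"
            )
        self._build()
        self.loss_history_ = []
        rng = np.random.default_rng(self.seed + 1)
        if self.epochs > 0:
            opt = nn.Adam(self._net.parameters(), lr=self.learning_rate)
            n = X.shape[0]
            for _ in range(self.epochs):
                perm = rng.permutation(n)
                total = 0.0
                for start in range(0, n, self.batch_size):
                    idx = perm[start : start + self.batch_size]
                    z = self._net.forward(nn.to_nhwc(X[idx])).ravel()
                    p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
                    t = y[idx].astype(np.float64)
                    if self.loss == "mse":
                        loss = float(np.mean((p - t) ** 2))
                        dz = (2.0 / len(idx)) * (p - t) * p * (1.0 - p)
                    else:
                        eps = 1e-12
                        loss = float(-np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
                        dz = (p - t) / len(idx)
                    opt.zero_grad()
                    self._net.backward(dz.astype(np.float32)[:, None])
                    opt.step()
                    total += loss * len(idx)
                self.loss_history_.append(total / n)
        self.n_parameters_ = sum(p.size for p in self._net.parameters())
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Quality scores in [0, 1], one per case."""
        if not hasattr(self, "_net"):
            raise ValidationError("IQA model is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1] != self.in_channels:
            raise ValidationError(
                f"expected {self.in_channels} channels, got {X.shape[1]}"
            )
        out = []
        for start in range(0, X.shape[0], 256):
            z = self._net.forward(nn.to_nhwc(X[start : start + 256])).ravel()
            out.append(1.0 / (1.0 + np.exp(-z.astype(np.float64))))
        return np.clip(np.concatenate(out), 0.0, 1.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary quality grades (1 = sharp, 0 = blurred); threshold ties -> sharp."""
        scores = self.predict_scores(X)
        return (scores >= self.threshold).astype(np.int64)

    def score_case(self, case_channels: np.ndarray) -> QualityScore:
        value = float(self.predict_scores(case_channels)[0])
        return QualityScore.from_value(value, self.threshold)
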